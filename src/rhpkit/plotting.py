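"""Standard figures: composition KDE overlays, nFWHM scatter-lines,
segment-length bars, and hydropathy traces."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .heterogeneity import chain_compositions, kde_fwhm
from .hydropathy import window_profile
from .polymerize import Batch
from .segments import SegmentDistribution


def plot_composition_kde(b: Batch, path: str | Path) -> None:
    """Overlayed per-monomer composition KDE curves for one batch."""
    comps = chain_compositions(b)
    fig, ax = plt.subplots(figsize=(6, 4))
    for sym in b.system.symbols:
        x, dens, _ = kde_fwhm(comps[sym].to_numpy())
        ax.plot(x, dens, label=sym)
    ax.set_xlabel("per-chain mole fraction")
    ax.set_ylabel("density")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_nfwhm(records_by_x: dict[float, list], path: str | Path,
               xlabel: str = "NC") -> None:
    """nFWHM scatter-line vs a swept parameter (NC or DP)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    xs = sorted(records_by_x)
    symbols = [r.symbol for r in records_by_x[xs[0]]]
    for i, sym in enumerate(symbols):
        ax.plot(xs, [records_by_x[x][i].nfwhm for x in xs], "o-", label=sym)
    ax.set_xscale("log")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("nFWHM")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_segment_distribution(dist: SegmentDistribution, path: str | Path,
                              highlight: tuple[int, ...] = ()) -> None:
    """Bar chart of a run-length distribution; highlighted lengths in color."""
    lengths = sorted(dist.values)
    vals = [dist.values[l] for l in lengths]
    colors = ["C1" if l in highlight else "C0" for l in lengths]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(lengths, vals, color=colors)
    ax.set_xlabel("segment length")
    ax.set_ylabel("count" if dist.level == "batch" else "avg frequency / chain")
    ax.set_title(f"{dist.cls} segments ({dist.level} level)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_hydropathy(b: Batch, w: int, path: str | Path,
                    n_chains: int = 5, seed: int = 0) -> None:
    """Hydropathy traces for a few randomly sampled chains."""
    rng = np.random.default_rng(seed)
    eligible = [c for c in b.chains if len(c) >= w]
    picks = rng.choice(len(eligible), size=min(n_chains, len(eligible)),
                       replace=False)
    fig, ax = plt.subplots(figsize=(7, 4))
    for i in picks:
        prof = window_profile(eligible[int(i)], b.system, w)
        ax.plot(prof.center_positions(), prof.values, alpha=0.7)
    ax.axhline(b.system.hlb_threshold, ls="--", c="k", lw=0.8)
    ax.set_xlabel("position (alpha end = 0)")
    ax.set_ylabel(f"window-{w} mean HLB")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
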