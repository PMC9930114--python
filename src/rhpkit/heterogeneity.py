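"""Chemical heterogeneity: per-chain composition distributions and nFWHM.

For every chain the mole fraction of each monomer is computed; the spread of
those fractions across a batch measures how chemically alike the chains are.
A Gaussian kernel density estimate of each monomer's per-chain fraction is
summarized by the full width at half-maximum (FWHM) of its tallest peak,
then normalized by that monomer's feed fraction (nFWHM) so that minority and
majority monomers are comparable on one plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .polymerize import Batch

KDE_GRID_POINTS = 512


class HeterogeneityError(ValueError):
    pass


def chain_compositions(b: Batch) -> pd.DataFrame:
    """Per-chain monomer mole fractions, one row per chain, one column per symbol.

    Each row sums to 1; the batch feed fractions are attached as
    ``df.attrs['feed_fractions']`` for normalization downstream.
    """
    if not b.chains:
        raise HeterogeneityError("empty batch")
    n = b.system.n_monomers
    counts = np.stack(
        [np.bincount(c.sequence, minlength=n) for c in b.chains]
    ).astype(float)
    fractions = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(fractions, columns=b.system.symbols)
    df.attrs["feed_fractions"] = dict(
        zip(b.system.symbols, b.system.feed_fractions)
    )
    return df


def kde_fwhm(
    samples: np.ndarray,
    grid: tuple[float, float] = (0.0, 1.0),
    n_grid: int = KDE_GRID_POINTS,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian-KDE density of ``samples`` on a fixed grid plus its peak FWHM.

    Returns ``(x, density, fwhm)``.  The FWHM is the distance between the two
    half-maximum crossings bracketing the *global* maximum, each located by
    linear interpolation; for multimodal densities minor peaks are ignored.
    A crossing that runs off the grid edge is clipped to the edge.

    Scott's rule sets the bandwidth.  At least two distinct sample values are
    required (a point mass has no width).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2 or np.unique(samples).size < 2:
        raise HeterogeneityError(
            "FWHM needs at least two distinct sample values"
        )
    x = np.linspace(grid[0], grid[1], n_grid)
    density = gaussian_kde(samples)(x)

    peak = int(np.argmax(density))
    half = density[peak] / 2.0

    left = x[0]
    for i in range(peak, 0, -1):
        if density[i - 1] < half <= density[i]:
            # linear interpolation between grid points i-1 and i
            frac = (half - density[i - 1]) / (density[i] - density[i - 1])
            left = x[i - 1] + frac * (x[i] - x[i - 1])
            break
    right = x[-1]
    for i in range(peak, n_grid - 1):
        if density[i + 1] < half <= density[i]:
            frac = (density[i] - half) / (density[i] - density[i + 1])
            right = x[i] + frac * (x[i + 1] - x[i])
            break
    return x, density, float(right - left)


@dataclass(frozen=True)
class NfwhmRecord:
    """FWHM of one monomer's composition peak, feed-normalized."""

    symbol: str
    fwhm: float
    nfwhm: float


def nfwhm_profile(b: Batch) -> list[NfwhmRecord]:
    """Feed-normalized FWHM of the per-chain composition KDE, per monomer.

    ``nfwhm = fwhm / feed_fraction``; every monomer present must have a
    nonzero feed fraction.
    """
    comps = chain_compositions(b)
    records = []
    for sym, feed in zip(b.system.symbols, b.system.feed_fractions):
        if feed <= 0:
            raise HeterogeneityError(
                f"monomer {sym} has zero feed fraction; nFWHM undefined"
            )
        _, _, fwhm = kde_fwhm(comps[sym].to_numpy())
        records.append(NfwhmRecord(symbol=sym, fwhm=fwhm, nfwhm=fwhm / feed))
    return records


def nfwhm_table(b: Batch) -> pd.DataFrame:
    """nFWHM records as a DataFrame (columns: symbol, fwhm, nfwhm)."""
    recs = nfwhm_profile(b)
    return pd.DataFrame(
        {"symbol": [r.symbol for r in recs],
         "fwhm": [r.fwhm for r in recs],
         "nfwhm": [r.nfwhm for r in recs]}
    )
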