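"""Sliding-window hydropathy analysis of monomer sequences.

A window of odd size ``w`` slides one position at a time from the alpha to
the omega end; the mean HLB of each full span is assigned to its center
monomer.  Positions without a full window are undefined, so a chain of
length L yields L - w + 1 profile values.  Window averaging damps
single-monomer noise, which makes segment statistics robust to the exact
placement of the hydrophobic/hydrophilic cutoff; segments can be
re-identified on the smoothed profile with the same run-length machinery.

Batch position statistics are alpha-anchored (position 0 = first full-window
center on every chain): alpha ends are synchronized by living polymerization
while omega ends vary with polydispersity, so later positions have fewer
contributing chains and noisier statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemistry import MonomerSystem
from .polymerize import Batch, Chain
from .segments import run_lengths

WINDOW_SIZES = (5, 9, 15)  # small / medium / large neighbor contexts


class HydropathyError(ValueError):
    pass


@dataclass
class HydropathyProfile:
    """Window-averaged HLB values for one chain.

    ``values[t]`` is the mean HLB of positions ``t .. t + w - 1`` of the
    source chain, i.e. the value assigned to center position
    ``t + (w - 1) // 2``.
    """

    window: int
    values: np.ndarray

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def half_span(self) -> int:
        return (self.window - 1) // 2

    def center_positions(self) -> np.ndarray:
        """Chain positions (0-based) the profile values are assigned to."""
        return np.arange(self.values.size) + self.half_span


def window_profile(c: Chain, system: MonomerSystem, w: int) -> HydropathyProfile:
    """Sliding-window mean HLB along one chain (full windows only)."""
    if w < 1 or w % 2 == 0:
        raise HydropathyError(f"window size must be odd and >= 1, got {w}")
    if w > len(c):
        raise HydropathyError(
            f"chain of length {len(c)} shorter than window {w}"
        )
    hlb = system.hlb_values[c.sequence]
    values = np.convolve(hlb, np.full(w, 1.0 / w), mode="valid")
    return HydropathyProfile(window=w, values=values)


def windowed_segments(
    profile: HydropathyProfile, threshold: float
) -> dict[str, list[int]]:
    """Run lengths on the binarized profile (value < threshold => hydrophobic).

    Same segment definition as the raw-monomer analysis, with window-averaged
    HLB standing in for per-monomer HLB; ties classify hydrophilic.
    """
    if len(profile) == 0:
        raise HydropathyError("empty profile")
    phobic, philic = run_lengths(profile.values < threshold)
    return {"phobic": phobic, "philic": philic}


@dataclass
class BatchPositionStats:
    """Per-position moments of window-averaged HLB across a batch.

    Arrays are alpha-anchored and indexed by profile position; ``count[t]``
    is the number of chains long enough to define position ``t`` and is
    non-increasing.  ``pooled_mean``/``pooled_var`` aggregate every window
    average in the batch regardless of position.
    """

    window: int
    mean: np.ndarray
    var: np.ndarray
    count: np.ndarray
    pooled_mean: float
    pooled_var: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": np.arange(self.mean.size),
             "mean": self.mean, "var": self.var, "count": self.count}
        )


def batch_position_stats(b: Batch, w: int) -> BatchPositionStats:
    """Alpha-anchored per-position mean/variance of window HLB over a batch.

    Every chain of length >= w contributes to the positions it spans;
    chains shorter than the window are skipped (none long enough is an
    error).  Variances are population variances over the contributors.
    """
    profiles = [
        window_profile(c, b.system, w) for c in b.chains if len(c) >= w
    ]
    if not profiles:
        raise HydropathyError(f"no chain of length >= {w} in batch")
    max_len = max(len(p) for p in profiles)
    s = np.zeros(max_len)
    s2 = np.zeros(max_len)
    n = np.zeros(max_len, dtype=np.int64)
    total_s = 0.0
    total_s2 = 0.0
    total_n = 0
    for p in profiles:
        v = p.values
        m = v.size
        s[:m] += v
        s2[:m] += v * v
        n[:m] += 1
        total_s += float(v.sum())
        total_s2 += float((v * v).sum())
        total_n += m
    mean = s / n
    var = s2 / n - mean**2
    pooled_mean = total_s / total_n
    pooled_var = total_s2 / total_n - pooled_mean**2
    return BatchPositionStats(
        window=w,
        mean=mean,
        var=np.maximum(var, 0.0),
        count=n,
        pooled_mean=pooled_mean,
        pooled_var=max(pooled_var, 0.0),
    )
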