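"""Run-length segment statistics on binarized chains, and the embedded-marker motif search.

Chains are binarized at the HLB cutoff into hydrophobic/hydrophilic labels and
scanned for maximal runs.  Run-length distributions are reported at two
levels: *sequence level* (average run count per chain, for each length) and
*batch level* (total run count over all chains).  The motif search finds
hydrophobic segments carrying exactly one embedded hydrophilic marker monomer
(OEGMA by default) at least ``end_gap`` monomers away from both segment ends
— the pattern associated with protein-like proton-transport function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import HYDROPHILIC, HYDROPHOBIC, MonomerSystem
from .polymerize import Batch, Chain

# highlighted lengths used in the standard plots; full distributions are
# always computed, these only select what gets emphasized
HIGHLIGHT_LENGTHS_RUNS = (1, 3, 5, 10)
HIGHLIGHT_LENGTHS_MOTIF = (5, 8, 10, 13)


class SegmentError(ValueError):
    pass


@dataclass
class BinarizedChain:
    """Hydrophobic/hydrophilic labels per position, with the source indices kept."""

    labels: np.ndarray  # bool array: True = hydrophobic
    source: np.ndarray  # original monomer indices, same length

    def __len__(self) -> int:
        return int(self.labels.size)

    def label_strings(self) -> list[str]:
        return [HYDROPHOBIC if v else HYDROPHILIC for v in self.labels]


@dataclass
class SegmentDistribution:
    """Mapping run length -> value for one class at one reporting level.

    ``level`` is ``"sequence"`` (average run frequency per chain) or
    ``"batch"`` (summed count); ``cls`` is ``"phobic"``, ``"philic"`` or
    ``"motif"``.
    """

    level: str
    cls: str
    values: dict[int, float] = field(default_factory=dict)

    def get(self, length: int) -> float:
        return self.values.get(length, 0.0)

    def to_frame(self) -> pd.DataFrame:
        lengths = sorted(self.values)
        return pd.DataFrame(
            {"level": self.level, "class": self.cls,
             "length": lengths,
             "value": [self.values[l] for l in lengths]}
        )


def binarize_chain(c: Chain, system: MonomerSystem) -> BinarizedChain:
    """Label each position hydrophobic (HLB < threshold) or hydrophilic."""
    hlb = system.hlb_values
    phobic = hlb < system.hlb_threshold
    return BinarizedChain(labels=phobic[c.sequence], source=c.sequence)


def run_lengths(labels: np.ndarray) -> tuple[list[int], list[int]]:
    """Maximal-run lengths of a boolean array: (true_runs, false_runs), left to right."""
    labels = np.asarray(labels, dtype=bool)
    if labels.size == 0:
        return [], []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [labels.size]))
    lens = ends - starts
    true_runs = [int(l) for l, s in zip(lens, starts) if labels[s]]
    false_runs = [int(l) for l, s in zip(lens, starts) if not labels[s]]
    return true_runs, false_runs


def run_segments(bc: BinarizedChain) -> dict[str, list[int]]:
    """Per-class maximal run lengths of one binarized chain."""
    phobic, philic = run_lengths(bc.labels)
    return {HYDROPHOBIC: phobic, HYDROPHILIC: philic}


def _class_runs_per_chain(b: Batch, cls: str) -> list[list[int]]:
    if not b.chains:
        raise SegmentError("empty batch")
    if cls not in (HYDROPHOBIC, HYDROPHILIC):
        raise SegmentError(f"unknown segment class {cls!r}")
    out = []
    for c in b.chains:
        runs = run_segments(binarize_chain(c, b.system))
        out.append(runs[cls])
    return out


def sequence_level_distribution(b: Batch, cls: str = HYDROPHOBIC) -> SegmentDistribution:
    """Average frequency per chain of each run length (class ``cls``)."""
    per_chain = _class_runs_per_chain(b, cls)
    counts: dict[int, float] = {}
    for runs in per_chain:
        for l in runs:
            counts[l] = counts.get(l, 0.0) + 1.0
    nc = len(per_chain)
    return SegmentDistribution(
        level="sequence", cls=cls, values={l: v / nc for l, v in counts.items()}
    )


def batch_level_distribution(b: Batch, cls: str = HYDROPHOBIC) -> SegmentDistribution:
    """Total count over all chains of each run length (class ``cls``)."""
    per_chain = _class_runs_per_chain(b, cls)
    counts: dict[int, float] = {}
    for runs in per_chain:
        for l in runs:
            counts[l] = counts.get(l, 0.0) + 1.0
    return SegmentDistribution(level="batch", cls=cls, values=counts)


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence: chain index and 0-based half-open coordinates."""

    chain: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _chain_motif_matches(
    seq: np.ndarray,
    phobic_mask: np.ndarray,
    marker_idx: int,
    end_gap: int,
) -> list[tuple[int, int]]:
    """Maximal runs over {hydrophobic monomers} + {marker} containing exactly
    one marker with >= end_gap non-marker units between it and each run end."""
    allowed = phobic_mask[seq] | (seq == marker_idx)
    matches = []
    n = seq.size
    i = 0
    while i < n:
        if not allowed[i]:
            i += 1
            continue
        j = i
        while j < n and allowed[j]:
            j += 1
        marker_pos = np.flatnonzero(seq[i:j] == marker_idx)
        if marker_pos.size == 1:
            p = int(marker_pos[0])
            if p >= end_gap and (j - i - 1 - p) >= end_gap:
                matches.append((i, j))
        i = j
    return matches


def find_specific_segments(
    b: Batch,
    marker: str = "OEGMA",
    end_gap: int = 2,
) -> tuple[SegmentDistribution, list[MotifMatch]]:
    """Search every chain for hydrophobic segments with one embedded marker.

    A match is a maximal run over the alphabet {hydrophobic monomers, marker}
    that contains exactly one marker unit, with at least ``end_gap``
    non-marker monomers strictly between the marker and each end of the run.
    Runs with two or more markers never match.  Returns the sequence-level
    length distribution (class ``"motif"``) and the per-chain match
    coordinates (0-based half-open).
    """
    if not b.chains:
        raise SegmentError("empty batch")
    system = b.system
    marker_idx = system.index_of(marker)
    phobic_mask = system.hlb_values < system.hlb_threshold
    matches: list[MotifMatch] = []
    counts: dict[int, float] = {}
    for ci, c in enumerate(b.chains):
        for s, e in _chain_motif_matches(c.sequence, phobic_mask, marker_idx, end_gap):
            matches.append(MotifMatch(chain=ci, start=s, end=e))
            counts[e - s] = counts.get(e - s, 0.0) + 1.0
    nc = len(b.chains)
    dist = SegmentDistribution(
        level="sequence", cls="motif",
        values={l: v / nc for l, v in counts.items()},
    )
    return dist, matches


def motif_length_kde(matches: list[MotifMatch]):
    """Batch-level kernel density over motif match lengths.

    Returns ``(x, density)`` on a grid spanning the observed lengths; needs
    at least two distinct lengths.
    """
    from .heterogeneity import kde_fwhm

    lengths = np.array([m.length for m in matches], dtype=float)
    if lengths.size < 2 or np.unique(lengths).size < 2:
        raise SegmentError("KDE needs at least two distinct motif lengths")
    lo, hi = lengths.min() - 2, lengths.max() + 2
    x, dens, _ = kde_fwhm(lengths, grid=(lo, hi))
    return x, dens


def matches_to_bed(matches: list[MotifMatch]) -> pd.DataFrame:
    """Motif matches as a BED-like table (chain, start, end, length)."""
    return pd.DataFrame(
        {"chain": [m.chain for m in matches],
         "start": [m.start for m in matches],
         "end": [m.end for m in matches],
         "length": [m.length for m in matches]}
    )
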