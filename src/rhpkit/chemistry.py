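"""Monomer chemistry: HLB group-contribution hydrophobicity and the monomer system.

The hydrophile-lipophile balance (HLB) of a monomer side chain is computed by
group contribution, ``HLB = 7 + sum_i n_i * HLB_i``, where ``n_i`` counts the
i-th functional group and ``HLB_i`` is its tabulated group value.  Lower HLB
means more hydrophobic.  A single cutoff (default 9) binarizes monomers into
hydrophobic and hydrophilic classes; this classification drives every
downstream segment statistic.

The five methacrylate/styrenic monomers used throughout the package ship as a
built-in registry with their literature HLB totals; group-value tables for new
monomers are user-supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

HLB_BASE = 7.0
DEFAULT_HLB_THRESHOLD = 9.0

HYDROPHOBIC = "phobic"
HYDROPHILIC = "philic"


class ChemistryError(ValueError):
    """Invalid monomer, group list, or monomer-system definition."""


@dataclass(frozen=True)
class Monomer:
    """A polymerizable monomer identified by a short symbol.

    Parameters
    ----------
    symbol : str
        Short unique label, e.g. ``"MMA"``.
    hlb : float
        Hydrophile-lipophile balance of the side chain (dimensionless).
    molecular_weight : float, optional
        Molar mass in g/mol; required only by the recipe solver.
    density : float, optional
        Density in g/mL; required only for recipe volumes.
    """

    symbol: str
    hlb: float
    molecular_weight: float | None = None
    density: float | None = None

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ChemistryError("monomer symbol must be nonempty")
        if not math.isfinite(self.hlb):
            raise ChemistryError(f"monomer {self.symbol}: HLB must be finite")
        if self.molecular_weight is not None and self.molecular_weight <= 0:
            raise ChemistryError(
                f"monomer {self.symbol}: molecular_weight must be > 0"
            )


# Literature HLB totals for the default monomer set.  MW/density are the
# commercial reagent values used by the recipe solver.
DEFAULT_MONOMERS: dict[str, Monomer] = {
    "MMA": Monomer("MMA", 8.45, molecular_weight=100.12, density=0.94),
    "EHMA": Monomer("EHMA", 5.12, molecular_weight=198.30, density=0.885),
    "OEGMA": Monomer("OEGMA", 11.4, molecular_weight=500.0, density=1.08),
    "SPMA": Monomer("SPMA", 18.5, molecular_weight=246.32, density=1.0),
    "STY": Monomer("STY", 4.865, molecular_weight=104.15, density=0.906),
}


def hlb_of_side_chain(groups: Iterable[tuple[float, float]]) -> float:
    """Group-contribution HLB of a side chain.

    ``groups`` is a list of ``(count, group_value)`` pairs; returns
    ``7 + sum(count * group_value)``.  An empty list yields the base
    constant 7.0.
    """
    total = HLB_BASE
    for count, value in groups:
        if count < 0:
            raise ChemistryError(f"negative group count {count}")
        if not (math.isfinite(count) and math.isfinite(value)):
            raise ChemistryError("group counts and values must be finite")
        total += count * value
    return total


def classify_monomer(m: Monomer, threshold: float = DEFAULT_HLB_THRESHOLD) -> str:
    """Binarize a monomer at an HLB cutoff.

    Hydrophobic iff ``hlb < threshold``; a tie (``hlb == threshold``)
    classifies hydrophilic so that the boundary rule is a single strict
    inequality.
    """
    if not math.isfinite(threshold):
        # +/- inf thresholds are permitted as degenerate all-one-class cutoffs
        if math.isnan(threshold):
            raise ChemistryError("threshold must not be NaN")
    return HYDROPHOBIC if m.hlb < threshold else HYDROPHILIC


@dataclass
class MonomerSystem:
    """The chemistry universe of a simulation run.

    Holds the ordered monomer list, feed mole fractions ``f_i``, the
    reactivity-ratio matrix ``r_ij = k_ii / k_ij`` of the Mayo-Lewis terminal
    model, and the HLB binarization cutoff.  ``r_ij = 1`` everywhere gives
    ideal (Bernoulli) copolymerization.
    """

    monomers: list[Monomer]
    feed_fractions: np.ndarray
    reactivity_ratios: np.ndarray | None = None
    hlb_threshold: float = DEFAULT_HLB_THRESHOLD
    _symbol_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.feed_fractions = np.asarray(self.feed_fractions, dtype=float)
        if self.reactivity_ratios is None:
            self.reactivity_ratios = np.ones((len(self.monomers),) * 2)
        self.reactivity_ratios = np.asarray(self.reactivity_ratios, dtype=float)
        self._symbol_index = {m.symbol: i for i, m in enumerate(self.monomers)}
        validate_system(self)

    @property
    def n_monomers(self) -> int:
        return len(self.monomers)

    @property
    def symbols(self) -> list[str]:
        return [m.symbol for m in self.monomers]

    @property
    def hlb_values(self) -> np.ndarray:
        return np.array([m.hlb for m in self.monomers])

    def index_of(self, symbol: str) -> int:
        try:
            return self._symbol_index[symbol]
        except KeyError:
            raise ChemistryError(f"unknown monomer symbol {symbol!r}") from None

    def classes(self) -> list[str]:
        """Hydrophobic/hydrophilic class per monomer, in system order."""
        return [classify_monomer(m, self.hlb_threshold) for m in self.monomers]


def validate_system(s: MonomerSystem) -> MonomerSystem:
    """Check all MonomerSystem invariants; return the system unchanged.

    Raises :class:`ChemistryError` on: duplicate symbols, feed fractions not
    summing to 1 (within 1e-9) or negative, a non-square reactivity matrix, a
    non-positive ratio, or a diagonal element differing from 1.
    """
    n = len(s.monomers)
    if n == 0:
        raise ChemistryError("system must contain at least one monomer")
    if len({m.symbol for m in s.monomers}) != n:
        raise ChemistryError("monomer symbols must be unique")
    f = s.feed_fractions
    if f.shape != (n,):
        raise ChemistryError(f"expected {n} feed fractions, got shape {f.shape}")
    if np.any(f < 0):
        raise ChemistryError("feed fractions must be non-negative")
    if abs(float(f.sum()) - 1.0) > 1e-9:
        raise ChemistryError(
            f"feed fractions must sum to 1 (got {float(f.sum()):.12g})"
        )
    r = s.reactivity_ratios
    if r.shape != (n, n):
        raise ChemistryError(
            f"reactivity-ratio matrix must be {n}x{n}, got {r.shape}"
        )
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise ChemistryError("all reactivity ratios must be finite and > 0")
    if not np.allclose(np.diag(r), 1.0, atol=1e-12):
        raise ChemistryError("reactivity-ratio diagonal must equal 1 (r_ii = k_ii/k_ii)")
    return s


def default_system(
    symbols: Sequence[str] = ("MMA", "OEGMA", "EHMA", "SPMA"),
    feed_fractions: Sequence[float] = (0.50, 0.25, 0.20, 0.05),
    reactivity_ratios: np.ndarray | None = None,
    hlb_threshold: float = DEFAULT_HLB_THRESHOLD,
) -> MonomerSystem:
    """The 4-monomer methacrylate reference system (MMA/OEGMA/EHMA/SPMA, 50:25:20:5).

    Symbols must come from the built-in registry; reactivity ratios default to
    all-ones (ideal copolymerization).
    """
    monomers = [DEFAULT_MONOMERS[s] for s in symbols]
    return MonomerSystem(
        monomers=monomers,
        feed_fractions=np.asarray(feed_fractions, dtype=float),
        reactivity_ratios=reactivity_ratios,
        hlb_threshold=hlb_threshold,
    )
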