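"""Translate protein sequences into monomer space for RHP comparison.

A residue map collapses the 20-letter amino-acid alphabet onto the 2-5
monomer alphabet of the active system, grouping residues by
hydrophobicity/hydrophilicity/charge.  The translated chain is then split
into overlapping fixed-length segments (default length 100, start offset 10)
and packaged as a Batch, so the entire analysis stack — heterogeneity,
segment statistics, hydropathy, motif search — runs unchanged on proteins.

The default grouping is a conventional hydrophobicity/charge classing and is
configurable; it is a package default, not a measured mapping:

    V L I M F W      -> EHMA   (strongly hydrophobic)
    A G P C          -> MMA    (mildly hydrophobic)
    S T N Q Y H      -> OEGMA  (polar, uncharged)
    D E K R          -> SPMA   (charged)

When the active system includes styrene (STY), the aromatic residues
F, W, Y map to STY instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .chemistry import MonomerSystem
from .polymerize import Batch, Chain, SimulationConfig

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

_BASE_GROUPS = {
    "EHMA": "VLIMFW",
    "MMA": "AGPC",
    "OEGMA": "STNQYH",
    "SPMA": "DEKR",
}
_AROMATIC = "FWY"


class ProteinBridgeError(ValueError):
    pass


@dataclass
class ResidueMap:
    """Mapping from one-letter amino-acid codes to monomer symbols."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        missing = [aa for aa in STANDARD_RESIDUES if aa not in self.mapping]
        if missing:
            raise ProteinBridgeError(
                f"residue map must cover all 20 standard residues; missing {missing}"
            )

    @classmethod
    def default(cls, system: MonomerSystem) -> "ResidueMap":
        """Hydrophobicity/charge-based default map for the active system."""
        mapping = {}
        for sym, residues in _BASE_GROUPS.items():
            if sym not in system.symbols:
                raise ProteinBridgeError(
                    f"default residue map needs monomer {sym} in the system"
                )
            for aa in residues:
                mapping[aa] = sym
        if "STY" in system.symbols:
            for aa in _AROMATIC:
                mapping[aa] = "STY"
        return cls(mapping)


@dataclass
class SegmentationParams:
    """Overlapping-segment parameters: fixed length and start offset."""

    segment_length: int = 100
    offset: int = 10

    def __post_init__(self) -> None:
        if self.segment_length < 1:
            raise ProteinBridgeError("segment_length must be >= 1")
        if not (1 <= self.offset <= self.segment_length):
            raise ProteinBridgeError("offset must be in [1, segment_length]")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercase residue string) pairs, in file order."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not rec.id or not seq:
            raise ProteinBridgeError(f"malformed or empty FASTA record in {path}")
        records.append((rec.id, seq))
    if not records:
        raise ProteinBridgeError(f"no FASTA records found in {path}")
    return records


def translate_protein(residues: str, rmap: ResidueMap, system: MonomerSystem) -> Chain:
    """Length-preserving substitution of residues by monomer indices.

    Non-standard characters (X, B, Z, ``*``, gaps) raise with the offending
    position rather than being skipped.
    """
    indices = np.empty(len(residues), dtype=np.int64)
    for pos, aa in enumerate(residues.upper()):
        sym = rmap.mapping.get(aa)
        if sym is None:
            raise ProteinBridgeError(
                f"unmapped residue {aa!r} at position {pos}"
            )
        indices[pos] = system.index_of(sym)
    if indices.size == 0:
        raise ProteinBridgeError("empty residue string")
    return Chain(indices)


def segment_protein(
    c: Chain,
    system: MonomerSystem,
    params: SegmentationParams | None = None,
) -> Batch:
    """Split a translated chain into overlapping fixed-length segments.

    Segments start at 0, offset, 2*offset, ...; each has exactly
    ``segment_length`` monomers, giving
    ``floor((L - segment_length)/offset) + 1`` segments.  Trailing residues
    that cannot fill a final full segment are dropped, keeping every segment
    DP-matched to the simulated chains it is compared with.  The result is a
    Batch flagged protein-derived (no polymerization pool).
    """
    params = params or SegmentationParams()
    L = len(c)
    if L < params.segment_length:
        raise ProteinBridgeError(
            f"chain of length {L} shorter than segment_length {params.segment_length}"
        )
    n_seg = (L - params.segment_length) // params.offset + 1
    chains = [
        Chain(c.sequence[i * params.offset: i * params.offset + params.segment_length])
        for i in range(n_seg)
    ]
    consumed = np.zeros(system.n_monomers, dtype=np.int64)
    for ch in chains:
        consumed += np.bincount(ch.sequence, minlength=system.n_monomers)
    config = SimulationConfig(
        system=system,
        nc=n_seg,
        dp_target=params.segment_length,
        conversion_target=1.0,
        pdi_target=1.0,
        seed=0,
    )
    return Batch(
        chains=chains,
        config=config,
        initial_pool=consumed.copy(),
        consumed=consumed,
        meta={"protein_derived": True,
              "segment_length": params.segment_length,
              "offset": params.offset},
    )


def protein_to_batch(
    residues: str,
    system: MonomerSystem,
    rmap: ResidueMap | None = None,
    params: SegmentationParams | None = None,
) -> Batch:
    """Convenience pipeline: translate then segment one protein sequence."""
    rmap = rmap or ResidueMap.default(system)
    return segment_protein(translate_protein(residues, rmap, system), system, params)
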