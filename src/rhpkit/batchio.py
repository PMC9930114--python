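"""Plain-text batch files and seeded test fixtures.

Sequence-file grammar: ``#``-prefixed header lines of ``key=value`` pairs
(config, seed, pool accounting), then one chain per line with monomer
symbols separated by single spaces.  UTF-8, no wrapping — human-diffable and
greppable.  Coordinates in all exports are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .chemistry import DEFAULT_MONOMERS, Monomer, MonomerSystem
from .polymerize import Batch, Chain, SimulationConfig


class BatchFormatError(ValueError):
    pass


def write_batch(b: Batch, path: str | Path) -> None:
    """Write a batch to the plain-text sequence format (lossless round trip)."""
    cfg = b.config
    lines = [
        "# rhpkit batch v1",
        f"# monomers={','.join(b.system.symbols)}",
        f"# feed_fractions={','.join(f'{x:.12g}' for x in b.system.feed_fractions)}",
        f"# hlb_threshold={cfg.system.hlb_threshold:.12g}",
        f"# nc={cfg.nc}",
        f"# dp_target={cfg.dp_target:.12g}",
        f"# conversion_target={cfg.conversion_target:.12g}",
        f"# pdi_target={cfg.pdi_target:.12g}",
        f"# seed={cfg.seed}",
        f"# initial_pool={','.join(str(int(x)) for x in b.initial_pool)}",
        f"# protein_derived={b.meta.get('protein_derived', False)}",
    ]
    syms = b.system.symbols
    for c in b.chains:
        lines.append(" ".join(syms[i] for i in c.sequence))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_batch(path: str | Path, system: MonomerSystem) -> Batch:
    """Read a sequence file back into a Batch against the given system.

    Unknown monomer symbols raise with the symbol and line number.  A
    header-only file yields an empty batch with the header config preserved.
    """
    header: dict[str, str] = {}
    chains: list[Chain] = []
    consumed = np.zeros(system.n_monomers, dtype=np.int64)
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    header[key.strip()] = value.strip()
                continue
            indices = []
            for sym in line.split(" "):
                try:
                    indices.append(system.index_of(sym))
                except Exception:
                    raise BatchFormatError(
                        f"{path}: unknown monomer symbol {sym!r} on line {lineno}"
                    ) from None
            chains.append(Chain(np.asarray(indices, dtype=np.int64)))
            consumed += np.bincount(chains[-1].sequence, minlength=system.n_monomers)
    config = SimulationConfig(
        system=system,
        nc=max(1, int(header.get("nc", len(chains) or 1))),
        dp_target=float(header.get("dp_target", 100.0)),
        conversion_target=float(header.get("conversion_target", 0.5)),
        pdi_target=float(header.get("pdi_target", 1.0)),
        seed=int(header.get("seed", 0)),
    )
    if "initial_pool" in header:
        initial_pool = np.array(
            [int(x) for x in header["initial_pool"].split(",")], dtype=np.int64
        )
        if initial_pool.size != system.n_monomers:
            raise BatchFormatError(
                f"{path}: initial_pool has {initial_pool.size} entries for "
                f"{system.n_monomers} monomers"
            )
    else:
        initial_pool = consumed.copy()
    meta = {"header": header}
    if header.get("protein_derived", "False") == "True":
        meta["protein_derived"] = True
    return Batch(chains=chains, config=config, initial_pool=initial_pool,
                 consumed=consumed, meta=meta)


def write_summary_json(summary, path: str | Path) -> None:
    """Companion JSON for a batch summary record."""
    Path(path).write_text(json.dumps({
        "dp_n": summary.dp_n, "dp_w": summary.dp_w, "pdi": summary.pdi,
        "conversion": summary.conversion,
        "incorporated_fractions": summary.incorporated_fractions,
    }, indent=2), encoding="utf-8")


def load_system_config(path: str | Path) -> MonomerSystem:
    """Build a MonomerSystem from a YAML config file.

    Schema::

        monomers:            # either registry symbols or full definitions
          - MMA
          - {symbol: XYZ, hlb: 6.2, molecular_weight: 150.0, density: 1.0}
        feed_fractions: [0.5, 0.5]
        reactivity_ratios:   # optional, defaults to all ones
          - [1.0, 2.0]
          - [0.5, 1.0]
        hlb_threshold: 9.0   # optional
    """
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    monomers = []
    for entry in data["monomers"]:
        if isinstance(entry, str):
            monomers.append(DEFAULT_MONOMERS[entry])
        else:
            monomers.append(Monomer(
                symbol=entry["symbol"], hlb=float(entry["hlb"]),
                molecular_weight=entry.get("molecular_weight"),
                density=entry.get("density"),
            ))
    ratios = data.get("reactivity_ratios")
    return MonomerSystem(
        monomers=monomers,
        feed_fractions=np.asarray(data["feed_fractions"], dtype=float),
        reactivity_ratios=np.asarray(ratios, dtype=float) if ratios else None,
        hlb_threshold=float(data.get("hlb_threshold", 9.0)),
    )


def generate_fixture(
    kind: str,
    system: MonomerSystem,
    seed: int = 0,
    *,
    probabilities=None,
    length: int = 100,
    nc: int = 100,
    lengths=None,
    sequences=None,
) -> Batch:
    """Seeded synthetic batches with analytically known statistics.

    kind="bernoulli"
        i.i.d. monomer draws at the given probabilities (default: system feed
        fractions), ``nc`` chains of ``length`` units; run lengths follow the
        geometric law exactly.
    kind="fixed_lengths"
        Bernoulli chains with a specified length multiset, for dispersity
        arithmetic.
    kind="handcrafted"
        Literal sequences given as lists of monomer symbols.
    """
    rng = np.random.default_rng(seed)
    if kind == "bernoulli" or kind == "fixed_lengths":
        p = np.asarray(
            probabilities if probabilities is not None else system.feed_fractions,
            dtype=float,
        )
        if abs(p.sum() - 1.0) > 1e-9:
            raise BatchFormatError("probabilities must sum to 1")
        if kind == "bernoulli":
            lengths = [length] * nc
        elif lengths is None:
            raise BatchFormatError("fixed_lengths requires a lengths list")
        chains = [
            Chain(rng.choice(system.n_monomers, size=int(L), p=p))
            for L in lengths
        ]
    elif kind == "handcrafted":
        if not sequences:
            raise BatchFormatError("handcrafted requires sequences")
        chains = [
            Chain(np.array([system.index_of(s) for s in seq], dtype=np.int64))
            for seq in sequences
        ]
    else:
        raise BatchFormatError(f"unknown fixture kind {kind!r}")

    consumed = np.zeros(system.n_monomers, dtype=np.int64)
    for c in chains:
        consumed += np.bincount(c.sequence, minlength=system.n_monomers)
    config = SimulationConfig(
        system=system, nc=len(chains),
        dp_target=float(np.mean([len(c) for c in chains])),
        conversion_target=1.0, pdi_target=1.0, seed=seed,
    )
    return Batch(chains=chains, config=config, initial_pool=consumed.copy(),
                 consumed=consumed, meta={"fixture": kind})
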