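"""Reverse design: turn batch targets into bench reagent masses and volumes.

Standard RDRP stoichiometry: the chain-transfer agent (CTA) sets the chain
count, so the number-average DP achieved at conversion ``c`` is
``DP_n = c * [M]0 / [CTA]0``.  Given a total monomer mass scale, feed mole
fractions, per-monomer molar masses and densities, a target DP and
conversion, and a CTA:initiator mole ratio, the solver outputs moles, masses
and volumes for every reagent plus the implied chain count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .chemistry import MonomerSystem

AVOGADRO = 6.02214076e23


class RecipeError(ValueError):
    pass


@dataclass
class RecipeSpec:
    """Bench-scale targets and reagent constants for one synthesis."""

    mass_scale: float                 # g of total monomer
    dp_target: float                  # target number-average DP
    conversion: float = 0.5           # fraction of monomer converted
    cta_mw: float = 280.4             # g/mol, chain-transfer agent
    initiator_mw: float = 164.2       # g/mol
    cta_initiator_ratio: float = 5.0  # CTA : initiator mole ratio
    solvent: str = "dioxane"
    monomer_molarity: float | None = None  # mol monomer / L solvent, optional

    def __post_init__(self) -> None:
        if self.mass_scale <= 0 or self.dp_target < 1:
            raise RecipeError("mass_scale must be > 0 and dp_target >= 1")
        if not (0.0 < self.conversion <= 1.0):
            raise RecipeError("conversion must be in (0, 1]")
        if min(self.cta_mw, self.initiator_mw, self.cta_initiator_ratio) <= 0:
            raise RecipeError("CTA/initiator parameters must be positive")


@dataclass
class Recipe:
    """Solved reagent amounts (moles in mol, masses in g, volumes in mL)."""

    monomer_moles: dict[str, float]
    monomer_masses: dict[str, float]
    monomer_volumes: dict[str, float | None]
    cta_moles: float
    cta_mass: float
    initiator_moles: float
    initiator_mass: float
    chain_count: float
    solvent: str
    solvent_volume_mL: float | None
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"monomer_moles": self.monomer_moles,
             "monomer_masses_g": self.monomer_masses,
             "monomer_volumes_mL": self.monomer_volumes,
             "cta_moles": self.cta_moles, "cta_mass_g": self.cta_mass,
             "initiator_moles": self.initiator_moles,
             "initiator_mass_g": self.initiator_mass,
             "estimated_chain_count": self.chain_count,
             "solvent": self.solvent,
             "solvent_volume_mL": self.solvent_volume_mL,
             **self.meta},
            indent=2,
        )

    def to_table(self) -> str:
        lines = [f"{'reagent':<12}{'mol':>14}{'mass (g)':>12}{'vol (mL)':>12}"]
        for sym in self.monomer_moles:
            vol = self.monomer_volumes[sym]
            lines.append(
                f"{sym:<12}{self.monomer_moles[sym]:>14.6g}"
                f"{self.monomer_masses[sym]:>12.4g}"
                + (f"{vol:>12.4g}" if vol is not None else f"{'-':>12}")
            )
        lines.append(f"{'CTA':<12}{self.cta_moles:>14.6g}{self.cta_mass:>12.4g}{'-':>12}")
        lines.append(
            f"{'initiator':<12}{self.initiator_moles:>14.6g}"
            f"{self.initiator_mass:>12.4g}{'-':>12}"
        )
        if self.solvent_volume_mL is not None:
            lines.append(f"{self.solvent:<12}{'-':>14}{'-':>12}{self.solvent_volume_mL:>12.4g}")
        lines.append(f"estimated chains: {self.chain_count:.3g}")
        return "\n".join(lines)


def solve_recipe(spec: RecipeSpec, system: MonomerSystem) -> Recipe:
    """Solve the reagent amounts realizing the target feed, DP and conversion.

    ``n_total = mass_scale / sum_i f_i MW_i`` (moles of monomer);
    ``n_i = f_i n_total``; ``n_CTA = n_total * conversion / dp_target`` so the
    mean DP at the stated conversion hits the target; initiator from the
    CTA:initiator ratio; chain count = ``n_CTA * N_A``.
    """
    mws = []
    for m in system.monomers:
        if m.molecular_weight is None:
            raise RecipeError(f"monomer {m.symbol} lacks a molecular weight")
        mws.append(m.molecular_weight)
    f = system.feed_fractions
    mean_mw = float(sum(fi * mw for fi, mw in zip(f, mws)))
    n_total = spec.mass_scale / mean_mw

    moles, masses, volumes = {}, {}, {}
    for m, fi, mw in zip(system.monomers, f, mws):
        n_i = float(fi) * n_total
        moles[m.symbol] = n_i
        masses[m.symbol] = n_i * mw
        if m.density is not None:
            volumes[m.symbol] = n_i * mw / m.density
        elif n_i > 0:
            raise RecipeError(f"monomer {m.symbol}: volume requested but density unknown")
        else:
            volumes[m.symbol] = None

    n_cta = n_total * spec.conversion / spec.dp_target
    n_ini = n_cta / spec.cta_initiator_ratio
    solvent_volume = (
        n_total / spec.monomer_molarity * 1000.0
        if spec.monomer_molarity else None
    )
    return Recipe(
        monomer_moles=moles,
        monomer_masses=masses,
        monomer_volumes=volumes,
        cta_moles=n_cta,
        cta_mass=n_cta * spec.cta_mw,
        initiator_moles=n_ini,
        initiator_mass=n_ini * spec.initiator_mw,
        chain_count=n_cta * AVOGADRO,
        solvent=spec.solvent,
        solvent_volume_mL=solvent_volume,
        meta={"total_monomer_moles": n_total, "mean_monomer_mw": mean_mw},
    )
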