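"""Reverse design: from batch targets to a bench-scale reagent table.

Given the feed composition, a total monomer mass, target DP and conversion,
the solver applies RDRP stoichiometry (DP_n = conversion * [M]0 / [CTA]0) to
output moles, masses and volumes of every monomer plus the chain-transfer
agent and initiator, and the implied number of chains.
"""

from rhpkit import RecipeSpec, default_system, solve_recipe

system = default_system()
spec = RecipeSpec(mass_scale=1.0, dp_target=100.0, conversion=0.5,
                  monomer_molarity=2.0)
recipe = solve_recipe(spec, system)
print(recipe.to_table())
print("\nThe CTA count fixes the chain population: at 50% conversion and a")
print("DP-100 target, 1 g of this monomer mix yields ~1e19 chains.")
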