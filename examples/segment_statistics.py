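"""Hydrophobic/hydrophilic segment statistics and the embedded-OEGMA motif.

Chains are binarized at HLB cutoff 9 (MMA, EHMA hydrophobic; OEGMA, SPMA
hydrophilic) and scanned for maximal runs.  The motif search then looks for
hydrophobic segments containing exactly one embedded OEGMA at least 2
monomers from both segment ends — the pattern linked to proton-transport
function in protein-mimetic heteropolymers.
"""

from rhpkit import (SimulationConfig, default_system, find_specific_segments,
                    sequence_level_distribution, simulate_batch)

batch = simulate_batch(SimulationConfig(system=default_system(), nc=2000,
                                        dp_target=100.0, pdi_target=1.2,
                                        seed=11))

dist = sequence_level_distribution(batch, "phobic")
print("hydrophobic runs, average frequency per chain:")
for length in (1, 3, 5, 10):
    print(f"  length {length:>2}: {dist.get(length):.3f}")

motif_dist, matches = find_specific_segments(batch, marker="OEGMA", end_gap=2)
print(f"\nembedded-OEGMA motif matches: {len(matches)} "
      f"({len(matches) / batch.nc:.2f} per chain)")
print("motif length frequencies (per chain):")
for length in (5, 8, 10, 13):
    print(f"  length {length:>2}: {motif_dist.get(length):.4f}")
print("\nShort runs dominate (geometric-like law at 70% hydrophobic feed);")
print("motif counts measure how often a lone OEGMA sits buried inside a")
print("hydrophobic segment rather than at its edge.")
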