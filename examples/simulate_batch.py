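"""Simulate a batch of random-heteropolymer sequences and summarize it.

Grows 2000 chains of the 4-monomer methacrylate system (MMA/OEGMA/EHMA/SPMA,
feed 50:25:20:5) under the Mayo-Lewis terminal model with ideal reactivity
ratios, stops at 50% pool conversion, then removes oligomers (DP < 15) as a
purification step would.
"""

from rhpkit import (SimulationConfig, batch_summary, default_system,
                    filter_oligomers, simulate_batch)

system = default_system()
config = SimulationConfig(system=system, nc=2000, dp_target=100.0,
                          conversion_target=0.5, pdi_target=1.2, seed=42)
batch = simulate_batch(config)
filtered = filter_oligomers(batch, min_dp=15)
s = batch_summary(filtered)

print(f"chains kept           : {filtered.nc} of {batch.nc} "
      f"({filtered.meta['oligomers_removed']} oligomers removed)")
print(f"number-average DP     : {s.dp_n:.2f}   (target 100)")
print(f"weight-average DP     : {s.dp_w:.2f}")
print(f"polydispersity index  : {s.pdi:.4f} (target <= 1.2)")
print(f"realized conversion   : {s.conversion:.4f} (target 0.50)")
print("incorporated fractions:",
      {k: round(v, 4) for k, v in s.incorporated_fractions.items()})
print("\nWith all reactivity ratios = 1 the incorporated fractions track the")
print("feed (50:25:20:5) and the chain-length spread matches the PDI target.")
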