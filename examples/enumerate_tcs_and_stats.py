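"""Enumerate T/Cs from a factorial design and compute ratio statistics.

Builds the classic 2-genotype x 4-cold-duration synthetic experiment
(8 replicate sample sets), enumerates every treatment-over-control pair
allowed by the single-differing-factor rule, and prints the recovered
LOG2R for a feature spiked by 2 log2 units under 24 h cold.
"""

from microtc.synth import Spike, generate_experiment, ice1_like_spec
from microtc.tc import compute_tc_stats, enumerate_tcs

spec = ice1_like_spec(seed=42, n_features=100,
                      spikes=(Spike("g00000", {"cold": "24 hr"}, 2.0),))
exp = generate_experiment(spec)
tcs = enumerate_tcs(exp.design.sample_sets, exp.design.factors)

print(f"{len(exp.design.sample_sets)} sample sets -> {len(tcs)} T/Cs:")
for tc in tcs:
    print(f"  [{tc.differing_factor:>8}] {tc.name}")

tc = next(t for t in tcs if t.tc_id == "wild_type_24_hr__vs__wild_type_none")
row = compute_tc_stats(exp.matrix, tc).loc["g00000"]
print(f"\nspiked feature in '{tc.name}':")
print(f"  LOG2R = {row['log2r']:.3f} (truth 2.0), fold = {row['fold']:.2f}, "
      f"P = {row['p_value']:.2e}")
# The recovered LOG2R sits within replicate noise (sigma=0.25, n=3) of the
# simulated 2.0 shift; the small P reflects 3-vs-3 replicate separation.
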