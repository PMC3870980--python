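"""Fermentation-kinetics traits and heritability.

Extracts lag time, maximal CO2-release rate (Rmax), the rate at 70% of
total release (R70), and total CO2 from a logistic fermentation curve, then
estimates broad-sense heritability of a simulated trait from segregant
variance versus pooled parental-replicate variance.
"""

import numpy as np

from winemap import simulate, traits

# a logistic fermentation releasing 94.3 g/l of CO2
t = np.linspace(0, 250, 600)
co2 = 94.3 / (1 + np.exp(-0.1 * (t - 70.0)))
k = traits.extract_kinetics(t, co2)
print(f"total CO2 {k.total_CO2:.1f} g/l; Rmax {k.Rmax:.2f} g/l/h; "
      f"R70 {k.R70:.2f} g/l/h (read at the {0.7 * k.total_CO2:.1f} g/l crossing); "
      f"lag {k.lag_time:.1f} h")

marker_map = simulate.simulate_marker_map(density_per_10kbp=0.3, seed=5)
genotypes, truth = simulate.simulate_cross(marker_map, n_segregants=44, seed=5)
table = simulate.simulate_traits(genotypes, truth, target_H2=90.0, parental_reps=4, seed=5)
for trait in table.segregants.columns:
    h2 = traits.heritability(
        table.trait(trait), table.parental[trait]["P1"], table.parental[trait]["P2"]
    )
    print(f"heritability of {trait!r}: {h2:.1f}% (target 90%)")
print("H2 = 100 (Var_seg - Var_env) / Var_seg with Var_env pooled over parental replicates")
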