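"""Exact permutation inference on the reseeding experiment.

Runs the subset-sum permutation test on the packaged days-to-half-full
table (faster vs slower reseeded wells, with interval- and
right-censored entries) and on a freshly simulated reseeding experiment.
"""

from clonewell import (
    ReseedingConfig,
    generate_reseeding_experiment,
    package_fixture_table2,
    permutation_test_mean_exact,
)
from clonewell.io import reseeding_records_to_table

faster, slower = package_fixture_table2()
res = permutation_test_mean_exact(faster, slower)
print("packaged reseeding table (32 vs 32 wells):")
print(f"  faster-arm mean crossing day : {res.extras['mean1']:.4f}")
print(f"  subsets with mean <= observed: {res.extras['count_le']} "
      f"of C(64,32) = {res.extras['total_combinations']}")
print(f"  two-sided exact p-value      : {res.p_value:.2g}")
print("  (tail count invariant to censor resolution:",
      res.extras["resolution_invariant"], ")")

records = generate_reseeding_experiment(ReseedingConfig(seed=7))
table = reseeding_records_to_table(records)
sim = permutation_test_mean_exact(table["fast"], table["moderate"])
print("\nsimulated reseeding (fast vs moderate arms, 78 cells each):")
print(f"  mean crossing days {sim.extras['mean1']:.1f} vs {sim.extras['mean2']:.1f}, "
      f"p = {sim.p_value:.2g}")
print("A tiny p-value says the two arms' crossing times cannot be one")
print("population split at random: the growth-rate difference is heritable.")
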