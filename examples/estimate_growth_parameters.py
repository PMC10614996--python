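"""Maximum-likelihood estimation of (g0, d, r) from daily cell counts.

Simulates ten growing single-cell wells whose cells are counted daily
while below 300 (where the density term is negligible), then fits the
birth probability g0, death probability d, and per-well modifier range r
by grid-search MLE over exact one-day transition probabilities.
"""

import numpy as np

from clonewell import ModelParams, mle_grid_search, simulate_count_series

true = ModelParams()  # g0=0.5, d=0.01, r=0.1
series = simulate_count_series(10, true, rng=np.random.default_rng(3))
print("daily counts of the first three wells:")
for s in series[:3]:
    print(f"  {s.well_id}: {s.counts}")

result = mle_grid_search(series)
print(f"\nMLE over the default grid (g0 in 0.30..0.70, d in 0..0.05, r in 0..0.15):")
print(f"  g0_hat = {result.g0_hat:.2f}   (truth 0.50)")
print(f"  d_hat  = {result.d_hat:.2f}   (truth 0.01)")
print(f"  r_hat  = {result.r_hat:.2f}   (truth 0.10)")
print(f"  log-likelihood = {result.log_likelihood:.1f}")
print("g0 is recovered to a few hundredths; d and g0 trade off along a")
print("likelihood ridge because the mean daily growth only pins g0 - d.")
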