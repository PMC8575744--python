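"""Returns-allowed decay curves and four-exponential lifetimes.

First validates the statistic against the two-state closed form on
simulated telegraph bonds, then round-trips a reference four-exponential
parameter set (zeaxanthin beta-ring hydroxyl-water H-bonds): the curve is
generated noiselessly from the printed (A_i, T_i) and the constrained fit
must give them back.
"""

import numpy as np

from xanmem import DECAY_PRESETS, generate_decay_curve, generate_event_matrix
from xanmem.lifetime import DecayConfig, decay_curve, fit_multiexp, fit_residuals

# --- telegraph closed form -------------------------------------------------
k_on, k_off = 0.002, 0.004
m = generate_event_matrix([{"n_pairs": 1000, "k_on": k_on, "k_off": k_off}],
                          duration=25_000.0, seed=5)
c = decay_curve(m, DecayConfig(lag=5000.0, origin_stride=500.0))
p = k_on / (k_on + k_off)
theory = p + (1 - p) * np.exp(-(k_on + k_off) * c.lags)
dev = np.max(np.abs(c.counts / c.counts[0] - theory))
print(f"telegraph bonds: C(tau)/C(0) vs closed form, max deviation {dev:.3f}")

# --- reference-row round trip ----------------------------------------------
par = DECAY_PRESETS["ZEA"]
curve = generate_decay_curve(par["fractions"], par["taus"], c0=100.0, lag=5000.0)
fit = fit_multiexp(curve, n=4, rng=0)
diag = fit_residuals(fit, curve)
print("\nzeaxanthin beta-ring OH...water decay, four-exponential fit:")
print(f"{'':>12s} {'A_i (%)':>10s} {'T_i (ps)':>10s}")
for i in range(4):
    print(f" component {i + 1} {fit.fractions[i]:10.2f} {fit.taus[i]:10.1f}")
print(f"sum A_i = {fit.fractions.sum():.2f} %, "
      f"max |residual|/C(0) = {diag['max_rel_residual']:.1e}")
print("\nThe dominant components (~30% at ~70 ps, ~32% at ~490 ps) describe")
print("the typical hydroxyl-water H-bond persistence at the bilayer depth")
print("of the ring; the slow ~3 ns tail is the long-engagement fraction.")
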