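"""Decline of the relative accumulation rate A(N, s, t) with sampling time.

A new mutation with fitness cost s accumulates more slowly than a neutral one
because purifying selection purges it before it can be sampled; A is the
ratio of expected divergence under selection to the neutral expectation t/N.
"""

import numpy as np

from bacrate import wright_fisher as wf

N = 100
times = wf.geometric_times(N, max_gen_in_N=4.0, n_points=9)

print("Single selection coefficients (N = 100):")
print("t/N      " + "".join(f"s={s:<8g}" for s in (0.0, 0.01, 0.05)))
curves = [wf.relative_rate_curve(N, s, times) for s in (0.0, 0.01, 0.05)]
for i, t in enumerate(times):
    row = "".join(f"{c.values[i]:<10.4f}" for c in curves)
    print(f"{t / N:<9.2f}{row}")

print("\nGamma DFE (shape 0.5, 100 sampled mutations), A at t = 0.05 N:")
for mean_ns in (10, 100, 1000):
    dfe = wf.DFESpec(shape=0.5, mean_Ns=mean_ns, n_samples=100, seed=1)
    a = wf.dfe_relative_rate(N, dfe, [int(0.05 * N)]).values[0]
    print(f"  mean N*s = {mean_ns:<5d} ->  A = {a:.3f}")

est, se = wf.monte_carlo_divergence(50, 0.1, 25, replicates=20000, seed=1)
exact = wf.expected_divergence(50, 0.1, 25)
print(f"\nMonte-Carlo check, D(50, 0.1, 25): simulation {est:.5f} +/- {se:.5f}, "
      f"transition matrix {exact:.5f}")
print("Stronger selection pushes A below 1, and the decline steepens with "
      "mean N*s; the matrix and forward simulation agree within error.")
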