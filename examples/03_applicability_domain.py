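"""Leverage and influence diagnostics for a fitted model's training design.

Plants one case far outside the descriptor range and one response outlier,
then computes hat values with the 3m/n leverage threshold and Cook's
distances with the 4/n cutoff.
"""

import numpy as np

from autoqsar import assess_domain

rng = np.random.default_rng(3)
n = 40
x1 = rng.standard_normal(n)
x2 = rng.standard_normal(n)
x1[5] = 8.0                       # descriptor-space outlier -> high leverage
y = 2 * x1 - x2 + 0.3 * rng.standard_normal(n)
y[17] += 6.0                      # response outlier -> high influence

report = assess_domain(np.column_stack([x1, x2]), y)

print(f"model parameters m = {report.m}, cases n = {n}")
print(f"mean hat value: {report.mean_hat:.4f}  (always m/n = {report.m / n:.4f})")
print(f"leverage threshold 3m/n = {report.leverage_threshold:.4f}")
print(f"high-leverage cases: {report.high_leverage_ids}")
print(f"Cook's distance cutoff 4/n = {report.cooks_cutoff:.4f}")
print(f"influential cases: {report.influential_ids}")

# Case 5 (planted descriptor outlier) exceeds the leverage threshold: the
# model's predictions there are extrapolations outside its applicability
# domain.  Case 17 (planted response outlier) gets a large Cook's distance:
# it materially shifts the fitted coefficients.
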