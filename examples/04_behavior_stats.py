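"""Signal-detection performance and within-subject statistics.

Walks through the behavioral layer on small hand-made inputs: d' from
hit/false-alarm counts, a paired contrast with Cohen's d, the 2x2
within-subject ANOVA, a partial correlation, the flanker ratio, and the
regression power analysis.
"""

import numpy as np

from gazehmm import (
    ResponseCounts,
    correlation,
    dprime,
    flanker_effect,
    paired_contrast,
    required_n_regression,
    rm_anova_2x2,
)

perf = dprime(ResponseCounts(n_old=32, hits=26, n_new=32, false_alarms=7))
print(f"d' = {perf.dprime:.3f}, criterion = {perf.criterion:.3f} "
      "(26/32 hits vs 7/32 false alarms)")

rng = np.random.default_rng(0)
baseline = rng.normal(2.2, 0.5, size=30)
masked = baseline - 0.4 + rng.normal(0, 0.4, size=30)
res = paired_contrast(masked, baseline)
print("masked vs baseline:", res.report())

cells = np.column_stack([baseline, masked,
                         baseline - 0.45 + rng.normal(0, 0.4, 30),
                         baseline - 0.35 + rng.normal(0, 0.4, 30)])
for effect, stat in rm_anova_2x2(cells).items():
    print(f"2x2 ANOVA {effect}: {stat.report()}")

iq = rng.normal(size=30)
x = 0.4 * iq + rng.normal(size=30)
y = -0.5 * x + 0.3 * iq + rng.normal(size=30)
plain = correlation(x, y)
partial = correlation(x, y, covariates=iq)
print(f"r = {plain.r:.3f} (df={plain.df}); "
      f"partialling the covariate: r = {partial.r:.3f} (df={partial.df})")

print(f"flanker effect (I=610 ms, C=540 ms): {flanker_effect(610, 540):.4f}")
n = required_n_regression(f2=0.15, n_predictors=4, power=0.80, alpha=0.05)
print(f"sample size for a medium regression effect (f2=.15, 4 predictors, "
      f"80% power): N = {n}")
# N = 85 is the classic result for this configuration; the paired t and the
# ANOVA's learning-mask F are linked by F = t^2 in a 2x2 within design.
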