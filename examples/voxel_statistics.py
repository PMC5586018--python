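"""The voxel-level recurrence statistics on simulated data.

Draws 100,000 voxels with TMR ~ Uniform(0.5, 2.5) and recurrence labels
from the logistic law anchored on the published curve (odds ratio 5.18
per unit TMR, 50% probability at TMR 1.88), then recovers the curve,
its odds ratio, the probability thresholds, and the ROC area.
"""

import numpy as np
import pandas as pd
from scipy.special import expit

from fmisovox import (
    fit_logistic_irls,
    mann_whitney,
    odds_ratio,
    roc_auc,
    tmr_at_probability,
)
from fmisovox.synthetic import DEFAULT_INTERCEPT, DEFAULT_SLOPE

rng = np.random.default_rng(0)
n = 100_000
tmr = rng.uniform(0.5, 2.5, n)
p = expit(DEFAULT_INTERCEPT + DEFAULT_SLOPE * tmr)
label = np.where(rng.random(n) < p, "ovl", "non_ovl")
table = pd.DataFrame({"patient_id": "sim", "i": np.arange(n), "j": 0, "k": 0,
                      "tmr": tmr, "label": label})

fit = fit_logistic_irls(table)
print(f"true curve:   logit p = {DEFAULT_INTERCEPT:.3f} + {DEFAULT_SLOPE:.3f} * TMR")
print(f"fitted curve: logit p = {fit.intercept:.3f} + {fit.slope:.3f} * TMR "
      f"({fit.n_iter} IRLS iterations)")

or_, lo, hi = odds_ratio(fit)
print(f"odds ratio per unit TMR: {or_:.2f} (95% CI {lo:.2f}-{hi:.2f}); "
      "the generating value is 5.18")

for prob in (0.5, 0.3):
    t, tlo, thi = tmr_at_probability(fit, prob)
    print(f"TMR at {prob:.0%} recurrence probability: {t:.2f} "
          f"(95% CI {tlo:.2f}-{thi:.2f})")

ovl = table.loc[table.label == "ovl", "tmr"]
non = table.loc[table.label == "non_ovl", "tmr"]
cmp = mann_whitney(ovl, non)
print(f"mean TMR: {cmp.mean_a:.3f} ({cmp.se_a:.5f} SE) overlap vs "
      f"{cmp.mean_b:.3f} ({cmp.se_b:.5f} SE) non-overlap, p = {cmp.p_value:.2e}")

roc = roc_auc(table)
print(f"ROC AUC: {roc.auc:.3f} — equals the Mann-Whitney U scaled by the "
      f"number of voxel pairs ({cmp.u_statistic / (roc.n_positive * roc.n_negative):.3f})")
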