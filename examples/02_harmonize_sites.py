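"""Remove scanner effects while preserving aging and disease signal.

Fits the empirical-Bayes location/scale harmonization on a two-site
cohort with planted site offsets, then shows the per-feature site ANOVA
before and after, and that the planted age slope survives.
"""

import numpy as np
from scipy import stats

import neuroage as na

cfg = na.SimulationConfig(n_training=400, site_shift=(0.6, -0.6), seed=7)
table, _ = na.simulate_training_cohort(cfg)

model = na.combat_fit(table, batch_col="site", design=("age", "sex"))
adjusted = na.combat_apply(model, table)

crit = stats.f.ppf(0.95, 1, len(table) - 2)
pre = na.site_effect_scan(table)
post = na.site_effect_scan(adjusted)
print(f"features with a significant site effect (F > {crit:.2f}):")
print(f"  before harmonization: {(pre['F'] > crit).sum()} / 28")
print(f"  after harmonization:  {(post['F'] > crit).sum()} / 28")

key = "thickness__VIS"
s_pre = np.polyfit(table["age"], table[key], 1)[0]
s_post = np.polyfit(adjusted["age"], adjusted[key], 1)[0]
print(f"\n{key} age slope: {s_pre:.5f} before, {s_post:.5f} after (mm/yr)")
print("The site effect is gone but the aging trajectory is untouched -- "
      "that is the harmonization contract.")
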