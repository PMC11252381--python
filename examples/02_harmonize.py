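"""Harmonize raw multi-site volumes into normative z-scores.

Residualizes sex, age, age^2, site and TIV, removes residual site effects
with empirical-Bayes ComBat, z-scores against the controls (flipped so
higher z = more volume loss), and drops subjects with any |z| > 5.
"""

import numpy as np

import zsustain as zs

cfg = zs.SimulationConfig(n_patients=400, n_controls=400, seed=1)
cohort = zs.generate_cohort(cfg)

z, report, coef = zs.harmonize_cohort(cohort)

print(f"subjects in: {len(cohort)}, after outlier removal: {len(z.values)}")
print(f"removed as >5 SD outliers: {len(report.removed_ids)}")
print(f"control z means (max |.|): {np.abs(z.controls.mean()).max():.2e}")
print(f"control z SDs (max |1-.|): {np.abs(z.controls.std() - 1).max():.2e}")
print(f"mean patient z (hippocampus): {z.patients['hippocampus'].mean():.2f}")
# Controls define the normative scale (mean 0, SD 1 per ROI); patients sit
# above zero on average because z is oriented so larger = more gray-matter
# loss. Outliers are almost all late-stage patients whose planted deviation
# reaches the 5-SD threshold.
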