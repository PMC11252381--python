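"""Choose the number of subtypes by cross-validated Dice consistency.

A small six-biomarker toy keeps this fast: two opposite planted sequences,
so the label agreement across independently fitted folds peaks at K = 2.
The Hopkins statistic answers the prior question of whether the patient
z-scores cluster at all.
"""

import numpy as np

import zsustain as zs
from zsustain.model import stage_expectations

rng = np.random.default_rng(8)
spec = zs.ZScoreEventModelSpec(biomarkers=tuple("abcdef"), waypoints=(1.0,), z_max=3.0)
o1, o2 = np.arange(6), np.arange(6)[::-1].copy()
S1, S2 = stage_expectations(o1, spec), stage_expectations(o2, spec)
n = 300
lab = (rng.random(n) < 0.4).astype(int)
stages = rng.integers(0, 7, n)
X = np.where(lab[:, None] == 0, S1[stages], S2[stages]) + rng.normal(0, 0.8, (n, 6))

hop = zs.hopkins(X, seed=1)
print(f"Hopkins H = {hop.H:.3f} (clustered at 90% level: {hop.clustered})")

settings = zs.FitSettings(n_starts=1, n_mcmc=0, split_restarts=2, split_em_iter=2)
curve = zs.select_K(X, spec, k_range=(2, 3), n_repeats=3, settings=settings, seed=6)
print("median Dice per K:", {k: round(v, 3) for k, v in curve.median.items()})
print(f"chosen K = {curve.chosen_k}")
# H well above 0.5 confirms clustering tendency; the Dice curve peaks at the
# planted K = 2 because a third subtype is not reproducible across folds.
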