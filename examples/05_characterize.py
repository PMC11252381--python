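"""Downstream characterization: stage correlates, symptom trajectories and
inter-subtype morphometry contrasts on a synthetic cohort with known truth."""

import zsustain as zs

cfg = zs.SimulationConfig(n_patients=1000, n_controls=100, seed=2)
cohort = zs.generate_clinical(zs.generate_cohort(cfg), cfg)
pat = cohort[cohort.group == "patient"].copy()
labels = pat["true_subtype"].to_numpy(int)
pat["stage"] = pat["true_stage"].astype(float)

corr = zs.stage_correlates(
    pat["stage"].to_numpy(), pat[["illness_duration", "panss_negative"]]
)
print("stage correlates (Spearman rho, FDR q):")
print(corr.round(4))

bins = zs.bin_duration(pat["illness_duration"])
traj = zs.symptom_trajectory(pat, labels, bins, subscales=["panss_negative"])
print("\nnegative-symptom ANOVA across duration bins, per subtype:")
print(traj["anova"].round(4).to_string(index=False))

z, _, _ = zs.harmonize_cohort(cohort)
sub = cohort.loc[z.values.index]
zpat = z.patients
contrast = zs.intersubtype_morphometry(
    zpat, sub.loc[zpat.index, "true_subtype"].to_numpy(int)
)
print("\nlargest inter-subtype morphometry effects (Cohen's d):")
print(contrast["cohens_d"].abs().sort_values(ascending=False).head(5).round(3))
# Stage correlates weakly with duration (the planted coupling), the planted
# negative-symptom worsening appears only in subtype 1's ANOVA, and the
# biggest regional contrasts are the early regions of the two trajectories.
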