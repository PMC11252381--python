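# zsustain

Z-score event-based **subtype and stage inference** for multi-site ROI
gray-matter-volume tables, with the full analysis chain around it: normative
harmonization, clustering-tendency testing, cross-validated choice of the
number of subtypes, and downstream clinical/neuroanatomical statistics.

## The problem

Cross-sectional case-control imaging studies mix two kinds of heterogeneity:
*which* disease process a patient has (subtype) and *how far along* it is
(stage). Given one scan per subject, `zsustain` disentangles both by
modelling disease progression as an ordered sequence of events, where an
event is a regional biomarker crossing a severity waypoint. It is aimed at
researchers analysing pooled multi-site ROI volume tables (e.g. psychiatric
or neurodegenerative consortium data) who need a reproducible, testable
implementation rather than a one-off analysis script.

## The model

Subjects are normative z-scores: per ROI, the deviation from the
healthy-control distribution after covariate adjustment, sign-flipped so
larger z = more volume loss. Each subtype c is an event sequence
S_c = (e_1, …, e_E) over E = 17 ROIs × 3 waypoints (z = 1, 2, 3); a subject
at stage k has experienced events e_1..e_k. The expected z of biomarker b at
stage k, g_c(k, b), interpolates linearly through (0, 0), b's waypoint
positions in S_c, and (E, z_max = 5). With a uniform stage prior, the
subject likelihood is

    p(x | S_c) = 1/(E+1) · Σ_{k=0..E} Π_b N(x_b ; g_c(k, b), σ_b²),  σ_b = 1,

and the cohort is a K-component mixture Σ_c f_c p(x | S_c). Sequences are
fitted by EM with greedy event repositioning plus Metropolis–Hastings over
orderings, growing K hierarchically by splitting subtypes. K itself is
chosen by two-fold cross-validated label agreement (Dice coefficient), and
the Hopkins statistic tests whether the data cluster at all. Full details
and assumptions are in [docs/methods.md](docs/methods.md).

A synthetic-cohort generator with planted trajectories (cortical-first from
Broca's area, subcortical-first from the hippocampus, mixed 0.62/0.38)
stands in for protected patient data, so every stage is testable end to end.

## Worked example

`examples/03_fit_subtypes.py` simulates 400 patients + 400 controls,
harmonizes them, fits the two-subtype model at reduced settings and assigns
every patient a subtype and stage:

```
$ python examples/03_fit_subtypes.py
fitted on 266 patients; log-likelihood -6820.2
mixture fractions: [0.403 0.597]
subtype 1 first events: (('amygdala', 1.0), ('hippocampus', 1.0), ('accumbens', 1.0))
subtype 2 first events: (('frontal lobe', 1.0), ('insula', 1.0), ('cingulate', 1.0))
stage Spearman vs planted truth: 0.945
```

266 of the 400 simulated patients survive the 5-SD outlier rule (late-stage
subjects sit at the threshold by construction). The recovered mixture
(0.40/0.60) tracks the planted 0.38/0.62; the first events of each sequence
fall in the earliest regions of the corresponding planted trajectory
(hippocampal complex vs fronto-insular cortex); and the fitted stages rank
subjects almost exactly as the planted progression does (ρ = 0.945). The
other examples cover simulation (`01`), harmonization (`02`), choosing K
with Hopkins + Dice-CV (`04`) and downstream characterization (`05`).

The same stages are scriptable from the shell:

```bash
zsustain simulate --n-patients 400 --n-controls 400 --seed 1 -o cohort.tsv
zsustain harmonize --cohort cohort.tsv -o zscores.tsv
zsustain fit --zscores zscores.tsv -k 2 -o model.json
zsustain run-all --out-dir run1 --seed 1    # full pipeline + manifest
```

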