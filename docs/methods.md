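# Methods

## The model

`zsustain` implements a z-score event-based subtype-and-stage mixture model
for cross-sectional biomarker tables. Each of K subtypes is an ordered
sequence S_c of E events, an event being one biomarker b crossing one
severity waypoint z ∈ {1, 2, 3} (17 ROIs × 3 waypoints gives E = 51 by
default). A subject at stage k has experienced the first k events of their
subtype's sequence. The expected z-score of biomarker b at stage k,
g_c(k, b), is piecewise-linear through (0, 0), the biomarker's waypoint
positions in S_c, and a terminal anchor (E, z_max) with z_max = 5 (a
replication mode with z_max = 4 is a parameter away); when a biomarker's
last waypoint falls at position E the terminal anchor would collide with it
and is dropped, so that biomarker tops out at its last waypoint. Observed
z-scores are g plus Gaussian noise with σ_b = 1 — the natural choice when
the inputs are normative z-scores, whose control distribution has unit SD by
construction.

The subject likelihood marginalises the stage under a uniform prior over
0..E:

    p(x | S_c) = 1/(E+1) · Σ_k Π_b N(x_b; g_c(k, b), σ_b²)

and subjects are a mixture Σ_c f_c · p(x | S_c) over subtypes. Everything is
evaluated in log space; the per-sequence stage-likelihood matrix reduces to
one matrix product, which is what makes the greedy and MCMC loops fast.

## Inference

*EM with greedy sequence moves.* From random valid sequences (uniform over
linear extensions of the per-biomarker chains), alternate: (i) subject
responsibilities under current sequences and fractions, (ii) fraction update
to the mean responsibility, (iii) per-subtype sequence improvement by
single-event repositioning — remove one event and reinsert it at the best
position that preserves the within-biomarker waypoint order, sweeping events
in random order until no move improves the responsibility-weighted
likelihood. Candidate moves are ranked with a float32 screen (constant terms
dropped) and the winning move is re-scored in float64 before acceptance, so
the arithmetic that decides acceptance is full precision. The best of
`n_starts` random starts is kept.

*MCMC.* Metropolis–Hastings over orderings: pick a subtype and an event
uniformly, reinsert the event uniformly among order-preserving positions
(a symmetric proposal), accept with min(1, exp(Δ log-likelihood)). The full
archive is retained; the returned model is the maximum-likelihood sample
with fractions refreshed by one E-step.

*Hierarchical growth of K.* Fit K = 1; to get C subtypes from C−1, try
splitting each current subtype: partition its assigned subjects in two, fit
one sequence per half, and rank the resulting C-subtype candidates by
full-data likelihood after a short EM refinement that only optimises the two
children (capped at `split_em_iter` iterations). The winning split is then
refined by full EM and MCMC. Split partitions comprise one deterministic
seed — 2-means on unit-normalised z-profiles, which removes the severity
axis and clusters on *which* regions deviate, i.e. the subtype signal — plus
`split_restarts` random binary partitions. The profile seed matters: with
random partitions alone at desk-scale restart counts, two-fold CV fits
regularly miss a well-separated two-subtype structure inside one fold,
because a random half-half split gives both children near-identical
sequences and the short candidate EM cannot pull them apart in time.

*Assignment.* Subtype probabilities are proportional to f_c · p(x | S_c),
averaged over a thinned MCMC archive (≤ 50 evenly spaced samples — the
point estimates stabilise well below that, and it keeps assignment cost
negligible); the hard label is the argmax (ties to the lower index), and the
stage is the argmax of the stage posterior within the hard subtype under the
final sequences (ties to the lower stage).

*Settings.* `FitSettings()` defaults to the reduced scale used throughout
the tests — 5 starts, 10,000 MCMC iterations; `FitSettings.full_scale()` gives
the full 25 starts / 100,000 iterations. EM stops at a log-likelihood gain
below 1e-4 or 15 iterations; greedy runs at most 8 sweeps standalone and 2
per EM iteration (the outer loop supplies convergence).

## Harmonization

Fixed order, mirroring the published pipeline: (1) per-ROI OLS
residualization on sex, age, age², site and TIV — coefficients estimated on
the pooled sample by default (the source does not say control-only; a
control-only mode is a flag away); (2) parametric empirical-Bayes ComBat —
per-feature standardization, per-batch location (γ, normal prior) and scale
(δ², inverse-gamma prior) with moment-matched hyperparameters, iterative
conditional updates to 1e-4 relative change (max 100 iterations) — the site
term thus appears twice (regression + ComBat), deliberately reproducing the
source procedure despite the redundancy; (3) z-scoring against the control
mean/SD per ROI, multiplied by −1 so larger z means more volume loss
(`to_zscores` takes a `loss_direction` so measures that already increase
with pathology are handled, and re-harmonizing a loss-oriented table is an
involution rather than a sign flip); (4) two-sided removal of subjects with
any regional |z| > 5.

Our ComBat matches Bioconductor `sva::ComBat` to ~1e-7 on shared input (one
test runs the R oracle). Two consequences of the EB machinery worth knowing:
a planted batch shift is removed in aggregate but each feature keeps a small
shrinkage remnant (~0.1 SD worst-case for a 0.5 SD planted shift — sva
leaves the identical remnant); and re-running harmonization on multi-batch
output changes values at the 1e-3 level because shrunk batch estimates never
hit zero exactly — idempotence is exact only in the single-batch case, and
is tested there.

## Model selection

Hopkins statistic H = Σu/(Σu+Σw) with m = 10% of n probe points sampled
uniformly over the data's bounding box (u: probe nearest-real distances; w:
sampled-real nearest-other-real distances, self excluded), with a one-sided
Beta(m, m) verdict at 90% confidence. The number of subtypes is chosen by
two-fold cross-validated label consistency: per repeat, patients are split
in half, each fold fits one hierarchical model up to max(K) (per-level
models are read off the same hierarchical pass — they are exactly the
models the hierarchical construction would produce, fitted once instead of
K−1 times), both models label all patients, labels are aligned by Hungarian
assignment on the K×K contingency table, and agreement is summarised by the
Dice coefficient 2|A_c∩B_c|/(|A_c|+|B_c|) per subtype. The overall Dice is
the subject-weighted mean, which equals the fraction of consistently
labelled subjects. K = 1 is excluded (its Dice is trivially 1); the Hopkins
test carries the "is there any clustering" question. Chosen K = argmax of
the median Dice across repeats, ties to the smaller K.

## Characterization

Stage correlates: Spearman ρ with two-sided p and Benjamini–Hochberg FDR
across measures. Illness-duration bins: early ≤ 2 y, middle (2, 10] y,
late > 10 y (an alternative convention with early < 2 is selectable; the two
differ only at exactly 2 years). Symptom trajectories: one-way ANOVA across
bins within each subtype; between-subtype two-sample t-tests within each bin
on residuals after regressing out age, sex and model stage (two-sided,
uncorrected). Morphometry contrasts: two-sample t per measure, Cohen's d on
the pooled SD (subtype1 − subtype2), Holm–Bonferroni FWE across measures —
chosen over plain Bonferroni because it is valid under arbitrary dependence
and uniformly more powerful. Generalization: fit on a training subset and on
the full data, label and stage the unseen subjects under both, report
matched-label agreement and the Spearman correlation of the two stagings.

## The synthetic cohort generator

The generator produces the study conditions every downstream stage assumes.
Controls: per-ROI baseline volumes (arbitrary units) plus covariate effects
(age −0.02 u/y, age² −4e-4 u/y², sex +0.25 u, TIV +0.004 u/unit around
centring constants) plus N(0, 1) population noise — the unit control SD is
what makes planted deviations exact z-units. Patients: a subtype from the
0.62/0.38 mixture, a stage uniform on 0..E (the empirical stage occupancy of
the real cohort is unpublished, so uniform is an assumption, and
configurable), and volumes lowered by g_subtype(stage, roi). Site effects:
3 sites, additive shifts {−0.3, 0, +0.3} control SD and multiplicative
scales {0.9, 1.0, 1.1} applied after the subject model — detectable (raw
site F-tests reject on essentially all ROIs) but realistic for testing
ComBat. The planted sequences order ROI onsets cortical-first from Broca's
area (trajectory 1) and subcortical-first from the hippocampus
(trajectory 2), with waypoint waves staggered six onset ranks apart so early
regions reach z = 3 before late regions cross z = 1.

Clinical scores: illness duration follows a three-part marginal (42%
uniform on (0, 2] years, 26% uniform on (2, 10], 32% of 10 + Exp(12 y)
capped at 45) — matching the early/middle/late occupancy of a mixed
first-episode + chronic population, which is what the bin statistics depend
on; its mean (~9 y) sits slightly below the real cohort's 10.5 y. Duration
couples to the true stage through a Gaussian copula at ρ = 0.11, giving a
stage–duration Spearman of ~0.105. PANSS subscales are continuous latent
severities: baseline + subtype-specific slope × duration + Gaussian noise,
with defaults read off the real cohort's bin means — positive symptoms
decline with duration in both subtypes, negative (0.15 pts/y) and
depression/anxiety (0.065 pts/y) worsen only in subtype 1. Scores are not
truncated at the scale minima: truncation would distort null ANOVA
calibration, and the tests verify exactly that calibration.

What the generator does *not* emulate: anatomical covariance beyond the
planted trajectories (ROI noise is independent), scanner-specific
covariate-by-site interactions, item-level PANSS structure, missing data,
and any dependence of noise on stage. Passing tests therefore demonstrate
that the machinery recovers structure of this planted form at these noise
levels — not that real acquisitions meet those assumptions.

One generator subtlety: subjects near the final stages carry expected
deviations at the 5-SD outlier threshold, so the faithful 5-SD rule removes
roughly a third of patients (almost all late-stage) from a default cohort.
The recovery checks run on the surviving subjects, as the real pipeline's
would.

## Numerical and design notes

- Stage-likelihood matrices are computed via one GEMM per sequence;
  candidate moves share a batched GEMM. The float32 screen only ranks;
  accepted values are float64.
- Degenerate inputs: zero control SD, zero within-batch variance,
  rank-deficient covariate designs (reported with the offending column
  names), non-finite z-rows, K > n, and empty subsets all raise with
  specific messages. Constant measures in correlation reports are returned
  as missing rather than raising.
- Ties everywhere resolve to the lower index / lower stage / smaller K, so
  repeated runs are stable.
- All randomness flows from per-call seeds or `numpy.random.Generator`s; the
  pipeline spawns one child seed per stage from a master seed
  (`SeedSequence.spawn`), so stages are individually reproducible.
- Test-scale problem sizes (800 + 800 subjects, 5 starts / 10,000 MCMC
  iterations, 3 CV repeats over K ∈ {2,3,4}) were chosen so the planted
  structure is comfortably recoverable on one core; the full-scale settings
  remain available through `FitSettings.full_scale()` and the config files.

## Known limitations

- The event model is the piecewise-linear z-score flavour only — no
  mixture-of-Gaussians event model, no continuous-time variant, no
  covariate-adjusted staging.
- ComBat is the parametric location/scale version; no GAM variant, no
  reference batch, no missing-data handling.
- The hierarchical split heuristic is greedy in C; it does not revisit
  earlier levels when a later split would have reshaped them.
- Uniform stage prior: cohorts strongly concentrated at early stages will
  bias stage posteriors toward the middle of the grid relative to an
  informed prior.
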