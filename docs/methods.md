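# Methods

This note documents the models, defaults and numerical choices behind
`ptsdconn`, and what the synthetic-data generator does and does not
emulate.

## Intrinsic connectivity estimation

**Censoring.** A frame is dropped when framewise displacement exceeds
0.5 mm or DVARS (frame-to-frame RMS signal change, divided by the run's
median DVARS) exceeds 1.5. The FD threshold is the common scrubbing
default for task data; both are config keys, not claims about any
particular study's thresholds. Frame 0 has no DVARS and is judged on FD
alone. A run keeping fewer than max(5, 10% of frames) is excluded from
concatenation with a warning.

**Nuisance model.** Per run: intercept, linear drift, task covariates as
given (no HRF convolution is applied — covariates are accepted in
whatever basis the user supplies), the Friston-24 motion set
[R, R(t−1), R², R(t−1)²] as the concrete realization of a Volterra
expansion of the realignment parameters, mean tissue signals, and one
spike indicator per censored frame. Zero-variance columns (judged on
retained frames) are dropped; rank-deficient designs fall back to
minimum-norm least squares with a warning rather than failing, since
spike regressors plus lagged motion can be collinear on short runs.

**Order of operations.** Filtering a series with gaps is ill-defined, so
the pipeline regresses with spike regressors first (which neutralizes
censored frames' influence on the fit), band-pass filters the residuals
on the regular grid (4th-order zero-phase Butterworth, 0.009–0.08 Hz),
and only then excludes the censored frames from the correlation. A
censored-in variant is not offered in v1. Masking and physically
deleting frames give identical correlations (tested).

**Correlation.** Node series are z-scored per run on retained frames,
concatenated across usable runs, and Pearson-correlated. |r| is clamped
to 1 − 1e−7 before atanh so degenerate pairs stay finite; the diagonal
is zero; zero-variance nodes get zero edges with a warning. Per-run
z-scoring before concatenation (rather than averaging per-run matrices)
weights every retained frame equally while removing run-level scale
differences.

**Filter-length guard.** Runs shorter than three filter lengths
(27 frames at the default order) are rejected: `filtfilt`'s edge padding
is meaningless below that.

## Outcome scores

The residual change score is −(observed − predicted) from the
least-squares regression of post-treatment CAPS on pre-treatment CAPS:
higher = greater improvement, zero in-sample mean, exactly uncorrelated
with baseline severity. The regression direction follows the
residualized-gain convention (predict post from pre); the transposed
variant is available behind a flag for comparability. The responder
label is a separate quantity — at least 50% symptom reduction, boundary
inclusive — and both coexist deliberately: the continuous score drives
the edgewise association, the binary label drives group splits and
prediction.

## Network-based statistic

Edgewise statistics are Pearson r (continuous outcome) or pooled-variance
two-sample t, both computed through the point-biserial identity
t = r·√(df/(1−r²)) in one vectorized path. The component score is
*extent* (edge count); suprathreshold means tail-specific p below the
component-forming threshold (default 0.001) with the matching sign for
one-sided tails. The permutation null shuffles the whole outcome vector
with a seeded generator; each permutation is thresholded at the critical
|r| equivalent to the p threshold and the maximal component's edge count
recorded (union-find fast path over the few surviving edges). Corrected
p uses the plus-one convention with ties counted toward the null, so it
is never exactly 0 and never below 1/(n_perm+1). Covariate adjustment is
Freedman–Lane style: outcome and edges are residualized on the
covariates, residuals are permuted, and the t-transform df is reduced by
the number of covariates.

Default tail is two-sided; one-sided tails are first-class because the
association of interest here is directional (lower baseline
connectivity, greater improvement).

## Composite metrics and group tests

The composite is the unweighted mean z over the significant edge set;
network-pair means partition the same edges by the unordered pair of
endpoint network labels, so the edge-count-weighted pair average
reconstructs the composite to numerical precision (asserted at 1e−10).
Baseline tests: one-way ANOVA for patients vs controls plus Welch
pairwise contrasts after the responder split (Welch because the split
groups are small and unequal); group × time uses a mixed between-within
ANOVA (pingouin), with paired-t within-group and Welch between-group
post hocs run only when the interaction is significant, all BH-FDR
adjusted. When pre and post are exactly identical the time and
interaction F ratios are 0/0; the package reports them as absent
(F = 0, p = 1) rather than NaN. Subjects missing the post session are
excluded listwise from time analyses only, mirroring follow-up
attrition. The covariate-adjusted association re-test is a partial
Pearson correlation (residualize both sides, correlate, t transform on
n − 2 − k df).

## Prediction

Leave-one-out cross-validation with an L2-regularized logistic model
(C = 1, lbfgs); features are standardized with training-fold statistics
only, which is what makes the leakage guard (flipping the held-out
label never changes its prediction) provable and tested. A training
fold containing one class predicts that class, logged. Class imbalance
is left unadjusted, matching the roughly 25/11 responder split the
design anticipates. Base features: age, sex, baseline CAPS, three DASS
subscales; the augmented set adds the connectivity composite. Models
are compared by a sign-flip permutation test on paired per-subject
correctness indicators (two-sided, plus-one convention) — identical
correctness vectors give p = 1 by construction.

## Synthetic cohorts

The generator's defaults are the study conditions: 36 patients and 36
controls, responder fraction 25/36, five runs of 120 frames at TR 2.5 s,
baseline CAPS ~ Normal(72, 14) truncated to [45, 120], DASS and age
moments matching the printed participant table, SSRI rate 27.8%.
Connectomes default to 40 nodes over 8 intrinsic networks — the desk
scale at which the simulation-based checks run — while the packaged
343-node atlas (333 cortical over 12 networks + 10 subcortical; a
synthetic stand-in, not the published parcel geometry) serves the
full-scale format paths.

**Connectome model.** Edge z = network-block mean (within 0.3, between
0.1) + per-subject global offset (SD 0.03) + per-edge noise (SD 0.08);
planted edges (default: a connected 15-edge subnetwork among the
cingulo-opercular, salience, default-mode, dorsal-attention and
frontoparietal networks) additionally carry a per-subject deviation
(SD 0.25). Improvement fraction = intercept − effect_size × (planted
mean z, centered) + Normal(0, noise_sd), with the intercept solved so
the expected responder rate equals the configured fraction; post CAPS =
pre × (1 − improvement), clipped to [0, 120] with a warning. The
default effect direction is negative (lower connectivity → greater
improvement), sign configurable. At the post session patients' planted
deviations shrink by `group_time_shift` toward the control mean —
responders (below control) rise, nonresponders (above) fall — which is
exactly the crossover the group × time test must detect; controls get
fresh measurement noise only. This is a shift-toward-the-mean model,
not a full repeated-measures covariance model: sufficient to exercise
the interaction test, not a claim about recovery dynamics.

**Calibration.** effect_size = 0.8 with the SDs above gives per-edge
|r| with residual change around 0.75–0.85 at n = 36, comfortably past
the |r| ≈ 0.52 needed at the p < 0.001 forming threshold, so
planted-subnetwork recovery is expected at high Jaccard; these
constants were fixed from this power reasoning and are part of the test
conditions.

**Time-series model.** Node i = √(w−b)·f_net(i) + √b·g + AR(1) noise,
with latent per-network factors f and a global factor g (both AR(1),
coefficient 0.3), giving within-block correlation w/(1+w) and
between-block b/(1+w). Contamination: two jittered boxcar task
covariates with per-node weights, linear + sub-band sinusoidal drift,
tissue-signal leakage, and motion spikes. Spikes are *persistent steps*
in one translation parameter (0.8 mm) and in the node signals, so FD
and DVARS are large exactly at the spiked frame — censoring then
removes precisely those frames and the censored fraction matches the
spike rate. A transient burst would instead contaminate two consecutive
frame-differences; the step form was chosen to keep the generator's
ground truth (the spike rate) directly checkable.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: hemodynamics (no HRF forward model),
spatial structure within parcels, distance-dependent motion artifact,
physiological noise spectra, heavy-tailed or skewed connectivity
distributions, correlated covariates (age/sex/DASS are drawn
independently of connectivity), and outcome nonlinearity (the
connectivity–improvement link is linear-Gaussian by construction, a
modeling convenience rather than an empirical claim).

## Problem sizes in the checked runs

The simulation-based checks use 40-node cohorts at the study's subject
counts: familywise-error calibration on 200 null cohorts at 500
permutations, planted recovery over 50 seeds, interaction detection
over 100 seeds. These sizes give stable Monte-Carlo estimates (binomial
SE ≤ 0.035 for the rates reported) while keeping the whole suite quick
to rerun; the pipeline itself is equally happy at 343 nodes and 5000
permutations, where the permutation pass is chunked to bound memory.

## Known limitations

- Correlations are computed on one common retained-frame mask per
  subject; per-pair masks are not supported.
- No global-signal regression option, no voxel-level processing, no
  imaging-format ingestion in the core (delimited text + JSON sidecars
  only).
- The permutation scheme assumes exchangeable subjects; no
  block/family exchangeability structure.
- LOOCV within one cohort quantifies added predictive value, not
  generalization to new cohorts — mirroring the design it implements,
  which flags the same limit.
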