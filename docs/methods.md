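# Methods

## Scope and model

capdyn implements the analysis chain of a three-condition within-subject
pharmaco-fMRI study — placebo (PBO), a methylphenidate-like condition (MPH)
and a haloperidol-like condition (HAL) — on top of a synthetic cohort
generator with planted ground truth.  Acquisition and preprocessing are out
of scope: the unit of input is an already-clean frames × ROIs matrix (or a
4-D NIfTI plus atlas/mask, reduced to that matrix by `timeseries_io`).

### Transient network states and dwell metrics

Eight transient network states are taken as given spatial maps (a
`CentroidSet`); the package never re-derives them by clustering, and the
synthetic stand-ins from `make_centroids` are orthonormal-basis rows
rescaled to unit standard deviation (pairwise cosine ≈ 0).  Frame
assignment computes the Pearson spatial correlation between each frame's
ROI vector and each state map after z-scoring each ROI column across time,
and takes the argmax with ties broken toward the lowest state index.  The
metric and the z-scoring are documented choices (Euclidean distance and raw
data are available behind flags): CAP toolkits differ on both and neither
choice affects the noiseless round trip.

Run-length accounting of the label sequence defines, per state,

* total time = (#frames in state) × TR,
* transitions = number of maximal runs (a run touching frame 1 counts as an
  entry),
* persistence = mean run length × TR; NaN when the state is never visited.

Counting the first-frame run as an entry makes
`total_time = transitions × persistence` hold exactly for every visited
state and makes the per-subject total times sum exactly to scan duration;
both identities are property-tested.  NaN persistence (absence) is
deliberately distinct from 0 (instantaneous visits) and is dropped pairwise
in group tests, with the dropped count reported.

### DMN–DAN anticorrelation

Each network's "beta series" is the per-frame OLS slope of the frame's ROI
vector on that network's state map — two separate simple regressions, not
one joint fit (a joint mode is not provided; the separate fits match how
the two time courses are usually obtained).  Anticorrelation is
`z = atanh(Pearson r)` between the two series.  The group model is a
subject-random-intercept linear mixed model (statsmodels MixedLM, REML) of
z on centered combined DMN+DAN time, centered age, sex, drug, and
drug × time; marginal and conditional R² follow the fixed/fixed+random
variance decomposition.

### Corticostriatal configuration profiles

A profile is the Fisher-z Pearson correlation of each striatal voxel with
each of 53 cortical ROI means.  A single-regressor OLS slope and a Pearson
correlation are equivalent up to scaling, so correlation is implemented; r
is clipped to |r| ≤ 1 − 1e-7 before atanh so degenerate noise-free inputs
stay finite.  Divergence metrics per voxel between conditions a and b:

* AD(v) = Σ_roi |z_a − z_b|;
* ROR(v) = Σ_roi |rank_a − rank_b| with ordinal ranks, rank 1 = most
  positive z, ties broken by ROI order (ties have measure zero on real
  data; determinism matters for tests).  ROR is invariant under strictly
  monotone transforms of z and bounded by ⌊K²/2⌋ for K ROIs;
* ES(v) = |H_a − H_b| where H is the Shannon entropy of the |z|-normalized
  profile with an ε = 1e-12 floor (an all-zero profile degrades to ln K).
  The entropy functional form is this package's concrete choice for
  "change in the distribution of connectivity strength"; the absolute value
  keeps all three metrics nonnegative and comparable to the null.

The within-session null computes the same metrics between profiles from
frames 1..⌊N/2⌋ and the remainder of the placebo run.  The drug pairs use
full-length runs while the null uses half-length runs; this asymmetry is
inherited from the study design the package replicates and inflates the
null slightly (half-length profiles are noisier), which is conservative for
drug-vs-null comparisons.  Voxelwise localization is a per-voxel paired t
(one-sided, drug-pair > null), thresholded at p < 0.001 uncorrected,
clustered by 6-connectivity with a 10-voxel minimum extent — a documented
thresholding rule standing in for unreported cluster-inference internals.

### Statistics

The repeated-measures ANOVA uses the classical balanced within-subject
partitioning: each within effect is tested against its effect × subject
interaction.  The design is required to be complete (missing cells raise),
where this estimator coincides with the mixed-model F and satisfies F = t²
for two-level factors exactly.  Between-subject covariates (age, sex)
enter only the between-subject stratum, which does not touch any reported
within-subject F on balanced data; they are accepted for interface parity
and logged.  Partial η² = SS_effect/(SS_effect + SS_error) =
F·df1/(F·df1 + df2).  No sphericity correction is applied; under the
exchangeable-state null generator the state covariance is compound
symmetric, and the measured type-I rate of the interaction is ≈ 7% at
nominal 5% (100 seeds).

Paired contrasts report t, raw and Bonferroni-corrected p
(min(1, p·m)) and Cohen's d_z = mean(diff)/sd(diff).

Steiger's z compares two dependent correlations sharing variable x, with
the pooled-r̄ covariance term; one-sided by default for the directional
subset comparison.  When the two y variables are identical (r_y1y2 = 1) the
statistic degenerates and is defined as 0 for equal correlations.  The
analytic z is validated against a Monte-Carlo resampling oracle of the
sampling spread of atanh(r1) − atanh(r2).

Node × state exploratory correlations are plain Pearson, Bonferroni-
corrected by the joint family n_nodes × n_states (5 × 3 = 15 ⇒ a raw p of
0.0015 becomes 0.0225).  Whether such exploratory tests should partial out
age and sex is left to the caller; plain Pearson is the default.

## Synthetic cohorts

The generator emulates the retained-scan geometry of an 8-minute scan:
235 frames at TR = 2 s, 129 ROIs of which the first 53 are "cortical",
59 subjects by default, ages Normal(39.32, 11.25) truncated to [18, 55] and
a 17:42 male:female ratio.

* **State dynamics**: a first-order Markov chain per condition.  Baseline:
  stay probability 0.6 (mean visit 5 s), uniform off-diagonal mass, uniform
  stationary occupancy (58.75 s per state).  Drug matrices scale
  off-diagonal *entry* probabilities into target states and renormalize,
  leaving the diagonal untouched — so simulated drugs alter transitions,
  not persistence.  Frozen multipliers: MPH 1.55 into DMN, 1.50 into DAN,
  0.80 into FPN; HAL 1.35 into SM-DMN.  The DMN value was calibrated once
  by Monte Carlo so the paired effect on total DMN time is d ≈ 0.7 at
  n = 59 (measured d ≈ 0.71); the chain starts from its stationary law so
  expected occupancy equals the stationary eigenvector from frame 1.
* **Frames**: active-state centroid + i.i.d. Gaussian noise, default
  sd 0.5, at which frame assignment recovers ≥ 95% of planted labels
  (Monte-Carlo check over 20 seeds).  An optional AR(1) coefficient adds
  temporal autocorrelation for stress tests.
* **Striatum**: each voxel is a fixed unit-norm Gaussian-weighted mixture
  of the 53 cortical series plus noise; voxels sit in a compact 3-D block
  enumerated (k, j, i) ascending so contiguity clustering behaves like a
  real mask.  Under MPH the weight vectors of half the voxels (default)
  are randomly permuted — the planted rank rearrangement.  HAL leaves
  weights untouched.
* **Coupling**: optionally each subject draws a common effect scale
  u ~ Uniform(0.2, 1) applied to both the transition-matrix interpolation
  and the number of permuted voxels, planting a positive correlation
  between dwell change and ROR.

All randomness flows from one seed through a seed tree; cohorts are
bit-reproducible and are written as plain TSV trees with a JSON ground-truth
ledger.

### What the generator does not emulate

No hemodynamics, head motion, physiological noise, spatial autocorrelation
between ROIs beyond the centroid structure, scanner drift, or
between-subject variation in state maps and baseline transition matrices.
Passing recovery tests therefore demonstrates that the estimators are
correct and adequately powered under the planted model — not that real
drug effects of this size would be detected in real data with these rates.

### A mechanical dynamics–connectivity coupling

Even with *no* planted effects, a subject's time-change score and apparent
ROR are positively related within a cohort: the realized state mix of a run
shapes the cortical covariance, so two runs that happened to differ more in
occupancy also yield more different connectivity-profile estimates.  This
is a property of finite scans, not an artifact of the estimators.  The
null calibration of the dynamics–CSCP correlation therefore pairs scores
from independently generated null cohorts (measured rejection ≈ 6% at
nominal 5%); the within-cohort coupling is worth remembering when
interpreting such correlations on real data.

## Problem sizes and numerical choices

The full pipeline default (59 subjects × 3 conditions, 235 frames, 129
ROIs, 300 striatal voxels) runs in a few seconds.  The Monte-Carlo
operating-characteristic studies repeat scaled-down replicas across 100
cohort seeds each — 48–64 striatal voxels, and 8 subjects for the
ROR-vs-null study, sizes chosen so the whole battery completes in minutes
on one CPU while leaving the per-seed effects far above their detection
thresholds.  Tolerances: transition-matrix rows must sum to 1 within
1e-12; r-clipping at 1 − 1e-7; entropy floor ε = 1e-12.  The dwell
identities are exact at the frame-count level; in seconds they are exact up
to one float ulp introduced by the persistence division round-trip (and the
scan-duration sum is bitwise exact for binary-representable TRs such as
2 s).

## Known limitations

* ES is one concrete realization of "distribution change"; other
  dispersion functionals (variance, Gini) would order voxels differently.
* The ANOVA layer requires balanced complete designs; unbalanced real
  datasets need the mixed-model route directly.
* One-sided voxelwise localization only detects drug > null divergence;
  stabilization (drug < null) is not searched.
* Anatomical labeling of striatal nodes is out of scope; nodes carry a
  free-text label slot.
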