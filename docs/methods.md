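# Methods

`tmsnet` infers which brain regions' functional-connectivity state explains
between-subject differences in the behavioral effect of inhibitory (1 Hz)
parietal rTMS. This note documents the model, the procedure, the synthetic
cohort generator the package is validated on, and every numerical convention
that had to be pinned.

## The inference chain

**Response variable.** For each subject the behavioral TMS effect is the
change in bilateral-target detection accuracy, TMS minus sham, computed from
trial-level responses (32 trials per stimulus x difficulty cell per
stimulation condition).

**Features.** Per subject and condition, voxel-level BOLD series are cleaned
(below), all pairwise Pearson correlations are Fisher z-transformed, negative
links are deleted, and each voxel is summarized by its mean connectivity to
same-hemisphere and to opposite-hemisphere voxels. This yields 2V candidate
regressors per condition (V intra- plus V cross-hemispheric means).

**Preselection.** Two stages: (1) a voxel is kept iff the magnitude of its
correlation with the stimulated-site seed in an independent reference map is
at least 0.1 (both its columns are kept or dropped together); (2) within each
link class separately, columns whose across-subject mean connectivity falls
strictly below the 20th percentile of that class (linear interpolation
between order statistics; boundary ties kept) are dropped. Preselection uses
no behavioral information; following the original design it is applied once,
outside cross-validation (a nested variant can be requested).

**Model.** Elastic net:

    min_{b0, b}  (1/2N) sum_i (y_i - b0 - x_i'b)^2
                 + lam * sum_j [ (1-alpha)/2 b_j^2 + alpha |b_j| ]

over 100 lambda values from 0.01 to 0.61, equally spaced on the log scale,
and alpha in {0.1, ..., 0.9, 0.99}. Regressors are standardized to zero mean
and unit population scale (divide by N, matching the 1/(2N) loss; the
convention changes the effective lambda and is therefore pinned), the
response is mean-centered, and the intercept is never penalized. The solver
is cyclic coordinate descent with exact single-coordinate updates
(soft-thresholding), an active-set strategy, warm starts along the descending
lambda path, convergence at max coefficient change < 1e-7, and a sweep cap of
1e5 (non-convergence is flagged, not silenced). Solutions are verified in the
test suite against a zooming grid-search minimizer, the orthonormal-design
soft-threshold closed form, the ridge closed form, and scikit-learn's
ElasticNet (same objective parameterization), none of which are used in the
implementation itself.

**Evaluation.** Leave-one-subject-out cross-validation; standardization is
recomputed inside every training fold. Per alpha, lambda* minimizes the sum
of squared held-out errors (PRESS), ties resolved toward the larger, sparser
lambda; R2_cv = 1 - PRESS(lambda*)/PRESS0, where PRESS0 is the intercept-only
LOSO error (fold prediction = training-fold mean). Note that R2_cv at
lambda* is optimistically biased under the null (it embeds a minimum over
100 lambdas); the significance test accounts for this, and the per-lambda
R2 surface is reported alongside.

**Significance.** One-sided permutation tests on the paired per-subject LOSO
errors of the model versus the intercept-only model, p = (#{null >=
observed} + 1)/(B + 1), B = 100,000 by default (1,000 in simulation tests).
The exchangeable operation swaps a subject's model/intercept error pair,
i.e. flips the sign of d_i = e0_i - e_model_i. Because lambda* is chosen to
maximize the observed error reduction, the scan's default statistic re-runs
that maximization inside every permutation draw: stat = max over lambda of
sum_i s_i d_i(lambda). In calibration simulations the fixed-model sign-flip
at lambda* alone had type-I error ~0.14 at nominal 0.05, while the
selection-aware statistic measured 0.067 (120 null cohorts); the
selection-aware form is therefore the default, with the fixed-model variant
(`sign_flip_star`) and a full response-permutation rerun (`permute_y`,
exact-design but ~B times slower) available and labeled. Per-alpha p-values
are reported unadjusted; a condition is called significant when any alpha
reaches p < 0.05. That condition-level call is a family of ten strongly
dependent tests: its realized null rate, measured on null-mode cohorts at
the default dimensions, is ~0.10, and comparisons of "no more than nominal"
for a condition refer to that measured level.

**Consistency.** Every significant (alpha, lambda*) pair is refit on all
subjects; a regressor is selected when its standardized coefficient exceeds
1e-8 in magnitude. The report lists per-alpha sets, their intersection, and
per-column selection frequencies; the intersection across all significant
models is the stability criterion for naming regions.

**Confound statistics.** Repeated-measures ANOVA of accuracy over
stimulation x block x stimulus x difficulty uses the balanced cell-means
(Moebius) decomposition; each effect is tested against its own
effect-by-subject interaction with uncorrected degrees of freedom (no
sphericity correction by default). Correlation p-values come from pairing
permutations (two-sided, 10,000 draws; exhaustive enumeration for n <= 7,
where the exact count is reported without the add-one term). Confound
control uses sequential (type-I) ANCOVAs - covariate, then connectivity,
then interaction - with each term's F formed against the full model's
residual mean square (the hybrid convention; a pure sequential test could
instead use reduced-model residuals, and the hybrid's early terms are
mildly anti-conservative when later terms explain much variance).
Mediation by post-TMS accuracy is probed with partial correlations
(residual method, identical to the closed form; permutation p on the
residual pairing).

## Signal cleaning

Order: nuisance regression -> linear detrend -> band-pass. The GLM residualizes
each voxel on an intercept plus 13 recorded confound series (6 rigid-body
motion, 4 white-matter, 3 CSF); any component linear in those columns is
removed exactly. Detrending removes the per-voxel best-fit line. The
band-pass is a Chebyshev Type 1 design, order 8, passband 0.01-0.1 Hz,
1 dB ripple (the ripple is a package default, exposed as a parameter),
applied forward-backward (zero phase; effective order 16, squared magnitude
response) with reflect padding of 3x the doubled order (48 samples).
Verified: DC and 0.3 Hz probes attenuated by more than 20 dB, 0.05 Hz
retained within the doubled ripple bound, in-band phase preserved.

Two limits of this chain are worth knowing. Each pre-filter stage is an
orthogonal projection and individually idempotent, but the stages do not
commute exactly (the trend is not orthogonal to the confound columns in
sample), and zero-phase filtering does not preserve orthogonality to the
*unfiltered* confound columns, so re-running the full pipeline on its own
output changes it by up to ~20-30% in norm rather than nothing; tests pin
the exact projection properties and bound the composition. Head motion is
summarized as mean framewise displacement with rotations converted to arc
length at a 50 mm head radius.

## The synthetic cohort generator

No public dataset accompanies the analysis, so the package validates on
cohorts with the statistical structure the analysis assumes. Voxels are
grouped into equal regions (half per hemisphere); each voxel mixes
band-limited (0.01-0.1 Hz) unit-variance latents - a global signal, a
hemisphere signal, a region signal, voxel noise - plus broadband noise,
additive contamination that is linear in the recorded confound series, and
a linear trend, so that pairwise correlations are set by variance shares:
within-region r = g2 + h2 + c, same-hemisphere r = g2 + h2, cross-hemisphere
r = g2. One region pair carries a sign-flipped shared latent (negative
links). The seed map is computed from a single long (12,000-sample)
independent run of the same process, standing in for a large normative
dataset.

Defaults (tuned once so that the planted effect is recoverable at N = 20 and
recorded here; they are the package's own operating point): seed region
g2 = 0.50; informative regions g2 = 0.12; other regions g2 = 0.035 with
h2 = 0.025; weakly connected regions g2 = 0.01, h2 = 0.01 (these fall below
the 0.1 seed threshold and exercise the filter); baseline within-region
c = 0.20; informative-region coupling c_ik ~ 0.45 +/- 0.20 in the post-TMS
session, clipped to the variance budget; broadband noise SD 0.25. The
calibration oracle - the correlation between a region's planted coupling
and its recovered mean intra-hemispheric connectivity at 50 subjects -
measures 0.79-0.89 across seeds (floor observed 0.70); weaker global/
hemispheric shares were required to get there because the feature's ~180
cross-region links carry coherent sampling noise through the shared latents.

The behavioral effect is planted as g_i = sum_k w_k (c_ik - c0) + eps, with
default weights (-0.4, -0.4, -0.4, +0.4) over four informative
left-hemisphere regions and eps SD 0.02, and is mapped into bilateral
success probabilities base +/- g_i/2 around 0.475 (easy/difficult shifted
by +/-0.15) so the expected per-subject accuracy difference equals g_i;
realized accuracies add binomial noise from the 64 bilateral trials per
condition. The informative couplings are drawn with between-region
correlation +0.6 (same effect sign) / -0.5 (opposite sign): this is the
regime in which each region also carries a strong marginal association with
the summed effect - with independent couplings each region's marginal
correlation is capped near 0.5 regardless of effect size and a sparse
model can explain the response with a single region, making consistent
multi-region selection unidentifiable at N = 20.

Sham and resting sessions draw informative-region couplings independently
of behavior (wider, SD 0.30, independent across regions) and add a
one-sided subject-level common mode on hemispheric coupling (half-normal,
SD 0.15). Exact joint nullity of the sham and TMS-minus-sham feature tables
is impossible - cov(y, f_tms) = cov(y, f_sham) + cov(y, f_diff) - so the
generator keeps sham strictly independent of behavior and inflates its
behavior-independent variance until the difference condition's residual
signal sits near the scan's null level. At this operating point, 50-cohort
simulations give: post-TMS condition significant in ~90-95% of cohorts with
the consistency intersection recovering a median of >= 3 of the 4 planted
regions with correct signs, and sham/difference conditions flagged at
~0.1-0.2, against the measured family-wise null rate of ~0.10.

What the generator does *not* emulate: hemodynamic response shapes, spatial
smoothness and anatomy, physiological rhythms aliasing into the band,
distance-dependent connectivity, or session-to-session registration error.
Passing tests therefore demonstrate that the inference chain recovers
effects of the assumed form at realistic dimensions and noise - not that it
would detect effects in any particular real acquisition.

## Numerical conventions and degenerate inputs

- Percentiles: linear interpolation between order statistics.
- Seed threshold comparison inclusive (|r| >= 0.1).
- Negative-link deletion: zeroed with the full link count as denominator
  (default) or dropped from the denominator (`drop` policy); a voxel whose
  links of one class are all negative gets mean 0 under either policy.
- Fisher z rejects |r| >= 1 - 1e-10 between distinct voxels and zero-variance
  series (named by index).
- Constant feature columns inside a training fold get scale 1 and hence a
  zero coefficient; an all-zero feature table yields the intercept-only model
  at every lambda.
- lambda* ties resolve toward the larger lambda; alpha = 0 is routed to the
  ridge closed form rather than coordinate descent.
- Permutation draws come from numpy's default generator seeded explicitly;
  all reported p-values are bitwise reproducible given the seed.
- Cohort determinism: a config seed fixes every array bitwise; per-condition
  substreams let a subset of sessions be generated without changing shared
  draws.

## Problem sizes used in the test suite

Simulation-based checks run at the defaults (20 subjects, 400 voxels, 781
task volumes) for recovery and condition-pattern tests (50 replicate
cohorts), at 100 voxels for type-I-error calibration (200 replicates), and
at 40-80 voxels for unit tests; permutation tests use B = 1,000 in
simulations and B = 100,000 in single-cohort runs. These sizes were chosen
so the full suite exercises the study-scale configuration while remaining
routinely runnable.

## Known limitations

- The preselection default mirrors the original single-sample design
  (outside cross-validation). The density filter uses group means of the
  features only, so no behavioral leakage arises, but fold-wise feature
  means do differ slightly from the full-sample means.
- The condition-level significance call aggregates ten unadjusted tests;
  its family-wise null rate (~0.10) exceeds the per-test level by design,
  matching the original reporting convention.
- The sequential-ANCOVA hybrid error term makes early (covariate) terms
  anti-conservative when connectivity explains much variance; conclusions
  about the connectivity term given covariates are unaffected.
- With 20 interchangeable voxels per synthetic region, which voxel of a
  region enters a sparse model is arbitrary; recovery is therefore assessed
  at region level (any voxel of the region, correct sign).
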