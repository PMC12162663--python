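# Methods

## The measurement model

The DTI-ALPS index rests on a geometric fact about the periventricular
white matter: at the body of the lateral ventricle, medullary vessels
and their perivascular sheaths run along the left–right (x) axis,
orthogonal to both the projection fibers (inferior–superior, z) and
the association fibers (anterior–posterior, y). Water displacement
along x inside those tracts is therefore dominated by perivascular
flow rather than axonal geometry, and the ratio

ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

isolates it: the numerator collects x-diffusivities where x is
cross-fiber, the denominator collects the matching cross-fiber
diffusivities unaffected by perivascular flow. Dyy_assoc and Dzz_proj
(the along-fiber diffusivities) are extracted and reported but never
enter the ratio. All Dij are *diagonal tensor elements in image axes*,
not eigenvalues — the index is deliberately axis-referenced, which is
why the package assumes RAS-aligned image axes and image-space bvecs.

## Phantom

The phantom realizes this geometry in a canonical, registration-free
space: axis-aligned boxes on a 32×32×16 grid of 2-mm isotropic voxels
(large enough to hold 5-mm ROIs, small enough for second-scale tests).
Tissue tensors are:

| region | tensor (10⁻³ mm²/s) |
| --- | --- |
| projection tracts | diag(λ⊥ + α, λ⊥, λ∥) |
| association tracts | diag(λ⊥ + α, λ∥, λ⊥) |
| ventricle | 3.0 · I (CSF) |
| background | 0.8 · I |

with defaults λ∥ = 1.05, λ⊥ = 0.46 — magnitudes chosen to echo
published periventricular diffusivities, treated throughout as
10⁻³ mm²/s (μm²/ms); the clinical literature frequently omits these
units. The perivascular boost α ≥ 0 is the ground-truth glymphatic
parameter: by construction the analytic index is (λ⊥ + α)/λ⊥, so
α = 0 forces ALPS = 1 exactly, and the index is strictly increasing
in α. Signals follow Stejskal–Tanner attenuation
s = s₀·exp(−b·gᵀDg). Noise is Rician by default (physically correct
for magnitude MR images, positively biased at low SNR), with Gaussian
available for analytically clean tests; SNR is s₀/σ on the b0 volume.

Gradient schemes are single-shell (default 32 directions at
b = 1000 s/mm² plus one b0), constructed by seeded
electrostatic-repulsion relaxation with antipodal symmetry. Six
directions is the admissibility floor (the 7-parameter tensor design
must have full rank).

What the phantom does **not** emulate: brain anatomy and registration
(tracts are pre-aligned boxes), partial-volume mixing at tissue
borders beyond voxel quantization, eddy/motion/susceptibility
artifacts, multi-shell or non-Gaussian diffusion. Passing tests
therefore demonstrate correctness of the measurement chain under the
stated signal model, not robustness to real-scanner artifacts.

## Tensor fit

Per-voxel ordinary least squares on log-signals against the
7-parameter design (log s₀ + 6 unique tensor components), solved with
one pseudo-inverse applied to all voxels. Signals at or below
`min_signal` (default 10⁻⁶ × mean b0) are clamped and the voxel
flagged invalid — never dropped, so maps stay rectangular. OLS inverts
noise-free data exactly; at the default acquisition the per-voxel
precision is noise-limited, not estimator-limited: the
generalized-least-squares bound for Dxx at SNR 30 is a standard error
of 0.045·10⁻³ mm²/s (≈ 4.2% median absolute error at a tract voxel),
and measured OLS error is 4.2–4.3%. Weighted LS was evaluated and
buys nothing here, so OLS is kept for its exact-inversion property;
the solver is isolated behind `fit_tensor` as a swap point. ROI
averaging (5 voxels per disc, 4 ROIs, 2 hemispheres) is what brings
the end-to-end index error down to ~0.01–0.03.

No negative-eigenvalue repair is applied beyond clamping FA inputs at
zero (with the voxel flagged): the index reads fitted diagonals, and
silently repairing them would bias exactly the quantity of interest.

## ROI protocol

Four 5-mm-diameter ROIs, one per fiber type per hemisphere, on a
single axial slice. A voxel belongs to a ROI if its center lies within
diameter/2 mm of the ROI center in-plane — at 2-mm voxels this is the
5-voxel plus-shape. No partial-volume weighting.

Manual radiologist adjustment is operationalized deterministically:
each projection ROI center moves to the centroid of voxels strictly
above the window-median of the blue color-FA channel (z-dominant
fibers) within a square in-plane search window; association ROIs use
the green channel. A constant window (nothing strictly above its
median) leaves the center in place. Centroids are rounded half-up;
ties and all arithmetic are deterministic, so two runs of the
"same rater" agree exactly. The refinement recovers the cross-tract
coordinate; positions along the tract's long axis are equivalent by
construction and not disambiguated.

The bilateral index defaults to computing the index per hemisphere and
averaging (preserving hemisphere-level reporting); pooling the six
means across hemispheres first is available as `pool_bilateral`. The
two agree exactly on left–right-symmetric input.

## Inter-rater agreement

ICC(2,1): two-way random-effects, absolute agreement, single measures,
computed from the two-way ANOVA mean squares, with the F-based 95% CI
(McGraw & Wong). This model fits the design — a fixed panel of raters
each rating every subject once, where calibration offsets between
raters should count against agreement. Zero between-subject variance
makes the coefficient undefined; it is reported as 0 with a degenerate
flag and a warning. Zero residual variance (e.g. one rater a constant
offset of the other) is handled by the analytic limit of the CI
formulas rather than floating-point division.

## Cohort generator

Three groups — healthy controls (one visit) and true/sham treatment
arms (pre/post) — with per-group sizes defaulting to 20/28/9. Each
subject draws a perivascular α from its group distribution; group
means map to ALPS levels of about 1.67 (HC), 1.45 (true arm), 1.39
(sham arm) via α = λ⊥(ALPS−1), with the true arm's post-treatment
mean shifted up by 0.06 in α (≈ +0.13 in ALPS) and sham unchanged.
Post values are pre values plus the group shift plus small
within-subject noise, giving the paired tests realistic correlation.

Two polysomnography fields are generated *from* the subject's true
index: N2 sleep duration = group mean + 120·(ALPS − group ref) +
N(0, 30) minutes, and arousal index = group mean − 25·(ALPS − ref) +
N(0, 5) events/h. These slopes give within-group correlations of
roughly +0.55 and −0.65 — strong enough that the designed signal is
recoverable at cohort scale, weak enough that selection against six
null covariates is non-trivial. Every other covariate (demographics,
questionnaires, remaining PSG fields) is drawn independently of ALPS
from group-specific normal distributions with means/SDs at
clinically plausible levels, clipped to valid ranges (percentages to
[0,100], durations and scores to ≥ 0). The generator is a
linear-Gaussian construction: it reproduces the correlational
structure a regression analysis consumes, not sleep physiology.

When imaging is enabled each visit also gets a phantom (α as drawn)
and a simulated DWI volume; otherwise the observed `alps` column is
alps_true + N(0, 0.02) measurement noise, standing in for fit/rater
variability at a magnitude matching the end-to-end pipeline error.

## Statistics ladder

- Three-group comparisons: one-way ANOVA (scipy) with Tukey HSD
  adjusted pairwise p (statsmodels); Pearson χ² without continuity
  correction for categorical variables. Identical groups (F = 0/0)
  report the no-effect limit F = 0, p = 1.
- Univariate screen: per-candidate simple OLS of the index, patients
  only at baseline; flag at p < 0.2; zero-variance candidates skipped
  with a warning. No multiple-testing correction is applied across
  the screen (none is standard at this stage); reports say so.
- Backward elimination at p-removal 0.1: refit, drop the candidate
  with the largest p ≥ 0.1, repeat. Adjustment covariates (model I:
  gender, age; model II: gender, age, education, and the cognitive /
  sleep questionnaires) are forced — never candidates for removal;
  the crude model forces nothing. Ties within 10⁻¹² of the maximal p
  drop the candidate declared later, making the trace deterministic.
  Designs with standardized condition number above 10⁸ are rejected
  naming the most correlated columns. Gender enters as a 0/1
  indicator with male as reference.
- Paired pre/post t tests per arm, subjects missing a timepoint
  excluded and counted. All-identical differences are reported as
  degenerate (t = 0, p = 1 when the common difference is zero) rather
  than propagating 0/0.
- The crude "model" of the regression report is the backward
  elimination run without forced covariates (per-variable univariate
  estimates appear separately in the screen table); printed
  regression output keeps full precision rather than rounded
  coefficients.

## Determinism and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline driver writes a manifest of
SHA-256 checksums, and identical config + seed reproduces identical
checksums (NIfTI outputs are written uncompressed to keep byte
identity independent of compression metadata). Validation problem
sizes — 50 replicates per recovery level, 200 simulated cohorts for
selection characteristics at 150 patients, 1000–2000 replicates for
null calibration — were chosen to put Monte-Carlo error well below
the margins being asserted while keeping a full validation run in the
order of a minute on one CPU.

## Known limitations

- Axis-aligned geometry means the phantom cannot probe errors from
  oblique acquisitions or imperfect registration, which are real
  failure modes of the index in practice.
- The OLS fit reports fitted (possibly negative) diagonals under
  extreme noise; downstream positivity checks reject such ROIs rather
  than repairing them.
- The ICC CI formula is asymptotic in the ANOVA framework; very small
  panels (the minimum 3 subjects × 2 raters) give wide, approximate
  intervals.
- Backward elimination inherits the usual caveats of stepwise
  selection (post-selection inference is not corrected); the package
  reproduces the procedure, it does not endorse it.
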