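# Methods

This note documents the models implemented in `atrograd`, their
assumptions, the defaults of the synthetic cohort generator, and the
numerical and design choices a user should know before interpreting
results.

## Normative atrophy scoring

Per region, gray-matter volume is modeled by ordinary least squares on
covariates (default: age, sex, and a total-intracranial-volume proxy —
the exact normative covariate set is a user choice). The residual SD uses
the n − p − 1 denominator. The W-score of a new subject is
(estimated − actual)/SD, i.e. *atrophy-positive*: larger W means more
tissue loss. The opposite sign convention is available via a flag;
atrophy-positive is the default because downstream coverage rules
threshold atrophy as W > 1.5. W-scores are invariant to affine rescaling
of any covariate column (the refit absorbs it). Regions with numerically
zero residual SD are flagged degenerate and produce NaN scores rather
than infinities.

Calibration caveat: with a held-out normative cohort of size m, each
region's mean W has irreducible sampling SD of about 1/√m plus a
reference-fit contribution of about 1/√n_ref; at m = 500 this is ≈ 0.05,
so the "per-region |mean W| < 0.1" calibration check is a roughly
2-sigma criterion per region and is run at a fixed seed with a large
(n = 2000) reference.

## Scanner harmonization

A location-and-scale batch adjustment in the ComBat family, without the
empirical-Bayes shrinkage step: per feature, OLS on biological covariates
plus batch indicators; residuals standardized by the pooled SD; per-batch
additive shifts and multiplicative scales estimated on the standardized
data and removed; covariate-linked variance restored. The estimator is
deterministic and idempotent (to 1e-8) and is applied identically to
W-score vectors and to vectorized gradient-covariance/FC features. EB
shrinkage matters when batches are small relative to the feature count;
at the cohort sizes used here the plain estimator is adequate.

## Gradient space

The gradient basis is the PCA of temporally concatenated regional BOLD
timeseries from a reference cohort. Columns (regions) are mean-centered
per scan before concatenation; no variance scaling is applied, because
the loadings' amplitude information is interpreted downstream (gradient 1
variance tracks global signal amplitude). Projection always uses the bare
orthonormal eigenvectors, so scores are unaffected by the loading
convention; displayed weight maps are eigenvector × √eigenvalue. Signs
are fixed so each component's largest-|weight| region is positive;
gradient 1 is additionally forced all-positive when its negative weights
carry under 1% of squared mass (this clips the subspace at the ~1e-4
level — the price of the unipolar display convention).

FC reconstruction from gradient covariance is exact with the full
component set (`V · C · Vᵀ`, then correlation normalization) and a
low-rank approximation with K components; both pathways are implemented.
The full set feeds FC reconstruction and harmonization; the truncated
K = 6 set feeds the dynamics stage.

Scan QC applies two fixed-order rules: mean framewise displacement
strictly above 0.55 mm excludes a scan; then a PCA across the survivors'
vectorized FC matrices excludes scans whose first-component score exceeds
the mean by more than one SD. Stage 2 is skipped with a warning below
three scans.

## PLSR structure–function linking

NIPALS PLS2 with Y-deflation (scikit-learn's `PLSRegression`,
`scale=False`): X (atrophy W-scores) and Y (FC upper-triangle edges,
fixed i<j row-major order) are centered, not variance-scaled — regional
W-scores share units, and scaling would break the interpretation of
component 1 as overall mean atrophy. Component signs are fixed so S1
correlates positively with mean atrophy and components 2+ have a positive
largest-|weight| region. Function scores are the Y-scores from the fit; a
ridge-predicted variant (edges → Y-scores, penalty by inner 3-fold CV
over a log grid 1e-2…1e4) is used for cross-validation and for the
behavior models. Out-of-sample coupling is summarized as the correlation
of held-out structure scores with ridge-predicted function scores over
4 folds.

Per-term "variance explained" in a function component by the 21 gradient
terms (6 variances, 15 covariances) is the squared semi-partial
correlation — the R² drop when the standardized term is removed from the
full regression — with signed t statistics from the full model.

## Coupled-oscillator eigenmode model

First and second derivatives of each gradient timeseries come from the
standard second-order `gradient` stencil (central differences interior,
one-sided ends); applying it twice gives the second derivative, whose
frequency response is −sin²ω. Each gradient's second derivative is
regressed on all K gradients' levels and velocities plus an intercept
(2K + 1 terms, K independent OLS fits). The companion matrix uses blocked
state ordering (positions, then velocities); eigenvector gradient
components are read from the position block, with each eigenvector kept
at unit 2-norm over the full state and rotated so its dominant position
entry is real-positive (a global phase that affects neither amplitudes
nor pair angles).

Of the 2K eigenpairs, the positive-frequency member of each conjugate
pair is kept; real eigenvalues yield zero-frequency modes flagged
non-oscillatory and excluded from phase-angle computation. Modes are
ordered by ascending frequency; β converts to hertz as β/(2π·TR).

Cumulative amplitude per gradient is Σ_m √((−a+b)² + (a+b)²) over modes
(a, b the real and imaginary parts of the gradient's component). Pair
phase angles are computed per oscillatory mode as the difference of
component arguments and combined as a circular mean weighted by the
product of the two gradients' per-mode amplitudes, then reported as a
magnitude folded into [0°, 180°] (90° = temporal orthogonality); pairs
with zero total weight return NaN with a flag rather than raising.

Mode-based simulation superposes all 2K eigenpairs with unit constants
by default (or constants solved from explicit initial conditions), which
keeps trajectories real. The damping policy defaults to zeroed-α for
stationary FC simulation — damped modes decay and give degenerate
long-horizon FC — with the as-fitted policy available for short-horizon
reconstruction. Group-level modes are fit to concatenated, per-subject-
centered member timeseries.

### Identifiability of damping under stationary forcing

For any stationary differentiable process, cov(ẍ, ẋ) = 0 (the cross
spectrum is odd), so the OLS fit of acceleration on positions and
velocities assigns velocity coefficients near zero no matter the true
damping: a stationary trajectory does not decay, and the best-fit linear
ODE on the attractor is undamped. The same cancellation appears for the
discrete per-step forcing through the equal-time noise–velocity
correlation of symmetric-difference estimators. Consequences built into
the package's defaults:

* fitted damping is interpreted as a deviation measure, not an estimate
  of the generative damping; recovery claims for damping are absolute
  (±0.02/sample), honest only because the generator is lightly damped;
* the generator's base damping is c = 0.015/sample (α = 0.0075; envelope
  decay time ≈ 130 samples ≈ 4.4 min at TR = 2 s), keeping modes
  oscillatory and the damping deviation within that band;
* base natural frequencies are 0.14–0.25 rad/sample (0.011–0.020 Hz at
  TR = 2 s), below the regime where the −sin²ω stencil bias (≈ ω²/6
  relative) exceeds 1–2%.

Colored (band-passed) forcing was evaluated and rejected: it correlates
with the state and biases the OLS fit far more than white forcing, which
is the closest discrete analogue of the consistent continuous-time case.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
not raw MRI. What it plants:

* **Atrophy**: three unit-norm spatial components (component 1 global and
  all-positive; 2 and 3 orthogonal signed contrasts). Subject scores:
  component 1 severity is half-normal |N(0,1)| for patients (disease
  severity is non-negative), components 2/3 standard normal; controls
  draw all scores from N(0, 0.05). Pattern amplitudes (6.0, 2.2, 1.2)
  W-score units per unit score make component 1 carry roughly half the
  atrophy variance, as in real AD/FTD cohorts, and keep components 2/3
  separable (with near-equal amplitudes their principal axes are
  rotation-degenerate and unrecoverable in principle). Per-region
  observation noise SD 0.2 (structure SNR ≈ 2:1).
* **Volumes**: expressed through the normative pathway — covariate
  prediction minus atrophy × residual SD — plus a two-scanner batch
  structure (location/scale on volumes, amplitude scale on BOLD), so the
  W-score and harmonization stages are exercised end to end.
* **Function scores**: f = s + N(0, 0.5) (structure→function SNR 2:1);
  the dynamics links are driven by f, so structure and function are
  coupled but not identical.
* **Dynamics links**: each gradient has a gain that scales both its
  stochastic forcing and its receiver-side coupling participations —
  this is what makes eigenmode amplitude and temporal variance co-vary
  across subjects (forcing alone changes variance but leaves the fitted
  coupling matrix, hence the amplitudes, untouched). f1 lowers gradient
  1's gain and pulls the gradient 1–4 angle below 90° (slope 12°/unit);
  f2 lowers gradient 3's gain and pushes the gradient 1–2 angle down
  (8°/unit); f3 raises gradient 2's gain and pushes the gradient 1–2
  angle up (12°/unit). Background jitter (gain SD 0.2 log-scale,
  frequency SD 0.02 log-scale, angle SD 10° on all remaining pairs) gives
  every gradient and pair across-subject variation.
* **Angle planting** is exact and closed-form: coupling receiver g to
  source h through κ_s G_h + κ_v G_h′ leaves the source's eigenvalue
  unchanged (the coupling graph is kept triangular) and sets the
  receiver's complex eigenvector component on the source's mode to
  (κ_s + κ_v λ_h)/(λ_h² + c_g λ_h + ω_g²); choosing the complex direction
  of κ_s + κ_v λ_h hits any target angle exactly, with magnitude set by a
  participation ratio (0.5 for planted links, 0.25 for jitter).
* **Integration**: exact one-sample propagation through the matrix
  exponential of the companion system, with white Gaussian velocity kicks
  per step and a 500-sample burn-in; noise-free runs match the analytic
  mode solution to machine precision.
* **Cognition**: linear plus optional quadratic functions of S1–S3/F1–F3
  with Gaussian noise (SD 1) and optional missingness; the default
  battery includes a global-severity test, a global-cognition test with a
  quadratic (U-shaped) term on S3, and memory/executive tests.

What the generator does *not* emulate: voxel-level structure, hemodynamic
convolution, physiological noise spectra, motion artifacts (mean FD is
drawn, not derived), site-specific frequency content, or nonlinear
neural dynamics. Passing recovery tests therefore demonstrates that the
analysis chain is correct and well-calibrated under its own assumptions —
linear dynamics, additive noise, planted low-rank structure — not that it
is robust to the full complexity of real MRI.

## Statistical modules

Brain–behavior models use regression splines with basis dimension capped
at 3 per brain term (spline basis from statsmodels' `BSplines`, degree 2)
and strictly linear covariates, fit unpenalized: with so small a basis
the cap itself limits wiggliness, and the unpenalized fit allows exact
partial F tests (verified type-I ≤ 5% + Monte-Carlo error at n = 300) and
an exact nested-model F for each term's nonlinear part. A test is skipped
when fewer than 120 responses are present (configurable). With basis
dimension 1 the model reproduces OLS exactly. FDR control is
Benjamini–Hochberg at q = 0.05, pooled over the analysis family
(tests × brain terms; family size configurable); NaN p-values are
excluded and flagged.

## Evaluation experiment sizes

`scripts/acceptance.py` and `tests/test_acceptance.py` run the recovery
experiments at: 50 random scans (R = 40, T = 500) for the FC identity;
T = 8000, forcing SD 0.05 for system identification; 200-subject cohorts
(T = 1200 in gradient space) for the amplitude/angle correspondence, 20
replicates; 10 seeds × 4 angle steps for phase collapse; 200-subject,
80-region, T = 400 cohorts for PLSR recovery (20 replicates in the test
suite, 10 in the script); 200 replicates at n = 300 for behavior
calibration; and 200 replicates of m = 144 p-value families for FDR
control. These sizes make each experiment's Monte-Carlo error small
relative to its acceptance margin while keeping the full suite inside a
few minutes on one CPU.
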