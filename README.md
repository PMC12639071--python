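# atrograd

Structure–function analysis of neurodegenerative atrophy cohorts: normative
W-score atrophy maps, low-dimensional activity gradients, partial least
squares linking of atrophy to brain-wide functional connectivity, and a
coupled damped-oscillator eigenmode model that explains hypo- and
hyper-connectivity as gradient amplitude loss and phase-angle collapse.

## Who this is for

Researchers studying how regional gray-matter atrophy (Alzheimer's disease
and frontotemporal dementia syndromes) reshapes resting-state functional
connectivity (FC), and anyone who wants a tested, fully synthetic sandbox
for that analysis chain. No patient data are required: a first-class cohort
generator plants known atrophy components, dynamics, and cognition so every
stage can be validated by parameter recovery.

## The models

**Atrophy.** Regional gray-matter volume is referenced to a normative OLS
model over covariates (age, sex, intracranial volume proxy); the W-score is
the deviation in units of the normative residual SD, stored
atrophy-positive:

    W = (estimated − actual) / SD_normative

A region is "affected" in a syndrome when five or more patients show
W > 1.5. Scanner differences are removed with a location–scale (ComBat
family, non-empirical-Bayes) harmonization that preserves covariate-linked
variance.

**Gradients.** PCA of region-averaged BOLD timeseries yields spatial
*gradients* (region weight maps; gradient 1 is unipolar) and their temporal
scores. FC is recoverable exactly from the full gradient covariance:
`cov(regions) = V · cov(gradients) · Vᵀ` with `V` the eigenvector matrix —
the package verifies this identity to 1e-10.

**Structure–function linking.** PLSR decomposes atrophy maps (X) into
components maximally covarying with vectorized FC edges (Y), giving paired
structure scores S1–S3 and function scores F1–F3, cross-validated function
scores via ridge regression, syndrome-typical subsets by LDA, and a
decomposition of each function component into 6 gradient variances + 15
covariances.

**Oscillator eigenmodes.** Each gradient's acceleration is regressed on all
gradients' levels and velocities (`G″ = β₀ + Σ β_G G + Σ β_G′ G′`); the
system `dY/dt = AY` is eigendecomposed into damped oscillatory modes
(eigenvalue α + iβ: damping and angular frequency; complex per-gradient
components: amplitude and phase). Per subject the package computes each
gradient's cumulative amplitude `Σ_m √((−a+b)² + (a+b)²)` and each pair's
cumulative phase angle (amplitude-weighted circular mean of eigenvector
phase differences, folded into [0°, 180°]; 90° = temporal orthogonality).
Angle collapse away from 90° produces simultaneous hypo-/hyper-connectivity
with a predictable sign structure.

**Brain–behavior.** Cognitive scores are fit by additive models on S1–S3 and
F1–F3 (regression splines capped at basis dimension 3, linear covariates),
with per-term F tests, nonlinearity tests, and Benjamini–Hochberg FDR over
the analysis family.

## Worked example

```python
import numpy as np
from atrograd import synthetic as syn, atrophy as atr, oscillator as osc
from atrograd import structure_function as sf
from atrograd.gradients import pearson_fc, project_to_gradients

cfg = syn.CohortConfig(n_subjects=200, n_controls=50, n_regions=80,
                       n_timepoints=400, seed=11)
cohort = syn.generate_cohort(cfg)

# atrophy stage: normative model -> W-scores -> scanner harmonization
nm = atr.fit_normative_model(cohort.normative_volumes, cohort.normative_covariates)
w = atr.compute_w_scores(cohort.volumes, cohort.covariates[["age", "sex", "tiv"]], nm)
design = np.column_stack([cohort.covariates["age"], cohort.covariates["sex"],
                          (cohort.covariates["group"] == "patient").astype(float)])
w = atr.harmonize_location_scale(w, cohort.covariates["batch"].to_numpy(), design)

# structure-function stage: PLSR of W-scores against FC edges
edges = np.array([sf.vectorize_fc(pearson_fc(s.values)) for s in cohort.scans])
model = sf.fit_plsr(w.to_numpy(), edges, n_components=3)
print("explained atrophy variance:", np.round(model.explained_x_variance, 3))
print("in-sample r(S, F):        ", np.round(model.score_correlations, 3))

# dynamics stage: fit the most atrophic subject's oscillator model
i = int(np.argmax(cohort.ground_truth.structure_scores[:, 0]))
gts = project_to_gradients(cohort.scans[i], cohort.ground_truth.basis)
modes = osc.eigenmodes_of(osc.fit_coupling(gts))
print("mode frequencies (Hz):    ", np.round([m.frequency_hz for m in modes], 4))
angles, _ = osc.pair_phase_angles(modes)
print("G1-G4 angle (deg):        ", round(angles[0, 3], 1))
```

Output:

```
explained atrophy variance: [0.584 0.147 0.064]
in-sample r(S, F):          [0.43  0.536 0.334]
mode frequencies (Hz):      [0.0111 0.0127 0.0145 0.017  0.0179 0.0218]
G1-G4 angle (deg):          67.4
```

The first structure–function component carries more than half of the
atrophy variance (it tracks overall mean atrophy), the three components'
structure and function scores correlate in-sample, and the most atrophic
patient shows a gradient 1–4 phase angle collapsed well below 90° — the
signature that raises FC between sign-aligned region pairs and lowers it
between opposed pairs.

A thin CLI covers the batch steps:

```bash
atrograd simulate-cohort --out cohort/ --seed 1
atrograd wscore-fit cohort/normative_volumes.tsv cohort/normative_covariates.tsv --out norm.json
atrograd gradients-derive cohort/scans --out basis.tsv --k 6
atrograd modes-fit gts.tsv --out coupling.json
atrograd modes-summarize coupling.json
```

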