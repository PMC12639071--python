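import numpy as np
import pytest

from atrograd import synthetic as syn


@pytest.fixture(scope="session")
def base_model():
    return syn.base_coupling_model(6)


@pytest.fixture(scope="session")
def small_basis():
    return syn.generate_gradient_basis(40, 6, seed=2)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact full cohort shared by integration-style tests."""
    cfg = syn.CohortConfig(
        n_subjects=60, n_controls=15, n_regions=40, n_timepoints=500, seed=7
    )
    return syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def plsr_cohort():
    """Recovery-scale cohort for structure-function tests."""
    cfg = syn.CohortConfig(
        n_subjects=200, n_controls=50, n_regions=80, n_timepoints=400, seed=13
    )
    return syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def plsr_fit(plsr_cohort):
    """(PLSRModel, harmonized W array, edge matrix) for the recovery cohort."""
    from atrograd import atrophy as atr
    from atrograd import structure_function as sf
    from atrograd.gradients import pearson_fc

    cohort = plsr_cohort
    nm = atr.fit_normative_model(cohort.normative_volumes,
                                 cohort.normative_covariates)
    w = atr.compute_w_scores(cohort.volumes,
                             cohort.covariates[["age", "sex", "tiv"]], nm)
    design = np.column_stack([
        cohort.covariates["age"], cohort.covariates["sex"],
        (cohort.covariates["group"] == "patient").astype(float),
    ])
    w_h = atr.harmonize_location_scale(
        w, cohort.covariates["batch"].to_numpy(), design
    ).to_numpy()
    edges = np.array([sf.vectorize_fc(pearson_fc(s.values))
                      for s in cohort.scans])
    model = sf.fit_plsr(w_h, edges, n_components=3)
    return model, w_h, edges


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
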