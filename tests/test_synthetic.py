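"""Generator contracts: basis geometry, oscillator construction, links."""

import numpy as np
import pytest

from atrograd import oscillator as osc
from atrograd import synthetic as syn
from atrograd.gradients import GradientTimeseries


class TestGradientBasis:
    def test_orthonormal_columns(self):
        basis = syn.generate_gradient_basis(4, 2, seed=1)
        v = basis.eigenvectors
        assert v.shape == (4, 2)
        assert abs(v[:, 0] @ v[:, 1]) < 1e-12
        assert np.allclose(np.linalg.norm(v, axis=0), 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_gradient_one_unipolar_and_dominant(self, seed):
        basis = syn.generate_gradient_basis(50, 6, seed=seed)
        assert np.min(basis.eigenvectors[:, 0]) > 0
        # loadings (weights) have strictly decreasing column norms
        norms = np.linalg.norm(basis.weights, axis=0)
        assert np.all(np.diff(norms) < 0)
        # columns beyond the first carry both signs
        for k in range(1, 6):
            col = basis.eigenvectors[:, k]
            assert (col > 0).any() and (col < 0).any()

    def test_deterministic(self):
        a = syn.generate_gradient_basis(30, 4, seed=5)
        b = syn.generate_gradient_basis(30, 4, seed=5)
        np.testing.assert_array_equal(a.eigenvectors, b.eigenvectors)

    def test_dimension_error(self):
        with pytest.raises(ValueError):
            syn.generate_gradient_basis(3, 5, seed=0)


class TestBuildCoupling:
    def test_undamped_closed_form(self):
        m = syn.build_coupling_matrix([0.2], [0.0])
        (mode,) = osc.eigenmodes_of(m)
        assert mode.eigenvalue == pytest.approx(0.2j, abs=1e-12)

    def test_damped_quadratic_roots(self):
        # lambda = (-c +- sqrt(c^2 - 4 w^2)) / 2
        m = syn.build_coupling_matrix([1.0], [0.2])
        (mode,) = osc.eigenmodes_of(m)
        assert mode.damping == pytest.approx(-0.1, abs=1e-10)
        assert mode.angular_frequency == pytest.approx(np.sqrt(0.99), abs=1e-10)

    def test_overdamped_rejected(self):
        with pytest.raises(ValueError, match="overdamped"):
            syn.build_coupling_matrix([0.1], [0.3])

    def test_cross_term_changes_only_receiver_row(self):
        m0 = syn.build_coupling_matrix([0.2, 0.3], [0.01, 0.01])
        m1 = syn.build_coupling_matrix(
            [0.2, 0.3], [0.01, 0.01], {(0, 1): (0.05, 0.01)}
        )
        diff = m1.coefficients - m0.coefficients
        assert np.any(diff[0] != 0)
        assert np.all(diff[1] == 0)


class TestSimulate:
    def test_undamped_sine_matches_analytic(self):
        m = syn.build_coupling_matrix([0.2], [0.0])
        gts = syn.simulate_gradient_timeseries(
            m, 300, forcing_sd=0.0, initial_state=np.array([0.0, 0.2])
        )
        t = np.arange(300)
        rmse = np.sqrt(np.mean((gts.values[:, 0] - np.sin(0.2 * t)) ** 2))
        assert rmse < 1e-3

    def test_damped_envelope(self):
        # c = 0.2 -> envelope exp(-0.1 t)
        m = syn.build_coupling_matrix([1.0], [0.2])
        gts = syn.simulate_gradient_timeseries(
            m, 200, forcing_sd=0.0, initial_state=np.array([1.0, -0.1])
        )
        beta = np.sqrt(0.99)
        t = np.arange(200)
        expected = np.exp(-0.1 * t) * np.cos(beta * t)
        assert np.max(np.abs(gts.values[:, 0] - expected)) < 1e-6

    def test_forced_deterministic_under_seed(self, base_model):
        a = syn.simulate_gradient_timeseries(base_model, 200, 0.05, seed=3)
        b = syn.simulate_gradient_timeseries(base_model, 200, 0.05, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unstable_model_warns(self):
        m = syn.build_coupling_matrix([0.2], [0.0])
        coeff = m.coefficients.copy()
        coeff[0, 2] = 0.05  # positive velocity feedback: growth
        bad = osc.CouplingModel(coeff)
        with pytest.warns(UserWarning, match="unstable"):
            syn.simulate_gradient_timeseries(bad, 50, forcing_sd=0.01, seed=0)

    @pytest.mark.parametrize("seed", [1, 3, 6])
    def test_forced_simulation_is_stationary(self, base_model, seed):
        """Split-half variance ratio stays near 1 for stable forced runs."""
        gts = syn.simulate_gradient_timeseries(
            base_model, 6000, forcing_sd=syn._BASE_FORCING, seed=seed
        )
        half = 3000
        ratio = gts.values[:half].var(axis=0) / gts.values[half:].var(axis=0)
        geo = np.exp(np.mean(np.log(ratio)))
        assert 0.8 < geo < 1.25


class TestRenderBold:
    def test_noise_free_round_trip(self, base_model, small_basis):
        from atrograd.gradients import project_to_gradients

        gts = syn.simulate_gradient_timeseries(base_model, 400, 0.05, seed=1)
        gts.values -= gts.values.mean(axis=0)
        scan = syn.render_bold(gts, small_basis, region_noise_sd=0.0)
        back = project_to_gradients(scan, small_basis, center=False)
        assert np.max(np.abs(back.values - gts.values)) < 1e-10

    def test_unipolar_column_gives_positive_correlations(self):
        basis = syn.generate_gradient_basis(20, 2, seed=0)
        t = np.linspace(0, 60, 500)
        g = np.column_stack([np.sin(t), np.zeros_like(t)])
        scan = syn.render_bold(GradientTimeseries(g), basis, 0.0)
        fc = np.corrcoef(scan.values, rowvar=False)
        assert np.min(fc) > 0.99

    def test_seeded_noise_reproducible(self, base_model, small_basis):
        gts = syn.simulate_gradient_timeseries(base_model, 100, 0.05, seed=1)
        a = syn.render_bold(gts, small_basis, 0.1, seed=4)
        b = syn.render_bold(gts, small_basis, 0.1, seed=4)
        np.testing.assert_array_equal(a.values, b.values)

    def test_dimension_mismatch(self, small_basis):
        with pytest.raises(ValueError):
            syn.render_bold(GradientTimeseries(np.zeros((10, 3))), small_basis)


class TestAtrophyCohort:
    def test_noise_free_single_component(self):
        cfg = syn.CohortConfig(
            n_subjects=5, n_controls=0, n_regions=30, atrophy_noise_sd=0.0, seed=0
        )
        w, s, _ = syn.generate_atrophy_cohort(cfg)
        patterns = syn.generate_atrophy_patterns(30, 0)
        amp = np.asarray(cfg.pattern_amplitudes)
        np.testing.assert_allclose(w, (s * amp) @ patterns, atol=1e-12)

    def test_zero_scores_zero_map(self):
        cfg = syn.CohortConfig(
            n_subjects=10, n_controls=10, n_regions=20,
            atrophy_noise_sd=0.0, control_score_sd=0.0, seed=1,
        )
        w, s, is_control = syn.generate_atrophy_cohort(cfg)
        assert np.all(is_control)
        np.testing.assert_allclose(w, 0.0, atol=1e-12)

    def test_least_squares_score_recovery(self):
        cfg = syn.CohortConfig(
            n_subjects=200, n_controls=0, n_regions=100,
            atrophy_noise_sd=0.1, seed=3,
        )
        w, s, _ = syn.generate_atrophy_cohort(cfg)
        patterns = syn.generate_atrophy_patterns(100, 3)
        amp = np.asarray(cfg.pattern_amplitudes)
        shat = (w @ patterns.T) / amp
        for k in range(3):
            ss_res = np.sum((shat[:, k] - s[:, k]) ** 2)
            ss_tot = np.sum((s[:, k] - s[:, k].mean()) ** 2)
            assert 1 - ss_res / ss_tot > 0.95


class TestStructureFunctionLink:
    def test_zero_scores_identity(self, base_model):
        model, forcing = syn.apply_structure_function_link(
            np.zeros(3), syn.LinkConfig(), base_model
        )
        assert model is base_model
        np.testing.assert_array_equal(forcing, syn._BASE_FORCING)

    def test_higher_s1_lowers_g1_variance(self, base_model):
        link = syn.LinkConfig()
        variances = []
        for s1 in (0.25, 1.28):  # ~20th and 80th percentile of |N(0,1)|
            model, forcing = syn.apply_structure_function_link(
                np.array([s1, 0.0, 0.0]), link, base_model
            )
            v = []
            for seed in range(5):
                gts = syn.simulate_gradient_timeseries(
                    model, 3000, forcing_sd=forcing, seed=seed
                )
                v.append(gts.values[:, 0].var())
            variances.append(np.mean(v))
        assert variances[1] < variances[0]

    def test_high_s1_collapses_g1_g4_angle(self, base_model):
        model, _ = syn.apply_structure_function_link(
            np.array([1.5, 0.0, 0.0]), syn.LinkConfig(), base_model
        )
        ang, _ = osc.pair_phase_angles(osc.eigenmodes_of(model))
        assert ang[0, 3] < 90.0
        assert ang[0, 3] == pytest.approx(90.0 - 12.0 * 1.5, abs=1.0)

    def test_angle_target_out_of_range_rejected(self, base_model):
        with pytest.raises(ValueError, match="outside"):
            syn.apply_structure_function_link(
                np.array([10.0, 0.0, 0.0]), syn.LinkConfig(), base_model
            )

    @pytest.mark.parametrize("target", [60.0, 80.0, 109.0, 135.0])
    def test_planted_angle_hit_exactly(self, base_model, target):
        model = syn.plant_pair_angle(base_model, 0, 3, target, participation=0.5)
        ang, weight = osc.pair_phase_angles(osc.eigenmodes_of(model))
        assert weight[0, 3] > 0
        assert ang[0, 3] == pytest.approx(target, abs=1e-6)


class TestCognition:
    def _truth(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        s = rng.standard_normal((n, 3))
        return syn.GroundTruth(
            structure_scores=s, function_scores=s.copy(),
            basis=syn.generate_gradient_basis(10, 2, 0), models=[],
            forcing_sds=np.ones((n, 2)), amplitudes=np.ones((n, 2)),
            angles=np.ones((n, 1)), is_control=np.zeros(n, bool),
            batch=np.zeros(n, int),
        )

    def test_zero_coefficients_pure_noise(self):
        gt = self._truth()
        table = syn.generate_cognition(gt, [{"name": "t", "coefficients": {}}],
                                       noise_sd=1.0, seed=1)
        assert abs(np.corrcoef(table["t"], gt.structure_scores[:, 0])[0, 1]) < 0.5

    def test_unit_coefficient_noise_free(self):
        gt = self._truth()
        table = syn.generate_cognition(
            gt, [{"name": "t", "coefficients": {"S1": 1.0}}], noise_sd=0.0, seed=1
        )
        np.testing.assert_allclose(table["t"], gt.structure_scores[:, 0])

    def test_unknown_predictor_raises(self):
        gt = self._truth()
        with pytest.raises(KeyError, match="S9"):
            syn.generate_cognition(gt, [{"name": "t", "coefficients": {"S9": 1.0}}])

    def test_missing_mask(self):
        gt = self._truth(n=200)
        table = syn.generate_cognition(
            gt, [{"name": "t", "coefficients": {"S1": 1.0}, "missing_rate": 0.3}],
            noise_sd=0.0, seed=2,
        )
        frac = table["t"].isna().mean()
        assert 0.2 < frac < 0.4


class TestNormativeReference:
    def test_zero_residual_exactly_linear(self):
        vols, covs, truth = syn.generate_normative_reference(
            50, n_regions=10, seed=0, residual_sds=np.zeros(10)
        )
        design = np.column_stack([np.ones(50), covs.to_numpy()])
        np.testing.assert_allclose(
            vols.to_numpy(), design @ truth["coefficients"].T, atol=1e-9
        )

    def test_deterministic(self):
        a, _, _ = syn.generate_normative_reference(40, 5, seed=9)
        b, _, _ = syn.generate_normative_reference(40, 5, seed=9)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            syn.generate_normative_reference(10, 5, seed=0)


def test_full_cohort_deterministic():
    cfg = syn.CohortConfig(n_subjects=6, n_controls=2, n_regions=15,
                           n_timepoints=120, seed=42)
    a = syn.generate_cohort(cfg)
    b = syn.generate_cohort(cfg)
    np.testing.assert_array_equal(a.volumes.to_numpy(), b.volumes.to_numpy())
    np.testing.assert_array_equal(a.scans[3].values, b.scans[3].values)
    np.testing.assert_array_equal(a.ground_truth.angles, b.ground_truth.angles)
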