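"""Recovery and calibration experiments for the full pipeline.

Each function runs a self-contained synthetic experiment and returns the
quantities a user would inspect to judge the implementation: algebraic
identity errors, parameter-recovery errors, correspondence contrasts,
calibration rates.  They are used by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import atrophy as atr
from . import behavior as bhv
from . import gradients as gr
from . import oscillator as osc
from . import structure_function as sf
from . import synthetic as syn

__all__ = [
    "fc_identity_error",
    "eigenmode_closed_form_errors",
    "system_identification_recovery",
    "correspondence_experiment",
    "phase_collapse_curves",
    "plsr_recovery_experiment",
    "wscore_calibration",
    "qc_conformance",
    "behavior_null_calibration",
    "behavior_nonlinearity_power",
    "fdr_calibration",
]


def fc_identity_error(n_scans: int = 50, n_regions: int = 40,
                      n_timepoints: int = 500, seed: int = 0) -> float:
    """Max |FC from full gradient covariance - direct Pearson FC|."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_scans):
        mix = rng.standard_normal((n_regions, n_regions))
        data = rng.standard_normal((n_timepoints, n_regions)) @ mix
        scan = gr.RegionalTimeseries(data)
        basis = gr.derive_gradient_basis([scan], n_regions)
        cov = gr.gradient_covariance(gr.project_to_gradients(scan, basis))
        fc = gr.fc_from_gradient_covariance(cov, basis.eigenvectors)
        direct = gr.pearson_fc(data)
        worst = max(worst, float(np.max(np.abs(fc - direct))))
    return worst


def eigenmode_closed_form_errors() -> dict:
    """Companion eigenvalues vs quadratic roots; Hz conversion check."""
    worst = 0.0
    for w in (0.05, 0.2, 0.5, 1.0):
        for c in (0.0, 0.05, 0.2, 0.5):
            if c**2 >= 4 * w**2:
                continue
            model = syn.build_coupling_matrix([w], [c])
            (mode,) = osc.eigenmodes_of(model)
            expected = complex(-c / 2.0, np.sqrt(4 * w**2 - c**2) / 2.0)
            worst = max(worst, abs(mode.eigenvalue - expected))
    m = syn.build_coupling_matrix([0.2], [0.0], tr_seconds=2.0)
    (mode,) = osc.eigenmodes_of(m)
    hz_err = abs(mode.frequency_hz - 0.2 / (2 * np.pi * 2.0))
    return {"eigenvalue_error": float(worst), "hz_error": float(hz_err)}


def system_identification_recovery(
    n_timepoints: int = 8000, forcing_sd: float = 0.05, seed: int = 0,
    cross_coefficient: float = 0.03,
) -> dict:
    """Simulate a 6-gradient coupled system, refit, compare eigenmodes.

    The planted system is the base oscillator plus one position
    cross-coupling term (gradient 4 driving gradient 1).
    """
    model = syn.build_coupling_matrix(
        syn._BASE_FREQS, np.full(6, syn._BASE_DAMPING),
        {(0, 3): (cross_coefficient, 0.0)},
    )
    gts = syn.simulate_gradient_timeseries(
        model, n_timepoints, forcing_sd=forcing_sd, seed=seed
    )
    fit = osc.fit_coupling(gts)
    true_modes = osc.eigenmodes_of(model)
    fit_modes = osc.eigenmodes_of(fit)
    tf = np.array([m.angular_frequency for m in true_modes])
    ff = np.array([m.angular_frequency for m in fit_modes])
    td = np.array([m.damping for m in true_modes])
    fd = np.array([m.damping for m in fit_modes])
    return {
        "max_frequency_rel_error": float(np.max(np.abs(ff - tf) / tf)),
        "max_damping_abs_error": float(np.max(np.abs(fd - td))),
        "cross_coefficient_rel_error": float(
            abs(fit.position_block[0, 3] - cross_coefficient)
            / cross_coefficient
        ),
    }


def correspondence_experiment(
    n_subjects: int = 200, n_timepoints: int = 1200, seed: int = 0,
) -> dict:
    """Amplitude/angle vs variance/covariance correspondence, one cohort.

    Per-subject dynamics come from the generator's planted links plus
    jitter; eigenmode summaries are measured from *fitted* models and
    compared with the empirical gradient covariance statistics.
    """
    cfg = syn.CohortConfig(n_subjects=n_subjects, n_controls=0, seed=seed)
    rng = np.random.default_rng(seed)
    k = cfg.n_gradients
    iu = np.triu_indices(k, 1)
    scores = np.column_stack([
        np.abs(rng.standard_normal(n_subjects)),
        rng.standard_normal(n_subjects),
        rng.standard_normal(n_subjects),
    ])
    amps = np.empty((n_subjects, k))
    angs = np.empty((n_subjects, iu[0].size))
    vrs = np.empty((n_subjects, k))
    cvs = np.empty((n_subjects, iu[0].size))
    for i in range(n_subjects):
        model, forcing = syn.subject_dynamics(scores[i], cfg, rng)
        gts = syn.simulate_gradient_timeseries(
            model, n_timepoints, forcing_sd=forcing,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fit = osc.fit_coupling(gts)
        modes = osc.eigenmodes_of(fit)
        amps[i] = osc.cumulative_amplitude(modes)
        a, _ = osc.pair_phase_angles(modes)
        angs[i] = a[iu]
        c = np.cov(gts.values, rowvar=False)
        vrs[i] = np.diag(c)
        cvs[i] = c[iu]
    return osc.amplitude_angle_correspondence(amps, angs, vrs, cvs)


def phase_collapse_curves(
    angles: tuple = (90.0, 80.0, 70.0, 60.0),
    n_regions: int = 40, n_timepoints: int = 4000, seed: int = 0,
) -> pd.DataFrame:
    """Mean FC of sign-aligned and sign-opposed region pairs vs angle.

    A G1-G4 angle is planted at each target; FC comes from a forced
    simulation rendered through a synthetic basis.  Pairs are classified
    by the sign of the covariance bracket v1_i*v4_j + v4_i*v1_j, which
    is the direction the planted covariance pushes each edge.
    """
    basis = syn.generate_gradient_basis(n_regions, 6, seed=2)
    v1 = basis.eigenvectors[:, 0]
    v4 = basis.eigenvectors[:, 3]
    bracket = np.outer(v1, v4) + np.outer(v4, v1)
    iu = np.triu_indices(n_regions, 1)
    b = bracket[iu]
    thr = np.quantile(np.abs(b), 0.5)
    pos, neg = b > thr, b < -thr
    base = syn.base_coupling_model(6)
    rows = []
    for angle in angles:
        model = syn.plant_pair_angle(base, 0, 3, angle, participation=0.5)
        gts = syn.simulate_gradient_timeseries(
            model, n_timepoints, forcing_sd=syn._BASE_FORCING, seed=seed
        )
        fc = gr.pearson_fc(syn.render_bold(gts, basis, 0.0).values)[iu]
        rows.append({"angle": angle, "aligned_fc": float(fc[pos].mean()),
                     "opposed_fc": float(fc[neg].mean())})
    return pd.DataFrame(rows)


def _matched_correlations(model: sf.PLSRModel, truth: np.ndarray) -> np.ndarray:
    c = np.abs(np.corrcoef(model.x_scores.T, truth.T)[:3, 3:])
    used: set[int] = set()
    out = np.empty(3)
    for k in range(3):
        j = int(np.argmax([c[k, j] if j not in used else -1.0
                           for j in range(3)]))
        used.add(j)
        out[j] = c[k, j]
    return out


def plsr_recovery_experiment(
    seed: int = 0, n_subjects: int = 200, n_regions: int = 80,
    n_timepoints: int = 400,
) -> dict:
    """One cohort: PLSR component recovery, CV coupling, shuffled null."""
    cfg = syn.CohortConfig(
        n_subjects=n_subjects, n_controls=n_subjects // 4,
        n_regions=n_regions, n_timepoints=n_timepoints, seed=seed,
    )
    cohort = syn.generate_cohort(cfg)
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
    edges = np.array([sf.vectorize_fc(gr.pearson_fc(s.values))
                      for s in cohort.scans])
    model = sf.fit_plsr(w_h, edges, 3)
    matched = _matched_correlations(model, cohort.ground_truth.structure_scores)
    cv = sf.crossval_function_scores(w_h, edges, 3, folds=4, seed=seed)
    rng = np.random.default_rng(seed)
    null = sf.crossval_function_scores(
        w_h, edges[rng.permutation(n_subjects)], 3, folds=4, seed=seed
    )
    return {"matched_r": matched, "cv_r": cv["r"], "null_r": null["r"],
            "explained_x_variance": model.explained_x_variance}


def wscore_calibration(seed: int = 5, n_reference: int = 2000,
                       n_heldout: int = 500, n_regions: int = 10) -> dict:
    """Held-out normative W-score calibration (mean ~ 0, SD ~ 1)."""
    vols, covs, truth = syn.generate_normative_reference(
        n_reference, n_regions, seed=seed
    )
    model = atr.fit_normative_model(vols, covs)
    fresh_v, fresh_c, _ = syn.generate_normative_reference(
        n_heldout, n_regions, seed=seed + 1000,
        coefficients=truth["coefficients"],
        residual_sds=truth["residual_sds"],
    )
    w = atr.compute_w_scores(fresh_v, fresh_c, model)
    return {
        "max_abs_mean_w": float(np.max(np.abs(w.mean(axis=0)))),
        "max_abs_sd_deviation": float(
            np.max(np.abs(w.std(axis=0, ddof=1) - 1.0))
        ),
    }


def qc_conformance(seed: int = 0) -> dict:
    """Hand-constructed scan sets exercising both QC rules."""
    rng = np.random.default_rng(seed)

    def scan(values, fd):
        return gr.RegionalTimeseries(values, mean_fd=fd)

    # FD rule: strict threshold at 0.55
    fd_scans = [scan(rng.standard_normal((60, 5)), fd)
                for fd in (0.10, 0.55, 0.551, 0.56, 1.0)]
    keep_fd, drop_fd = gr.qc_filter_scans(fd_scans, pc_sd_threshold=np.inf)
    fd_ok = (keep_fd == [0, 1] and drop_fd == [2, 3, 4])
    # PC rule: one planted outlier among near-identical FC structures
    t = np.linspace(0, 40 * np.pi, 400)
    base = np.column_stack([np.sin(t), 0.9 * np.sin(t), np.cos(t),
                            0.8 * np.cos(t), np.sin(2 * t)])
    pc_scans = [scan(base + 0.05 * rng.standard_normal(base.shape), 0.2)
                for _ in range(30)]
    pc_scans.append(scan(rng.standard_normal((400, 5)), 0.2))
    keep_pc, drop_pc = gr.qc_filter_scans(pc_scans)
    pc_ok = 30 in drop_pc and len(keep_pc) >= 28
    return {"fd_rule_conformant": fd_ok, "pc_rule_conformant": pc_ok}


def behavior_null_calibration(n_replicates: int = 200, n: int = 300,
                              seed: int = 0) -> dict:
    """Per-term type-I error of the additive model under the null."""
    rng = np.random.default_rng(seed)
    preds = ["S1", "S2", "S3", "F1", "F2", "F3"]
    spec = bhv.BehaviorModelSpec(response="resp", covariates=["age"])
    rej = []
    for _ in range(n_replicates):
        d = pd.DataFrame({p: rng.standard_normal(n) for p in preds})
        d["age"] = rng.uniform(55, 85, n)
        d["resp"] = rng.standard_normal(n)
        res = bhv.fit_additive_model(d, spec)
        rej.append([res.term_p[p] < 0.05 for p in preds])
    rates = np.mean(rej, axis=0)
    mc_se = np.sqrt(0.05 * 0.95 / n_replicates)
    return {"per_term_type1": rates, "max_type1": float(rates.max()),
            "mc_se": float(mc_se)}


def behavior_nonlinearity_power(n_replicates: int = 50, n: int = 300,
                                seed: int = 0) -> float:
    """Power to detect the planted quadratic cognition term."""
    rng = np.random.default_rng(seed)
    preds = ["S1", "S2", "S3", "F1", "F2", "F3"]
    spec = bhv.BehaviorModelSpec(response="resp", covariates=["age"])
    quad = syn.DEFAULT_TEST_SPECS[1]["quadratic"]["S3"]
    hits = 0
    for _ in range(n_replicates):
        d = pd.DataFrame({p: rng.standard_normal(n) for p in preds})
        d["age"] = rng.uniform(55, 85, n)
        d["resp"] = (-0.8 * d["S1"] - 0.5 * d["F3"] + quad * d["S3"] ** 2
                     + rng.standard_normal(n))
        res = bhv.fit_additive_model(d, spec)
        hits += res.nonlinear_p["S3"] < 0.05
    return hits / n_replicates


def fdr_calibration(m: int = 144, m_alt: int = 24, n_replicates: int = 200,
                    q: float = 0.05, seed: int = 0) -> dict:
    """Empirical FDR of BH on mixed null/alternative p-value sets."""
    rng = np.random.default_rng(seed)
    fdrs = []
    for _ in range(n_replicates):
        p = np.concatenate([
            rng.uniform(size=m - m_alt),
            stats.beta(0.05, 1).rvs(size=m_alt, random_state=rng),
        ])
        flags, _ = bhv.fdr_correct(p, q=q)
        null_rej = flags[: m - m_alt].sum()
        fdrs.append(null_rej / max(flags.sum(), 1))
    fdrs = np.asarray(fdrs)
    return {
        "empirical_fdr": float(fdrs.mean()),
        "mc_se": float(fdrs.std(ddof=1) / np.sqrt(n_replicates)),
    }
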