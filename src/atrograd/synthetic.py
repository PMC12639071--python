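"""Synthetic cohort generator with planted structure-function components.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without patient data:

* regional atrophy maps built as weighted sums of three planted spatial
  components plus noise, expressed through a normative-volume pathway
  (volumes = covariate prediction - atrophy * residual SD);
* regional BOLD rendered from K latent gradient timeseries governed by a
  linear second-order coupled-oscillator system; a subject's atrophy
  component scores shift gradient forcing amplitudes, natural
  frequencies, and between-gradient phase-angle targets;
* cognitive scores as noisy linear/quadratic functions of the planted
  structure and function scores;
* a normative reference cohort and a two-scanner batch structure.

Phase angles are planted in closed form: coupling a receiver gradient g
to a source gradient h through position and velocity terms
``kappa_s G_h + kappa_v G_h'`` leaves the source's eigenvalue unchanged
and sets the receiver's complex eigenvector component on the source's
mode to ``(kappa_s + kappa_v lambda_h) / (lambda_h^2 + c_g lambda_h +
omega_g^2)``, whose argument — and hence the measured pair angle — can
be dialed exactly by choosing the coupling direction in the
(position, velocity) plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .gradients import GradientBasis, GradientTimeseries, RegionalTimeseries
from .oscillator import (
    CouplingModel,
    cumulative_amplitude,
    eigenmodes_of,
    pair_phase_angles,
)

__all__ = [
    "LinkConfig",
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_gradient_basis",
    "build_coupling_matrix",
    "simulate_gradient_timeseries",
    "render_bold",
    "plant_pair_angle",
    "apply_structure_function_link",
    "generate_atrophy_patterns",
    "generate_atrophy_cohort",
    "generate_cognition",
    "generate_normative_reference",
    "generate_cohort",
]

# base oscillator: gradient 1 slowest and most strongly forced, mirroring
# the dominant, low-frequency unipolar gradient of resting-state data;
# frequencies kept below ~0.3 rad/sample so the finite-difference fitting
# stage sees the system in its accurate regime
_BASE_FREQS = np.array([0.14, 0.16, 0.18, 0.20, 0.22, 0.25])  # rad/sample
_BASE_DAMPING = 0.015  # per sample
_BASE_FORCING = np.array([1.0, 0.70, 0.55, 0.45, 0.40, 0.35])


@dataclass
class LinkConfig:
    """How atrophy component scores shift oscillator parameters.

    Each gradient carries a multiplicative *gain* that scales both its
    stochastic forcing and its receiver-side coupling participations, so
    a gain change moves the gradient's temporal variance and its
    eigenmode amplitude together.  Component 1 (overall atrophy) lowers
    gradient 1's gain and pulls the gradient 1-4 angle below 90 degrees;
    components 2/3 shift the gradient 1-2 angle in opposite directions
    and modulate gradient 2's gain.
    """

    amp1_slope: float = 0.25  # gain_1 = exp(-slope * f1)
    angle14_slope_deg: float = 12.0  # target = 90 - slope * f1
    angle12_slope_s3_deg: float = 12.0  # target = 90 + a*f3 - b*f2
    angle12_slope_s2_deg: float = 8.0
    amp2_slope: float = 0.15  # gain_2 = exp(+slope * f3)
    amp3_slope: float = 0.30  # gain_3 = exp(-slope * f2)
    participation: float = 0.5  # |v_receiver| / |v_source| on the planted mode

    def gains(self, scores: np.ndarray, n_gradients: int) -> np.ndarray:
        """Per-gradient gain implied by a subject's component scores."""
        f1, f2, f3 = scores
        g = np.ones(n_gradients)
        g[0] = np.exp(-self.amp1_slope * f1)
        if n_gradients >= 2:
            g[1] = np.exp(self.amp2_slope * f3)
        if n_gradients >= 3:
            g[2] = np.exp(-self.amp3_slope * f2)
        return g

    def angle_targets(self, scores: np.ndarray) -> dict[tuple[int, int], float]:
        """Planted (receiver, source) angle targets in degrees."""
        f1, f2, f3 = scores
        return {
            (0, 3): 90.0 - self.angle14_slope_deg * f1,
            (0, 1): 90.0
            + self.angle12_slope_s3_deg * f3
            - self.angle12_slope_s2_deg * f2,
        }


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 120
    n_controls: int = 40  # included in n_subjects, drawn with scores near 0
    n_regions: int = 246
    n_gradients: int = 6
    n_timepoints: int = 375
    tr_seconds: float = 2.0
    atrophy_patterns: np.ndarray | None = None  # 3 x n_regions, unit norm
    severity_scales: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # W-score units carried by each unit of component score; component 1
    # (overall atrophy) dominates the atrophy variance as in real
    # cohorts.  Component 1 severity is half-normal (variance 1 - 2/pi),
    # so its amplitude is set higher to keep it the dominant component.
    pattern_amplitudes: tuple[float, float, float] = (6.0, 2.2, 1.2)
    control_score_sd: float = 0.05
    atrophy_noise_sd: float = 0.2  # W-score units, per region
    function_noise_sd: float = 0.5  # structure->function coupling noise
    region_noise_sd: float = 0.5  # BOLD observation noise
    cognition_noise_sd: float = 1.0
    link: LinkConfig = field(default_factory=LinkConfig)
    # per-subject idiosyncratic dynamics (gives every gradient/pair
    # across-subject variation beyond the planted links)
    freq_jitter_sd: float = 0.02  # log-scale on omega_g
    gain_jitter_sd: float = 0.20  # log-scale on per-gradient gain
    angle_jitter_sd_deg: float = 10.0  # jitter-coupled background pairs
    jitter_participation: float = 0.25
    batch_volume_shift: float = 5.0  # scanner 2 additive volume offset
    batch_volume_scale: float = 1.15  # scanner 2 residual scale
    batch_bold_scale: float = 1.10  # scanner 2 BOLD amplitude factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gradients > self.n_regions:
            raise ValueError("n_gradients cannot exceed n_regions")
        if self.n_controls > self.n_subjects:
            raise ValueError("n_controls cannot exceed n_subjects")
        for name in ("atrophy_noise_sd", "function_noise_sd", "region_noise_sd",
                     "cognition_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Planted quantities for recovery oracles."""

    structure_scores: np.ndarray  # n x 3
    function_scores: np.ndarray  # n x 3
    basis: GradientBasis
    models: list[CouplingModel]
    forcing_sds: np.ndarray  # n x K
    amplitudes: np.ndarray  # n x K, eigenmode cumulative amplitudes
    angles: np.ndarray  # n x K(K-1)/2, degrees, upper-triangle order
    is_control: np.ndarray
    batch: np.ndarray
    cognition_coefficients: dict | None = None


@dataclass
class SyntheticCohort:
    config: CohortConfig
    ground_truth: GroundTruth
    volumes: pd.DataFrame  # subject x region gray-matter volumes
    covariates: pd.DataFrame  # age, sex, tiv, batch, group
    scans: list[RegionalTimeseries]
    cognition: pd.DataFrame
    normative_volumes: pd.DataFrame
    normative_covariates: pd.DataFrame


# ---------------------------------------------------------------------------
# basis


def generate_gradient_basis(
    n_regions: int, n_gradients: int, seed: int
) -> GradientBasis:
    """Random orthonormal spatial basis with a unipolar dominant gradient.

    Column 1 is the absolute value of a random orthonormal column
    (all-positive weights); the remaining columns are re-orthogonalized
    against it, so the basis stays exactly orthonormal.  Explained
    variance decreases strictly, making gradient 1 dominant.
    """
    if n_gradients < 2:
        raise ValueError("need at least 2 gradients")
    if n_gradients > n_regions:
        raise ValueError(
            f"n_gradients={n_gradients} exceeds n_regions={n_regions}"
        )
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n_regions, n_gradients + 1)))
    u1 = np.abs(q[:, 0])
    u1[u1 < 1e-12] = 1e-12  # keep strictly positive
    u1 /= np.linalg.norm(u1)
    rest = q[:, 1:]
    rest = rest - np.outer(u1, u1 @ rest)
    qr_rest, r_rest = np.linalg.qr(rest)
    qr_rest = qr_rest[:, : n_gradients - 1] * np.sign(np.diag(r_rest))[: n_gradients - 1]
    vecs = np.column_stack([u1, qr_rest])
    explained = 1.0 / np.arange(1, n_gradients + 1) ** 1.2
    return GradientBasis(vecs, explained, reference_id=f"synthetic-seed-{seed}")


# ---------------------------------------------------------------------------
# oscillator construction


def build_coupling_matrix(
    frequencies: np.ndarray,
    dampings: np.ndarray,
    cross_couplings: dict[tuple[int, int], tuple[float, float]] | None = None,
    tr_seconds: float = 2.0,
) -> CouplingModel:
    """Assemble a coupling model from per-gradient oscillator parameters.

    ``frequencies`` are natural angular frequencies (rad/sample),
    ``dampings`` the damping constants c (per sample), so gradient g's
    uncoupled equation is ``G'' = -omega_g^2 G - c_g G'``.
    ``cross_couplings`` maps (receiver, source) index pairs to
    (position, velocity) coefficients added to the receiver's equation.
    Diagonal terms must be underdamped (c^2 < 4 omega^2).
    """
    freqs = np.asarray(frequencies, dtype=float)
    damps = np.asarray(dampings, dtype=float)
    if freqs.ndim != 1 or damps.shape != freqs.shape:
        raise ValueError("frequencies and dampings must be 1-D and same length")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    over = damps**2 >= 4 * freqs**2
    if np.any(over):
        bad = np.flatnonzero(over).tolist()
        raise ValueError(
            f"overdamped diagonal terms (c^2 >= 4 omega^2) for gradients {bad}; "
            "the oscillator model requires underdamped diagonals"
        )
    k = freqs.size
    coeff = np.zeros((k, 2 * k + 1))
    coeff[:, 1 : k + 1] = np.diag(-(freqs**2))
    coeff[:, k + 1 :] = np.diag(-damps)
    if cross_couplings:
        for (g, h), (pos, vel) in cross_couplings.items():
            if g == h:
                raise ValueError("cross-coupling indices must differ")
            coeff[g, 1 + h] += pos
            coeff[g, 1 + k + h] += vel
    return CouplingModel(coeff, tr_seconds=tr_seconds)


def plant_pair_angle(
    model: CouplingModel,
    receiver: int,
    source: int,
    angle_deg: float,
    participation: float = 0.5,
) -> CouplingModel:
    """Set the receiver-source phase angle on the source's eigenmode.

    Adds position and velocity coupling terms from ``source`` into the
    ``receiver`` equation such that the receiver's complex eigenvector
    component on the source's mode sits at ``angle_deg`` (signed,
    degrees) relative to the source's component, with magnitude
    ``participation`` times the source's.  The source equation is left
    untouched, so its eigenvalue is preserved exactly.
    """
    if not 0.0 < abs(angle_deg) < 180.0:
        raise ValueError("target angle must lie strictly between 0 and 180 degrees")
    k = model.n_gradients
    # source's own eigenvalue from its diagonal terms
    w2 = -model.position_block[source, source]
    c_s = -model.velocity_block[source, source]
    disc = c_s**2 - 4 * w2
    if disc >= 0:
        raise ValueError("source gradient is not an underdamped oscillator")
    lam = complex(-c_s / 2.0, np.sqrt(-disc) / 2.0)
    # receiver's transfer denominator at the source's eigenvalue
    w2_r = -model.position_block[receiver, receiver]
    c_r = -model.velocity_block[receiver, receiver]
    denom = lam**2 + c_r * lam + w2_r
    target = participation * abs(denom) * np.exp(
        1j * (np.radians(angle_deg) + np.angle(denom))
    )
    kappa_v = target.imag / lam.imag
    kappa_s = target.real - kappa_v * lam.real
    coeff = model.coefficients.copy()
    coeff[receiver, 1 + source] += kappa_s
    coeff[receiver, 1 + k + source] += kappa_v
    return CouplingModel(coeff, tr_seconds=model.tr_seconds,
                         r_squared=model.r_squared)


# ---------------------------------------------------------------------------
# simulation


def simulate_gradient_timeseries(
    model: CouplingModel,
    n_timepoints: int,
    forcing_sd: float | np.ndarray = 0.05,
    seed: int | None = 0,
    initial_state: np.ndarray | None = None,
    burn_in: int = 500,
) -> GradientTimeseries:
    """Stochastically forced trajectory by exact per-step propagation.

    The state advances one sample at a time through the matrix
    exponential of the companion system (exact for the deterministic
    part, so noise-free runs match the analytic mode solution to machine
    precision); Gaussian forcing is injected into the velocity
    components after each step.  ``forcing_sd`` may be scalar or
    per-gradient.  A burn-in is discarded so forced runs start near
    stationarity; with explicit ``initial_state`` the burn-in is skipped.
    """
    k = model.n_gradients
    a = model.companion()
    max_re = np.max(np.real(np.linalg.eigvals(a)))
    forcing = np.broadcast_to(np.asarray(forcing_sd, dtype=float), (k,)).copy()
    if np.any(forcing < 0):
        raise ValueError("forcing_sd must be >= 0")
    forced = np.any(forcing > 0)
    if max_re > 1e-9:
        warnings.warn(
            f"unstable coupling model (max eigenvalue real part {max_re:.3g}); "
            "the trajectory will grow over the requested horizon",
            stacklevel=2,
        )
    phi = expm(a)  # one-sample propagator
    if initial_state is not None:
        state = np.asarray(initial_state, dtype=float).copy()
        if state.shape != (2 * k,):
            raise ValueError(f"initial_state must have shape ({2 * k},)")
        burn_in = 0
    else:
        state = np.zeros(2 * k)
    rng = np.random.default_rng(seed)
    total = burn_in + n_timepoints
    if forced:
        kicks = rng.standard_normal((total, k)) * forcing
    out = np.empty((n_timepoints, k))
    for t in range(total):
        if t >= burn_in:
            out[t - burn_in] = state[:k]
        state = phi @ state
        if forced:
            state[k:] += kicks[t]
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite values in simulated trajectory")
    return GradientTimeseries(out, tr_seconds=model.tr_seconds)


def render_bold(
    gradients: GradientTimeseries,
    basis: GradientBasis,
    region_noise_sd: float = 0.0,
    seed: int | None = 0,
) -> RegionalTimeseries:
    """Render regional BOLD as basis-weighted gradient activity plus noise.

    This is the generative inverse of the projection step: with zero
    noise, projecting the output back through the orthonormal basis
    recovers the gradient timeseries exactly.
    """
    if gradients.n_gradients != basis.n_gradients:
        raise ValueError(
            f"gradient count {gradients.n_gradients} does not match basis "
            f"({basis.n_gradients})"
        )
    x = gradients.values @ basis.eigenvectors.T
    if region_noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.standard_normal(x.shape) * region_noise_sd
    return RegionalTimeseries(
        x, tr_seconds=gradients.tr_seconds, region_ids=basis.region_ids
    )


# ---------------------------------------------------------------------------
# structure-function link


def base_coupling_model(
    n_gradients: int = 6, tr_seconds: float = 2.0
) -> CouplingModel:
    """The healthy-reference oscillator (uncoupled, underdamped)."""
    freqs = _BASE_FREQS[:n_gradients]
    if n_gradients > _BASE_FREQS.size:
        freqs = np.linspace(0.14, 0.3, n_gradients)
    return build_coupling_matrix(
        freqs, np.full(n_gradients, _BASE_DAMPING), tr_seconds=tr_seconds
    )


def apply_structure_function_link(
    scores: np.ndarray,
    link: LinkConfig,
    base_model: CouplingModel,
    base_forcing: np.ndarray | None = None,
) -> tuple[CouplingModel, np.ndarray]:
    """Shift a subject's oscillator parameters according to their scores.

    Returns the subject's coupling model and per-gradient forcing SDs.
    With all scores zero the base model is returned unchanged.  Target
    angles falling outside (0, 180) degrees are rejected.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (3,):
        raise ValueError("expected exactly 3 component scores")
    k = base_model.n_gradients
    if base_forcing is None:
        base_forcing = _BASE_FORCING[:k].copy()
    forcing = np.asarray(base_forcing, dtype=float).copy()
    if np.all(scores == 0):
        return base_model, forcing
    gains = link.gains(scores, k)
    forcing = forcing * gains
    model = base_model
    # angle links: gradient 1 receives from gradients 4 and 2, with the
    # receiver's gain scaling its participation on the source modes
    for (receiver, source), angle in link.angle_targets(scores).items():
        if not 0.0 < angle < 180.0:
            raise ValueError(
                f"linked angle target {angle:.1f} deg falls outside (0, 180); "
                "reduce the link slopes or the score range"
            )
        if k > source:
            model = plant_pair_angle(
                model, receiver=receiver, source=source, angle_deg=angle,
                participation=link.participation * gains[receiver],
            )
    return model, forcing


# ---------------------------------------------------------------------------
# cohort assembly


def generate_atrophy_patterns(n_regions: int, seed: int) -> np.ndarray:
    """Three unit-norm planted atrophy components.

    Component 1 is global (all-positive, emulating overall mean
    atrophy); components 2 and 3 are signed contrasts orthogonal to it
    and to each other.
    """
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n_regions, 3)))
    p1 = np.abs(q[:, 0])
    p1 /= np.linalg.norm(p1)
    rest = q[:, 1:]
    rest -= np.outer(p1, p1 @ rest)
    rest, _ = np.linalg.qr(rest)
    return np.column_stack([p1, rest]).T  # 3 x n_regions


def _draw_scores(config: CohortConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n, nc = config.n_subjects, config.n_controls
    n_pat = n - nc
    s = np.zeros((n, 3))
    sc = np.asarray(config.severity_scales)
    s[:n_pat, 0] = np.abs(rng.standard_normal(n_pat)) * sc[0]
    s[:n_pat, 1] = rng.standard_normal(n_pat) * sc[1]
    s[:n_pat, 2] = rng.standard_normal(n_pat) * sc[2]
    s[n_pat:] = rng.standard_normal((nc, 3)) * config.control_score_sd
    is_control = np.zeros(n, dtype=bool)
    is_control[n_pat:] = True
    return s, is_control


def generate_atrophy_cohort(
    config: CohortConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted atrophy maps: ``W[i] = sum_k s[i,k] pattern_k + noise``.

    Returns (W maps n x R, structure scores n x 3, is_control mask).
    """
    rng = np.random.default_rng(config.seed)
    patterns = config.atrophy_patterns
    if patterns is None:
        patterns = generate_atrophy_patterns(config.n_regions, config.seed)
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape != (3, config.n_regions):
        raise ValueError("atrophy_patterns must be 3 x n_regions")
    norms = np.linalg.norm(patterns, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("atrophy patterns must be unit-normalized")
    scores, is_control = _draw_scores(config, rng)
    w = (scores * np.asarray(config.pattern_amplitudes)) @ patterns
    if config.atrophy_noise_sd > 0:
        w = w + rng.standard_normal(w.shape) * config.atrophy_noise_sd
    return w, scores, is_control


def generate_cognition(
    ground_truth: GroundTruth,
    test_specs: list[dict],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cognitive scores as linear + quadratic functions of component scores.

    Each spec is ``{"name": str, "coefficients": {predictor: beta},
    "quadratic": {predictor: beta}, "missing_rate": float}`` with
    predictors named S1-S3 (structure) and F1-F3 (function).
    """
    rng = np.random.default_rng(seed)
    preds = {}
    for i in range(3):
        preds[f"S{i + 1}"] = ground_truth.structure_scores[:, i]
        preds[f"F{i + 1}"] = ground_truth.function_scores[:, i]
    n = ground_truth.structure_scores.shape[0]
    out = {}
    for spec in test_specs:
        y = np.zeros(n)
        for name, beta in spec.get("coefficients", {}).items():
            if name not in preds:
                raise KeyError(f"unknown predictor '{name}' in test '{spec['name']}'")
            y += beta * preds[name]
        for name, beta in spec.get("quadratic", {}).items():
            if name not in preds:
                raise KeyError(f"unknown predictor '{name}' in test '{spec['name']}'")
            y += beta * preds[name] ** 2
        if noise_sd > 0:
            y = y + rng.standard_normal(n) * noise_sd
        rate = spec.get("missing_rate", 0.0)
        if rate > 0:
            y = y.copy()
            y[rng.random(n) < rate] = np.nan
        out[spec["name"]] = y
    return pd.DataFrame(out)


DEFAULT_TEST_SPECS = [
    {"name": "global_severity",
     "coefficients": {"S1": 1.0, "F1": 0.6, "S3": 0.4}},
    {"name": "global_cognition",
     "coefficients": {"S1": -0.8, "F3": -0.5},
     "quadratic": {"S3": -0.4}},
    {"name": "memory", "coefficients": {"S1": -0.7, "S2": 0.5, "F1": -0.3}},
    {"name": "executive", "coefficients": {"S1": -0.6, "S2": -0.6},
     "missing_rate": 0.1},
]


def generate_normative_reference(
    n: int,
    n_regions: int = 246,
    seed: int = 0,
    coefficients: np.ndarray | None = None,
    residual_sds: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Cognitively normal reference cohort for normative-model fitting.

    Regional volume is a linear function of age, sex, and a total
    intracranial volume proxy plus Gaussian residual with known
    per-region SD.  Returns (volumes, covariates, truth) where ``truth``
    holds the generating coefficients for recovery oracles.
    """
    if n < 30:
        raise ValueError("normative reference needs n >= 30")
    rng = np.random.default_rng(seed)
    age = rng.uniform(55, 85, n)
    sex = rng.integers(0, 2, n).astype(float)
    tiv = rng.normal(1400.0, 120.0, n)
    x = np.column_stack([age, sex, tiv])
    if coefficients is None:
        coefficients = np.column_stack([
            rng.uniform(-0.05, -0.01, n_regions),  # volume loss with age
            rng.uniform(-0.5, 0.5, n_regions),
            rng.uniform(0.002, 0.006, n_regions),
        ])
        intercept = rng.uniform(5.0, 15.0, n_regions)
        coefficients = np.column_stack([intercept, coefficients])
    if residual_sds is None:
        residual_sds = rng.uniform(0.4, 1.2, n_regions)
    residual_sds = np.asarray(residual_sds, dtype=float)
    design = np.column_stack([np.ones(n), x])
    vols = design @ coefficients.T
    if np.any(residual_sds > 0):
        vols = vols + rng.standard_normal((n, n_regions)) * residual_sds
    regions = [f"R{i:03d}" for i in range(n_regions)]
    volumes = pd.DataFrame(vols, columns=regions)
    covariates = pd.DataFrame({"age": age, "sex": sex, "tiv": tiv})
    truth = {"coefficients": coefficients, "residual_sds": residual_sds}
    return volumes, covariates, truth


def subject_dynamics(
    scores: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
    base: CouplingModel | None = None,
) -> tuple[CouplingModel, np.ndarray]:
    """One subject's coupling model and forcing SDs.

    Combines the planted score links with the subject's idiosyncratic
    jitter: per-gradient gains (scaling forcing and receiver-side
    coupling participations), natural-frequency jitter, and background
    angle jitter on every pair not used by the planted links.
    """
    k = config.n_gradients
    if base is None:
        base = base_coupling_model(k, config.tr_seconds)
    gains = config.link.gains(np.asarray(scores, float), k)
    if config.gain_jitter_sd > 0:
        gains = gains * np.exp(rng.normal(0, config.gain_jitter_sd, k))
    forcing = _BASE_FORCING[:k] * gains
    coeff = base.coefficients.copy()
    if config.freq_jitter_sd > 0:
        for g in range(k):
            w_g = np.sqrt(-coeff[g, 1 + g])
            w_g *= np.exp(rng.normal(0, config.freq_jitter_sd))
            coeff[g, 1 + g] = -(w_g**2)
    model = CouplingModel(coeff, tr_seconds=config.tr_seconds)
    linked = set()
    for (receiver, source), target in config.link.angle_targets(scores).items():
        linked.add((receiver, source))
        target = float(np.clip(target, 5.0, 175.0))
        if k > source:
            model = plant_pair_angle(
                model, receiver=receiver, source=source, angle_deg=target,
                participation=config.link.participation * gains[receiver],
            )
    if config.angle_jitter_sd_deg > 0:
        jitter_pairs = [
            (g, h) for g in range(k) for h in range(g + 1, k)
            if (g, h) not in linked
        ]
        for g, h in jitter_pairs:
            target = 90.0 + rng.normal(0, config.angle_jitter_sd_deg)
            target = float(np.clip(target, 5.0, 175.0))
            model = plant_pair_angle(
                model, receiver=g, source=h, angle_deg=target,
                participation=config.jitter_participation * gains[g],
            )
    return model, forcing


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Full generative pipeline: atrophy, dynamics, BOLD, cognition.

    Function scores are the structure scores plus independent noise
    (``function_noise_sd``); the dynamics links are driven by the
    function scores, so structure and function are coupled but not
    identical, as in real cohorts.  Background per-subject jitter on
    frequencies, forcing, and all gradient-pair angles provides the
    across-subject variation the correspondence analyses measure.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_gradients
    w_maps, s, is_control = generate_atrophy_cohort(config)
    n = config.n_subjects
    f = s + rng.standard_normal(s.shape) * config.function_noise_sd
    f[is_control] = s[is_control]  # controls stay near the origin

    basis = generate_gradient_basis(config.n_regions, k, config.seed + 1)
    base = base_coupling_model(k, config.tr_seconds)
    batch = rng.integers(0, 2, n)

    # normative reference and subject covariates / volumes
    norm_vols, norm_covs, norm_truth = generate_normative_reference(
        max(400, 3 * config.n_regions // 2), config.n_regions,
        seed=config.seed + 2,
    )
    age = rng.uniform(55, 85, n)
    sex = rng.integers(0, 2, n).astype(float)
    tiv = rng.normal(1400.0, 120.0, n)
    design = np.column_stack([np.ones(n), age, sex, tiv])
    predicted = design @ norm_truth["coefficients"].T
    resid_sd = norm_truth["residual_sds"]
    vols = predicted - w_maps * resid_sd  # atrophy-positive convention
    vols = vols + rng.standard_normal(vols.shape) * (0.1 * resid_sd)
    # scanner batch effects on volumes (location + scale about prediction)
    b2 = batch == 1
    vols[b2] = predicted[b2] + (vols[b2] - predicted[b2]) * config.batch_volume_scale
    vols[b2] += config.batch_volume_shift * resid_sd * 0.1

    regions = list(norm_vols.columns)
    basis.region_ids = regions
    models: list[CouplingModel] = []
    forcing_all = np.empty((n, k))
    scans: list[RegionalTimeseries] = []
    n_pairs = k * (k - 1) // 2
    amplitudes = np.empty((n, k))
    angles = np.empty((n, n_pairs))
    iu = np.triu_indices(k, 1)
    for i in range(n):
        model, forcing = subject_dynamics(f[i], config, rng, base)
        models.append(model)
        forcing_all[i] = forcing
        modes = eigenmodes_of(model)
        amplitudes[i] = cumulative_amplitude(modes)
        ang, _ = pair_phase_angles(modes)
        angles[i] = ang[iu]
        gts = simulate_gradient_timeseries(
            model, config.n_timepoints, forcing_sd=forcing,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        scan = render_bold(
            gts, basis, config.region_noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        if b2[i]:
            scan.values *= config.batch_bold_scale
        scan.scan_id = f"sub{i:04d}"
        scan.mean_fd = float(np.clip(rng.normal(0.2, 0.1), 0.02, None))
        scans.append(scan)

    truth = GroundTruth(
        structure_scores=s,
        function_scores=f,
        basis=basis,
        models=models,
        forcing_sds=forcing_all,
        amplitudes=amplitudes,
        angles=angles,
        is_control=is_control,
        batch=batch,
        cognition_coefficients={
            spec["name"]: spec for spec in DEFAULT_TEST_SPECS
        },
    )
    cognition = generate_cognition(
        truth, DEFAULT_TEST_SPECS, config.cognition_noise_sd, config.seed + 3
    )
    subject_ids = [f"sub{i:04d}" for i in range(n)]
    volumes = pd.DataFrame(vols, columns=regions, index=subject_ids)
    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "tiv": tiv,
            "batch": batch,
            "group": np.where(is_control, "CN", "patient"),
        },
        index=subject_ids,
    )
    cognition.index = pd.Index(subject_ids)
    return SyntheticCohort(
        config=config,
        ground_truth=truth,
        volumes=volumes,
        covariates=covariates,
        scans=scans,
        cognition=cognition,
        normative_volumes=norm_vols,
        normative_covariates=norm_covs,
    )
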