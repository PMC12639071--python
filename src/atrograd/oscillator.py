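"""Coupled damped harmonic oscillator model of gradient dynamics.

Each gradient's acceleration is modeled as a linear function of all
gradients' levels and velocities:

    G_g'' = b_g0 + sum_h beta_pos[g,h] G_h + sum_h beta_vel[g,h] G_h'

The K second-order equations are rewritten as a first-order system
dY/dt = A Y with the companion matrix A (blocked: positions first, then
velocities).  Eigendecomposition A V = lambda V yields damped oscillatory
eigenmodes: eigenvalue alpha + i*beta carries damping (per sample) and
angular frequency (rad per sample); the complex eigenvector components
a + i*b carry each gradient's amplitude and phase on that mode.

Summaries per subject:

* cumulative amplitude of gradient g: sum over modes of
  sqrt((-a+b)^2 + (a+b)^2)
* cumulative phase angle of a gradient pair: weighted circular mean of
  the per-mode angle differences arg(a1+i b1) - arg(a2+i b2), with
  weights equal to the product of the two gradients' per-mode amplitudes,
  folded to [0, 180] degrees (90 = temporal orthogonality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientBasis, GradientTimeseries, pearson_fc

__all__ = [
    "CouplingModel",
    "Eigenmode",
    "finite_difference",
    "fit_coupling",
    "eigenmodes_of",
    "mode_amplitudes",
    "cumulative_amplitude",
    "pair_phase_angles",
    "simulate_from_model",
    "eigenmode_fc",
    "amplitude_angle_correspondence",
]

_IMAG_TOL = 1e-9


@dataclass
class CouplingModel:
    """Per-gradient second-order regression coefficients.

    ``coefficients`` is K x (2K+1): column 0 intercept, columns 1..K the
    position terms (G_1..G_K), columns K+1..2K the velocity terms
    (G_1'..G_K').  Units are per-sample; ``tr_seconds`` is kept for
    frequency conversion only.
    """

    coefficients: np.ndarray
    tr_seconds: float = 2.0
    r_squared: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        k = self.coefficients.shape[0]
        if self.coefficients.shape != (k, 2 * k + 1):
            raise ValueError("coefficient matrix must be K x (2K+1)")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coupling coefficients")

    @property
    def n_gradients(self) -> int:
        return self.coefficients.shape[0]

    @property
    def intercept(self) -> np.ndarray:
        return self.coefficients[:, 0]

    @property
    def position_block(self) -> np.ndarray:
        k = self.n_gradients
        return self.coefficients[:, 1 : k + 1]

    @property
    def velocity_block(self) -> np.ndarray:
        k = self.n_gradients
        return self.coefficients[:, k + 1 :]

    def companion(self) -> np.ndarray:
        """2K x 2K first-order system matrix (positions, then velocities)."""
        k = self.n_gradients
        a = np.zeros((2 * k, 2 * k))
        a[:k, k:] = np.eye(k)
        a[k:, :k] = self.position_block
        a[k:, k:] = self.velocity_block
        return a


@dataclass
class Eigenmode:
    """One representative damped oscillatory mode of the fitted system."""

    eigenvalue: complex  # alpha + i*beta, per-sample units
    components: np.ndarray  # per-gradient complex component (position block)
    tr_seconds: float
    is_oscillatory: bool = True

    @property
    def damping(self) -> float:
        return float(self.eigenvalue.real)

    @property
    def angular_frequency(self) -> float:
        """rad per sample."""
        return float(self.eigenvalue.imag)

    @property
    def frequency_hz(self) -> float:
        return self.angular_frequency / (2.0 * np.pi * self.tr_seconds)


def finite_difference(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivatives by the standard gradient stencil.

    Central differences in the interior, one-sided at the boundaries;
    the second derivative is the stencil applied twice.  Units are per
    sample.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for finite differences")
    first = np.gradient(values, axis=0)
    second = np.gradient(first, axis=0)
    return first, second


def fit_coupling(gts: GradientTimeseries) -> CouplingModel:
    """Estimate the coupling matrix by per-gradient OLS.

    Each gradient's second-derivative series is regressed on all
    gradients' levels and first derivatives plus an intercept (2K+1
    terms), giving K independent fits.
    """
    g = gts.values
    n, k = g.shape
    if n <= 2 * k + 1:
        raise ValueError(f"need more than {2 * k + 1} timepoints to fit {k} gradients")
    g1, g2 = finite_difference(g)
    design = np.column_stack([np.ones(n), g, g1])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        sd = g.std(axis=0)
        degenerate = [int(i) for i in np.flatnonzero(sd < 1e-12)]
        raise ValueError(
            f"rank-deficient design (rank {rank} of {design.shape[1]}); "
            f"near-constant gradients: {degenerate}"
        )
    beta, *_ = np.linalg.lstsq(design, g2, rcond=None)
    resid = g2 - design @ beta
    tss = np.sum((g2 - g2.mean(axis=0)) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - np.sum(resid**2, axis=0) / tss
    return CouplingModel(beta.T, tr_seconds=gts.tr_seconds, r_squared=r2)


def _fix_phase(vec: np.ndarray, k: int) -> np.ndarray:
    """Rotate an eigenvector so its dominant position entry is real-positive.

    A global complex rotation changes neither amplitudes nor pairwise
    angle differences; fixing it makes outputs deterministic.
    """
    pos = vec[:k]
    j = int(np.argmax(np.abs(pos)))
    phase = np.angle(pos[j]) if np.abs(pos[j]) > 0 else 0.0
    return vec * np.exp(-1j * phase)


def eigenmodes_of(model: CouplingModel) -> list[Eigenmode]:
    """Reduce the 2K companion eigenpairs to K representative modes.

    The positive-frequency member of each conjugate pair is kept; real
    eigenvalues yield zero-frequency modes flagged non-oscillatory.
    Modes are ordered by ascending frequency.  Eigenvectors keep the
    unit 2-norm of the full (position + velocity) vector so amplitudes
    are comparable across subjects.
    """
    a = model.companion()
    k = model.n_gradients
    eigvals, eigvecs = np.linalg.eig(a)
    cond = np.linalg.cond(eigvecs)
    if cond > 1e10:
        raise np.linalg.LinAlgError(
            f"defective or near-defective companion matrix (eigenvector "
            f"condition number {cond:.3g})"
        )
    modes = []
    for i, lam in enumerate(eigvals):
        if lam.imag < -_IMAG_TOL:
            continue  # conjugate partner of a retained mode
        vec = _fix_phase(eigvecs[:, i], k)
        oscillatory = lam.imag > _IMAG_TOL
        modes.append(
            Eigenmode(
                eigenvalue=complex(lam.real, lam.imag if oscillatory else 0.0),
                components=vec[:k].copy(),
                tr_seconds=model.tr_seconds,
                is_oscillatory=oscillatory,
            )
        )
    modes.sort(key=lambda m: m.angular_frequency)
    return modes


def mode_amplitudes(mode: Eigenmode) -> np.ndarray:
    """Per-gradient amplitude on one mode: sqrt((-a+b)^2 + (a+b)^2)."""
    a = mode.components.real
    b = mode.components.imag
    return np.sqrt((-a + b) ** 2 + (a + b) ** 2)


def cumulative_amplitude(modes: list[Eigenmode]) -> np.ndarray:
    """Each gradient's amplitude summed over all modes."""
    if not modes:
        raise ValueError("no modes supplied")
    return np.sum([mode_amplitudes(m) for m in modes], axis=0)


def pair_phase_angles(
    modes: list[Eigenmode],
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative phase angle per gradient pair, with total weight.

    For each oscillatory mode the pair's angle difference is
    ``arg(c_g) - arg(c_h)`` of the complex eigenvector components; the
    cumulative angle is the circular mean of these differences weighted
    by the product of the two gradients' per-mode amplitudes, reported
    as a magnitude in [0, 180] degrees.  Pairs with zero total weight
    get NaN (angle undefined), not an exception.

    Returns ``(angles_deg, weights)``, both K x K symmetric with NaN /
    0 diagonals.
    """
    if not modes:
        raise ValueError("no modes supplied")
    k = modes[0].components.shape[0]
    osc = [m for m in modes if m.is_oscillatory]
    angles = np.full((k, k), np.nan)
    weights = np.zeros((k, k))
    if not osc:
        warnings.warn("no oscillatory modes; all pair angles undefined", stacklevel=2)
        return angles, weights
    amps = np.array([mode_amplitudes(m) for m in osc])  # modes x K
    phases = np.array([np.angle(m.components) for m in osc])  # modes x K
    for g in range(k):
        for h in range(g + 1, k):
            w = amps[:, g] * amps[:, h]
            total = float(w.sum())
            weights[g, h] = weights[h, g] = total
            if total <= 0:
                continue
            delta = phases[:, g] - phases[:, h]
            resultant = np.sum(w * np.exp(1j * delta))
            if np.abs(resultant) == 0:
                continue
            mean_angle = np.degrees(np.angle(resultant))
            folded = abs(((mean_angle + 180.0) % 360.0) - 180.0)
            angles[g, h] = angles[h, g] = folded
    return angles, weights


def simulate_from_model(
    model: CouplingModel,
    n_timepoints: int,
    initial_conditions: np.ndarray | None = None,
    damping_policy: str = "zeroed",
) -> GradientTimeseries:
    """Deterministic trajectory as a superposition of eigenmodes.

    The solution is ``Y(t) = sum_j k_j exp(lambda_j t) v_j`` over all 2K
    companion eigenpairs.  With ``initial_conditions`` (a 2K state
    vector) the constants k solve ``V k = y0``; by default every
    eigenpair gets unit weight (one unit of displacement per mode,
    superposed), which keeps the trajectory real.  ``damping_policy``
    'zeroed' replaces alpha by 0 so modes neither decay nor blow up
    (stationary FC); 'fitted' keeps alpha as estimated.
    """
    if damping_policy not in ("zeroed", "fitted"):
        raise ValueError("damping_policy must be 'zeroed' or 'fitted'")
    a = model.companion()
    k = model.n_gradients
    eigvals, eigvecs = np.linalg.eig(a)
    cond = np.linalg.cond(eigvecs)
    if cond > 1e10:
        raise np.linalg.LinAlgError("ill-conditioned eigenvector matrix")
    if initial_conditions is None:
        consts = np.ones(2 * k, dtype=complex)
    else:
        y0 = np.asarray(initial_conditions, dtype=complex)
        if y0.shape != (2 * k,):
            raise ValueError(f"initial conditions must have shape ({2 * k},)")
        consts = np.linalg.solve(eigvecs, y0)
    lam = eigvals.copy()
    if damping_policy == "zeroed":
        lam = 1j * lam.imag
    t = np.arange(n_timepoints)[:, None]  # sample units
    expo = np.exp(lam[None, :] * t)  # T x 2K
    traj = (expo * consts[None, :]) @ eigvecs[:k].T
    if np.max(np.abs(traj.imag)) > 1e-8 * max(1.0, np.max(np.abs(traj.real))):
        warnings.warn("non-negligible imaginary part in simulated trajectory",
                      stacklevel=2)
    return GradientTimeseries(traj.real, tr_seconds=model.tr_seconds)


def eigenmode_fc(
    model: CouplingModel,
    basis: GradientBasis,
    n_timepoints: int = 4000,
    damping_policy: str = "zeroed",
) -> np.ndarray:
    """FC matrix of basis-rendered, eigenmode-simulated gradient activity."""
    if basis.n_gradients != model.n_gradients:
        raise ValueError("basis gradient count does not match model")
    gts = simulate_from_model(model, n_timepoints, damping_policy=damping_policy)
    bold = gts.values @ basis.eigenvectors.T
    return pearson_fc(bold)


def _upper(values: np.ndarray) -> np.ndarray:
    k = values.shape[0]
    iu = np.triu_indices(k, 1)
    return values[iu]


def amplitude_angle_correspondence(
    amplitudes: np.ndarray,
    angles: np.ndarray,
    variances: np.ndarray,
    covariances: np.ndarray,
) -> dict:
    """Correlate eigenmode summaries with gradient temporal statistics.

    Inputs are per-subject arrays: ``amplitudes`` (n x K), ``angles``
    (n x K(K-1)/2 upper-triangle order), ``variances`` (n x K),
    ``covariances`` (n x K(K-1)/2).  Returns the full (K + P) x (K + P)
    cross-correlation matrix between [amplitudes, angles] and
    [variances, covariances] plus the median absolute correlation over
    corresponding (diagonal) and non-corresponding cells.
    """
    amplitudes = np.asarray(amplitudes, float)
    angles = np.asarray(angles, float)
    variances = np.asarray(variances, float)
    covariances = np.asarray(covariances, float)
    n = amplitudes.shape[0]
    if n < 10:
        warnings.warn("fewer than 10 subjects; correlations are unstable",
                      stacklevel=2)
    left = np.column_stack([amplitudes, angles])
    right = np.column_stack([variances, covariances])
    if np.any(left.std(axis=0) == 0) or np.any(right.std(axis=0) == 0):
        warnings.warn("zero-variance summary column; correlations undefined",
                      stacklevel=2)
    p = left.shape[1]
    corr = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            x, y = left[:, i], right[:, j]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                corr[i, j] = np.nan
            else:
                corr[i, j] = np.corrcoef(x[ok], y[ok])[0, 1]
    diag = np.abs(np.diag(corr))
    off = np.abs(corr[~np.eye(p, dtype=bool)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        med_diag = float(np.nanmedian(diag))
        med_off = float(np.nanmedian(off))
    return {
        "correlation_matrix": corr,
        "median_corresponding_abs_r": med_diag,
        "median_noncorresponding_abs_r": med_off,
    }
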