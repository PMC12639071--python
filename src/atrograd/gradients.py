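"""Latent activity-gradient space: derivation, projection, covariance, and FC.

Regional BOLD timeseries are decomposed by PCA into spatial *gradients*
(region weight maps) and their temporal score series.  Functional
connectivity (FC) can be reconstructed exactly from the covariance of the
full set of gradient timeseries, because the eigenvector change of basis
preserves the data covariance:

    cov(regions) = V @ cov(gradients) @ V.T

with V the orthonormal eigenvector matrix.  Truncating to the leading K
gradients gives the low-dimensional approximation used for dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionalTimeseries",
    "GradientBasis",
    "GradientTimeseries",
    "GradientCovariance",
    "qc_filter_scans",
    "derive_gradient_basis",
    "project_to_gradients",
    "gradient_covariance",
    "pearson_fc",
    "fc_from_gradient_covariance",
    "match_gradient_bases",
]


@dataclass
class RegionalTimeseries:
    """One scan's region-averaged BOLD signal, time x region."""

    values: np.ndarray
    tr_seconds: float = 2.0
    region_ids: list[str] | None = None
    mean_fd: float | None = None  # mean framewise displacement, mm
    scan_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (time x region) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("regional timeseries contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class GradientBasis:
    """Region x K spatial basis from PCA of regional BOLD.

    ``eigenvectors`` holds orthonormal columns used for projection; the
    displayed spatial ``weights`` are the standard loadings, eigenvector
    scaled by the square root of its explained variance.  Component order
    is by decreasing explained variance and gradient 1 is typically
    unipolar (all-positive weights).
    """

    eigenvectors: np.ndarray
    explained_variance: np.ndarray
    region_ids: list[str] | None = None
    reference_id: str | None = None

    def __post_init__(self) -> None:
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.eigenvectors.ndim != 2:
            raise ValueError("eigenvectors must be region x K")
        if self.explained_variance.shape != (self.eigenvectors.shape[1],):
            raise ValueError("explained_variance length must match K")

    @property
    def n_regions(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_gradients(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def weights(self) -> np.ndarray:
        """Spatial loading maps: eigenvector * sqrt(explained variance)."""
        return self.eigenvectors * np.sqrt(np.maximum(self.explained_variance, 0.0))

    def truncate(self, k: int) -> "GradientBasis":
        if k > self.n_gradients:
            raise ValueError(f"cannot truncate to {k} > {self.n_gradients} gradients")
        return GradientBasis(
            self.eigenvectors[:, :k],
            self.explained_variance[:k],
            region_ids=self.region_ids,
            reference_id=self.reference_id,
        )


@dataclass
class GradientTimeseries:
    """Time x gradient latent activity for one scan."""

    values: np.ndarray
    tr_seconds: float = 2.0
    scan_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be time x gradient")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_gradients(self) -> int:
        return self.values.shape[1]


@dataclass
class GradientCovariance:
    """K x K temporal covariance of gradient timeseries for one scan."""

    values: np.ndarray
    scan_id: str | None = None
    degenerate_gradients: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("covariance must be square")


def qc_filter_scans(
    scans: list[RegionalTimeseries],
    fd_threshold: float = 0.55,
    pc_sd_threshold: float = 1.0,
) -> tuple[list[int], list[int]]:
    """Two-stage scan quality control.

    Stage 1 excludes scans whose mean framewise displacement strictly
    exceeds ``fd_threshold`` (mm).  Stage 2 runs a PCA across the
    vectorized FC matrices of the survivors and excludes scans scoring
    more than ``pc_sd_threshold`` standard deviations above the mean on
    the first principal component.  Returns (included, excluded) index
    lists into ``scans``.
    """
    included = []
    excluded = []
    for i, scan in enumerate(scans):
        if scan.mean_fd is not None and scan.mean_fd > fd_threshold:
            excluded.append(i)
        else:
            included.append(i)

    if len(included) < 3:
        warnings.warn(
            "fewer than 3 scans after motion filtering; PCA outlier stage skipped",
            stacklevel=2,
        )
        return included, excluded

    r = scans[included[0]].n_regions
    iu = np.triu_indices(r, k=1)
    edges = np.array([pearson_fc(scans[i].values)[iu] for i in included])
    centered = edges - edges.mean(axis=0)
    # PC1 scores via SVD of the centered edge matrix
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    cutoff = pc1.mean() + pc_sd_threshold * pc1.std(ddof=1)
    keep, drop = [], []
    for idx, score in zip(included, pc1):
        (drop if score > cutoff else keep).append(idx)
    return keep, sorted(excluded + drop)


def derive_gradient_basis(
    reference_scans: list[RegionalTimeseries],
    n_gradients: int,
    region_ids: list[str] | None = None,
    reference_id: str | None = None,
) -> GradientBasis:
    """PCA of temporally concatenated reference scans.

    Each scan's regional columns are mean-centered before concatenation;
    no variance scaling is applied, so loadings retain amplitude
    information.  Component signs are fixed so the largest-magnitude
    region weight is positive; a component whose negative weights carry
    under 1% of squared mass is forced all-positive (unipolar
    convention for gradient 1).
    """
    if not reference_scans:
        raise ValueError("no reference scans supplied")
    blocks = []
    for scan in reference_scans:
        x = scan.values
        blocks.append(x - x.mean(axis=0))
    data = np.vstack(blocks)
    n_total, n_regions = data.shape
    if n_total <= n_regions:
        raise ValueError("total timepoints must exceed the region count")

    _, s, vt = np.linalg.svd(data, full_matrices=False)
    explained = s**2 / (n_total - 1)
    rank = int(np.sum(s > s[0] * 1e-10))
    if rank < n_gradients:
        raise ValueError(
            f"data rank {rank} is below the requested {n_gradients} gradients"
        )
    vecs = vt[:n_gradients].T.copy()
    for k in range(n_gradients):
        col = vecs[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            col *= -1
        if k == 0:
            # gradient 1 forced all-positive when essentially unipolar
            neg_mass = np.sum(col[col < 0] ** 2)
            if neg_mass < 0.01 * np.sum(col**2):
                col[:] = np.abs(col)
    return GradientBasis(
        vecs,
        explained[:n_gradients],
        region_ids=region_ids or (reference_scans[0].region_ids),
        reference_id=reference_id,
    )


def project_to_gradients(
    scan: RegionalTimeseries,
    basis: GradientBasis,
    center: bool = True,
) -> GradientTimeseries:
    """Project a scan into the gradient latent space.

    Scores are the (column-centered) data multiplied by the bare
    eigenvector matrix, so projecting the derivation data reproduces its
    PCA scores exactly.
    """
    if basis.region_ids is not None and scan.region_ids is not None:
        if list(scan.region_ids) != list(basis.region_ids):
            bad = [r for r in scan.region_ids if r not in set(basis.region_ids)]
            raise ValueError(
                f"scan region order does not match basis; offending ids: {bad[:10]}"
            )
    if scan.n_regions != basis.n_regions:
        raise ValueError(
            f"scan has {scan.n_regions} regions, basis expects {basis.n_regions}"
        )
    x = scan.values
    if center:
        x = x - x.mean(axis=0)
    return GradientTimeseries(
        x @ basis.eigenvectors, tr_seconds=scan.tr_seconds, scan_id=scan.scan_id
    )


def gradient_covariance(gts: GradientTimeseries) -> GradientCovariance:
    """Unbiased temporal covariance of the gradient columns."""
    if gts.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints for a covariance")
    c = np.cov(gts.values, rowvar=False, ddof=1)
    c = np.atleast_2d(c)
    degenerate = [int(i) for i in np.flatnonzero(np.diag(c) == 0.0)]
    return GradientCovariance(c, scan_id=gts.scan_id, degenerate_gradients=degenerate)


def pearson_fc(values: np.ndarray) -> np.ndarray:
    """Region-pairwise Pearson correlation matrix of a time x region array."""
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("constant region timeseries; correlations set to NaN", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    return fc


def fc_from_gradient_covariance(
    cov: GradientCovariance | np.ndarray,
    eigenvectors: np.ndarray,
) -> np.ndarray:
    """Reconstruct region-level FC from gradient covariance.

    Region covariance is ``V @ C @ V.T``; normalizing by the square root
    of the diagonal gives correlations.  With the full component set this
    equals the direct Pearson FC of the scan exactly; with a truncated
    basis it is the low-rank approximation.
    """
    c = cov.values if isinstance(cov, GradientCovariance) else np.asarray(cov, float)
    v = np.asarray(eigenvectors, dtype=float)
    if v.shape[1] != c.shape[0]:
        raise ValueError(
            f"eigenvector matrix has {v.shape[1]} components, covariance is "
            f"{c.shape[0]}x{c.shape[0]}"
        )
    region_cov = v @ c @ v.T
    var = np.diag(region_cov).copy()
    bad = var <= 0
    if np.any(bad):
        warnings.warn("zero region variance; correlation rows set to NaN", stacklevel=2)
        var[bad] = np.nan
    d = 1.0 / np.sqrt(var)
    fc = region_cov * d[:, None] * d[None, :]
    np.fill_diagonal(fc, 1.0)
    fc[bad, :] = np.nan
    fc[:, bad] = np.nan
    return fc


def match_gradient_bases(
    basis_a: GradientBasis, basis_b: GradientBasis
) -> tuple[np.ndarray, np.ndarray]:
    """Per-component spatial correlation after optimal sign alignment.

    Returns ``(r, flips)`` where ``r[k]`` is the Pearson correlation of
    component k's weight maps after applying sign flip ``flips[k]`` (+1
    or -1) to basis B.
    """
    if basis_a.n_regions != basis_b.n_regions:
        raise ValueError("bases cover different region sets")
    k = min(basis_a.n_gradients, basis_b.n_gradients)
    r = np.empty(k)
    flips = np.empty(k)
    for i in range(k):
        a = basis_a.eigenvectors[:, i]
        b = basis_b.eigenvectors[:, i]
        raw = np.corrcoef(a, b)[0, 1]
        flips[i] = 1.0 if raw >= 0 else -1.0
        r[i] = raw * flips[i]
    return r, flips
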