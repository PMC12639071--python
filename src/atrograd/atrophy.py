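"""Normative atrophy scoring, scanner harmonization, and cohort summaries.

The W-score expresses a subject's regional gray-matter volume as a
deviation from a covariate-adjusted normative prediction, in units of
the normative residual SD.  Scores are stored *atrophy-positive*:

    W = (estimated - actual) / SD

so that more atrophy gives a larger W and affected-region thresholds
read naturally as ``W > 1.5``.  The opposite (actual - estimated)
convention is available through ``atrophy_positive=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NormativeModel",
    "fit_normative_model",
    "compute_w_scores",
    "harmonize_location_scale",
    "flag_affected_regions",
    "jaccard_overlap",
]


@dataclass
class NormativeModel:
    """Per-region OLS over covariates, with residual SDs."""

    coefficients: np.ndarray  # (p+1) x n_regions, row 0 = intercept
    residual_sds: np.ndarray  # n_regions
    covariate_names: list[str]
    region_ids: list[str]
    degenerate_regions: list[str]

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        x = _design(covariates, self.covariate_names)
        return x @ self.coefficients


def _design(covariates: pd.DataFrame, names: list[str]) -> np.ndarray:
    missing = [c for c in names if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariate columns missing: {missing}")
    x = covariates[names].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(covariates)), x])


def fit_normative_model(
    volumes: pd.DataFrame, covariates: pd.DataFrame
) -> NormativeModel:
    """Fit per-region OLS of volume on covariates.

    Residual SD uses the n - p - 1 denominator (p covariates plus
    intercept).  Regions whose residual SD is numerically zero are
    flagged degenerate.  Rank-deficient covariates raise an error naming
    the collinear columns.
    """
    names = list(covariates.columns)
    y = volumes.to_numpy(dtype=float)
    if np.any(~np.isfinite(y)) or covariates.isna().any().any():
        raise ValueError("missing values in volumes or covariates")
    n, p1 = len(volumes), len(names) + 1
    if n <= p1 + 1:
        raise ValueError(f"need more than {p1 + 1} subjects to fit {p1} terms")
    x = _design(covariates, names)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        collinear = []
        base_rank = np.linalg.matrix_rank(x[:, :1])
        kept = [0]
        for j in range(1, x.shape[1]):
            r = np.linalg.matrix_rank(x[:, kept + [j]])
            if r == base_rank:
                collinear.append(names[j - 1])
            else:
                kept.append(j)
                base_rank = r
        raise ValueError(f"rank-deficient covariates; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sd = np.sqrt(np.sum(resid**2, axis=0) / (n - p1))
    degenerate = [volumes.columns[i] for i in np.flatnonzero(sd < 1e-12)]
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} regions have (near-)zero residual SD; "
            "W-scores are degenerate there",
            stacklevel=2,
        )
    return NormativeModel(
        coefficients=beta,
        residual_sds=sd,
        covariate_names=names,
        region_ids=list(volumes.columns),
        degenerate_regions=degenerate,
    )


def compute_w_scores(
    volumes: pd.DataFrame,
    covariates: pd.DataFrame,
    model: NormativeModel,
    atrophy_positive: bool = True,
) -> pd.DataFrame:
    """Regional W-scores against a fitted normative model."""
    unknown = [r for r in volumes.columns if r not in set(model.region_ids)]
    if unknown:
        raise KeyError(f"regions not in the normative model: {unknown[:10]}")
    vols = volumes[model.region_ids]
    predicted = model.predict(covariates)
    sd = model.residual_sds.copy()
    sd[sd < 1e-12] = np.nan
    w = (predicted - vols.to_numpy(dtype=float)) / sd
    if not atrophy_positive:
        w = -w
    return pd.DataFrame(w, index=volumes.index, columns=model.region_ids)


def harmonize_location_scale(
    features: pd.DataFrame | np.ndarray,
    batch: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame | np.ndarray:
    """Remove batch location and scale effects, preserving covariates.

    A location-and-scale adjustment in the ComBat family without the
    empirical-Bayes shrinkage step: per feature, fit OLS on biological
    covariates plus batch indicators, standardize residuals by the
    pooled SD, estimate each batch's additive shift and multiplicative
    scale on the standardized data, and remove them.  Applies uniformly
    to W-score vectors and vectorized FC/covariance features.
    """
    is_frame = isinstance(features, pd.DataFrame)
    x = features.to_numpy(dtype=float) if is_frame else np.asarray(features, float)
    batch = np.asarray(batch)
    n, d = x.shape
    if batch.shape[0] != n:
        raise ValueError("batch labels must match the number of rows")
    levels, idx = np.unique(batch, return_inverse=True)
    if levels.size < 2:
        warnings.warn("single batch; harmonization is the identity", stacklevel=2)
        return features
    counts = np.bincount(idx)
    if np.any(counts < 2):
        raise ValueError("every batch needs at least 2 subjects")

    cov = np.empty((n, 0))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    onehot = np.eye(levels.size)[idx]
    design = np.column_stack([np.ones(n), cov, onehot[:, 1:]])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ beta
    pooled_sd = resid.std(axis=0, ddof=design.shape[1])
    pooled_sd[pooled_sd < 1e-12] = 1.0
    # the covariate-only part of the fit (batch terms excluded) is what
    # harmonized data should retain
    n_keep = 1 + cov.shape[1]
    stand_mean = design[:, :n_keep] @ beta[:n_keep]
    # grand batch offset folded back into the retained mean so the output
    # is centered like a batch-balanced cohort
    batch_effects = np.vstack([np.zeros(d), beta[n_keep:]])
    grand = (counts / n) @ batch_effects
    stand_mean = stand_mean + grand
    z = (x - stand_mean - (batch_effects[idx] - grand)) / pooled_sd
    gamma = np.zeros((levels.size, d))
    delta = np.ones((levels.size, d))
    for b in range(levels.size):
        zb = z[idx == b]
        gamma[b] = zb.mean(axis=0)
        sdb = zb.std(axis=0, ddof=1)
        sdb[sdb < 1e-12] = 1.0
        delta[b] = sdb
    adjusted = (z - gamma[idx]) / delta[idx] * pooled_sd + stand_mean
    if is_frame:
        return pd.DataFrame(adjusted, index=features.index, columns=features.columns)
    return adjusted


def flag_affected_regions(
    w_scores: pd.DataFrame | np.ndarray,
    w_threshold: float = 1.5,
    min_patients: int = 5,
) -> np.ndarray:
    """Flag regions where >= ``min_patients`` subjects exceed the W cutoff.

    The W threshold is strict (W > threshold); the patient count is
    inclusive (five or more).
    """
    if w_threshold <= 0:
        raise ValueError("w_threshold must be positive")
    w = w_scores.to_numpy() if isinstance(w_scores, pd.DataFrame) else np.asarray(w_scores)
    if w.shape[0] == 0:
        warnings.warn("empty cohort; no regions flagged", stacklevel=2)
        return np.zeros(w.shape[1] if w.ndim == 2 else 0, dtype=bool)
    counts = np.sum(w > w_threshold, axis=0)
    return counts >= min_patients


def jaccard_overlap(flags_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Jaccard index of affected-region sets across groups.

    Returns a symmetric group x group matrix with unit diagonal; the
    mean over the off-diagonal upper triangle is stored in
    ``result.attrs['mean_off_diagonal']``.
    """
    names = list(flags_by_group)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    sets = {g: np.asarray(v, dtype=bool) for g, v in flags_by_group.items()}
    m = len(names)
    j = np.eye(m)
    for a in range(m):
        for b in range(a + 1, m):
            fa, fb = sets[names[a]], sets[names[b]]
            union = np.sum(fa | fb)
            if union == 0:
                warnings.warn(
                    f"groups {names[a]} and {names[b]} both empty; J set to 0",
                    stacklevel=2,
                )
                j[a, b] = j[b, a] = 0.0
            else:
                j[a, b] = j[b, a] = np.sum(fa & fb) / union
    out = pd.DataFrame(j, index=names, columns=names)
    iu = np.triu_indices(m, 1)
    out.attrs["mean_off_diagonal"] = float(j[iu].mean())
    return out
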