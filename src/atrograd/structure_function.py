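"""PLSR linking of atrophy maps to functional connectivity edges.

Partial least squares regression decomposes the atrophy matrix X
(subjects x regions) into components that maximally covary with the FC
edge matrix Y (subjects x edges).  Each component pairs a structure
score S_k (X side) with a function score F_k (Y side); syndromes'
typical FC alterations can be reconstructed from three components'
scores and edge loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import Ridge, RidgeCV
from sklearn.model_selection import KFold

__all__ = [
    "PLSRModel",
    "vectorize_fc",
    "devectorize_fc",
    "fit_plsr",
    "crossval_function_scores",
    "reconstruct_fc",
    "typical_subset_lda",
    "mds_embed",
    "explain_fc_by_gradient_terms",
]

RIDGE_GRID = np.logspace(-2, 4, 13)


def vectorize_fc(fc: np.ndarray) -> np.ndarray:
    """Upper-triangle edge vector in fixed (i<j, row-major) order."""
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError("FC matrix must be square")
    if np.nanmax(np.abs(fc - fc.T)) > 1e-8:
        raise ValueError("FC matrix is not symmetric")
    return fc[np.triu_indices(fc.shape[0], 1)]


def devectorize_fc(edges: np.ndarray, diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric matrix from an upper-triangle edge vector."""
    edges = np.asarray(edges, dtype=float)
    m = edges.size
    r = int((1 + np.sqrt(1 + 8 * m)) / 2)
    if r * (r - 1) // 2 != m:
        raise ValueError(f"edge vector length {m} is not a triangular number")
    fc = np.zeros((r, r))
    iu = np.triu_indices(r, 1)
    fc[iu] = edges
    fc = fc + fc.T
    np.fill_diagonal(fc, diagonal)
    return fc


@dataclass
class PLSRModel:
    """Fitted PLSR with paired structure/function scores.

    Structure scores S (X side) and function scores F (Y side) are
    per-subject; weights/loadings live on the region (X) and edge (Y)
    sides.  Component signs are fixed so S1 correlates positively with
    overall mean atrophy and components 2+ have a positive
    largest-magnitude region weight.
    """

    n_components: int
    x_weights: np.ndarray  # regions x k
    x_loadings: np.ndarray
    y_weights: np.ndarray  # edges x k
    y_loadings: np.ndarray
    x_scores: np.ndarray  # subjects x k (S)
    y_scores: np.ndarray  # subjects x k (F)
    x_mean: np.ndarray
    y_mean: np.ndarray
    explained_x_variance: np.ndarray  # fraction per component
    score_correlations: np.ndarray  # in-sample r(S_k, F_k)
    _pls: PLSRegression | None = None

    def transform_x(self, x: np.ndarray) -> np.ndarray:
        """Structure scores for new atrophy maps."""
        return self._pls.transform(np.asarray(x, float))


def fit_plsr(x: np.ndarray, y: np.ndarray, n_components: int = 3) -> PLSRModel:
    """NIPALS PLS2 with Y-deflation (regression mode).

    X and Y are centered but not variance-scaled: regional W-scores
    share units, and scaling would distort the interpretation of
    component 1 as overall mean atrophy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must have the same number of subjects")
    if x.shape[0] <= n_components:
        raise ValueError("need more subjects than components")
    if np.allclose(y.std(axis=0), 0):
        raise ValueError("Y has zero variance")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(x, y)
    xs = pls.x_scores_.copy()
    ys = pls.y_scores_.copy()
    xw = pls.x_weights_.copy()
    xl = pls.x_loadings_.copy()
    yw = pls.y_weights_.copy()
    yl = pls.y_loadings_.copy()
    # sign convention
    xc = x - x.mean(axis=0)
    mean_atrophy = xc.mean(axis=1)
    for k in range(n_components):
        if k == 0:
            flip = np.corrcoef(xs[:, 0], mean_atrophy)[0, 1] < 0
        else:
            flip = xw[np.argmax(np.abs(xw[:, k])), k] < 0
        if flip:
            xs[:, k] *= -1
            ys[:, k] *= -1
            xw[:, k] *= -1
            xl[:, k] *= -1
            yw[:, k] *= -1
            yl[:, k] *= -1
            # keep the sklearn transformer consistent with the flip
            pls.x_weights_[:, k] *= -1
            pls.x_loadings_[:, k] *= -1
            pls.y_weights_[:, k] *= -1
            pls.y_loadings_[:, k] *= -1
            pls.x_scores_[:, k] *= -1
            pls.y_scores_[:, k] *= -1
            pls.x_rotations_[:, k] *= -1
            pls.y_rotations_[:, k] *= -1
    total_x = np.sum(xc**2)
    explained = np.array(
        [np.sum(np.outer(xs[:, k], xl[:, k]) ** 2) / total_x
         for k in range(n_components)]
    )
    score_r = np.array(
        [np.corrcoef(xs[:, k], ys[:, k])[0, 1] for k in range(n_components)]
    )
    return PLSRModel(
        n_components=n_components,
        x_weights=xw,
        x_loadings=xl,
        y_weights=yw,
        y_loadings=yl,
        x_scores=xs,
        y_scores=ys,
        x_mean=x.mean(axis=0),
        y_mean=y.mean(axis=0),
        explained_x_variance=explained,
        score_correlations=score_r,
        _pls=pls,
    )


def ridge_function_scores(
    y: np.ndarray, model: PLSRModel, alpha: float | None = None
) -> np.ndarray:
    """Function scores predicted from FC edges by ridge regression.

    Ridge maps the edge matrix onto the fitted Y-scores; the penalty is
    chosen by 3-fold CV over a log grid unless given.
    """
    yc = np.asarray(y, float) - model.y_mean
    if alpha is None:
        est = RidgeCV(alphas=RIDGE_GRID, cv=3)
    else:
        est = Ridge(alpha=alpha)
    est.fit(yc, model.y_scores)
    return est.predict(yc)


def crossval_function_scores(
    x: np.ndarray,
    y: np.ndarray,
    n_components: int = 3,
    folds: int = 4,
    seed: int = 0,
    ridge_alphas: np.ndarray = RIDGE_GRID,
) -> dict:
    """Out-of-sample function scores via k-fold ridge prediction.

    For each fold, PLSR is fit on the training subjects; a ridge model
    (penalty by inner 3-fold CV over a log grid) maps training FC edges
    to training Y-scores; held-out function scores are predicted from
    held-out edges and correlated with held-out structure scores.
    Returns per-component out-of-sample r plus the score arrays.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.shape[0]
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if n // folds < 3:
        raise ValueError("folds with fewer than 3 subjects")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    s_oos = np.full((n, n_components), np.nan)
    f_oos = np.full((n, n_components), np.nan)
    for train, test in kf.split(x):
        model = fit_plsr(x[train], y[train], n_components)
        ridge = RidgeCV(alphas=ridge_alphas, cv=3)
        ridge.fit(y[train] - model.y_mean, model.y_scores)
        f_oos[test] = ridge.predict(y[test] - model.y_mean)
        s_oos[test] = model.transform_x(x[test])
    r = np.array(
        [np.corrcoef(s_oos[:, k], f_oos[:, k])[0, 1] for k in range(n_components)]
    )
    return {"r": r, "structure_scores": s_oos, "function_scores": f_oos}


def reconstruct_fc(scores: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Edge vectors reconstructed as score-loading outer products.

    ``scores`` is subjects x k (function scores), ``loadings`` edges x
    k; the result is subjects x edges, i.e. each subject's modeled FC
    deviation pattern.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    loadings = np.asarray(loadings, float)
    if scores.shape[1] != loadings.shape[1]:
        raise ValueError(
            f"component mismatch: scores have {scores.shape[1]}, "
            f"loadings {loadings.shape[1]}"
        )
    return scores @ loadings.T


def typical_subset_lda(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Subjects whose syndrome is correctly predicted from their scores.

    In-sample linear discriminant analysis on the structure component
    scores; the retained "typical" subset is where prediction matches
    the true label.  Returns (boolean retained mask, predicted labels).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if np.any(counts < 4):
        small = classes[counts < 4].tolist()
        raise ValueError(f"classes with fewer than 4 subjects: {small}")
    lda = LinearDiscriminantAnalysis()
    try:
        lda.fit(scores, labels)
    except np.linalg.LinAlgError:
        warnings.warn("singular within-class covariance; shrinkage applied",
                      stacklevel=2)
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        lda.fit(scores, labels)
    pred = lda.predict(scores)
    return pred == labels, pred


def mds_embed(scores: np.ndarray, dim: int = 2) -> tuple[np.ndarray, float]:
    """Classical (Torgerson) MDS of the score cloud.

    For Euclidean input this is PCA of the centered coordinates.
    Returns (embedded coordinates, correlation between original and
    embedded pairwise distances).
    """
    scores = np.asarray(scores, float)
    if dim >= scores.shape[1] + 1:
        raise ValueError("embedding dimension must be below the score dimension")
    centered = scores - scores.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    coords = u[:, :dim] * s[:dim]
    from scipy.spatial.distance import pdist

    d_orig = pdist(scores)
    d_emb = pdist(coords)
    if d_orig.std() == 0 or d_emb.std() == 0:
        r = 1.0 if np.allclose(d_orig, d_emb) else 0.0
    else:
        r = float(np.corrcoef(d_orig, d_emb)[0, 1])
    return coords, r


def explain_fc_by_gradient_terms(
    f_scores: np.ndarray, features: np.ndarray, feature_names: list[str] | None = None
) -> dict:
    """Variance in a function component explained by gradient terms.

    ``features`` holds each subject's gradient temporal variances and
    pairwise covariances (K + K(K-1)/2 columns, fixed order).  Features
    are standardized and regressed on the function score; each term's
    share is its squared semi-partial correlation (the R-squared drop
    when that term is removed), with signed t statistics from the full
    model.
    """
    f_scores = np.asarray(f_scores, float)
    features = np.asarray(features, float)
    n, p = features.shape
    sd = features.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant feature column")
    z = (features - features.mean(axis=0)) / sd
    design = sm.add_constant(z)
    if np.linalg.cond(design) > 1e8:
        warnings.warn("collinear gradient features; ridge fallback used",
                      stacklevel=2)
        ridge = Ridge(alpha=1.0).fit(z, f_scores)
        pred = ridge.predict(z)
        r2 = 1 - np.sum((f_scores - pred) ** 2) / np.sum(
            (f_scores - f_scores.mean()) ** 2
        )
        return {"r_squared": float(r2), "shares": None,
                "t_values": None, "names": feature_names}
    fit = sm.OLS(f_scores, design).fit()
    r2_full = fit.rsquared
    shares = np.empty(p)
    for j in range(p):
        cols = [0] + [1 + i for i in range(p) if i != j]
        r2_red = sm.OLS(f_scores, design[:, cols]).fit().rsquared
        shares[j] = r2_full - r2_red
    return {
        "r_squared": float(r2_full),
        "shares": shares,
        "t_values": fit.tvalues[1:],
        "p_values": fit.pvalues[1:],
        "names": feature_names,
    }
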