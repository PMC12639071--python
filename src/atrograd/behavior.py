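"""Brain-behavior additive models and FDR control.

Cognitive scores are modeled as additive functions of the six brain
predictors (structure scores S1-S3 and function scores F1-F3), each
entering as a regression spline with basis dimension capped at 3, plus
strictly linear nuisance covariates (age, sex, education, scanner, head
motion).  With so small a basis the spline cap itself controls
wiggliness, so terms are fit unpenalized and tested with exact
partial F tests; a separate nested-model F isolates each term's
nonlinear part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.gam.smooth_basis import BSplines
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BehaviorModelSpec",
    "BehaviorResult",
    "fit_additive_model",
    "fdr_correct",
    "variance_explained_summary",
]


@dataclass
class BehaviorModelSpec:
    """Model layout for one cognitive test."""

    response: str
    brain_predictors: list[str] = field(
        default_factory=lambda: ["S1", "S2", "S3", "F1", "F2", "F3"]
    )
    covariates: list[str] = field(default_factory=list)
    basis_dim: int = 3
    min_n: int = 120

    def __post_init__(self) -> None:
        if self.basis_dim > 3:
            raise ValueError("smooth basis dimension is capped at 3")


@dataclass
class BehaviorResult:
    response: str
    n: int
    r_squared: float
    term_f: dict[str, float]
    term_p: dict[str, float]
    nonlinear_f: dict[str, float]
    nonlinear_p: dict[str, float]
    partial_effects: dict[str, pd.DataFrame]
    fdr_flags: dict[str, bool] | None = None


def _spline_basis(x: np.ndarray, df: int):
    """Regression-spline columns for one standardized predictor.

    Returns (basis, transform) where ``transform`` evaluates the same
    basis (same knots) at new points.
    """
    if df < 2:
        return x[:, None], lambda g: g[:, None]
    bs = BSplines(x[:, None], df=[df], degree=[min(df - 1, 3)],
                  include_intercept=False)
    return bs.basis, lambda g: bs.transform(np.clip(g, x.min(), x.max())[:, None])


def _nested_f(rss_full: float, rss_red: float, df_diff: int, df_resid: int):
    if df_diff <= 0 or rss_full <= 0:
        return np.nan, np.nan
    f = ((rss_red - rss_full) / df_diff) / (rss_full / df_resid)
    f = max(f, 0.0)
    p = stats.f.sf(f, df_diff, df_resid)
    return float(f), float(p)


def fit_additive_model(
    data: pd.DataFrame, spec: BehaviorModelSpec
) -> BehaviorResult | None:
    """Fit one cognitive test's additive model.

    ``data`` holds the response column plus all predictor and covariate
    columns; rows with a missing response are dropped, and the test is
    skipped (returns None) when fewer than ``spec.min_n`` responses
    remain.  Brain predictors are standardized and enter through a
    basis-3 regression spline; covariates enter linearly.  Each brain
    term gets a partial F test (all its columns) and a nonlinearity F
    test (its columns beyond the linear one).
    """
    needed = [spec.response] + spec.brain_predictors + spec.covariates
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise KeyError(f"columns missing from data: {missing}")
    sub = data[needed].dropna(subset=[spec.response])
    sub = sub.dropna()
    n = len(sub)
    if n < spec.min_n:
        return None
    y = sub[spec.response].to_numpy(dtype=float)

    blocks: list[np.ndarray] = [np.ones((n, 1))]
    term_cols: dict[str, list[int]] = {}
    linear_col: dict[str, int] = {}
    col = 1
    xgrids: dict[str, np.ndarray] = {}
    for name in spec.brain_predictors:
        x = sub[name].to_numpy(dtype=float)
        mu, sd = x.mean(), x.std(ddof=1)
        sd = sd if sd > 0 else 1.0
        z = (x - mu) / sd
        basis, transform = _spline_basis(z, spec.basis_dim)
        # put the raw linear column first so the nonlinear part is the rest
        block = np.column_stack([z, basis])
        blocks.append(block)
        term_cols[name] = list(range(col, col + block.shape[1]))
        linear_col[name] = col
        col += block.shape[1]
        xgrids[name] = (np.linspace(z.min(), z.max(), 50), mu, sd, transform)
    for name in spec.covariates:
        c = sub[name].to_numpy(dtype=float)[:, None]
        blocks.append(c)
        col += 1
    design = np.column_stack(blocks)
    # drop numerically dependent columns within each term (the linear
    # column can be collinear with the spline basis)
    keep = _independent_columns(design)
    design_k = design[:, keep]
    beta, *_ = np.linalg.lstsq(design_k, y, rcond=None)
    fitted = design_k @ beta
    rss_full = float(np.sum((y - fitted) ** 2))
    df_resid = n - design_k.shape[1]
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1 - rss_full / tss if tss > 0 else 0.0

    def _rss_without(cols: list[int]) -> tuple[float, int]:
        cset = set(cols)
        sub_keep = [i for i, j in enumerate(keep) if j not in cset]
        red = design_k[:, sub_keep]
        b, *_ = np.linalg.lstsq(red, y, rcond=None)
        dropped = design_k.shape[1] - red.shape[1]
        return float(np.sum((y - red @ b) ** 2)), dropped

    term_f, term_p, nl_f, nl_p = {}, {}, {}, {}
    effects: dict[str, pd.DataFrame] = {}
    cov_beta = rss_full / df_resid * np.linalg.pinv(design_k.T @ design_k)
    for name in spec.brain_predictors:
        rss_red, dropped = _rss_without(term_cols[name])
        term_f[name], term_p[name] = _nested_f(rss_full, rss_red, dropped, df_resid)
        nl_cols = [c for c in term_cols[name] if c != linear_col[name]]
        rss_lin, dropped_nl = _rss_without(nl_cols)
        nl_f[name], nl_p[name] = _nested_f(rss_full, rss_lin, dropped_nl, df_resid)
        # partial effect on a grid with +-2 SE bands
        grid, mu, sd, transform = xgrids[name]
        gb = np.column_stack([grid, transform(grid)])
        gb_full = np.zeros((grid.size, design.shape[1]))
        gb_full[:, term_cols[name]] = gb
        gb_k = gb_full[:, keep]
        est = gb_k @ beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", gb_k, cov_beta, gb_k), 0))
        effects[name] = pd.DataFrame(
            {"x": grid * sd + mu, "effect": est - est.mean(),
             "lower": est - est.mean() - 2 * se,
             "upper": est - est.mean() + 2 * se}
        )
    return BehaviorResult(
        response=spec.response, n=n, r_squared=float(r2),
        term_f=term_f, term_p=term_p,
        nonlinear_f=nl_f, nonlinear_p=nl_p,
        partial_effects=effects,
    )


def _independent_columns(design: np.ndarray, tol: float = 1e-8) -> list[int]:
    keep: list[int] = []
    basis = np.empty((design.shape[0], 0))
    for j in range(design.shape[1]):
        candidate = np.column_stack([basis, design[:, j]])
        if np.linalg.matrix_rank(candidate, tol * np.linalg.norm(design)) > basis.shape[1]:
            keep.append(j)
            basis = candidate
    return keep


def fdr_correct(
    p_values: np.ndarray | pd.Series, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over one analysis family.

    NaN p-values are excluded (their flags stay False, adjusted p NaN).
    Returns (rejection flags, adjusted p-values).
    """
    p = np.asarray(p_values, dtype=float)
    flags = np.zeros(p.shape, dtype=bool)
    adjusted = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum() == 0:
        return flags, adjusted
    rej, adj, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
    flags[ok] = rej
    adjusted[ok] = adj
    return flags, adjusted


def variance_explained_summary(results: list[BehaviorResult]) -> pd.DataFrame:
    """Per-test R-squared with the strongest predictors by F statistic."""
    if not results:
        raise ValueError("no fitted behavior models")
    rows = []
    for res in results:
        top = sorted(res.term_f, key=lambda k: -res.term_f[k])[:3]
        rows.append(
            {"test": res.response, "n": res.n, "r_squared": res.r_squared,
             "top_terms": ",".join(top)}
        )
    out = pd.DataFrame(rows).set_index("test")
    out.attrs["mean_r_squared"] = float(out["r_squared"].mean())
    out.attrs["sd_r_squared"] = float(out["r_squared"].std(ddof=1)) if len(out) > 1 else 0.0
    return out
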