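"""Gaussian GLMs for the elevation × footprint comparison, BIC Bayes factors,
Pearson correlations, and penalized-spline upstream–downstream trends.

mod0 (direct) regresses a scaled facet on scaled elevation, footprint,
AutoCor and Type; mod1 (synergy) adds the elevation × footprint interaction.
The Bayes factor bf01 = exp(0.5·(BIC(mod1) − BIC(mod0))) quantifies evidence
in favour of the direct model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import BSpline


@dataclass
class GLMFit:
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    bic: float
    residuals: np.ndarray
    n: int
    k: int  # estimated parameters incl. intercept and dispersion


@dataclass
class InteractionVerdict:
    facet: str
    fit0: GLMFit
    fit1: GLMFit
    bf01: float
    interaction_supported: bool


def zscore(x: pd.Series | np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot scale a constant column")
    return (x - x.mean()) / sd


def fit_glm(y: np.ndarray | pd.Series, X: pd.DataFrame, family: str = "gaussian") -> GLMFit:
    """Maximum-likelihood Gaussian GLM (identity link) with Wald inference.

    BIC = −2·logLik + k·ln(n) with k counting every estimated parameter,
    including the intercept and the Gaussian dispersion.  A rank-deficient
    design raises an error naming the collinear columns.
    """
    if family != "gaussian":
        raise ValueError(f"unsupported family {family!r}")
    y = np.asarray(y, float)
    design = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.shape[1]:
        collinear = []
        base_cols: list[int] = []
        for j in range(design.shape[1]):
            if np.linalg.matrix_rank(design.values[:, base_cols + [j]]) == len(base_cols):
                collinear.append(design.columns[j])
            else:
                base_cols.append(j)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("need more observations than parameters")
    res = sm.OLS(y, design).fit()
    k = design.shape[1] + 1  # + dispersion
    n = len(y)
    bic = -2 * res.llf + k * math.log(n)
    return GLMFit(
        terms=list(design.columns),
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        llf=float(res.llf),
        bic=float(bic),
        residuals=np.asarray(res.resid),
        n=n,
        k=k,
    )


def bayes_factor_bf01(bic1: float, bic0: float) -> float:
    """BIC-approximate Bayes factor in favour of mod0: exp(0.5·(BIC1 − BIC0))."""
    return math.exp(0.5 * (bic1 - bic0))


def compare_interaction(
    facet: pd.Series,
    covariates: pd.DataFrame,
    facet_name: str = "facet",
) -> InteractionVerdict:
    """Fit the direct (mod0) and synergy (mod1) models and compare by bf01.

    The facet and elevation are scaled (mean 0, sd 1) before fitting; mod1
    adds the scaled-elevation × footprint product.  bf01 < 1 means the BIC
    evidence favours the synergy model, so the interaction is supported;
    bf01 ≥ 1 (including ties) yields a no-interaction verdict.  Raw BICs are
    carried in the verdict for reinterpretation.
    """
    required = ["elevation", "footprint", "AutoCor", "Type"]
    missing = [c for c in required if c not in covariates.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    y = zscore(facet)
    X0 = pd.DataFrame(
        {
            "elevation": zscore(covariates["elevation"]),
            "footprint": covariates["footprint"].astype(float).values,
            "AutoCor": covariates["AutoCor"].astype(float).values,
            "Type": covariates["Type"].astype(float).values,
        },
        index=covariates.index,
    )
    X1 = X0.copy()
    X1["elevation:footprint"] = X0["elevation"] * X0["footprint"]
    fit0 = fit_glm(y, X0)
    fit1 = fit_glm(y, X1)
    bf01 = bayes_factor_bf01(fit1.bic, fit0.bic)
    return InteractionVerdict(
        facet=facet_name,
        fit0=fit0,
        fit1=fit1,
        bf01=bf01,
        interaction_supported=bf01 < 1,
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Penalized-spline trend (GAM-style smooth)


@dataclass
class SmoothTrend:
    x: np.ndarray           # sorted predictor
    fitted: np.ndarray
    lower: np.ndarray       # pointwise 95% band
    upper: np.ndarray
    edf: float              # effective degrees of freedom
    gcv_alpha: float
    pearson: tuple[float, float]  # r, p of (x, y)


def _bspline_basis(x: np.ndarray, df: int, degree: int = 3) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = x.min(), x.max()
    n_interior = max(df - degree - 1, 0)
    interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior else np.array([])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    basis = BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()
    return basis, knots


def smooth_trend(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    df: int = 8,
    alphas: np.ndarray | None = None,
) -> SmoothTrend:
    """Penalized cubic B-spline smooth with GCV-selected penalty.

    Minimises ||y − Bβ||² + α·||D₂β||² (second-difference penalty) over an
    α grid by generalized cross-validation.  Returns fitted values with a
    pointwise 95% band from the smoother matrix, plus the Pearson r of (x, y)
    reported alongside the trend.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 8:
        raise ValueError("need at least 8 observations")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    df = min(df, len(xs) - 2)
    B, _ = _bspline_basis(xs, df)
    p = B.shape[1]
    D = np.diff(np.eye(p), n=2, axis=0)
    P = D.T @ D
    if alphas is None:
        alphas = np.concatenate([[1e-8], np.logspace(-4, 6, 41)])
    BtB = B.T @ B
    Bty = B.T @ ys
    n = len(ys)
    best = None
    for alpha in alphas:
        A = BtB + alpha * P
        try:
            beta = np.linalg.solve(A, Bty)
            H_diag_sum = np.trace(np.linalg.solve(A, BtB))
        except np.linalg.LinAlgError:
            continue
        fitted = B @ beta
        rss = float(((ys - fitted) ** 2).sum())
        edf = float(H_diag_sum)
        denom = (1 - edf / n) ** 2
        if denom <= 0:
            continue
        gcv = rss / n / denom
        if best is None or gcv < best[0]:
            best = (gcv, alpha, beta, fitted, edf, A)
    if best is None:
        raise ValueError("GCV selection failed")
    _, alpha, beta, fitted, edf, A = best
    sigma2 = float(((ys - fitted) ** 2).sum()) / max(n - edf, 1.0)
    # smoother matrix H = B A^{-1} Bᵀ; var(fit) = σ²·diag(H Hᵀ)
    Ainv_Bt = np.linalg.solve(A, B.T)
    H = B @ Ainv_Bt
    se = np.sqrt(np.clip(sigma2 * np.einsum("ij,ij->i", H, H), 0, None))
    r, pv = pearson_r(xs, ys)
    return SmoothTrend(
        x=xs,
        fitted=fitted,
        lower=fitted - 1.96 * se,
        upper=fitted + 1.96 * se,
        edf=edf,
        gcv_alpha=float(alpha),
        pearson=(r, pv),
    )


def site_grouping_lrt(residuals: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Likelihood-ratio comparison of pooled vs per-group residual variance.

    A lightweight stand-in for a random site effect: compares the normal
    log-likelihood under one pooled variance against per-group variances.
    Returns (LR statistic, chi-square p with g−1 df).
    """
    r = np.asarray(residuals, float)
    g = np.asarray(groups)
    labels = np.unique(g)
    n = len(r)
    pooled = np.var(r)
    if pooled == 0:
        return 0.0, 1.0
    ll_pooled = -0.5 * n * (math.log(2 * math.pi * pooled) + 1)
    ll_group = 0.0
    for lab in labels:
        sub = r[g == lab]
        v = max(np.var(sub), 1e-12)
        ll_group += -0.5 * len(sub) * (math.log(2 * math.pi * v) + 1)
    lr = 2 * (ll_group - ll_pooled)
    p = float(stats.chi2.sf(lr, df=max(len(labels) - 1, 1)))
    return float(lr), p
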