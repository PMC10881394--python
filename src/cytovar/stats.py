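"""Statistical primitives shared by the screening modules.

The workhorse is a likelihood-ratio test between nested Gaussian linear
models fitted by ordinary least squares.  For a Gaussian outcome the
profile log-likelihood of a linear model with residual sum of squares RSS
is, up to an additive constant, ``-(n/2) * ln(RSS/n)``, so the LRT
statistic for nested models reduces to ``n * ln(RSS_reduced / RSS_full)``
and is referred to a chi-square distribution with as many degrees of
freedom as parameters added by the full model.

Multiple-testing corrections (Benjamini-Yekutieli, Benjamini-Hochberg,
Holm, Bonferroni) are delegated to :mod:`statsmodels`.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import CollinearityError, InsufficientDataError

__all__ = [
    "encode_variable",
    "covariate_design",
    "ols_rss",
    "lrt_from_rss",
    "fit_nested_lrt",
    "NestedLrtFit",
    "adjust_pvalues",
    "by_adjust",
    "holm_adjust",
]

_RANK_TOL = 1e-8


def _is_numeric(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(
        series
    )


def encode_variable(series: pd.Series, reference: str | None = None) -> pd.DataFrame:
    """Encode one donor variable as design columns.

    Numeric variables map to a single column.  Categorical (or boolean)
    variables are treatment-coded against ``reference`` (default: first
    level in sorted order), one column per non-reference observed level,
    named ``<variable>[<level>]``.
    """
    name = series.name or "variable"
    if _is_numeric(series):
        return series.astype(float).to_frame(name)
    s = series.astype("object")
    levels = sorted(s.dropna().unique(), key=str)
    if reference is None:
        reference = levels[0] if levels else None
    elif reference not in levels:
        raise InsufficientDataError(
            f"reference level {reference!r} of {name!r} not observed"
        )
    cols = {}
    for lev in levels:
        if lev == reference:
            continue
        cols[f"{name}[{lev}]"] = (s == lev).astype(float)
    out = pd.DataFrame(cols, index=series.index)
    return out


def covariate_design(
    covariates: pd.DataFrame,
    numeric: tuple[str, ...] = ("age",),
    categorical: tuple[str, ...] = ("sex", "batch"),
) -> pd.DataFrame:
    """Baseline adjustment design: intercept + age + sex + batch dummies.

    Any covariate absent from ``covariates`` is silently skipped so the
    same helper serves reduced designs (e.g. age-only or no-covariate
    fits).
    """
    parts = [pd.DataFrame({"intercept": 1.0}, index=covariates.index)]
    for c in numeric:
        if c in covariates:
            parts.append(covariates[c].astype(float).to_frame(c))
    for c in categorical:
        if c in covariates:
            parts.append(encode_variable(covariates[c]))
    return pd.concat(parts, axis=1)


def ols_rss(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Least-squares fit returning (coefficients, RSS per column, rank).

    ``Y`` may hold several outcomes as columns; the design is shared.
    Rank-deficient designs are solved in the minimum-norm sense.
    """
    Y2 = Y if Y.ndim == 2 else Y[:, None]
    beta, _, rank, _ = np.linalg.lstsq(X, Y2, rcond=None)
    resid = Y2 - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    return beta, rss, int(rank)


def lrt_from_rss(
    rss_full: np.ndarray | float,
    rss_reduced: np.ndarray | float,
    n: int,
    df: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian profile-likelihood LRT statistic and chi-square p value."""
    rss_full = np.asarray(rss_full, dtype=float)
    rss_reduced = np.asarray(rss_reduced, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * np.log(rss_reduced / rss_full)
    stat = np.where(np.isfinite(stat), np.maximum(stat, 0.0), np.inf)
    p = sps.chi2.sf(stat, df)
    return stat, p


def nested_f_test(
    rss_full: float, rss_reduced: float, n: int, df_added: int, rank_full: int
) -> tuple[float, float]:
    """Exact F test for the same nested comparison, as a cross-check on
    the chi-square-referenced LRT."""
    df_resid = n - rank_full
    F = ((rss_reduced - rss_full) / df_added) / (rss_full / df_resid)
    return F, float(sps.f.sf(F, df_added, df_resid))


@dataclasses.dataclass
class NestedLrtFit:
    """Result of one nested-model comparison."""

    statistic: float
    df: int
    p_value: float
    n_used: int
    rss_full: float
    rss_reduced: float
    coefficients: pd.DataFrame  # index: full-design columns; estimate/se/t_p/ci

    def added_coefficients(self, added: list[str]) -> pd.DataFrame:
        return self.coefficients.loc[[c for c in added if c in self.coefficients.index]]


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Columns with (near-)zero residual norm given the preceding columns."""
    M = X.to_numpy(dtype=float)
    aliased = []
    for j in range(1, M.shape[1]):
        prev = M[:, :j]
        col = M[:, j]
        coef, _, _, _ = np.linalg.lstsq(prev, col, rcond=None)
        resid = col - prev @ coef
        scale = max(np.linalg.norm(col), 1.0)
        if np.linalg.norm(resid) < 1e-7 * scale:
            aliased.append(X.columns[j])
    return aliased


def fit_nested_lrt(
    y: pd.Series,
    X_full: pd.DataFrame,
    X_reduced: pd.DataFrame,
    ci_level: float = 0.95,
) -> NestedLrtFit:
    """Fit nested OLS models on the shared complete-case donor set.

    Raises :class:`InsufficientDataError` when the full model adds no
    effective parameters or when n does not exceed the parameter count,
    and :class:`CollinearityError` (naming aliased columns) when the full
    design is rank deficient beyond the added-parameter accounting.
    """
    mask = y.notna() & X_full.notna().all(axis=1)
    n = int(mask.sum())
    yv = y[mask].to_numpy(dtype=float)
    Xf = X_full.loc[mask]
    Xr = X_reduced.loc[mask]
    if n <= Xf.shape[1]:
        raise InsufficientDataError(
            f"{n} complete cases for {Xf.shape[1]} parameters"
        )
    Mf = Xf.to_numpy(dtype=float)
    Mr = Xr.to_numpy(dtype=float)
    beta_f, rss_f, rank_f = ols_rss(Mf, yv)
    _, rss_r, rank_r = ols_rss(Mr, yv)
    df = rank_f - rank_r
    if df <= 0:
        raise InsufficientDataError(
            "full model adds no parameters beyond the reduced model "
            "(variable constant or aliased with covariates)"
        )
    if rank_f < Mf.shape[1]:
        raise CollinearityError(
            "rank-deficient full design; aliased columns: "
            + ", ".join(map(str, _aliased_columns(Xf)))
        )
    stat, p = lrt_from_rss(rss_f[0], rss_r[0], n, df)
    # coefficient table from the full model
    sigma2 = rss_f[0] / (n - rank_f)
    xtx_inv = np.linalg.pinv(Mf.T @ Mf)
    se = np.sqrt(np.maximum(np.diag(xtx_inv), 0.0) * sigma2)
    est = beta_f[:, 0]
    tq = sps.t.ppf(0.5 + ci_level / 2, n - rank_f)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, est / se, np.inf * np.sign(est))
    t_p = 2 * sps.t.sf(np.abs(tval), n - rank_f)
    coefs = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "t_p": t_p,
            "exp_estimate": np.exp(est),
            "ci_low": np.exp(est - tq * se),
            "ci_high": np.exp(est + tq * se),
        },
        index=Xf.columns,
    )
    return NestedLrtFit(
        statistic=float(stat),
        df=df,
        p_value=float(p),
        n_used=n,
        rss_full=float(rss_f[0]),
        rss_reduced=float(rss_r[0]),
        coefficients=coefs,
    )


def adjust_pvalues(p: np.ndarray | pd.Series, method: str = "by") -> np.ndarray:
    """Adjust p values; NaNs are passed through unadjusted.

    ``method``: ``by`` (Benjamini-Yekutieli), ``bh``, ``holm`` or
    ``bonferroni``.
    """
    mapping = {
        "by": "fdr_by",
        "bh": "fdr_bh",
        "holm": "holm",
        "bonferroni": "bonferroni",
    }
    if method not in mapping:
        raise ValueError(f"unknown adjustment method {method!r}")
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    flat = arr.ravel()
    ok = np.isfinite(flat)
    if ok.sum() == 0:
        return out
    adj = multipletests(flat[ok], method=mapping[method])[1]
    res = np.full(flat.shape, np.nan)
    res[ok] = adj
    return res.reshape(arr.shape)


def by_adjust(p):
    """Benjamini-Yekutieli step-up adjustment (valid under dependence)."""
    return adjust_pvalues(p, "by")


def holm_adjust(p):
    """Holm step-down adjustment."""
    return adjust_pvalues(p, "holm")
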