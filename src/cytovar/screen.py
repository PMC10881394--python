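"""Donor-variable association screen for induced cytokine responses.

Each eligible donor variable is tested against each induced cytokine of
a stimulation with a likelihood-ratio test between nested linear models

    lm(log cytokine ~ variable + age + sex + batch)   vs
    lm(log cytokine ~ age + sex + batch)

followed by Benjamini-Yekutieli correction over the whole
variable x cytokine family of that stimulation (families never pool
across stimulations).  An age-interaction variant adds variable:age terms
to the full model so the LRT tests main effect and interaction jointly.

Effect sizes are treatment-coded coefficients on the log scale,
exponentiated with t-based 95% confidence intervals; for smoking status
the reference level is "never".  Group contrasts use two-sided Wilcoxon
rank-sum tests with Holm adjustment.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CytokineMatrix
from .errors import InsufficientDataError
from .induction import flag_induced
from .stats import (
    NestedLrtFit,
    adjust_pvalues,
    covariate_design,
    encode_variable,
    fit_nested_lrt,
    lrt_from_rss,
    ols_rss,
)

BASE_COVARIATES = ("age", "sex", "batch")
REFERENCE_LEVELS = {"smoking_status": "never"}
SCREEN_ALPHA = 0.01


def eligible_variables(
    cov: pd.DataFrame,
    exclude: tuple[str, ...] = BASE_COVARIATES,
    min_share: float = 0.05,
) -> list[str]:
    """Variables admissible for the screen.

    Numeric variables are always eligible.  A categorical variable with L
    observed levels is eligible iff at least ceil(L/2) levels each
    contain >= ``min_share`` of its non-missing donors.
    """
    out = []
    for name in cov.columns:
        if name in exclude:
            continue
        s = cov[name]
        if pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s):
            out.append(name)
            continue
        shares = s.dropna().value_counts(normalize=True)
        L = len(shares)
        if L >= 2 and (shares >= min_share).sum() >= math.ceil(L / 2):
            out.append(name)
    return out


def _variable_design(
    variable: pd.Series,
    covariates: pd.DataFrame,
    age_interaction: bool = False,
    reference: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Full and reduced designs plus the names of the added columns."""
    if reference is None:
        reference = REFERENCE_LEVELS.get(variable.name)
    X_red = covariate_design(covariates)
    V = encode_variable(variable, reference=reference)
    parts = [X_red, V]
    if age_interaction and "age" in covariates:
        inter = V.mul(covariates["age"].astype(float), axis=0)
        inter.columns = [f"{c}:age" for c in V.columns]
        parts.append(inter)
    X_full = pd.concat(parts, axis=1)
    added = [c for c in X_full.columns if c not in X_red.columns]
    return X_full, X_red, added


def fit_lrt(
    y: pd.Series,
    variable: pd.Series,
    covariates: pd.DataFrame,
    age_interaction: bool = False,
    reference: str | None = None,
) -> NestedLrtFit:
    """Nested-model LRT of one variable against one log cytokine vector."""
    X_full, X_red, _ = _variable_design(
        variable, covariates, age_interaction, reference
    )
    return fit_nested_lrt(y, X_full, X_red)


@dataclasses.dataclass
class ScreenResult:
    """Association screen output for one stimulation."""

    stimulation: str
    table: pd.DataFrame  # variable, cytokine, n_used, lrt_statistic, df, p_raw, p_adjusted, significant
    coefficients: pd.DataFrame  # long: variable, cytokine, level, estimate, ...
    alpha: float
    family_size: int


def screen(
    cyt: CytokineMatrix,
    cov: pd.DataFrame,
    stimulation: str,
    variables: list[str] | None = None,
    induced: pd.DataFrame | None = None,
    alpha: float = SCREEN_ALPHA,
    age_interaction: bool = False,
    responder_labels: pd.Series | None = None,
    induction_threshold: float = 0.30,
) -> ScreenResult:
    """Screen eligible variables against induced cytokines of a stimulation.

    The BY adjustment family is exactly the set of tests performed here:
    every eligible variable crossed with every induced cytokine of this
    stimulation.  When ``responder_labels`` is given (the
    anti-CD3+CD28-style case) the screen is restricted to responders.
    Variable/cytokine pairs whose model cannot be fitted (no variation,
    collinearity) are dropped with a warning and do not count toward the
    family.
    """
    if induced is None:
        induced = flag_induced(cyt, threshold=induction_threshold)
    cyt_list = [c for c in cyt.cytokines if induced.loc[stimulation, c]]
    if not cyt_list:
        warnings.warn(f"no induced cytokines for {stimulation!r}; empty screen")
        return ScreenResult(stimulation, pd.DataFrame(), pd.DataFrame(), alpha, 0)
    donors = cyt.donors.intersection(cov.index)
    if responder_labels is not None:
        resp = responder_labels.reindex(donors).fillna(False).astype(bool)
        donors = donors[resp.to_numpy()]
    Y = cyt.log_values(stimulation).loc[donors, cyt_list]
    covariates = cov.loc[donors]
    if variables is None:
        variables = eligible_variables(covariates)

    rows, coef_rows = [], []
    for var in variables:
        try:
            X_full, X_red, added = _variable_design(
                covariates[var], covariates, age_interaction
            )
        except InsufficientDataError as exc:
            warnings.warn(f"skipping {var!r}: {exc}")
            continue
        base_mask = X_full.notna().all(axis=1)
        # batch cytokines sharing a complete-case mask through one lstsq
        masks = {}
        for c in cyt_list:
            m = (base_mask & Y[c].notna()).to_numpy()
            masks.setdefault(m.tobytes(), (m, []))[1].append(c)
        for m, group in masks.values():
            n = int(m.sum())
            Mf = X_full.loc[m].to_numpy(dtype=float)
            Mr = X_red.loc[m].to_numpy(dtype=float)
            if n <= Mf.shape[1]:
                warnings.warn(f"skipping {var!r}: insufficient data (n={n})")
                continue
            rank_f = np.linalg.matrix_rank(Mf)
            rank_r = np.linalg.matrix_rank(Mr)
            df = rank_f - rank_r
            if df <= 0:
                warnings.warn(f"skipping {var!r}: no added parameters")
                continue
            Yg = Y.loc[m, group].to_numpy(dtype=float)
            beta_f, rss_f, _ = ols_rss(Mf, Yg)
            _, rss_r, _ = ols_rss(Mr, Yg)
            stat, p = lrt_from_rss(rss_f, rss_r, n, df)
            sigma2 = rss_f / (n - rank_f)
            xtx_inv_diag = np.maximum(np.diag(np.linalg.pinv(Mf.T @ Mf)), 0.0)
            tq = sps.t.ppf(0.975, n - rank_f)
            added_idx = [X_full.columns.get_loc(a) for a in added]
            for j, c in enumerate(group):
                rows.append(
                    {
                        "variable": var,
                        "cytokine": c,
                        "n_used": n,
                        "lrt_statistic": stat[j],
                        "df": df,
                        "p_raw": p[j],
                    }
                )
                se = np.sqrt(xtx_inv_diag * sigma2[j])
                for a, ai in zip(added, added_idx):
                    est = beta_f[ai, j]
                    sea = se[ai]
                    with np.errstate(divide="ignore", invalid="ignore"):
                        tval = est / sea if sea > 0 else np.inf * np.sign(est)
                    coef_rows.append(
                        {
                            "variable": var,
                            "cytokine": c,
                            "level": a,
                            "estimate": est,
                            "se": sea,
                            "exp_estimate": np.exp(est),
                            "ci_low": np.exp(est - tq * sea),
                            "ci_high": np.exp(est + tq * sea),
                            "t_p": 2 * sps.t.sf(abs(tval), n - rank_f),
                        }
                    )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = adjust_pvalues(table["p_raw"], "by")
        table["significant"] = table["p_adjusted"] < alpha
        table.insert(0, "stimulation", stimulation)
    coefs = pd.DataFrame(coef_rows)
    return ScreenResult(stimulation, table, coefs, alpha, len(table))


def effect_sizes(
    y: pd.Series,
    variable: pd.Series,
    covariates: pd.DataFrame,
    reference: str | None = None,
    t_alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-level exponentiated effects with 95% CIs and significance marks.

    One row per non-reference level of a categorical variable (or one
    row for a numeric variable): exp(estimate), exp(estimate +/- t * se)
    with residual-df t quantiles, the coefficient t-test p, and a
    ``significant`` mark at t-test p < ``t_alpha``.
    """
    X_full, X_red, added = _variable_design(variable, covariates, False, reference)
    fit = fit_nested_lrt(y, X_full, X_red)
    out = fit.added_coefficients(added).copy()
    out["significant"] = out["t_p"] < t_alpha
    out.index.name = "level"
    return out.reset_index()


def pairwise_group_tests(
    y: pd.Series,
    group: pd.Series,
    method: str = "holm",
    exact_threshold: int = 50,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests for all group pairs.

    Exact p values for small tie-free samples (both groups below
    ``exact_threshold``), otherwise the normal approximation with tie
    correction.  Adjusted across pairs with Holm by default.
    Groups with zero observations are excluded with a warning.
    """
    levels = [g for g in pd.unique(group.dropna())]
    df = pd.DataFrame({"y": y, "g": group}).dropna()
    counts = df["g"].value_counts()
    empty = [g for g in levels if counts.get(g, 0) == 0]
    if empty:
        warnings.warn(f"excluding empty groups: {empty}")
        levels = [g for g in levels if g not in empty]
    if len(levels) < 2:
        raise InsufficientDataError("need at least 2 non-empty groups")
    rows = []
    for a, b in combinations(sorted(levels, key=str), 2):
        xa = df.loc[df["g"] == a, "y"].to_numpy()
        xb = df.loc[df["g"] == b, "y"].to_numpy()
        small = max(len(xa), len(xb)) < exact_threshold
        ties = len(np.unique(np.concatenate([xa, xb]))) < len(xa) + len(xb)
        meth = "exact" if (small and not ties) else "asymptotic"
        res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=meth)
        rows.append({"group_a": a, "group_b": b, "p_raw": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = adjust_pvalues(out["p_raw"], method)
    return out
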