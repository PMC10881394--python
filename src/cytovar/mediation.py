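"""Covariate-elimination mediation screen and TSS-window CpG tests.

A candidate mediator (an immune-cell subset count, a plasma protein or a
CpG methylation level) is declared to "eliminate" a variable-cytokine
association when the baseline association is significant but the LRT of

    lm(log cytokine ~ variable x mediator + age + sex + batch)   vs
    lm(log cytokine ~ mediator + age + sex + batch)

is no longer significant once the mediator (with interaction) enters the
model.  This is a screening procedure, not a formal causal-mediation
decomposition.  Significance gates use Benjamini-Yekutieli-adjusted p
values at alpha = 0.01 over the whole mediator x cytokine matrix of one
stimulation and panel.

CpG-cytokine association tests are restricted to CpGs within a genomic
window (default 1 Mb, closed interval) of the cytokine gene's
transcription start site on the same chromosome, and FDR-adjusted at the
0.05 level.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .containers import CytokineMatrix
from .errors import CollinearityError, DataError, InsufficientDataError
from .induction import flag_induced
from .screen import REFERENCE_LEVELS, fit_lrt
from .stats import (
    adjust_pvalues,
    covariate_design,
    encode_variable,
    fit_nested_lrt,
)

ELIMINATION_ALPHA = 0.01
CPG_WINDOW = 1_000_000


def transform_mediator(
    values: pd.Series, kind: str, logit_beta: bool = False
) -> pd.Series:
    """Mediator transform per kind: log(count + 0.5) for cells, log for
    proteins, untransformed beta for CpGs (logit-beta optionally)."""
    if kind == "cell":
        return np.log(values.astype(float) + 0.5)
    if kind == "protein":
        return np.log(values.astype(float))
    if kind == "cpg":
        v = values.astype(float)
        if logit_beta:
            return np.log(v / (1.0 - v))
        return v
    raise DataError(f"unknown mediator kind {kind!r}")


def covariate_elimination(
    y: pd.Series,
    variable: pd.Series,
    mediator: pd.Series,
    covariates: pd.DataFrame,
    interaction: bool = True,
    reference: str | None = None,
) -> dict:
    """Raw p values of the baseline and with-mediator model pairs.

    Baseline: variable + age/sex/batch vs age/sex/batch.  With-mediator:
    variable (+ variable:mediator when ``interaction``) + mediator +
    age/sex/batch vs mediator + age/sex/batch, both on that model pair's
    own complete-case donor set.  A mediator collinear with the variable
    renders the pair untestable (flagged, not raised).
    """
    if reference is None:
        reference = REFERENCE_LEVELS.get(variable.name)
    baseline = fit_lrt(y, variable, covariates, reference=reference)
    X_base = covariate_design(covariates)
    med = mediator.astype(float).rename(mediator.name or "mediator")
    X_red = pd.concat([X_base, med], axis=1)
    V = encode_variable(variable, reference=reference)
    parts = [X_red, V]
    if interaction:
        inter = V.mul(med, axis=0)
        inter.columns = [f"{c}:{med.name}" for c in V.columns]
        parts.append(inter)
    X_full = pd.concat(parts, axis=1)
    try:
        fit = fit_nested_lrt(y, X_full, X_red)
        p_med, n_med, untestable = fit.p_value, fit.n_used, False
    except (CollinearityError, InsufficientDataError) as exc:
        warnings.warn(f"untestable mediator {med.name!r}: {exc}")
        p_med, n_med, untestable = np.nan, 0, True
    return {
        "p_baseline": baseline.p_value,
        "p_with_mediator": p_med,
        "n_baseline": baseline.n_used,
        "n_with_mediator": n_med,
        "untestable": untestable,
    }


@dataclasses.dataclass
class EliminationResult:
    stimulation: str
    variable: str
    panel_kind: str
    table: pd.DataFrame
    alpha: float


def elimination_matrix(
    cyt: CytokineMatrix,
    cov: pd.DataFrame,
    variable: str,
    panel: pd.DataFrame,
    panel_kind: str,
    stimulation: str,
    alpha: float = ELIMINATION_ALPHA,
    induced: pd.DataFrame | None = None,
    responder_labels: pd.Series | None = None,
    interaction: bool = True,
) -> EliminationResult:
    """Elimination screen of one variable over a whole mediator panel.

    One record per mediator x induced cytokine.  The BY family for the
    with-mediator p values is this whole matrix; baseline p values (one
    per cytokine, no mediator) are BY-adjusted across the cytokines.
    ``eliminated`` requires the baseline association to pass the gate
    while the with-mediator association fails it.  Eliminated mediators
    sort first, by with-mediator p.
    """
    if panel.shape[1] == 0:
        warnings.warn("empty mediator panel; empty elimination table")
        return EliminationResult(stimulation, variable, panel_kind, pd.DataFrame(), alpha)
    if induced is None:
        induced = flag_induced(cyt)
    cyt_list = [c for c in cyt.cytokines if induced.loc[stimulation, c]]
    donors = cyt.donors.intersection(cov.index).intersection(panel.index)
    if responder_labels is not None:
        resp = responder_labels.reindex(donors).fillna(False).astype(bool)
        donors = donors[resp.to_numpy()]
    Y = cyt.log_values(stimulation).loc[donors]
    covariates = cov.loc[donors]
    var = covariates[variable]

    base_p = {}
    for c in cyt_list:
        base_p[c] = fit_lrt(Y[c], var, covariates).p_value
    base_adj = dict(
        zip(base_p, adjust_pvalues(np.array(list(base_p.values())), "by"))
    )

    rows = []
    for m in panel.columns:
        med = transform_mediator(panel.loc[donors, m], panel_kind).rename(m)
        for c in cyt_list:
            rec = covariate_elimination(
                Y[c], var, med, covariates, interaction=interaction
            )
            rows.append(
                {
                    "variable": variable,
                    "mediator": m,
                    "stimulation": stimulation,
                    "cytokine": c,
                    "p_baseline": rec["p_baseline"],
                    "p_with_mediator": rec["p_with_mediator"],
                    "n_with_mediator": rec["n_with_mediator"],
                    "untestable": rec["untestable"],
                }
            )
    table = pd.DataFrame(rows)
    table["p_baseline_adjusted"] = table["cytokine"].map(base_adj)
    table["p_with_mediator_adjusted"] = adjust_pvalues(
        table["p_with_mediator"], "by"
    )
    table["eliminated"] = (
        (table["p_baseline_adjusted"] < alpha)
        & (table["p_with_mediator_adjusted"] >= alpha)
        & ~table["untestable"]
    )
    table = table.sort_values(
        ["eliminated", "p_with_mediator"], ascending=[False, True]
    ).reset_index(drop=True)
    return EliminationResult(stimulation, variable, panel_kind, table, alpha)


def cpg_window_assoc(
    methylation: pd.DataFrame,
    cpg_positions: pd.DataFrame,
    cyt: CytokineMatrix,
    gene_tss: pd.DataFrame,
    cov: pd.DataFrame,
    stimulation: str,
    window: int = CPG_WINDOW,
    fdr_alpha: float = 0.05,
    cell_covariates: pd.DataFrame | None = None,
    induced: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """LRT associations of TSS-proximal CpGs with induced cytokines.

    For each induced cytokine whose gene TSS is known, CpGs on the same
    chromosome with |position - TSS| <= window (closed interval) are
    tested via the nested-model LRT with age/sex/batch (plus optional
    major cell count) covariates, and BH-FDR adjusted over all tests of
    the stimulation.  CpGs lacking coordinates are skipped; the skip
    count is reported in a warning.
    """
    if induced is None:
        induced = flag_induced(cyt)
    cyt_list = [c for c in cyt.cytokines if induced.loc[stimulation, c]]
    donors = cyt.donors.intersection(cov.index).intersection(methylation.index)
    Y = cyt.log_values(stimulation).loc[donors]
    covariates = cov.loc[donors].copy()
    if cell_covariates is not None:
        for col in cell_covariates.columns:
            covariates[col] = np.log(
                cell_covariates[col].reindex(donors).astype(float) + 0.5
            )
        extra_numeric = ("age",) + tuple(cell_covariates.columns)
    else:
        extra_numeric = ("age",)

    missing_pos = [c for c in methylation.columns if c not in cpg_positions.index]
    if missing_pos:
        warnings.warn(f"skipping {len(missing_pos)} CpGs without coordinates")

    rows = []
    for c in cyt_list:
        if c not in gene_tss.index:
            continue
        chrom, tss = gene_tss.loc[c, "chrom"], gene_tss.loc[c, "tss"]
        pos = cpg_positions.loc[
            cpg_positions.index.intersection(methylation.columns)
        ]
        nearby = pos[
            (pos["chrom"] == chrom) & ((pos["pos"] - tss).abs() <= window)
        ].index
        for cpg in nearby:
            X_red = covariate_design(covariates, numeric=extra_numeric)
            beta = methylation.loc[donors, cpg].astype(float).rename(cpg)
            X_full = pd.concat([X_red, beta], axis=1)
            try:
                fit = fit_nested_lrt(Y[c], X_full, X_red)
            except (CollinearityError, InsufficientDataError) as exc:
                warnings.warn(f"skipping CpG {cpg!r} for {c!r}: {exc}")
                continue
            rows.append(
                {
                    "stimulation": stimulation,
                    "cytokine": c,
                    "cpg": cpg,
                    "distance_to_tss": int(abs(cpg_positions.loc[cpg, "pos"] - tss)),
                    "n_used": fit.n_used,
                    "lrt_statistic": fit.statistic,
                    "df": fit.df,
                    "p_raw": fit.p_value,
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = adjust_pvalues(table["p_raw"], "bh")
        table["significant"] = table["p_adjusted"] < fdr_alpha
    return table
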