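"""Response-pQTL scan of induced cytokines against genotype dosages.

Per (SNP, induced cytokine): ordinary least squares of the log cytokine
concentration on the additive dosage plus covariates (age, sex, batch
and the stimulation's main associated cell subset), with the slope
t-test as the association test.  For speed the covariates are projected
out of both phenotypes and genotypes once per scan (Frisch-Waugh
residualization) with degrees of freedom adjusted accordingly; the
result is numerically identical to per-SNP full fits.

SNPs are filtered to minor allele frequency strictly above 5%.  A SNP is
cis for a cytokine when it lies within 1 Mb (closed interval, 1-based)
of the cytokine gene's TSS on the same chromosome, else trans.  Records
are kept below class-specific detection thresholds (1e-3 cis, 1e-5
trans) and Bonferroni-adjusted over the full scan family (all retained
SNPs x all tested cytokines of the stimulation); hits require adjusted
p < 0.05.  Cytokines identical to the stimulus agonist (IFNg under IFNg
stimulation, etc.) are excluded because they do not reflect endogenous
secretion.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CytokineMatrix, GenotypeMatrix
from .errors import ConfigurationError, DataError
from .induction import flag_induced
from .stats import adjust_pvalues, covariate_design, encode_variable, fit_nested_lrt

MAF_THRESHOLD = 0.05
CIS_WINDOW = 1_000_000
CIS_DETECTION = 1e-3
TRANS_DETECTION = 1e-5
BONFERRONI_ALPHA = 0.05

# stimulation -> main associated cell subset used as covariate
MAIN_CELL_SUBSET = {
    "LPS": "monocytes",
    "E. coli": "monocytes",
    "C. albicans": "monocytes",
    "SEB": "CD4pos",
    "anti-CD3+CD28": "CD8posEMRA",
    "BCG": "CD45pos",
    "poly I:C": "cDC3",
    "influenza": "CD3pos",
    "TNF": "CD45pos",
    "null": None,
    "IL-1b": None,
    "IFNg": None,
}
# cytokines added to the culture tube as the agonist itself
AGONIST_CYTOKINE = {"TNF": "TNF", "IL-1b": "IL-1b", "IFNg": "IFNg"}


def maf_filter(gt: GenotypeMatrix, threshold: float = MAF_THRESHOLD) -> GenotypeMatrix:
    """Retain SNPs with MAF strictly above ``threshold`` (non-missing dosages)."""
    maf = gt.observed_maf()
    keep = maf.index[maf > threshold]
    removed = gt.dosages.shape[1] - len(keep)
    if len(keep) == 0:
        warnings.warn("all SNPs removed by the MAF filter; empty scan")
    elif removed:
        warnings.warn(f"MAF filter removed {removed} of {gt.dosages.shape[1]} SNPs")
    return gt.subset(keep)


def classify_cis_trans(
    snp_chrom: str, snp_pos: int, gene_chrom: str | None, gene_tss: int | None,
    window: int = CIS_WINDOW,
) -> str:
    """cis iff same chromosome and |position - TSS| <= window."""
    if gene_chrom is None or gene_tss is None or (
        isinstance(gene_tss, float) and np.isnan(gene_tss)
    ):
        return "unclassified"
    if snp_chrom == gene_chrom and abs(int(snp_pos) - int(gene_tss)) <= window:
        return "cis"
    return "trans"


@dataclasses.dataclass
class ScanResult:
    stimulation: str
    table: pd.DataFrame  # records below detection thresholds
    n_snps: int
    n_cytokines: int
    family_size: int
    conditioned_on: tuple[str, ...] = ()


def _scan_matrices(
    gt: GenotypeMatrix,
    cyt: CytokineMatrix,
    cov: pd.DataFrame,
    stimulation: str,
    cells: pd.DataFrame | None,
    main_subset_map: dict,
    responder_labels: pd.Series | None,
    induced: pd.DataFrame | None,
    extra_covariates: pd.DataFrame | None = None,
):
    if induced is None:
        induced = flag_induced(cyt)
    excluded = AGONIST_CYTOKINE.get(stimulation)
    cyt_list = [
        c
        for c in cyt.cytokines
        if induced.loc[stimulation, c] and c != excluded
    ]
    donors = cyt.donors.intersection(cov.index).intersection(gt.donors)
    if responder_labels is not None:
        resp = responder_labels.reindex(donors).fillna(False).astype(bool)
        donors = donors[resp.to_numpy()]
    X = covariate_design(cov.loc[donors])
    if stimulation not in main_subset_map:
        raise ConfigurationError(
            f"no main-cell-subset mapping for stimulation {stimulation!r}"
        )
    subset = main_subset_map[stimulation]
    if subset is not None:
        if cells is None or subset not in cells.columns:
            raise ConfigurationError(
                f"main cell subset {subset!r} required for {stimulation!r} not available"
            )
        X[subset] = np.log(cells[subset].reindex(donors).astype(float) + 0.5)
    if extra_covariates is not None:
        for col in extra_covariates.columns:
            X[col] = extra_covariates[col].reindex(donors).astype(float)
    Y = cyt.log_values(stimulation).loc[donors, cyt_list]
    mask = X.notna().all(axis=1) & Y.notna().all(axis=1)
    donors = donors[mask.to_numpy()]
    X, Y = X.loc[donors], Y.loc[donors]
    G = gt.dosages.reindex(donors)
    # mean-impute missing dosages per SNP (logged)
    n_missing = int(G.isna().to_numpy().sum())
    if n_missing:
        warnings.warn(f"mean-imputing {n_missing} missing dosages")
        G = G.apply(lambda c: c.fillna(c.mean()))
    return X, Y, G, donors, cyt_list


def scan(
    gt: GenotypeMatrix,
    cyt: CytokineMatrix,
    cov: pd.DataFrame,
    stimulation: str,
    cells: pd.DataFrame | None = None,
    gene_tss: pd.DataFrame | None = None,
    main_subset_map: dict | None = None,
    responder_labels: pd.Series | None = None,
    induced: pd.DataFrame | None = None,
    cis_detection: float = CIS_DETECTION,
    trans_detection: float = TRANS_DETECTION,
    bonferroni_alpha: float = BONFERRONI_ALPHA,
    cis_window: int = CIS_WINDOW,
    extra_covariates: pd.DataFrame | None = None,
) -> ScanResult:
    """Matrix pQTL scan of one stimulation.

    Returns every record passing its class's detection threshold with
    slope, t statistic, raw and Bonferroni-adjusted p (family = all
    retained SNPs x all tested cytokines of this scan), cis/trans label
    and a ``hit`` flag at adjusted p < ``bonferroni_alpha``.
    """
    main_subset_map = main_subset_map if main_subset_map is not None else MAIN_CELL_SUBSET
    X, Y, G, donors, cyt_list = _scan_matrices(
        gt, cyt, cov, stimulation, cells, main_subset_map,
        responder_labels, induced, extra_covariates,
    )
    n = len(donors)
    if n == 0 or G.shape[1] == 0 or len(cyt_list) == 0:
        warnings.warn("empty pQTL scan")
        return ScanResult(stimulation, pd.DataFrame(), G.shape[1], len(cyt_list), 0)
    M = X.to_numpy(dtype=float)
    Q, _ = np.linalg.qr(M)
    k = np.linalg.matrix_rank(M)
    Yr = Y.to_numpy(dtype=float)
    Yr = Yr - Q @ (Q.T @ Yr)
    Gm = G.to_numpy(dtype=float)
    Gr = Gm - Q @ (Q.T @ Gm)
    gg = np.einsum("ij,ij->j", Gr, Gr)
    yy = np.einsum("ij,ij->j", Yr, Yr)
    num = Gr.T @ Yr  # snps x cytokines
    dof = n - k - 1
    if dof <= 0:
        raise DataError("not enough donors for the covariate-adjusted scan")
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = num / gg[:, None]
        rss = yy[None, :] - num**2 / gg[:, None]
        se = np.sqrt(np.maximum(rss, 0.0) / dof / gg[:, None])
        tstat = slope / se
    p = 2 * sps.t.sf(np.abs(tstat), dof)
    family = G.shape[1] * len(cyt_list)
    p_adj = np.minimum(1.0, p * family)

    info = gt.snp_info
    tss = gene_tss if gene_tss is not None else pd.DataFrame(columns=["chrom", "tss"])
    rows = []
    unknown_tss = set()
    for j, c in enumerate(cyt_list):
        if c in tss.index:
            gchrom, gtss = tss.loc[c, "chrom"], tss.loc[c, "tss"]
        else:
            gchrom = gtss = None
            unknown_tss.add(c)
        for i, snp in enumerate(G.columns):
            label = classify_cis_trans(
                info.loc[snp, "chrom"], info.loc[snp, "pos"], gchrom, gtss, cis_window
            )
            detect = cis_detection if label == "cis" else trans_detection
            if p[i, j] >= detect:
                continue
            rows.append(
                {
                    "snp": snp,
                    "stimulation": stimulation,
                    "cytokine": c,
                    "slope": slope[i, j],
                    "t_statistic": tstat[i, j],
                    "p_raw": p[i, j],
                    "p_adjusted": p_adj[i, j],
                    "cis_trans": label,
                    "n_used": n,
                }
            )
    if unknown_tss:
        warnings.warn(
            f"unknown TSS for {sorted(unknown_tss)}; labelled unclassified, "
            "trans detection threshold applied"
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["hit"] = table["p_adjusted"] < bonferroni_alpha
        table = table.sort_values("p_raw").reset_index(drop=True)
    return ScanResult(stimulation, table, G.shape[1], len(cyt_list), family)


def conditional_scan(
    gt: GenotypeMatrix,
    cyt: CytokineMatrix,
    cov: pd.DataFrame,
    stimulation: str,
    conditioning_snps: list[str] | str,
    **scan_kwargs,
) -> ScanResult:
    """Re-run the scan with conditioning SNP dosages added as covariates.

    SNPs in perfect LD with a conditioning SNP (zero residual dosage
    variance) are flagged untestable (NaN statistics) rather than
    reported.
    """
    if isinstance(conditioning_snps, str):
        conditioning_snps = [conditioning_snps]
    for s in conditioning_snps:
        if s not in gt.dosages.columns:
            raise ConfigurationError(f"conditioning SNP {s!r} absent from genotypes")
    extra = gt.dosages[conditioning_snps].apply(lambda c: c.fillna(c.mean()))
    extra.columns = [f"cond_{s}" for s in conditioning_snps]
    tested = gt.subset([s for s in gt.snps if s not in conditioning_snps])
    # untestable: residual variance of the tested dosage given conditioning ~ 0
    E = extra.to_numpy(dtype=float)
    E = np.column_stack([np.ones(len(E)), E])
    D = tested.dosages.apply(lambda c: c.fillna(c.mean())).to_numpy(dtype=float)
    coef, _, _, _ = np.linalg.lstsq(E, D, rcond=None)
    resid_var = ((D - E @ coef) ** 2).sum(axis=0)
    scale = np.maximum((D**2).sum(axis=0), 1.0)
    testable = resid_var / scale > 1e-10
    dropped = [s for s, ok in zip(tested.snps, testable) if not ok]
    if dropped:
        warnings.warn(f"untestable (perfect LD with conditioning SNP): {dropped}")
        tested = tested.subset([s for s, ok in zip(tested.snps, testable) if ok])
    result = scan(
        tested, cyt, cov, stimulation, extra_covariates=extra, **scan_kwargs
    )
    result.conditioned_on = tuple(conditioning_snps)
    return result


def gxe_interaction(
    hits: pd.DataFrame,
    gt: GenotypeMatrix,
    cyt: CytokineMatrix,
    cov: pd.DataFrame,
    smoking: str = "smoking_status",
    cells: pd.DataFrame | None = None,
    main_subset_map: dict | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genotype x smoking interaction tests for identified pQTL hits.

    Per hit: LRT of the model adding dosage x smoking-status terms
    against the no-interaction model, BY-adjusted over the tested hits;
    exponentiated interaction coefficients with 95% CIs are reported.
    Smoking levels with empty genotype crossing are dropped with a
    warning by the underlying complete-case fit.
    """
    main_subset_map = main_subset_map if main_subset_map is not None else MAIN_CELL_SUBSET
    rows = []
    coef_rows = []
    for _, hit in hits.iterrows():
        stim, c, snp = hit["stimulation"], hit["cytokine"], hit["snp"]
        donors = cyt.donors.intersection(cov.index).intersection(gt.donors)
        X = covariate_design(cov.loc[donors])
        subset = main_subset_map.get(stim)
        if subset is not None and cells is not None and subset in cells.columns:
            X[subset] = np.log(cells[subset].reindex(donors).astype(float) + 0.5)
        y = cyt.log_values(stim).loc[donors, c]
        dose = gt.dosages[snp].reindex(donors).astype(float)
        smoke = encode_variable(cov.loc[donors, smoking], reference="never")
        X_red = pd.concat([X, smoke, dose.rename("dosage")], axis=1)
        inter = smoke.mul(dose, axis=0)
        inter.columns = [f"dosage:{cl}" for cl in smoke.columns]
        X_full = pd.concat([X_red, inter], axis=1)
        fit = fit_nested_lrt(y, X_full, X_red)
        rows.append(
            {
                "snp": snp,
                "stimulation": stim,
                "cytokine": c,
                "lrt_statistic": fit.statistic,
                "df": fit.df,
                "p_raw": fit.p_value,
                "n_used": fit.n_used,
            }
        )
        cc = fit.added_coefficients(list(inter.columns))
        for lev, r in cc.iterrows():
            coef_rows.append(
                {
                    "snp": snp,
                    "stimulation": stim,
                    "cytokine": c,
                    "term": lev,
                    "estimate": r["estimate"],
                    "exp_estimate": r["exp_estimate"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "t_p": r["t_p"],
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = adjust_pvalues(table["p_raw"], "by")
        table["significant"] = table["p_adjusted"] < alpha
    coefs = pd.DataFrame(coef_rows)
    if len(coefs) and len(table):
        coefs = coefs.merge(
            table[["snp", "stimulation", "cytokine", "p_adjusted", "significant"]],
            on=["snp", "stimulation", "cytokine"],
        )
    return GxeResult(table, coefs)


@dataclasses.dataclass
class GxeResult:
    """Interaction LRTs (one row per hit) and per-term coefficients."""

    table: pd.DataFrame
    coefficients: pd.DataFrame
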