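"""Induction profiling of stimulated cytokine responses.

A cytokine is "induced" by a stimulation when its median concentration
deviates by at least 30% (in either direction) from its median in the
non-stimulated null condition.  The induction landscape is summarised by
standardized log mean differences (SLMD: paired mean log difference over
the standard deviation of the paired differences), hierarchically
clustered with complete linkage on Euclidean distance.  The module also
provides k-means detection of non-responding donors for stimulations with
a bimodal response (the anti-CD3+CD28 case, driven by an FcgRIIA
polymorphism) and a PCA overview of the log concentrations.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from .containers import CytokineMatrix
from .errors import DataError

INDUCTION_THRESHOLD = 0.30


def flag_induced(
    cyt: CytokineMatrix, threshold: float = INDUCTION_THRESHOLD
) -> pd.DataFrame:
    """Induction flags, stimulations x cytokines.

    True iff ``|median_stim / median_null - 1| >= threshold`` with
    medians over non-missing donors.  Degenerate-null rule: if the null
    median sits on the LLOQ floor and the stimulated median exceeds it,
    the cytokine is flagged induced regardless of the ratio.
    """
    null = cyt.concentrations(cyt.null_condition)
    med_null = null.median()
    rows = {}
    for stim in cyt.stimulations:
        if stim == cyt.null_condition:
            continue
        block = cyt.concentrations(stim)
        common = block.index.intersection(null.index)
        if len(common) == 0:
            raise DataError(f"no overlapping donors between {stim!r} and null")
        med_stim = block.loc[common].median()
        ratio_dev = (med_stim / med_null).sub(1.0).abs()
        flag = ratio_dev >= threshold
        floor = cyt.lloq.get(cyt.null_condition)
        if floor is not None:
            at_floor = med_null <= floor.reindex(med_null.index)
            flag = flag | (at_floor & (med_stim > med_null))
        rows[stim] = flag
    return pd.DataFrame(rows).T.fillna(False).astype(bool)


def compute_slmd(cyt: CytokineMatrix, log: bool = True) -> pd.DataFrame:
    """Standardized log mean differences, stimulations x cytokines.

    Per (stimulation, cytokine): mean(stim) - mean(null) over complete
    donor pairs, divided by the standard deviation (ddof=1) of the paired
    per-donor differences.  Computed on natural-log concentrations by
    default.  A zero difference-SD yields NaN with a warning; such
    entries are excluded from clustering.
    """
    get = cyt.log_values if log else cyt.concentrations
    null = get(cyt.null_condition)
    rows = {}
    for stim in cyt.stimulations:
        if stim == cyt.null_condition:
            continue
        block = get(stim)
        common = block.index.intersection(null.index)
        diffs = block.loc[common] - null.loc[common]
        sd = diffs.std(ddof=1)
        if (sd == 0).any():
            bad = list(sd.index[sd == 0])
            warnings.warn(
                f"zero paired-difference SD for {stim!r}: {bad}; SLMD set to NaN"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            rows[stim] = diffs.mean() / sd.replace(0.0, np.nan)
    return pd.DataFrame(rows).T


@dataclasses.dataclass
class ClusterOrder:
    """Row/column dendrogram orders from hierarchical clustering."""

    row_order: list
    col_order: list
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def cluster_profile(slmd: pd.DataFrame) -> ClusterOrder:
    """Complete-linkage Euclidean clustering of the SLMD matrix.

    Rows or columns containing non-finite entries are excluded first.
    Deterministic given input order; scipy breaks distance ties by the
    lower original observation index.  With fewer than 2 rows (or
    columns) on an axis, clustering of that axis is skipped with a notice
    and the input order is kept.
    """
    clean = slmd.loc[
        np.isfinite(slmd).all(axis=1), np.isfinite(slmd).all(axis=0)
    ]

    def _axis(mat: np.ndarray, labels) -> tuple[list, np.ndarray | None]:
        if mat.shape[0] < 2:
            warnings.warn("fewer than 2 rows; clustering skipped")
            return list(labels), None
        Z = hierarchy.linkage(mat, method="complete", metric="euclidean")
        order = hierarchy.leaves_list(Z)
        return [labels[i] for i in order], Z

    row_order, row_Z = _axis(clean.to_numpy(dtype=float), list(clean.index))
    col_order, col_Z = _axis(clean.to_numpy(dtype=float).T, list(clean.columns))
    return ClusterOrder(row_order, col_order, row_Z, col_Z)


def detect_responders(
    cyt: CytokineMatrix,
    stimulation: str,
    cytokine_set: list[str],
    seed: int,
    n_restarts: int = 25,
) -> pd.Series:
    """Label responders via k-means (k=2) on log concentrations.

    Donors with complete data for ``cytokine_set`` are clustered; the
    cluster whose centroid has the larger Euclidean norm is labelled
    responder.  ``n_restarts`` seeded restarts are run and the best
    inertia kept.  Degenerate case (all donors identical): everyone is
    labelled responder with a warning.
    """
    X = cyt.log_values(stimulation)[cytokine_set].dropna()
    if len(X) < 2:
        raise DataError("need at least 2 donors with complete data")
    arr = X.to_numpy(dtype=float)
    if np.allclose(arr, arr[0]):
        warnings.warn("all donors identical; single-cluster degenerate result")
        return pd.Series(True, index=X.index, name="responder")
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(arr)
    responder_cluster = int(
        np.argmax(np.linalg.norm(km.cluster_centers_, axis=1))
    )
    return pd.Series(labels == responder_cluster, index=X.index, name="responder")


@dataclasses.dataclass
class PcaOverview:
    scores: pd.DataFrame  # donors x PCs
    loadings: pd.DataFrame  # features x PCs
    variance_fraction: pd.Series


def pca_overview(cyt: CytokineMatrix, stimulations: list[str] | None = None) -> PcaOverview:
    """PCA of log concentrations across (stimulation, cytokine) features.

    Missing values are imputed by the feature mean, features are
    log-transformed, centred and scaled to unit variance, and the
    decomposition is by SVD.  Zero-variance features are dropped with a
    warning.  Variance fractions sum to 1.
    """
    stims = stimulations or [s for s in cyt.stimulations]
    blocks = []
    for s in stims:
        b = cyt.log_values(s)
        b.columns = pd.MultiIndex.from_product([[s], b.columns])
        blocks.append(b)
    X = pd.concat(blocks, axis=1)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise DataError("need at least 2 donors and 2 features for PCA")
    X = X.apply(lambda c: c.fillna(c.mean()))
    sd = X.std(ddof=1)
    if (sd == 0).any():
        warnings.warn(f"dropping zero-variance features: {list(sd.index[sd == 0])}")
        X = X.loc[:, sd > 0]
        sd = sd[sd > 0]
    Z = (X - X.mean()) / sd
    U, S, Vt = np.linalg.svd(Z.to_numpy(dtype=float), full_matrices=False)
    pcs = [f"PC{i + 1}" for i in range(len(S))]
    scores = pd.DataFrame(U * S, index=X.index, columns=pcs)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=pcs)
    var_frac = pd.Series(S**2 / np.sum(S**2), index=pcs)
    return PcaOverview(scores, loadings, var_frac)
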