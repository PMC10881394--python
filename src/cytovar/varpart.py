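"""LMG (Shapley) decomposition of explained cytokine variance.

Each regressor group's share is its R-squared contribution averaged over
all orderings of the groups (Lindeman-Merenda-Gold relative importance;
equivalently the Shapley value of the R-squared game).  A multi-level
factor, a SNP dosage or a CpG is one group: all of its design columns
move together through the orderings.  Shares are nonnegative and sum to
the full-model R-squared (the efficiency property).

Exact mode enumerates all 2^p subset fits (memoized); sampled mode
averages sequential R-squared gains over seeded random orderings and
reports a Monte-Carlo standard error per share.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import CytokineMatrix
from .errors import ConfigurationError, InsufficientDataError
from .stats import encode_variable

EXACT_CAP = 20


@dataclasses.dataclass
class VarianceShares:
    """Per-group R-squared shares for one outcome."""

    shares: pd.Series  # group -> share
    total_r2: float
    method: str  # "exact" | "sampled"
    n_orderings: int | None = None
    seed: int | None = None
    mc_se: pd.Series | None = None


class _SubsetR2:
    """Memoized R-squared of OLS fits over column subsets (by bitmask)."""

    def __init__(self, y: np.ndarray, blocks: list[np.ndarray]):
        self.y = y
        self.blocks = blocks
        self.n = len(y)
        ybar = y.mean()
        self.tss = float(((y - ybar) ** 2).sum())
        self._cache: dict[int, float] = {}

    def r2(self, mask: int) -> float:
        if self.tss == 0:
            return 0.0
        got = self._cache.get(mask)
        if got is not None:
            return got
        cols = [self.blocks[i] for i in range(len(self.blocks)) if mask >> i & 1]
        X = np.column_stack([np.ones(self.n)] + cols) if cols else np.ones((self.n, 1))
        beta, _, _, _ = np.linalg.lstsq(X, self.y, rcond=None)
        resid = self.y - X @ beta
        val = 1.0 - float(resid @ resid) / self.tss
        val = min(max(val, 0.0), 1.0)
        self._cache[mask] = val
        return val


def _prepare_blocks(
    y: pd.Series, groups: dict[str, pd.DataFrame]
) -> tuple[np.ndarray, list[str], list[np.ndarray]]:
    frames = {k: (v.to_frame() if isinstance(v, pd.Series) else v) for k, v in groups.items()}
    mask = y.notna()
    for f in frames.values():
        mask &= f.notna().all(axis=1)
    n = int(mask.sum())
    if n < len(frames) + 2:
        raise InsufficientDataError(f"{n} complete cases for {len(frames)} groups")
    yv = y[mask].to_numpy(dtype=float)
    names = list(frames)
    blocks = [frames[k].loc[mask].to_numpy(dtype=float) for k in names]
    return yv, names, blocks


def lmg_shares(
    y: pd.Series,
    groups: dict[str, pd.DataFrame],
    mode: str = "exact",
    seed: int | None = None,
    n_orderings: int = 1000,
) -> VarianceShares:
    """LMG/Shapley R-squared shares of named regressor groups.

    ``groups`` maps a group name to its design columns (a DataFrame or
    Series aligned with ``y``); treatment coding of factors is the
    caller's responsibility (see :func:`factor_group`).  Exact mode
    requires at most 20 groups; sampled mode requires a seed.
    Collinear groups are handled (least squares in the minimum-norm
    sense keeps R-squared well defined).
    """
    yv, names, blocks = _prepare_blocks(y, groups)
    p = len(names)
    solver = _SubsetR2(yv, blocks)
    full_mask = (1 << p) - 1
    total = solver.r2(full_mask)
    if mode == "exact":
        if p > EXACT_CAP:
            raise ConfigurationError(
                f"{p} groups exceed the exact-mode cap of {EXACT_CAP}; use sampled mode"
            )
        shares = np.zeros(p)
        others = list(range(p))
        fact = math.factorial
        for k in range(p):
            rest = [i for i in others if i != k]
            for s in range(p):
                w = fact(s) * fact(p - s - 1) / fact(p)
                for combo in combinations(rest, s):
                    m = 0
                    for i in combo:
                        m |= 1 << i
                    shares[k] += w * (solver.r2(m | 1 << k) - solver.r2(m))
        return VarianceShares(
            pd.Series(shares, index=names), total, "exact"
        )
    if mode == "sampled":
        if seed is None:
            raise ConfigurationError("sampled mode requires an explicit seed")
        rng = np.random.default_rng(seed)
        gains = np.zeros((n_orderings, p))
        order = np.arange(p)
        for t in range(n_orderings):
            rng.shuffle(order)
            m = 0
            prev = 0.0
            for i in order:
                m |= 1 << i
                cur = solver.r2(m)
                gains[t, i] = cur - prev
                prev = cur
        shares = gains.mean(axis=0)
        se = gains.std(axis=0, ddof=1) / math.sqrt(n_orderings)
        return VarianceShares(
            pd.Series(shares, index=names),
            total,
            "sampled",
            n_orderings=n_orderings,
            seed=seed,
            mc_se=pd.Series(se, index=names),
        )
    raise ConfigurationError(f"unknown mode {mode!r}")


def factor_group(series: pd.Series, reference: str | None = None) -> pd.DataFrame:
    """Design columns of one variable as a single LMG group."""
    return encode_variable(series, reference=reference)


def variance_report(
    cyt: CytokineMatrix,
    cov: pd.DataFrame,
    stimulation: str,
    associated_variables: list[str],
    cytokine_list: list[str],
    cells: pd.DataFrame | None = None,
    main_cell_subset: str | None = None,
    snps: pd.DataFrame | None = None,
    cpgs: pd.DataFrame | None = None,
    responder_labels: pd.Series | None = None,
    mode: str = "exact",
    seed: int | None = None,
    n_orderings: int = 1000,
) -> pd.DataFrame:
    """Variance decomposition for each induced cytokine of a stimulation.

    The regressor set mirrors the global models of the analysis: every
    screened variable associated with at least one induced cytokine,
    plus (when provided) the stimulation's main cell subset (log
    counts), associated SNP dosages and CpG beta values.  Returns a long
    table (stimulation, cytokine, group, share, total_r2, method).
    """
    donors = cyt.donors.intersection(cov.index)
    if responder_labels is not None:
        resp = responder_labels.reindex(donors).fillna(False).astype(bool)
        donors = donors[resp.to_numpy()]
    if not associated_variables and snps is None and cpgs is None:
        warnings.warn("empty associated set; variance report skipped")
        return pd.DataFrame()
    groups: dict[str, pd.DataFrame] = {}
    for v in associated_variables:
        groups[v] = factor_group(cov.loc[donors, v])
    if main_cell_subset is not None and cells is not None:
        groups[main_cell_subset] = np.log(
            cells[main_cell_subset].reindex(donors).astype(float) + 0.5
        ).to_frame(main_cell_subset)
    if snps is not None:
        for s in snps.columns:
            groups[s] = snps[s].reindex(donors).astype(float).to_frame(s)
    if cpgs is not None:
        for c in cpgs.columns:
            groups[c] = cpgs[c].reindex(donors).astype(float).to_frame(c)
    Y = cyt.log_values(stimulation).loc[donors]
    rows = []
    for c in cytokine_list:
        vs = lmg_shares(Y[c], groups, mode=mode, seed=seed, n_orderings=n_orderings)
        for g, share in vs.shares.items():
            rows.append(
                {
                    "stimulation": stimulation,
                    "cytokine": c,
                    "group": g,
                    "share": share,
                    "total_r2": vs.total_r2,
                    "method": vs.method,
                }
            )
    return pd.DataFrame(rows)
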