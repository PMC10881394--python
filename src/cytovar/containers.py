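"""In-memory containers for cohort data.

All tables are pandas DataFrames indexed by donor id.  Cytokine
concentrations live in a wide matrix with a (stimulation, cytokine)
column MultiIndex together with a per-(stimulation, cytokine) lower limit
of quantification (LLOQ); concentrations below the LLOQ are clamped to it
before the natural-log transform used throughout the analysis.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError


@dataclasses.dataclass
class CytokineMatrix:
    """Donor x (stimulation, cytokine) concentration matrix with LLOQs."""

    values: pd.DataFrame  # columns: MultiIndex (stimulation, cytokine)
    lloq: pd.Series  # index: MultiIndex (stimulation, cytokine)
    null_condition: str = "null"

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise DataError("cytokine matrix needs (stimulation, cytokine) columns")
        if self.null_condition not in self.stimulations:
            raise DataError(
                f"null condition {self.null_condition!r} missing from cytokine matrix"
            )
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) <= 0:
            raise DataError("cytokine concentrations must be strictly positive")

    @property
    def donors(self) -> pd.Index:
        return self.values.index

    @property
    def stimulations(self) -> list[str]:
        return list(self.values.columns.get_level_values(0).unique())

    @property
    def cytokines(self) -> list[str]:
        return list(self.values.columns.get_level_values(1).unique())

    def concentrations(self, stimulation: str) -> pd.DataFrame:
        """Raw (LLOQ-clamped) concentrations for one stimulation."""
        block = self.values[stimulation].copy()
        floor = self.lloq.get(stimulation)
        if floor is not None:
            block = block.clip(lower=floor.reindex(block.columns), axis=1)
        return block

    def log_values(self, stimulation: str) -> pd.DataFrame:
        """Natural-log concentrations, clamped at the LLOQ."""
        return np.log(self.concentrations(stimulation))


@dataclasses.dataclass
class GenotypeMatrix:
    """Additive dosages (0/1/2, NaN for missing) plus a SNP map."""

    dosages: pd.DataFrame  # donors x snp ids
    snp_info: pd.DataFrame  # index snp id; columns: chrom, pos, maf
    assembly: str = "synthetic"

    def __post_init__(self) -> None:
        missing = set(self.dosages.columns) - set(self.snp_info.index)
        if missing:
            raise DataError(f"snp map missing entries for {sorted(missing)[:5]}")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise DataError("dosages must be 0/1/2 or missing")

    @property
    def donors(self) -> pd.Index:
        return self.dosages.index

    @property
    def snps(self) -> pd.Index:
        return self.dosages.columns

    def observed_maf(self) -> pd.Series:
        """Minor allele frequency recomputed from non-missing dosages."""
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset(self, snps: Iterable[str]) -> "GenotypeMatrix":
        snps = list(snps)
        return GenotypeMatrix(
            self.dosages[snps], self.snp_info.loc[snps], self.assembly
        )


@dataclasses.dataclass
class TruthLedger:
    """Ground truth of a synthetic cohort, for parameter-recovery tests."""

    planted_associations: list[tuple]  # (variable, stimulation, cytokine, beta)
    planted_mediators: list[tuple]  # (variable, mediator, stimulation, cytokine)
    planted_pqtls: list[tuple]  # (snp, stimulation, cytokine, slope, cis/trans)
    responder_labels: pd.Series | None = None  # donor -> bool


@dataclasses.dataclass
class CohortBundle:
    """All per-donor tables of one cohort plus (for synthetic data) truth."""

    covariates: pd.DataFrame
    cytokines: CytokineMatrix
    cells: pd.DataFrame | None = None
    proteins: pd.DataFrame | None = None
    methylation: pd.DataFrame | None = None
    cpg_positions: pd.DataFrame | None = None  # index cpg id; chrom, pos
    genotypes: GenotypeMatrix | None = None
    gene_tss: pd.DataFrame | None = None  # index gene/cytokine; chrom, tss
    truth: TruthLedger | None = None

    def __post_init__(self) -> None:
        if self.covariates.index.has_duplicates:
            dup = self.covariates.index[self.covariates.index.duplicated()][0]
            raise DataError(f"duplicated donor id {dup!r} in covariate table")

    @property
    def donors(self) -> pd.Index:
        return self.covariates.index
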