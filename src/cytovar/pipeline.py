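"""Pipeline configuration and end-to-end orchestration.

Stage order mirrors the analysis flow: induction profiling, responder
detection, donor-variable screen, mediation (when mediator panels are
available), pQTL scan (when genotypes are available) and variance
partitioning.  Every output TSV carries a provenance header (config
hash, seed, stage); all randomness flows from the configured seed, so
re-running with an identical configuration reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import induction, mediation, pqtl, varpart
from .screen import screen as run_screen
from .containers import CohortBundle
from .errors import ConfigurationError
from .io import config_hash, load_bundle, write_table
from .simulate import SimulationConfig, simulate_cohort

log = logging.getLogger("cytovar")


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds, designations and paths driving a pipeline run."""

    bundle_dir: str | None = None  # input bundle; None -> synthetic default
    null_condition: str = "null"
    responder_stimulation: str | None = "anti-CD3+CD28"
    responder_cytokines: list | None = None  # default: all induced
    stimulations: list | None = None  # default: all non-null in the bundle
    main_subset_map: dict | None = None  # default: pqtl.MAIN_CELL_SUBSET
    induction_threshold: float = 0.30
    screen_alpha: float = 0.01
    cpg_fdr: float = 0.05
    maf_threshold: float = 0.05
    cis_window: int = 1_000_000
    cis_detection: float = 1e-3
    trans_detection: float = 1e-5
    bonferroni_alpha: float = 0.05
    variance_q: float = 0.05
    seed: int = 0
    mediation_variable: str = "smoking_status"
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in (
            "screen_alpha", "cpg_fdr", "maf_threshold", "cis_detection",
            "trans_detection", "bonferroni_alpha", "variance_q",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        if self.cis_window <= 0:
            raise ConfigurationError("cis_window must be positive")
        if self.bundle_dir is not None and not Path(self.bundle_dir).exists():
            raise ConfigurationError(f"bundle_dir {self.bundle_dir!r} does not exist")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from YAML, rejecting unknown keys."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**payload)
    cfg.validate()
    return cfg


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every applicable stage; returns the report directory.

    Optional stages are skipped (and the skip recorded in report.txt)
    when their inputs are absent from the bundle.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    prov = {"config": config_hash(dataclasses.asdict(config)), "seed": config.seed}
    report: list[str] = []

    if config.bundle_dir is not None:
        bundle = load_bundle(config.bundle_dir, null_condition=config.null_condition)
    else:
        bundle, _ = simulate_cohort(SimulationConfig(seed=config.seed))
        report.append("input: synthetic default cohort (no bundle_dir configured)")
    cyt = bundle.cytokines
    log.info("loaded %d donors, %d stimulations", len(bundle.donors), len(cyt.stimulations))

    # --- induction
    flags = induction.flag_induced(cyt, threshold=config.induction_threshold)
    slmd = induction.compute_slmd(cyt)
    write_table(flags, outdir / "induced_flags.tsv", {**prov, "stage": "induction"})
    write_table(slmd, outdir / "slmd.tsv", {**prov, "stage": "induction"})
    order = induction.cluster_profile(slmd)
    write_table(
        pd.DataFrame({"row_order": pd.Series(order.row_order)}),
        outdir / "cluster_row_order.tsv",
        {**prov, "stage": "induction"},
    )
    report.append(f"induction: {int(flags.to_numpy().sum())} induced pairs")

    # --- responders
    responder_labels = None
    rstim = config.responder_stimulation
    if rstim is not None and rstim in cyt.stimulations:
        cyts = config.responder_cytokines or [
            c for c in cyt.cytokines if flags.loc[rstim, c]
        ]
        responder_labels = induction.detect_responders(
            cyt, rstim, cyts, seed=config.seed
        )
        write_table(
            responder_labels.to_frame(),
            outdir / "responder_labels.tsv",
            {**prov, "stage": "responders"},
        )
        report.append(
            f"responders: {int(responder_labels.sum())}/{len(responder_labels)}"
            f" responding to {rstim}"
        )

    stims = config.stimulations or [
        s for s in cyt.stimulations if s != cyt.null_condition
    ]

    # --- screen
    screen_tables = []
    for stim in stims:
        labels = responder_labels if stim == rstim else None
        res = run_screen(
            cyt, bundle.covariates, stim,
            induced=flags, alpha=config.screen_alpha, responder_labels=labels,
        )
        if len(res.table):
            screen_tables.append(res.table)
            write_table(
                res.table, outdir / f"screen_{stim.replace(' ', '_')}.tsv",
                {**prov, "stage": "screen"}, index=False,
            )
        report.append(
            f"screen[{stim}]: {res.family_size} tests,"
            f" {int(res.table['significant'].sum()) if len(res.table) else 0} significant"
        )
    screen_all = (
        pd.concat(screen_tables, ignore_index=True) if screen_tables else pd.DataFrame()
    )

    # --- mediation
    if bundle.cells is not None and len(stims):
        stim = stims[0]
        labels = responder_labels if stim == rstim else None
        elim = mediation.elimination_matrix(
            cyt, bundle.covariates, config.mediation_variable, bundle.cells,
            "cell", stim, alpha=config.screen_alpha, induced=flags,
            responder_labels=labels,
        )
        if len(elim.table):
            write_table(
                elim.table, outdir / f"elimination_cells_{stim.replace(' ', '_')}.tsv",
                {**prov, "stage": "mediation"}, index=False,
            )
        report.append(
            f"mediation[{stim}]: {int(elim.table['eliminated'].sum()) if len(elim.table) else 0}"
            " eliminating cell subsets"
        )
    else:
        report.append("mediation: skipped (no cell panel)")

    # --- pQTL
    pqtl_hits = pd.DataFrame()
    if bundle.genotypes is not None:
        gt = pqtl.maf_filter(bundle.genotypes, config.maf_threshold)
        scan_tables = []
        for stim in stims:
            labels = responder_labels if stim == rstim else None
            res = pqtl.scan(
                gt, cyt, bundle.covariates, stim,
                cells=bundle.cells, gene_tss=bundle.gene_tss,
                main_subset_map=config.main_subset_map,
                responder_labels=labels, induced=flags,
                cis_detection=config.cis_detection,
                trans_detection=config.trans_detection,
                bonferroni_alpha=config.bonferroni_alpha,
                cis_window=config.cis_window,
            )
            if len(res.table):
                scan_tables.append(res.table)
            report.append(
                f"pqtl[{stim}]: family {res.family_size},"
                f" {int(res.table['hit'].sum()) if len(res.table) else 0} hits"
            )
        if scan_tables:
            pqtl_hits = pd.concat(scan_tables, ignore_index=True)
            write_table(
                pqtl_hits, outdir / "pqtl_hits.tsv",
                {**prov, "stage": "pqtl"}, index=False,
            )
    else:
        report.append("pqtl: skipped (no genotypes)")

    # --- variance partition
    var_tables = []
    for stim in stims:
        if not len(screen_all):
            break
        sub = screen_all[screen_all["stimulation"] == stim]
        assoc = sorted(
            sub.loc[sub["p_adjusted"] < config.variance_q, "variable"].unique()
        )
        if not assoc:
            report.append(f"varpart[{stim}]: skipped (no associated variables)")
            continue
        cyt_list = sorted(
            sub.loc[sub["p_adjusted"] < config.variance_q, "cytokine"].unique()
        )
        snps = None
        if len(pqtl_hits):
            hit_snps = pqtl_hits.loc[
                (pqtl_hits["stimulation"] == stim) & pqtl_hits["hit"], "snp"
            ].unique()
            if len(hit_snps):
                snps = bundle.genotypes.dosages[list(hit_snps)]
        labels = responder_labels if stim == rstim else None
        tab = varpart.variance_report(
            cyt, bundle.covariates, stim, assoc, cyt_list,
            cells=bundle.cells,
            main_cell_subset=None,
            snps=snps, responder_labels=labels,
            mode="exact",
        )
        if len(tab):
            var_tables.append(tab)
        report.append(f"varpart[{stim}]: {len(assoc)} groups, {len(cyt_list)} cytokines")
    if var_tables:
        write_table(
            pd.concat(var_tables, ignore_index=True),
            outdir / "variance_shares.tsv",
            {**prov, "stage": "varpart"}, index=False,
        )

    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    return outdir
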