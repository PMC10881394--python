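"""Synthetic cohort generator with planted, recoverable effects.

The generator emulates the statistical structure the downstream analysis
assumes: a cohort of ~1,000 healthy donors balanced by sex within each
decade of age between 20 and 69; log-scale cytokine responses driven by
age, sex, batch, planted donor-variable effects, mediator chains and
genotypes plus Gaussian noise (i.e. lognormal concentrations); a
non-stimulated null condition free of stimulation effects;
smoking-dose-dependent CpG hypomethylation that reverts with years since
cessation; memory-cell counts elevated in CMV-seropositive donors;
Hardy-Weinberg genotypes with planted cis/trans effects; and a bimodal
responder/non-responder split for one designated stimulation.

Every planted effect is recorded in a :class:`TruthLedger` so recovery
tests can compare what the pipeline finds against what was planted.

Randomness: a single global seed drives a ``numpy`` SeedSequence from
which per-table child streams are spawned in a fixed, documented order
(covariates, cells, proteins, genotypes, methylation, cytokines,
responders) so adding one table never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import CohortBundle, CytokineMatrix, GenotypeMatrix, TruthLedger
from .errors import ConfigurationError, DataError
from .screen import REFERENCE_LEVELS

DEFAULT_CYTOKINES = (
    "CXCL5", "CSF2", "IFNg", "IL-1b", "TNF", "IL-2", "IL-6",
    "IL-8", "IL-10", "IL-12p70", "IL-13", "IL-17", "IL-23",
)
DEFAULT_STIMULATIONS = (
    "null", "E. coli", "LPS", "SEB", "anti-CD3+CD28", "BCG",
    "C. albicans", "influenza", "poly I:C", "TNF", "IL-1b", "IFNg",
)
DEFAULT_CELL_SUBSETS = (
    "monocytes", "CD4pos", "CD8posEMRA", "CD45pos", "cDC3", "CD3pos",
    "CD4_EM", "CD8_EM", "B_memory", "Tregs",
)
# memory compartments expanded in CMV-seropositive donors
CMV_MEMORY_SUBSETS = ("CD4_EM", "CD8_EM", "CD8posEMRA")
DEFAULT_PROTEINS = ("CEACAM6", "protein_02", "protein_03", "protein_04", "protein_05")


@dataclasses.dataclass
class PlantedEffect:
    """A donor-variable effect on one (stimulation, cytokine) log level.

    For a categorical variable the log-scale coefficient ``beta`` applies
    to donors at ``level`` (or to every non-reference level when ``level``
    is None, e.g. an "ever smoked" effect).  For a numeric variable it
    applies per standard deviation of the variable.
    """

    variable: str
    stimulation: str
    cytokine: str
    beta: float
    level: str | None = None


@dataclasses.dataclass
class MediationSpec:
    """A mediation chain variable -> mediator -> cytokine.

    ``alpha`` is the variable's effect on the mediator's modelling scale
    (log counts for cells, log abundance for proteins, logit beta for
    CpGs); ``beta`` the mediator's effect on the log cytokine level.
    ``direct`` adds a residual direct path (0 = full mediation).
    """

    variable: str
    mediator: str
    mediator_kind: str  # cell | protein | cpg
    stimulation: str
    cytokine: str
    alpha: float
    beta: float
    direct: float = 0.0
    level: str | None = None


@dataclasses.dataclass
class SnpSpec:
    """One simulated SNP, optionally with a planted cytokine effect.

    ``ld_with``/``ld_r`` generate this SNP's haplotypes in linkage
    disequilibrium (haplotype correlation ``ld_r``, so dosage r^2 is
    about ``ld_r**2``) with a previously declared SNP of the same MAF.
    """

    id: str
    chrom: str
    pos: int
    maf: float
    stimulation: str | None = None
    cytokine: str | None = None
    slope: float = 0.0
    ld_with: str | None = None
    ld_r: float | None = None


@dataclasses.dataclass
class CpgSpec:
    """One simulated CpG with smoking-dose hypomethylation.

    Logit-scale model: logit(baseline_beta) - packyear_coef * pack_years
    + reversion_coef * years_since_quit (past smokers only) + noise.
    """

    id: str
    chrom: str
    pos: int
    baseline_beta: float = 0.85
    packyear_coef: float = 0.03
    reversion_coef: float = 0.05
    sd: float = 0.3


def _default_tss(cytokines: Sequence[str]) -> pd.DataFrame:
    """Synthetic gene TSS coordinates, one per cytokine (not real loci)."""
    rows = {
        c: {"chrom": f"chr{(i % 5) + 1}", "tss": 10_000_000 * (i + 1)}
        for i, c in enumerate(cytokines)
    }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the cohort design the pipeline targets: 1,000 donors,
    100 per sex per decade of age 20-69, two technical batches, lognormal
    cytokine concentrations with unit log-scale noise, a 29.5%
    non-responder fraction for the anti-CD3+CD28-style stimulation and a
    CMV seroprevalence of 35%.
    """

    n_donors: int = 1000
    seed: int = 0
    age_range: tuple[int, int] = (20, 69)
    sex_balance: float = 0.5
    batch_levels: int = 2
    smoking_prevalence: tuple[float, float, float] = (0.5, 0.25, 0.25)
    cmv_seroprevalence: float = 0.35
    stimulations: tuple[str, ...] = DEFAULT_STIMULATIONS
    null_condition: str = "null"
    cytokines: tuple[str, ...] = DEFAULT_CYTOKINES
    effect_ledger: tuple[PlantedEffect, ...] = ()
    mediation_specs: tuple[MediationSpec, ...] = ()
    snp_specs: tuple[SnpSpec, ...] = ()
    cpg_specs: tuple[CpgSpec, ...] = ()
    noise_sd: float = 1.0
    responder_stimulation: str | None = "anti-CD3+CD28"
    responder_split: float = 0.295  # fraction of non-responders
    # nuisance structure
    age_beta: float = 0.10  # per SD of age, log scale
    sex_beta: float = 0.15  # female vs male, log scale
    batch_beta: float = 0.10  # per batch step, log scale
    stim_log_level: float = 4.6  # log concentration of an induced analyte
    null_log_level: float = 0.7  # log concentration in the null condition
    lloq: float = 0.5
    cell_subsets: tuple[str, ...] = DEFAULT_CELL_SUBSETS
    cmv_memory_boost: float = 0.5  # log-count elevation in CMV+ donors
    proteins: tuple[str, ...] = DEFAULT_PROTEINS
    n_extra_numeric: int = 0
    n_extra_categorical: int = 0
    missing_rate: float = 0.0

    def validate(self) -> None:
        if self.n_donors < 2:
            raise ConfigurationError("n_donors must be at least 2")
        for name in ("sex_balance", "cmv_seroprevalence", "responder_split",
                     "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        sp = self.smoking_prevalence
        if len(sp) != 3 or any(not 0 <= p <= 1 for p in sp) or abs(sum(sp) - 1) > 1e-9:
            raise ConfigurationError(
                "smoking_prevalence must be three proportions summing to 1"
            )
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range must be (low, high) with low < high")
        if self.batch_levels < 1:
            raise ConfigurationError("batch_levels must be >= 1")
        if self.null_condition not in self.stimulations:
            raise ConfigurationError(
                f"null_condition {self.null_condition!r} not in stimulations"
            )
        if sum(s == self.null_condition for s in self.stimulations) != 1:
            raise ConfigurationError("exactly one stimulation must be the null condition")
        if (
            self.responder_stimulation is not None
            and self.responder_stimulation not in self.stimulations
        ):
            raise ConfigurationError(
                f"responder_stimulation {self.responder_stimulation!r} not in stimulations"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        for spec in self.snp_specs:
            if not 0.05 < spec.maf <= 0.5:
                raise ConfigurationError(
                    f"snp_specs: maf of {spec.id!r} must lie in (0.05, 0.5]"
                )
        for spec in self.cpg_specs:
            if not 0.0 < spec.baseline_beta < 1.0:
                raise ConfigurationError(
                    f"cpg_specs: baseline_beta of {spec.id!r} must lie in (0, 1)"
                )
        stims, cyts = set(self.stimulations), set(self.cytokines)
        for eff in self.effect_ledger:
            if eff.stimulation not in stims or eff.cytokine not in cyts:
                raise ConfigurationError(
                    f"effect_ledger: unknown target ({eff.stimulation!r}, {eff.cytokine!r})"
                )
        for med in self.mediation_specs:
            if med.mediator_kind not in ("cell", "protein", "cpg"):
                raise ConfigurationError(
                    f"mediation_specs: mediator_kind {med.mediator_kind!r} invalid"
                )
            if med.stimulation not in stims or med.cytokine not in cyts:
                raise ConfigurationError(
                    f"mediation_specs: unknown target ({med.stimulation!r}, {med.cytokine!r})"
                )


def _simulate_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_donors
    low, high = config.age_range
    n_dec = max(1, (high + 1 - low) // 10)
    base, rem = divmod(n, n_dec)
    ages = []
    for d in range(n_dec):
        size = base + (1 if d < rem else 0)
        span = min(10, high + 1 - (low + 10 * d))
        ages.append(low + 10 * d + rng.uniform(0, span, size=size))
    age = np.concatenate(ages)
    # balanced sex within decade strata
    sex = np.concatenate(
        [
            np.where(np.arange(len(a)) < round(len(a) * config.sex_balance), "F", "M")
            for a in ages
        ]
    )
    order = rng.permutation(n)
    age, sex = age[order], sex[order]
    batch = np.array([f"B{b + 1}" for b in rng.integers(0, config.batch_levels, n)])
    smoking = rng.choice(
        ["never", "past", "current"], size=n, p=list(config.smoking_prevalence)
    )
    ever = smoking != "never"
    years_smoking = np.where(
        ever, rng.uniform(1.0, np.maximum(2.0, age - 18.0)), 0.0
    )
    cpd = rng.uniform(5, 25, n)  # cigarettes per day
    total_cigarettes = np.where(ever, years_smoking * 365.25 * cpd, 0.0)
    pack_years = np.where(ever, years_smoking * cpd / 20.0, 0.0)
    max_quit = np.maximum(1.0, age - 19.0 - years_smoking)
    years_since_quit = np.where(
        smoking == "past", rng.uniform(0.5, max_quit), np.nan
    )
    cmv = rng.random(n) < config.cmv_seroprevalence
    bmi = np.clip(rng.normal(24.5, 3.8, n), 16, 45)
    cov = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "batch": batch,
            "smoking_status": smoking,
            "years_smoking": years_smoking,
            "years_since_quit": years_since_quit,
            "total_cigarettes": total_cigarettes,
            "pack_years": pack_years,
            "cmv_seropositive": cmv,
            "bmi": bmi,
        },
        index=pd.Index([f"D{i + 1:04d}" for i in range(n)], name="donor"),
    )
    extras: dict[str, np.ndarray] = {}
    for j in range(config.n_extra_numeric):
        extras[f"var_num_{j + 1:03d}"] = rng.normal(size=n)
    for j in range(config.n_extra_categorical):
        n_levels = int(rng.integers(2, 5))
        probs = rng.dirichlet(np.full(n_levels, 3.0))
        extras[f"var_cat_{j + 1:03d}"] = rng.choice(
            [f"L{k + 1}" for k in range(n_levels)], size=n, p=probs
        )
    if extras:
        cov = pd.concat([cov, pd.DataFrame(extras, index=cov.index)], axis=1)
    return cov


def simulate_genotypes(
    n_donors: int,
    snp_specs: Sequence[SnpSpec],
    seed: int | np.random.Generator,
) -> GenotypeMatrix:
    """Draw Hardy-Weinberg dosages for each SNP spec.

    LD pairs are generated at the haplotype level: each of the two
    haplotypes of the dependent SNP copies the partner's allele state
    with the probability that yields haplotype correlation ``ld_r``.
    """
    if n_donors < 2:
        raise ConfigurationError("n_donors must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    haplos: dict[str, np.ndarray] = {}
    cols: dict[str, np.ndarray] = {}
    info_rows = []
    for spec in snp_specs:
        if not 0.0 < spec.maf <= 0.5:
            raise ConfigurationError(
                f"maf of {spec.id!r} must lie in (0, 0.5], got {spec.maf}"
            )
        p = spec.maf
        if spec.ld_with is not None:
            if spec.ld_with not in haplos:
                raise ConfigurationError(
                    f"ld_with {spec.ld_with!r} of {spec.id!r} not declared earlier"
                )
            r = float(spec.ld_r or 0.0)
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"ld_r of {spec.id!r} must lie in [0, 1]")
            a = haplos[spec.ld_with]
            q1 = p + r * (1 - p)  # P(b=1 | a=1), equal-MAF pair
            q0 = p * (1 - r)
            u = rng.random(a.shape)
            h = np.where(a == 1, u < q1, u < q0).astype(np.int8)
        else:
            h = (rng.random((n_donors, 2)) < p).astype(np.int8)
        haplos[spec.id] = h
        cols[spec.id] = h.sum(axis=1).astype(float)
        info_rows.append(
            {"snp": spec.id, "chrom": spec.chrom, "pos": spec.pos, "maf": spec.maf}
        )
    index = pd.Index([f"D{i + 1:04d}" for i in range(n_donors)], name="donor")
    dosages = pd.DataFrame(cols, index=index)
    info = pd.DataFrame(info_rows).set_index("snp") if info_rows else pd.DataFrame(
        columns=["chrom", "pos", "maf"]
    )
    return GenotypeMatrix(dosages, info)


def simulate_methylation(
    covariates: pd.DataFrame,
    cpg_specs: Sequence[CpgSpec],
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CpG beta values with smoking-dose hypomethylation and reversion.

    Returns (beta matrix, CpG position table).  Current and past smokers
    are hypomethylated proportionally to pack-years; past smokers revert
    toward baseline with years since quitting.
    """
    for field in ("smoking_status", "pack_years", "years_since_quit"):
        if field not in covariates:
            raise DataError(f"covariate table lacks required field {field!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pack_years = covariates["pack_years"].to_numpy(dtype=float)
    past = (covariates["smoking_status"] == "past").to_numpy()
    ysq = np.where(past, covariates["years_since_quit"].fillna(0.0), 0.0)
    n = len(covariates)
    cols = {}
    pos_rows = []
    for spec in cpg_specs:
        lin = (
            logit(spec.baseline_beta)
            - spec.packyear_coef * pack_years
            + spec.reversion_coef * ysq
            + spec.sd * rng.standard_normal(n)
        )
        cols[spec.id] = expit(lin)
        pos_rows.append({"cpg": spec.id, "chrom": spec.chrom, "pos": spec.pos})
    beta = pd.DataFrame(cols, index=covariates.index)
    positions = (
        pd.DataFrame(pos_rows).set_index("cpg")
        if pos_rows
        else pd.DataFrame(columns=["chrom", "pos"])
    )
    return beta, positions


def _variable_exposure(
    cov: pd.DataFrame, variable: str, level: str | None
) -> np.ndarray:
    """Design vector a planted effect multiplies: level indicator for a
    categorical variable (all non-reference levels when level is None),
    standardized values for a numeric variable."""
    if variable not in cov:
        raise ConfigurationError(f"planted effect references unknown variable {variable!r}")
    s = cov[variable]
    if pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s):
        v = s.to_numpy(dtype=float)
        sd = np.nanstd(v)
        return (v - np.nanmean(v)) / (sd if sd > 0 else 1.0)
    if level is not None:
        return (s == level).to_numpy(dtype=float)
    levels = sorted(s.dropna().unique(), key=str)
    # reference mirrors the screen's treatment coding ("never" for smoking)
    ref = REFERENCE_LEVELS.get(variable, levels[0])
    return (s != ref).to_numpy(dtype=float)


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[CohortBundle, TruthLedger]:
    """Generate a full synthetic cohort plus its ground-truth ledger.

    Deterministic given (config, seed); ``seed`` defaults to
    ``config.seed``.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    children = np.random.SeedSequence(seed).spawn(7)
    (ss_cov, ss_cells, ss_prot, ss_geno, ss_meth, ss_cyt, ss_resp) = children

    cov = _simulate_covariates(config, np.random.default_rng(ss_cov))
    n = config.n_donors
    donors = cov.index

    # --- cells: lognormal counts; CMV+ donors carry expanded memory subsets
    rng_cells = np.random.default_rng(ss_cells)
    cmv = cov["cmv_seropositive"].to_numpy(dtype=float)
    log_cells = {}
    for i, subset in enumerate(config.cell_subsets):
        base = 6.0 + 0.2 * (i % 5)
        lc = base + 0.5 * rng_cells.standard_normal(n)
        if subset in CMV_MEMORY_SUBSETS:
            lc = lc + config.cmv_memory_boost * cmv
        log_cells[subset] = lc

    # --- proteins: lognormal abundances
    rng_prot = np.random.default_rng(ss_prot)
    log_prot = {
        name: 2.0 + 0.5 * rng_prot.standard_normal(n) for name in config.proteins
    }

    # --- genotypes
    genotypes = (
        simulate_genotypes(n, config.snp_specs, np.random.default_rng(ss_geno))
        if config.snp_specs
        else None
    )

    # --- methylation (latent logit values needed for cpg mediators)
    rng_meth = np.random.default_rng(ss_meth)
    methylation = cpg_positions = None
    if config.cpg_specs:
        methylation, cpg_positions = simulate_methylation(
            cov, config.cpg_specs, rng_meth
        )

    # --- mediator chains: variable -> mediator (modelling scale)
    mediator_values: dict[str, np.ndarray] = {}
    for med in config.mediation_specs:
        x = _variable_exposure(cov, med.variable, med.level)
        if med.mediator_kind == "cell":
            if med.mediator not in log_cells:
                log_cells[med.mediator] = 6.0 + 0.5 * rng_cells.standard_normal(n)
            log_cells[med.mediator] = log_cells[med.mediator] + med.alpha * x
            mediator_values[med.mediator] = log_cells[med.mediator]
        elif med.mediator_kind == "protein":
            if med.mediator not in log_prot:
                log_prot[med.mediator] = 2.0 + 0.5 * rng_prot.standard_normal(n)
            log_prot[med.mediator] = log_prot[med.mediator] + med.alpha * x
            mediator_values[med.mediator] = log_prot[med.mediator]
        else:  # cpg
            if methylation is None or med.mediator not in methylation:
                lin = logit(0.85) + 0.3 * rng_meth.standard_normal(n)
                col = pd.Series(expit(lin), index=donors, name=med.mediator)
                methylation = (
                    col.to_frame() if methylation is None
                    else pd.concat([methylation, col], axis=1)
                )
                pos = pd.DataFrame(
                    {"chrom": ["chr9"], "pos": [1_000_000]}, index=[med.mediator]
                )
                cpg_positions = (
                    pos if cpg_positions is None else pd.concat([cpg_positions, pos])
                )
            else:
                lin = logit(methylation[med.mediator].to_numpy()) + med.alpha * x
                methylation[med.mediator] = expit(lin)
            mediator_values[med.mediator] = logit(
                methylation[med.mediator].to_numpy()
            )

    cells = pd.DataFrame(
        {k: np.exp(v) for k, v in log_cells.items()}, index=donors
    )
    proteins = pd.DataFrame(
        {k: np.exp(v) for k, v in log_prot.items()}, index=donors
    )

    # --- cytokines
    rng_cyt = np.random.default_rng(ss_cyt)
    gene_tss = _default_tss(config.cytokines)
    age_z = (cov["age"] - cov["age"].mean()) / cov["age"].std()
    female = (cov["sex"] == "F").to_numpy(dtype=float)
    batch_idx = cov["batch"].str.removeprefix("B").astype(int).to_numpy() - 1.0

    columns = pd.MultiIndex.from_product(
        [config.stimulations, config.cytokines], names=["stimulation", "cytokine"]
    )
    log_conc = pd.DataFrame(
        np.nan, index=donors, columns=columns, dtype=float
    )
    truth_assoc: list[tuple] = []
    truth_med: list[tuple] = []
    truth_pqtl: list[tuple] = []
    for stim in config.stimulations:
        is_null = stim == config.null_condition
        for k, cyt in enumerate(config.cytokines):
            noise = config.noise_sd * rng_cyt.standard_normal(n)
            if is_null:
                log_conc[(stim, cyt)] = config.null_log_level + noise
                continue
            y = (
                config.stim_log_level
                + 0.1 * (k % 3)
                + config.age_beta * age_z.to_numpy()
                + config.sex_beta * female
                + config.batch_beta * batch_idx
                + noise
            )
            for eff in config.effect_ledger:
                if (eff.stimulation, eff.cytokine) == (stim, cyt):
                    y = y + eff.beta * _variable_exposure(cov, eff.variable, eff.level)
            for med in config.mediation_specs:
                if (med.stimulation, med.cytokine) == (stim, cyt):
                    m = mediator_values[med.mediator]
                    y = y + med.beta * (m - m.mean())
                    if med.direct:
                        y = y + med.direct * _variable_exposure(
                            cov, med.variable, med.level
                        )
            for spec in config.snp_specs:
                if spec.slope and (spec.stimulation, spec.cytokine) == (stim, cyt):
                    y = y + spec.slope * genotypes.dosages[spec.id].to_numpy()
            log_conc[(stim, cyt)] = y

    # --- non-responders: null-level response for the designated stimulation
    rng_resp = np.random.default_rng(ss_resp)
    responder_labels = None
    rstim = config.responder_stimulation
    if rstim is not None and config.responder_split > 0:
        non_resp = rng_resp.random(n) < config.responder_split
        responder_labels = pd.Series(~non_resp, index=donors, name="responder")
        for cyt in config.cytokines:
            noise = config.noise_sd * rng_resp.standard_normal(n)
            null_level = config.null_log_level + noise
            col = log_conc[(rstim, cyt)].to_numpy()
            log_conc[(rstim, cyt)] = np.where(non_resp, null_level, col)

    values = np.exp(log_conc)
    if config.missing_rate > 0:
        mask = rng_cyt.random(values.shape) < config.missing_rate
        values = values.mask(mask)
    lloq = pd.Series(config.lloq, index=columns)
    cytokines = CytokineMatrix(values, lloq, null_condition=config.null_condition)

    for eff in config.effect_ledger:
        truth_assoc.append((eff.variable, eff.stimulation, eff.cytokine, eff.beta))
    for med in config.mediation_specs:
        truth_med.append((med.variable, med.mediator, med.stimulation, med.cytokine))
    for spec in config.snp_specs:
        if spec.slope and spec.cytokine is not None:
            tss = gene_tss.loc[spec.cytokine]
            label = (
                "cis"
                if spec.chrom == tss["chrom"] and abs(spec.pos - tss["tss"]) <= 1_000_000
                else "trans"
            )
            truth_pqtl.append(
                (spec.id, spec.stimulation, spec.cytokine, spec.slope, label)
            )
    truth = TruthLedger(
        planted_associations=truth_assoc,
        planted_mediators=truth_med,
        planted_pqtls=truth_pqtl,
        responder_labels=responder_labels,
    )
    bundle = CohortBundle(
        covariates=cov,
        cytokines=cytokines,
        cells=cells,
        proteins=proteins,
        methylation=methylation,
        cpg_positions=cpg_positions,
        genotypes=genotypes,
        gene_tss=gene_tss,
        truth=truth,
    )
    return bundle, truth
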