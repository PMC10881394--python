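"""Table readers/writers and cohort bundle (de)serialization.

The canonical tabular dialect is TSV with a header row, UTF-8, "." for
missing values; CSV is accepted on read.  Output tables carry provenance
header lines starting with "#" (package version, stage, config hash,
seed) which readers skip.  Genotypes round-trip either as a dosage TSV
plus SNP map or as a minimal VCF v4.2 with a GT-only FORMAT field.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CohortBundle, CytokineMatrix, GenotypeMatrix, TruthLedger
from .errors import DataError

NA_REP = "."


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    from . import __version__

    items = " ".join(f"{k}={v}" for k, v in provenance.items())
    return f"# cytovar {__version__} {items}\n"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    provenance: dict | None = None,
    index: bool = True,
) -> None:
    """Write a TSV with optional '#' provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep="\t", na_rep=NA_REP, index=index)


def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    """Read a TSV/CSV table, skipping '#' comment lines; '.' is missing."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    # keep_default_na=False so condition names like "null" survive; only
    # the canonical "." (and empty fields) mean missing
    return pd.read_csv(
        path, sep=sep, comment="#", na_values=[NA_REP, ""], index_col=index_col,
        keep_default_na=False,
    )


# --- minimal VCF v4.2 (GT only) -------------------------------------------

def write_vcf(gt: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal VCF v4.2 with GT-only genotype fields."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    donors = list(gt.donors)
    gtmap = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(gt.snp_info["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(donors)
            + "\n"
        )
        info = gt.snp_info.assign(_pos=lambda d: d["pos"].astype(int))
        order = info.sort_values(["chrom", "_pos"]).index
        for snp in order:
            row = gt.snp_info.loc[snp]
            calls = [
                gtmap.get(v, "./.") if not pd.isna(v) else "./."
                for v in gt.dosages[snp]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\tA\tG\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Decode GT fields of a VCF into additive dosages (./. -> missing)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    donors = list(vcf.samples)
    cols, rows = {}, []
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    dose_map = np.array([0.0, 1.0, np.nan, 2.0])
    for rec in vcf:
        snp = rec.ID or f"{rec.CHROM}:{rec.POS}"
        cols[snp] = dose_map[rec.gt_types]
        rows.append({"snp": snp, "chrom": rec.CHROM, "pos": rec.POS})
    info = pd.DataFrame(rows).set_index("snp")
    dosages = pd.DataFrame(cols, index=pd.Index(donors, name="donor"))
    info["maf"] = np.minimum(
        dosages.mean() / 2.0, 1 - dosages.mean() / 2.0
    )
    return GenotypeMatrix(dosages, info)


# --- cohort bundle ---------------------------------------------------------

def cytokines_to_long(cyt: CytokineMatrix) -> pd.DataFrame:
    long = (
        cyt.values.stack(["stimulation", "cytokine"], future_stack=True)
        .rename("concentration")
        .reset_index()
        .dropna(subset=["concentration"])
    )
    return long


def write_bundle(
    bundle: CohortBundle,
    outdir: str | Path,
    provenance: dict | None = None,
    genotypes_as_vcf: bool = False,
) -> None:
    """Write every table of a bundle as TSV (one file per table)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(bundle.covariates, outdir / "covariates.tsv", provenance)
    write_table(
        cytokines_to_long(bundle.cytokines),
        outdir / "cytokines.tsv",
        provenance,
        index=False,
    )
    lloq = bundle.cytokines.lloq.rename("lloq").reset_index()
    lloq.columns = ["stimulation", "cytokine", "lloq"]
    write_table(lloq, outdir / "lloq.tsv", provenance, index=False)
    for name, table in (
        ("cells", bundle.cells),
        ("proteins", bundle.proteins),
        ("methylation", bundle.methylation),
        ("cpg_positions", bundle.cpg_positions),
        ("gene_tss", bundle.gene_tss),
    ):
        if table is not None:
            write_table(table, outdir / f"{name}.tsv", provenance)
    if bundle.genotypes is not None:
        if genotypes_as_vcf:
            write_vcf(bundle.genotypes, outdir / "genotypes.vcf")
        else:
            write_table(bundle.genotypes.dosages, outdir / "genotypes.tsv", provenance)
        write_table(bundle.genotypes.snp_info, outdir / "snp_map.tsv", provenance)
    if bundle.truth is not None:
        t = bundle.truth
        payload = {
            "planted_associations": [list(x) for x in t.planted_associations],
            "planted_mediators": [list(x) for x in t.planted_mediators],
            "planted_pqtls": [list(x) for x in t.planted_pqtls],
            "responder_labels": (
                {k: bool(v) for k, v in t.responder_labels.items()}
                if t.responder_labels is not None
                else None
            ),
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1))


def load_bundle(
    indir: str | Path, null_condition: str = "null", max_mismatch: float = 0.05
) -> CohortBundle:
    """Load a bundle directory written by :func:`write_bundle`.

    Donor ids are aligned on the covariate table; a table whose donor
    overlap with it falls below ``1 - max_mismatch`` raises a hard
    error.  Duplicated donor ids raise.  Genotypes are read from
    ``genotypes.vcf`` when present, else from the dosage TSV.
    """
    indir = Path(indir)
    cov = read_table(indir / "covariates.tsv")
    if cov.index.has_duplicates:
        dup = cov.index[cov.index.duplicated()][0]
        raise DataError(f"duplicated donor id {dup!r} in covariates.tsv")

    long = read_table(indir / "cytokines.tsv", index_col=None)
    values = long.pivot_table(
        index="donor",
        columns=["stimulation", "cytokine"],
        values="concentration",
        aggfunc="first",
    )
    lloq_tab = read_table(indir / "lloq.tsv", index_col=None)
    lloq = lloq_tab.set_index(["stimulation", "cytokine"])["lloq"]
    values = values.reindex(columns=lloq.index)

    def _check(name: str, idx: pd.Index) -> None:
        overlap = len(cov.index.intersection(idx)) / max(len(cov.index), 1)
        if overlap < 1 - max_mismatch:
            raise DataError(
                f"{name}: only {overlap:.0%} of covariate donors present"
            )

    _check("cytokines.tsv", values.index)
    cytokines = CytokineMatrix(
        values.reindex(cov.index), lloq, null_condition=null_condition
    )

    def _opt(name: str):
        p = indir / f"{name}.tsv"
        if not p.exists():
            return None
        tab = read_table(p)
        if name in ("cells", "proteins", "methylation"):
            _check(f"{name}.tsv", tab.index)
            tab = tab.reindex(cov.index)
        return tab

    cells = _opt("cells")
    proteins = _opt("proteins")
    methylation = _opt("methylation")
    cpg_positions = _opt("cpg_positions")
    gene_tss = _opt("gene_tss")

    genotypes = None
    if (indir / "genotypes.vcf").exists():
        genotypes = read_vcf(indir / "genotypes.vcf")
    elif (indir / "genotypes.tsv").exists():
        dosages = read_table(indir / "genotypes.tsv")
        snp_info = read_table(indir / "snp_map.tsv")
        genotypes = GenotypeMatrix(dosages, snp_info)
    if genotypes is not None:
        _check("genotypes", genotypes.donors)
        genotypes = GenotypeMatrix(
            genotypes.dosages.reindex(cov.index), genotypes.snp_info,
            genotypes.assembly,
        )

    truth = None
    if (indir / "truth.json").exists():
        payload = json.loads((indir / "truth.json").read_text())
        labels = payload.get("responder_labels")
        truth = TruthLedger(
            planted_associations=[tuple(x) for x in payload["planted_associations"]],
            planted_mediators=[tuple(x) for x in payload["planted_mediators"]],
            planted_pqtls=[tuple(x) for x in payload["planted_pqtls"]],
            responder_labels=(
                pd.Series(labels, name="responder") if labels else None
            ),
        )
    return CohortBundle(
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


def config_hash(obj) -> str:
    """Stable short hash of a configuration object for provenance lines."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
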