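"""Tests of the response-pQTL scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cytovar as cv
from cytovar.containers import GenotypeMatrix
from cytovar.errors import ConfigurationError
from conftest import make_cytokine_matrix


def naive_per_snp_pvalues(G, Y, X):
    """Oracle: full per-SNP OLS fits with the covariates in the design."""
    n = len(Y)
    out_p = np.empty((G.shape[1], Y.shape[1]))
    out_b = np.empty_like(out_p)
    for i in range(G.shape[1]):
        M = np.column_stack([X, G[:, i]])
        beta, _, rank, _ = np.linalg.lstsq(M, Y, rcond=None)
        resid = Y - M @ beta
        rss = (resid**2).sum(axis=0)
        dof = n - rank
        xtx_inv = np.linalg.inv(M.T @ M)
        se = np.sqrt(xtx_inv[-1, -1] * rss / dof)
        t = beta[-1] / se
        out_p[i] = 2 * sps.t.sf(np.abs(t), dof)
        out_b[i] = beta[-1]
    return out_b, out_p


class TestMafFilter:
    @pytest.mark.parametrize(
        "dosages,kept",
        [
            ([0] * 10, False),              # monomorphic
            ([0] * 8 + [1] * 2, True),      # maf 0.10
            ([0] * 9 + [1] * 1, False),     # maf exactly 0.05 -> strict
        ],
    )
    def test_boundaries(self, dosages, kept):
        donors = pd.Index([f"D{i}" for i in range(10)])
        gt = GenotypeMatrix(
            pd.DataFrame({"rs1": np.asarray(dosages, dtype=float)}, index=donors),
            pd.DataFrame({"chrom": ["c"], "pos": [1], "maf": [np.nan]}, index=["rs1"]),
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filtered = cv.maf_filter(gt)
        assert ("rs1" in filtered.snps) is kept


class TestCisTrans:
    @pytest.mark.parametrize(
        "chrom,pos,expected",
        [
            ("chr1", 11_000_000, "cis"),     # exactly 1 Mb
            ("chr1", 11_000_001, "trans"),   # 1 bp past the window
            ("chr2", 10_000_000, "trans"),   # other chromosome
        ],
    )
    def test_window_rule(self, chrom, pos, expected):
        assert cv.classify_cis_trans(chrom, pos, "chr1", 10_000_000) == expected

    def test_unknown_tss_unclassified(self):
        assert cv.classify_cis_trans("chr1", 5, None, None) == "unclassified"


def scan_fixture(n=300, n_snps=50, seed=0, slope=0.0):
    rng = np.random.default_rng(seed)
    specs = [cv.SnpSpec(f"rs{i}", "chr1", 9_000_000 + 1000 * i, 0.3) for i in range(n_snps)]
    if slope:
        specs[0] = cv.SnpSpec("rs0", "chr1", 9_000_000, 0.3,
                              stimulation="E. coli", cytokine="CXCL5", slope=slope)
    cfg = cv.SimulationConfig(
        n_donors=n, stimulations=("null", "E. coli"), responder_stimulation=None,
        cytokines=("CXCL5", "IL-6", "TNF", "IL-2"), snp_specs=tuple(specs),
    )
    return cv.simulate_cohort(cfg, seed=seed)


class TestScan:
    def test_noiseless_linear_phenotype(self):
        bundle, _ = scan_fixture(n=200, n_snps=5, seed=1)
        cyt = bundle.cytokines
        d = bundle.genotypes.dosages["rs2"]
        values = cyt.values.copy()
        values[("E. coli", "CXCL5")] = np.exp(3.0 + 0.5 * d)
        cyt2 = cv.CytokineMatrix(values, cyt.lloq, "null")
        cov = pd.DataFrame(index=bundle.donors)  # no covariates
        res = cv.scan(
            bundle.genotypes, cyt2, cov, "E. coli",
            main_subset_map={"E. coli": None}, gene_tss=bundle.gene_tss,
        )
        hit = res.table[(res.table["snp"] == "rs2") & (res.table["cytokine"] == "CXCL5")]
        assert hit.iloc[0]["slope"] == pytest.approx(0.5, abs=1e-10)
        assert hit.iloc[0]["hit"]

    def test_matrix_scan_matches_per_snp_oracle(self):
        bundle, _ = scan_fixture(n=250, n_snps=40, seed=2)
        res = cv.scan(
            bundle.genotypes, bundle.cytokines, bundle.covariates, "E. coli",
            cells=bundle.cells, gene_tss=bundle.gene_tss,
            cis_detection=1.0, trans_detection=1.0,  # keep every record
        )
        from cytovar.stats import covariate_design

        donors = bundle.donors
        X = covariate_design(bundle.covariates)
        X["monocytes"] = np.log(bundle.cells["monocytes"] + 0.5)
        Y = bundle.cytokines.log_values("E. coli").to_numpy()
        G = bundle.genotypes.dosages.to_numpy(dtype=float)
        b, p = naive_per_snp_pvalues(G, Y, X.to_numpy(dtype=float))
        tab = res.table.set_index(["snp", "cytokine"])
        cyts = bundle.cytokines.cytokines
        for i, snp in enumerate(bundle.genotypes.snps):
            for j, c in enumerate(cyts):
                row = tab.loc[(snp, c)]
                assert row["p_raw"] == pytest.approx(p[i, j], rel=1e-10)
                assert row["slope"] == pytest.approx(b[i, j], rel=1e-10)

    def test_allele_flip_consistency(self):
        bundle, _ = scan_fixture(n=250, n_snps=10, seed=3, slope=0.5)
        kwargs = dict(
            cells=bundle.cells, gene_tss=bundle.gene_tss,
            cis_detection=1.0, trans_detection=1.0,
        )
        a = cv.scan(bundle.genotypes, bundle.cytokines, bundle.covariates,
                    "E. coli", **kwargs).table
        flipped = GenotypeMatrix(
            2.0 - bundle.genotypes.dosages, bundle.genotypes.snp_info
        )
        b = cv.scan(flipped, bundle.cytokines, bundle.covariates,
                    "E. coli", **kwargs).table
        key = ["snp", "cytokine"]
        m = a.set_index(key).join(b.set_index(key), rsuffix="_f")
        np.testing.assert_allclose(m["slope"], -m["slope_f"], rtol=1e-10)
        np.testing.assert_allclose(
            np.abs(m["t_statistic"]), np.abs(m["t_statistic_f"]), rtol=1e-10
        )

    def test_phenotype_shift_and_scale_equivariance(self):
        bundle, _ = scan_fixture(n=200, n_snps=8, seed=4, slope=0.5)
        kwargs = dict(cells=bundle.cells, gene_tss=bundle.gene_tss,
                      cis_detection=1.0, trans_detection=1.0)
        base = cv.scan(bundle.genotypes, bundle.cytokines, bundle.covariates,
                       "E. coli", **kwargs).table
        cyt = bundle.cytokines
        scaled = cv.CytokineMatrix(
            (cyt.values**2.0) * np.exp(1.0), cyt.lloq * 0 + 1e-12, "null"
        )  # log scale: 2*y + 1
        out = cv.scan(bundle.genotypes, scaled, bundle.covariates,
                      "E. coli", **kwargs).table
        key = ["snp", "cytokine"]
        m = base.set_index(key).join(out.set_index(key), rsuffix="_s")
        np.testing.assert_allclose(m["slope_s"], 2 * m["slope"], rtol=1e-8)
        np.testing.assert_allclose(m["p_raw_s"], m["p_raw"], rtol=1e-8)

    def test_agonist_cytokine_excluded(self):
        bundle, _ = scan_fixture(n=200, n_snps=5, seed=5)
        cfg = cv.SimulationConfig(
            n_donors=200, stimulations=("null", "TNF"), responder_stimulation=None,
            cytokines=("CXCL5", "TNF"),
            snp_specs=tuple(cv.SnpSpec(f"rs{i}", "chr1", 1000 * i + 1000, 0.3)
                            for i in range(5)),
        )
        b, _ = cv.simulate_cohort(cfg, seed=5)
        res = cv.scan(b.genotypes, b.cytokines, b.covariates, "TNF",
                      cells=b.cells, gene_tss=b.gene_tss,
                      cis_detection=1.0, trans_detection=1.0)
        assert res.n_cytokines == 1  # TNF itself dropped
        assert "TNF" not in set(res.table["cytokine"])

    def test_missing_main_subset_mapping_raises(self):
        bundle, _ = scan_fixture(n=100, n_snps=3, seed=6)
        with pytest.raises(ConfigurationError, match="mapping"):
            cv.scan(bundle.genotypes, bundle.cytokines, bundle.covariates,
                    "E. coli", cells=bundle.cells, main_subset_map={})


class TestConditional:
    def test_identical_snp_untestable(self):
        bundle, _ = scan_fixture(n=150, n_snps=4, seed=7)
        gt = bundle.genotypes
        dup = gt.dosages.copy()
        dup["rs_dup"] = dup["rs1"]
        info = pd.concat(
            [gt.snp_info,
             pd.DataFrame({"chrom": ["chr1"], "pos": [99], "maf": [0.3]},
                          index=["rs_dup"])]
        )
        gt2 = GenotypeMatrix(dup, info)
        with pytest.warns(UserWarning, match="untestable"):
            res = cv.conditional_scan(
                gt2, bundle.cytokines, bundle.covariates, "E. coli", "rs1",
                cells=bundle.cells, gene_tss=bundle.gene_tss,
            )
        assert "rs_dup" not in set(res.table.get("snp", []))

    def test_independent_conditioning_leaves_p_stable(self):
        bundle, _ = scan_fixture(n=500, n_snps=10, seed=8, slope=0.6)
        kwargs = dict(cells=bundle.cells, gene_tss=bundle.gene_tss,
                      cis_detection=1.0, trans_detection=1.0)
        base = cv.scan(bundle.genotypes, bundle.cytokines, bundle.covariates,
                       "E. coli", **kwargs).table.set_index(["snp", "cytokine"])
        cond = cv.conditional_scan(
            bundle.genotypes, bundle.cytokines, bundle.covariates,
            "E. coli", "rs5", **kwargs,
        ).table.set_index(["snp", "cytokine"])
        p0 = base.loc[("rs0", "CXCL5"), "p_raw"]
        p1 = cond.loc[("rs0", "CXCL5"), "p_raw"]
        assert abs(np.log10(p0) - np.log10(p1)) < 0.5


class TestGxe:
    def _interaction_bundle(self, gamma, seed):
        specs = (cv.SnpSpec("rsA", "chr1", 9_000_000, 0.3),)
        cfg = cv.SimulationConfig(
            n_donors=600, stimulations=("null", "BCG"), responder_stimulation=None,
            cytokines=("IL-8", "IL-6"), snp_specs=specs,
        )
        bundle, _ = cv.simulate_cohort(cfg, seed=seed)
        cyt = bundle.cytokines
        d = bundle.genotypes.dosages["rsA"]
        cur = (bundle.covariates["smoking_status"] == "current").astype(float)
        extra = 0.3 * d + gamma * d * cur
        values = cyt.values.copy()
        values[("BCG", "IL-8")] = values[("BCG", "IL-8")] * np.exp(extra)
        cyt2 = cv.CytokineMatrix(values, cyt.lloq, "null")
        return bundle, cyt2

    def test_planted_interaction_recovered(self):
        gamma = np.log(1.6)
        bundle, cyt2 = self._interaction_bundle(gamma, seed=9)
        hits = pd.DataFrame(
            [{"snp": "rsA", "stimulation": "BCG", "cytokine": "IL-8"}]
        )
        res = cv.gxe_interaction(hits, bundle.genotypes, cyt2,
                                 bundle.covariates, cells=bundle.cells)
        assert res.table.iloc[0]["p_adjusted"] < 0.05
        row = res.coefficients.set_index("term").loc["dosage:smoking_status[current]"]
        assert row["ci_low"] < np.exp(gamma) < row["ci_high"]

    def test_noiseless_null_interaction_is_zero(self):
        bundle, _ = self._interaction_bundle(0.0, seed=10)
        cyt = bundle.cytokines
        d = bundle.genotypes.dosages["rsA"]
        values = cyt.values.copy()
        values[("BCG", "IL-8")] = np.exp(2.0 + 0.4 * d)  # same effect all strata
        cyt2 = cv.CytokineMatrix(values, cyt.lloq, "null")
        hits = pd.DataFrame(
            [{"snp": "rsA", "stimulation": "BCG", "cytokine": "IL-8"}]
        )
        res = cv.gxe_interaction(hits, bundle.genotypes, cyt2,
                                 bundle.covariates, cells=bundle.cells)
        ests = res.coefficients.set_index("term")["estimate"]
        assert abs(ests["dosage:smoking_status[current]"]) < 1e-8
        assert abs(ests["dosage:smoking_status[past]"]) < 1e-8
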