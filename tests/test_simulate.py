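"""Tests of the synthetic-cohort generator."""

import numpy as np
import pandas as pd
import pytest

import cytovar as cv
from cytovar.errors import ConfigurationError, DataError


def small_config(**kw):
    base = dict(
        n_donors=200,
        stimulations=("null", "E. coli"),
        responder_stimulation=None,
    )
    base.update(kw)
    return cv.SimulationConfig(**base)


class TestDeterminismAndValidation:
    def test_same_seed_bit_identical(self):
        cfg = small_config(snp_specs=(cv.SnpSpec("rs1", "chr1", 100, 0.3),),
                          cpg_specs=(cv.CpgSpec("cg1", "chr2", 500),))
        b1, _ = cv.simulate_cohort(cfg, seed=7)
        b2, _ = cv.simulate_cohort(cfg, seed=7)
        pd.testing.assert_frame_equal(b1.covariates, b2.covariates)
        pd.testing.assert_frame_equal(b1.cytokines.values, b2.cytokines.values)
        pd.testing.assert_frame_equal(b1.genotypes.dosages, b2.genotypes.dosages)
        pd.testing.assert_frame_equal(b1.methylation, b2.methylation)
        b3, _ = cv.simulate_cohort(cfg, seed=8)
        assert not b1.cytokines.values.equals(b3.cytokines.values)

    @pytest.mark.parametrize(
        "field,value,match",
        [
            ("smoking_prevalence", (0.5, 0.5, 0.5), "smoking_prevalence"),
            ("cmv_seroprevalence", 1.5, "cmv_seroprevalence"),
            ("noise_sd", 0.0, "noise_sd"),
            ("null_condition", "missing", "null_condition"),
            ("age_range", (69, 20), "age_range"),
        ],
    )
    def test_invalid_config_names_field(self, field, value, match):
        with pytest.raises(ConfigurationError, match=match):
            cv.simulate_cohort(small_config(**{field: value}), seed=0)

    def test_value_ranges(self):
        cfg = small_config(cpg_specs=(cv.CpgSpec("cg1", "chr2", 500),),
                           snp_specs=(cv.SnpSpec("rs1", "chr1", 100, 0.4),))
        b, _ = cv.simulate_cohort(cfg, seed=3)
        assert (b.cytokines.values.to_numpy() > 0).all()
        beta = b.methylation.to_numpy()
        assert ((beta > 0) & (beta < 1)).all()
        assert set(np.unique(b.genotypes.dosages.to_numpy())) <= {0.0, 1.0, 2.0}
        age = b.covariates["age"]
        assert age.between(*cfg.age_range, inclusive="both").all() or (
            age.between(cfg.age_range[0], cfg.age_range[1] + 1).all()
        )

    def test_smoking_category_counts_within_binomial_tolerance(self):
        cfg = small_config(n_donors=2000, smoking_prevalence=(0.5, 0.25, 0.25))
        b, _ = cv.simulate_cohort(cfg, seed=11)
        counts = b.covariates["smoking_status"].value_counts()
        for level, p in zip(("never", "past", "current"), cfg.smoking_prevalence):
            se = np.sqrt(2000 * p * (1 - p))
            assert abs(counts[level] - 2000 * p) < 3 * se

    def test_empty_effect_ledger_gives_empty_truth(self):
        b, truth = cv.simulate_cohort(small_config(), seed=0)
        assert truth.planted_associations == []
        assert truth.planted_mediators == []
        assert truth.planted_pqtls == []


class TestGenotypes:
    def test_hwe_frequencies(self):
        specs = [cv.SnpSpec("rs1", "chr1", 100, 0.3)]
        gt = cv.simulate_genotypes(20_000, specs, seed=5)
        d = gt.dosages["rs1"]
        obs = d.value_counts(normalize=True)
        for dose, expected in ((0.0, 0.49), (1.0, 0.42), (2.0, 0.09)):
            se = np.sqrt(expected * (1 - expected) / 20_000)
            assert abs(obs[dose] - expected) < 4 * se

    def test_allele_frequency_recovered(self):
        gt = cv.simulate_genotypes(10_000, [cv.SnpSpec("rs1", "c", 1, 0.2)], seed=1)
        freq = gt.dosages["rs1"].mean() / 2
        se = np.sqrt(0.2 * 0.8 / (2 * 10_000))
        assert abs(freq - 0.2) < 3 * se

    def test_symmetric_maf_mean_one(self):
        gt = cv.simulate_genotypes(50_000, [cv.SnpSpec("rs1", "c", 1, 0.5)], seed=2)
        assert gt.dosages["rs1"].mean() == pytest.approx(1.0, abs=0.02)

    def test_bad_maf_raises(self):
        with pytest.raises(ConfigurationError, match="maf"):
            cv.simulate_genotypes(10, [cv.SnpSpec("rs1", "c", 1, 0.7)], seed=0)

    def test_ld_pair_dosage_correlation(self):
        specs = [
            cv.SnpSpec("A", "c", 1, 0.3),
            cv.SnpSpec("B", "c", 2, 0.3, ld_with="A", ld_r=0.8),
        ]
        gt = cv.simulate_genotypes(20_000, specs, seed=3)
        r = np.corrcoef(gt.dosages["A"], gt.dosages["B"])[0, 1]
        assert r**2 == pytest.approx(0.64, abs=0.03)


class TestMethylation:
    def _cov(self, status, pack_years, ysq):
        return pd.DataFrame(
            {
                "smoking_status": status,
                "pack_years": pack_years,
                "years_since_quit": ysq,
            }
        )

    def test_never_smoker_zero_noise_hits_baseline(self):
        cov = self._cov(["never"], [0.0], [np.nan])
        beta, _ = cv.simulate_methylation(
            cov, [cv.CpgSpec("cg1", "c", 1, baseline_beta=0.8, sd=0.0)], seed=0
        )
        assert beta.iloc[0, 0] == pytest.approx(0.8, abs=1e-12)

    def test_monotone_in_pack_years(self):
        cov = self._cov(["current", "current"], [10.0, 30.0], [np.nan, np.nan])
        beta, _ = cv.simulate_methylation(
            cov, [cv.CpgSpec("cg1", "c", 1, sd=0.0)], seed=0
        )
        assert beta.iloc[1, 0] < beta.iloc[0, 0]

    def test_reversion_sign_in_past_smokers(self):
        rng = np.random.default_rng(4)
        n = 5000
        cov = self._cov(
            ["past"] * n, rng.uniform(5, 40, n), rng.uniform(0.5, 30, n)
        )
        spec = cv.CpgSpec("cg1", "c", 1, packyear_coef=0.03, reversion_coef=0.05, sd=0.2)
        beta, _ = cv.simulate_methylation(cov, [spec], seed=1)
        r = np.corrcoef(beta["cg1"], cov["years_since_quit"])[0, 1]
        assert r > 0.2  # sign of the reversion coefficient

    def test_missing_smoking_fields_raise(self):
        with pytest.raises(DataError, match="pack_years"):
            cv.simulate_methylation(
                pd.DataFrame({"smoking_status": ["never"]}),
                [cv.CpgSpec("cg1", "c", 1)],
                seed=0,
            )


class TestStructure:
    def test_cmv_memory_cells_elevated(self, demo_bundle):
        _, bundle, _ = demo_bundle
        cmv = bundle.covariates["cmv_seropositive"].astype(bool)
        mem = np.log(bundle.cells["CD8_EM"])
        assert mem[cmv].mean() > mem[~cmv].mean() + 0.2

    def test_responder_split_fraction(self, demo_bundle):
        cfg, bundle, truth = demo_bundle
        frac = 1 - truth.responder_labels.mean()
        se = np.sqrt(0.295 * 0.705 / cfg.n_donors)
        assert abs(frac - 0.295) < 3 * se

    def test_truth_ledger_references_existing_names(self, demo_bundle):
        _, bundle, truth = demo_bundle
        for var, stim, cyt, _ in truth.planted_associations:
            assert var in bundle.covariates.columns
            assert (stim, cyt) in bundle.cytokines.values.columns
        for snp, stim, cyt, _, label in truth.planted_pqtls:
            assert snp in bundle.genotypes.snps
            assert label in ("cis", "trans")
        for _, mediator, _, _ in truth.planted_mediators:
            assert mediator in bundle.cells.columns

    def test_age_stratified_by_decade(self):
        b, _ = cv.simulate_cohort(small_config(n_donors=1000), seed=5)
        decades = (b.covariates["age"] // 10).value_counts()
        assert decades.min() >= 190 and decades.max() <= 210
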