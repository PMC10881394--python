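"""Tests of the donor-variable association screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cytovar as cv
from cytovar.errors import InsufficientDataError
from cytovar.screen import fit_lrt


def covariates(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.uniform(20, 70, n),
            "sex": rng.choice(["F", "M"], n),
            "batch": rng.choice(["B1", "B2"], n),
        }
    )


class TestEligibility:
    @pytest.mark.parametrize(
        "shares,expected",
        [
            ((0.90, 0.06, 0.04), True),   # 2 of 3 levels >= 5% >= ceil(3/2)
            ((0.97, 0.03), True),          # 1 >= ceil(2/2) = 1
            ((0.94, 0.02, 0.02, 0.02), False),  # 1 < ceil(4/2) = 2
        ],
    )
    def test_level_share_rule(self, shares, expected):
        n = 1000
        counts = [int(round(s * n)) for s in shares]
        counts[0] += n - sum(counts)
        values = np.repeat([f"L{i}" for i in range(len(shares))], counts)
        cov = pd.DataFrame({"v": values})
        assert (["v"] == cv.eligible_variables(cov, exclude=())) is expected

    def test_numeric_always_eligible(self):
        cov = pd.DataFrame({"x": np.r_[np.zeros(99), 1.0]})
        assert cv.eligible_variables(cov, exclude=()) == ["x"]


class TestFitLrt:
    def test_textbook_example(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0])
        var = pd.Series([0.0, 0.0, 1.0, 1.0], name="x")
        fit = fit_lrt(y, var, pd.DataFrame(index=y.index))
        assert fit.statistic == pytest.approx(4 * np.log(5.0), abs=1e-10)
        assert fit.df == 1
        assert fit.p_value == pytest.approx(0.01117, abs=1e-4)

    def test_constant_variable_raises(self):
        y = pd.Series(np.random.default_rng(0).normal(size=30))
        var = pd.Series(["a"] * 30, name="v")
        with pytest.raises(InsufficientDataError):
            fit_lrt(y, var, covariates(30))

    def test_age_interaction_adds_df(self):
        rng = np.random.default_rng(1)
        n = 100
        cov = covariates(n)
        y = pd.Series(rng.normal(size=n))
        var = pd.Series(rng.choice(["a", "b", "c"], n), name="v")
        plain = fit_lrt(y, var, cov)
        inter = fit_lrt(y, var, cov, age_interaction=True)
        assert plain.df == 2 and inter.df == 4

    def test_lrt_and_t_test_agree_asymptotically(self):
        rng = np.random.default_rng(2)
        n = 10_000
        cov = covariates(n)
        var = pd.Series(rng.normal(size=n), name="x")
        y = pd.Series(0.03 * var + rng.normal(size=n))
        fit = fit_lrt(y, var, cov)
        t_p = fit.coefficients.loc["x", "t_p"]
        assert np.log10(fit.p_value) == pytest.approx(np.log10(t_p), abs=0.05)


class TestEffectSizes:
    def test_noiseless_multiplicative_recovery(self):
        n = 60
        cov = covariates(n, seed=3)
        smoking = pd.Series(
            np.random.default_rng(3).choice(["never", "current"], n),
            name="smoking_status",
        )
        y = pd.Series(np.where(smoking == "current", np.log(1.5), 0.0))
        out = cv.effect_sizes(y, smoking, pd.DataFrame(index=cov.index))
        row = out.set_index("level").loc["smoking_status[current]"]
        assert row["exp_estimate"] == pytest.approx(1.5, abs=1e-10)
        assert row["ci_high"] - row["ci_low"] == pytest.approx(0.0, abs=1e-8)

    def test_reference_swap_negates_log_estimate(self):
        rng = np.random.default_rng(4)
        n = 80
        cov = covariates(n, seed=4)
        smoking = pd.Series(rng.choice(["never", "current"], n), name="smoking_status")
        y = pd.Series(rng.normal(size=n) + 0.4 * (smoking == "current"))
        a = cv.effect_sizes(y, smoking, cov, reference="never")
        b = cv.effect_sizes(y, smoking, cov, reference="current")
        est_a = a.set_index("level").loc["smoking_status[current]", "estimate"]
        est_b = b.set_index("level").loc["smoking_status[never]", "estimate"]
        assert est_b == pytest.approx(-est_a, abs=1e-10)

    def test_ci_coverage_at_nominal_level(self):
        """t-based CI covers a true multiplicative effect ~95% of the time."""
        rng = np.random.default_rng(5)
        n, reps, covered = 200, 400, 0
        for _ in range(reps):
            x = pd.Series(rng.integers(0, 2, n).astype(float), name="x")
            y = pd.Series(np.log(1.3) * x + rng.normal(size=n))
            out = cv.effect_sizes(y, x, pd.DataFrame(index=x.index)).set_index("level")
            covered += out.loc["x", "ci_low"] <= 1.3 <= out.loc["x", "ci_high"]
        assert covered / reps == pytest.approx(0.95, abs=0.035)


class TestScreen:
    def test_family_and_planted_recovery(self, demo_bundle):
        cfg, bundle, truth = demo_bundle
        res = cv.screen(bundle.cytokines, bundle.covariates, "SEB")
        n_vars = len(cv.eligible_variables(bundle.covariates))
        n_induced = cv.flag_induced(bundle.cytokines).loc["SEB"].sum()
        assert res.family_size == n_vars * n_induced
        planted = res.table.set_index(["variable", "cytokine"]).loc[
            ("smoking_status", "IL-2")
        ]
        assert planted["significant"]

    def test_by_adjustment_over_family(self, demo_bundle):
        _, bundle, _ = demo_bundle
        res = cv.screen(bundle.cytokines, bundle.covariates, "E. coli")
        m = len(res.table)
        c = np.sum(1.0 / np.arange(1, m + 1))
        # smallest raw p's step-up value bounds its adjusted p from below
        top = res.table.nsmallest(1, "p_raw").iloc[0]
        assert top["p_adjusted"] >= top["p_raw"] * m * c / m
        assert (res.table["p_adjusted"] >= res.table["p_raw"] - 1e-12).all()

    def test_responder_restriction_shrinks_n(self, demo_bundle):
        _, bundle, truth = demo_bundle
        full = cv.screen(bundle.cytokines, bundle.covariates, "anti-CD3+CD28")
        resp = cv.screen(
            bundle.cytokines, bundle.covariates, "anti-CD3+CD28",
            responder_labels=truth.responder_labels,
        )
        assert resp.table["n_used"].max() == int(truth.responder_labels.sum())
        assert full.table["n_used"].max() == len(bundle.donors)

    def test_no_induced_cytokines_yields_empty(self):
        rng = np.random.default_rng(6)
        from conftest import make_cytokine_matrix

        vals = rng.uniform(9, 11, 40)
        cyt = make_cytokine_matrix({"c": vals}, {"c": vals * 1.01})
        cov = covariates(40).set_index(cyt.donors)
        with pytest.warns(UserWarning, match="no induced"):
            res = cv.screen(cyt, cov, "stim")
        assert res.family_size == 0


class TestPairwiseGroupTests:
    def test_exact_enumeration_example(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        g = pd.Series(["a"] * 3 + ["b"] * 3)
        out = cv.pairwise_group_tests(y, g)
        assert out.loc[0, "p_raw"] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        y = pd.Series(np.r_[np.arange(30.0), np.arange(30.0) + 0.5])
        g = pd.Series(["a"] * 30 + ["b"] * 30)
        out = cv.pairwise_group_tests(y, g)
        assert out.loc[0, "p_raw"] > 0.5

    def test_holm_adjustment_across_pairs(self):
        rng = np.random.default_rng(7)
        y = pd.Series(
            np.r_[rng.normal(0, 1, 30), rng.normal(1.5, 1, 30), rng.normal(0.2, 1, 30)]
        )
        g = pd.Series(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        out = cv.pairwise_group_tests(y, g)
        assert len(out) == 3
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()

    def test_empty_group_excluded(self):
        y = pd.Series([1.0, 2.0, np.nan, 4.0])
        g = pd.Series(["a", "a", "b", "c"])
        with pytest.warns(UserWarning, match="empty"):
            out = cv.pairwise_group_tests(y, g)
        assert set(out["group_a"]) | set(out["group_b"]) == {"a", "c"}
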