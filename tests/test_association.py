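import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omictwas.association import (
    inflation_factor,
    moa_scan,
    moment_test,
    significance_report,
)
from omictwas.expression import ExpressionMatrix
from omictwas.relationship import RelationshipMatrix, build_orm
from omictwas.varcomp import CovariateDesign, VarianceComponents, fit_reml

from conftest import make_counts


def wrap_std(z):
    z = np.asarray(z, float)
    cm = make_counts(np.ones_like(z, dtype=int))
    return ExpressionMatrix(
        values=z, feature_meta=cm.feature_meta,
        individual_ids=cm.individual_ids, scale_tag="standardized",
    )


def standardize_rows(raw):
    return (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1, keepdims=True)


class TestMoaScan:
    def test_reduces_to_ols_when_variance_all_residual(self):
        """With A = I and the random component fixed at zero, the scan is
        per-feature ordinary least squares."""
        rng = np.random.default_rng(0)
        n, m = 60, 15
        z = standardize_rows(rng.normal(size=(m, n)))
        y = rng.normal(size=n)
        X = CovariateDesign(np.ones((n, 1)), ["intercept"])
        iden = RelationshipMatrix(np.eye(n), m, [f"s{j:03d}" for j in range(n)])
        null = VarianceComponents(0.0, 1.0, 0.0, 0, 0, 0, 0.0, 0, True)
        res = moa_scan(y, X, wrap_std(z), iden, null_fit=null).set_index("feature_id")
        for i in range(m):
            ols = np.linalg.lstsq(
                np.column_stack([z[i], np.ones(n)]), y, rcond=None
            )[0][0]
            assert res.loc[f"g{i:03d}", "beta"] == pytest.approx(ols, abs=1e-8)

    def test_orthogonal_feature_has_null_effect(self):
        n = 50
        rng = np.random.default_rng(5)
        y = rng.normal(size=n)
        y -= y.mean()
        w = rng.normal(size=n)
        w -= w.mean()
        w -= (w @ y) / (y @ y) * y  # orthogonal to y and the intercept
        z = standardize_rows(np.vstack([w, rng.normal(size=(9, n))]))
        X = CovariateDesign(np.ones((n, 1)), ["intercept"])
        iden = RelationshipMatrix(np.eye(n), 10, [f"s{j:03d}" for j in range(n)])
        null = VarianceComponents(0.0, float(np.var(y)), 0.0, 0, 0, 0, 0.0, 0, True)
        res = moa_scan(y, X, wrap_std(z), iden, null_fit=null).set_index("feature_id")
        row = res.loc["g000"]
        assert abs(row["beta"]) < 3 * row["se_beta"]
        assert abs(row["beta"]) < 1e-10  # exactly orthogonal by construction

    def test_aborts_on_nonconverged_null(self, null_sim):
        bad = VarianceComponents(np.nan, np.nan, np.nan, 0, 0, 0, 0.0, 0, False,
                                 message="synthetic failure")
        with pytest.raises(RuntimeError, match="did not converge"):
            moa_scan(null_sim["y"], null_sim["X"], null_sim["std"],
                     null_sim["orm"], null_fit=bad)

    def test_pvalue_invariant_to_rescaling(self, null_sim):
        # invariance holds up to the REML optimizer's tolerance on the
        # refitted variance ratio
        res1 = moa_scan(null_sim["y"], null_sim["X"], null_sim["std"], null_sim["orm"])
        res2 = moa_scan(10.0 * null_sim["y"], null_sim["X"], null_sim["std"],
                        null_sim["orm"])
        np.testing.assert_allclose(res1["chi2"], res2["chi2"], rtol=1e-3, atol=1e-8)

    def test_type_i_error_under_polygenic_background(self, null_sim):
        """No causal fixed effects: the single-ORM scan keeps the target
        inside the random component, so its tests stay calibrated even
        with an infinitesimal background; p < 0.05 at a rate of 0.05 +/- 0.02."""
        res = moa_scan(null_sim["y"], null_sim["X"], null_sim["std"], null_sim["orm"])
        frac = float((res["p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_power_injected_effect_ranks_first(self):
        """A feature explaining ~20% of trait variance should give the
        smallest p-value among all features in nearly every replicate."""
        rng = np.random.default_rng(77)
        n, m = 500, 100
        wins = 0
        reps = 20
        for _ in range(reps):
            z = standardize_rows(rng.normal(size=(m, n)))
            beta = np.sqrt(0.20 / 0.80)
            y = beta * z[0] + rng.normal(size=n)
            X = CovariateDesign(np.ones((n, 1)), ["intercept"])
            orm = build_orm(wrap_std(z))
            res = moa_scan(y, X, wrap_std(z), orm)
            if res.sort_values("p_value").iloc[0]["feature_id"] == "g000":
                wins += 1
        assert wins >= reps - 1


class TestMoment:
    def test_downdated_orm_equals_direct_leave_one_out(self):
        """(m A - z z') / (m - 1) reconstructs build_orm on the matrix with
        the target row deleted, for random targets on a 50x20 system."""
        rng = np.random.default_rng(42)
        m, n = 50, 20
        z = standardize_rows(rng.normal(size=(m, n)))
        A = build_orm(wrap_std(z)).A
        for i in rng.choice(m, size=10, replace=False):
            direct = build_orm(wrap_std(np.delete(z, i, axis=0))).A
            downdated = (m * A - np.outer(z[i], z[i])) / (m - 1)
            np.testing.assert_allclose(downdated, direct, atol=1e-10)

    def test_single_bin_no_downdate_reduces_to_moa(self, null_sim):
        null = fit_reml(null_sim["y"], null_sim["X"], null_sim["orm"])
        prelim = moa_scan(null_sim["y"], null_sim["X"], null_sim["std"],
                          null_sim["orm"], null_fit=null)
        res = moment_test(null_sim["y"], null_sim["X"], null_sim["std"],
                          prelim, bins=2, downdate=False, null_fit=null)
        merged = prelim.merge(res, on="feature_id", suffixes=("_moa", "_mom"))
        assert (merged["component_bin_mom"] == 0).all()  # empty top bin collapsed
        np.testing.assert_allclose(
            merged["chi2_moa"], merged["chi2_mom"], atol=1e-8
        )

    def test_single_feature_falls_back_to_fixed_effects(self):
        rng = np.random.default_rng(2)
        n = 30
        z = standardize_rows(rng.normal(size=(1, n)))
        y = rng.normal(size=n)
        X = CovariateDesign(np.ones((n, 1)), ["intercept"])
        prelim = pd.DataFrame({"feature_id": ["g000"], "p_value": [0.5]})
        with pytest.warns(RuntimeWarning, match="single feature"):
            res = moment_test(y, X, wrap_std(z), prelim)
        assert len(res) == 1 and np.isfinite(res["p_value"].iloc[0])

    def test_null_calibration_and_inflation(self, pure_noise_sim):
        """Strict null (expression unrelated to trait, n=500, m=1,000):
        leave-target-out type-I error at alpha=0.05 within 0.05 +/- 0.02
        and lambda in [0.9, 1.1]."""
        sim = pure_noise_sim
        prelim = moa_scan(sim["y"], sim["X"], sim["std"], sim["orm"])
        res = moment_test(sim["y"], sim["X"], sim["std"], prelim)
        frac = float((res["p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07
        infl = inflation_factor(res["chi2"].to_numpy(), seed=1)
        assert 0.9 <= infl.lam <= 1.1
        assert infl.ci_low <= infl.lam <= infl.ci_high

    def test_polygenic_share_detected_when_target_left_out(self, null_sim):
        """Under an infinitesimal polygenic background the leave-target-out
        statistic legitimately absorbs the target's own share of the
        genome-wide signal, so its mean chi-square exceeds the strict-null
        value of 1 by about n*sigma_o2/(m*sigma_e2)."""
        prelim = moa_scan(null_sim["y"], null_sim["X"], null_sim["std"],
                          null_sim["orm"])
        res = moment_test(null_sim["y"], null_sim["X"], null_sim["std"], prelim)
        infl = inflation_factor(res["chi2"].to_numpy(), seed=3)
        assert infl.lam > 1.02  # visibly above the strict null
        assert infl.lam < 1.5


class TestInflation:
    def test_definitional_lambda_of_uniform_grid(self):
        u = (np.arange(1, 10001) - 0.5) / 10000
        chi2 = stats.chi2.isf(u, df=1)
        infl = inflation_factor(chi2, n_boot=50, seed=0)
        assert infl.lam == pytest.approx(1.0, abs=1e-3)
        scaled = inflation_factor(2 * chi2, n_boot=50, seed=0)
        assert scaled.lam == pytest.approx(2 * infl.lam, rel=1e-12)

    def test_null_draws_cover_one(self):
        rng = np.random.default_rng(123)
        chi2 = rng.chisquare(1, size=10000)
        infl = inflation_factor(chi2, seed=7)
        assert infl.lam == pytest.approx(1.0, abs=0.05)
        assert infl.ci_low <= 1.0 <= infl.ci_high

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 10"):
            inflation_factor(np.ones(5))
        with pytest.raises(ValueError, match="non-negative"):
            inflation_factor(np.linspace(-1, 5, 20))


class TestSignificanceReport:
    @staticmethod
    def results(m, p=None, coding=None):
        rng = np.random.default_rng(0)
        pv = p if p is not None else rng.uniform(0.01, 1.0, m)
        return pd.DataFrame(
            {
                "feature_id": [f"g{i:05d}" for i in range(m)],
                "chromosome": 1, "start": np.arange(m), "end": np.arange(m) + 10,
                "beta": 0.0, "se_beta": 1.0,
                "chi2": stats.chi2.isf(pv, 1), "p_value": pv,
                "component_bin": 0,
                "biotype": coding if coding is not None else "protein_coding",
            }
        )

    def test_bonferroni_threshold_arithmetic(self):
        rep = significance_report(self.results(10290))
        assert rep.threshold == pytest.approx(4.8591e-6, rel=1e-4)
        assert rep.threshold == 0.05 / 10290

    def test_significant_hit_suppresses_suggestive_list(self):
        p = np.linspace(0.1, 1.0, 1000)
        p[17] = 1e-9
        rep = significance_report(self.results(1000, p=p))
        assert rep.n_significant == 1
        assert rep.significant_ids == ["g00017"]
        assert rep.suggestive.empty

    def test_top20_fallback_excludes_noncoding_but_counts_them(self):
        m = 60
        coding = np.where(np.arange(m) < 25, "protein_coding", "lncRNA")
        rep = significance_report(self.results(m, coding=coding))
        assert rep.threshold == 0.05 / m  # non-coding still count as tests
        assert rep.n_significant == 0
        assert len(rep.suggestive) == 20
        assert (rep.suggestive["biotype"] == "protein_coding").all()
        assert rep.suggestive["p_value"].is_monotonic_increasing

    def test_suggestive_deterministic_under_ties(self):
        p = np.full(30, 0.5)
        rep1 = significance_report(self.results(30, p=p), top_k=5)
        rep2 = significance_report(self.results(30, p=p), top_k=5)
        assert list(rep1.suggestive["feature_id"]) == list(rep2.suggestive["feature_id"])
        assert list(rep1.suggestive["feature_id"]) == sorted(
            rep1.suggestive["feature_id"]
        )
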