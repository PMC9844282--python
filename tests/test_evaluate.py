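import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prsport.evaluate import (
    EvaluateError,
    dichotomize,
    group_prs_compare,
    linear_incremental_r2,
    logistic_pseudo_r2,
    prepare_phenotypes,
    tail_contrast,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def ols_oracle(y, X):
    """Normal-equations OLS: beta, R²."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return beta, 1.0 - (resid @ resid) / tss


def irls_deviance(y, X, tol=1e-12, max_iter=200):
    """Hand-written IRLS for logistic regression; returns -2 loglik."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.clip(w, 1e-12, None)
        z = eta + (y - mu) / w
        wx = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return -2.0 * ll, beta


# ---------------------------------------------------------------------------
# prepare_phenotypes
# ---------------------------------------------------------------------------

class TestPreparePhenotypes:
    def _raw(self):
        return pd.DataFrame(
            {
                "sample": ["a", "b", "c", "d", "d"],
                "age": [30, 40, 50, 60, 61],
                "sex": [0, 1, 0, 1, 1],
                "sleep_duration": [3.0, 16.0, 3.5, 7.0, 8.0],
                "insomnia": [1, 2, 3, 1, 3],
            }
        )

    def test_sleep_cut_values_excluded(self):
        out, counts = prepare_phenotypes(self._raw(), seed=1)
        by_id = out.set_index("sample")
        assert np.isnan(by_id.loc["a", "sleep_duration"])  # 3.0 excluded
        assert np.isnan(by_id.loc["b", "sleep_duration"])  # 16.0 excluded
        assert by_id.loc["c", "sleep_duration"] == 3.5
        assert counts["sleep_excluded"] == 2

    def test_multi_wave_single_survivor_reproducible(self):
        out1, c1 = prepare_phenotypes(self._raw(), seed=42)
        out2, _ = prepare_phenotypes(self._raw(), seed=42)
        assert (out1["sample"] == sorted(set(self._raw()["sample"]))).all()
        d1 = out1.set_index("sample").loc["d"]
        d2 = out2.set_index("sample").loc["d"]
        assert d1["sleep_duration"] == d2["sleep_duration"]
        assert d1["sleep_duration"] in (7.0, 8.0)
        assert c1["multi_answer"] >= 1

    def test_different_seed_can_differ(self):
        picks = {
            prepare_phenotypes(self._raw(), seed=s)[0].set_index("sample").loc["d", "insomnia"]
            for s in range(20)
        }
        assert picks == {1.0, 3.0}

    def test_single_answer_unchanged(self):
        out, _ = prepare_phenotypes(self._raw(), seed=0)
        assert out.set_index("sample").loc["c", "insomnia"] == 3

    def test_non_numeric_counted(self):
        raw = self._raw()
        raw["insomnia"] = raw["insomnia"].astype(object)
        raw.loc[0, "insomnia"] = "often"
        out, counts = prepare_phenotypes(raw, seed=0)
        assert counts["non_numeric"] == 1
        assert np.isnan(out.set_index("sample").loc["a", "insomnia"])


# ---------------------------------------------------------------------------
# dichotomize
# ---------------------------------------------------------------------------

class TestDichotomize:
    def test_chronotype(self):
        labels, counts = dichotomize([1, 2, 3, 4], "chronotype_extremes")
        np.testing.assert_array_equal(labels, [1.0, np.nan, np.nan, 0.0])
        assert counts == {"case": 1, "control": 1, "excluded": 2, "missing": 0}

    def test_sleep(self):
        labels, _ = dichotomize([6.0, 9.0, 7.5, 3.5], "sleep_extremes")
        np.testing.assert_array_equal(labels, [1.0, 0.0, np.nan, 1.0])

    def test_insomnia_finrisk(self):
        labels, _ = dichotomize([1, 2, 3], "insomnia_finrisk")
        np.testing.assert_array_equal(labels, [1.0, np.nan, 0.0])

    def test_insomnia_health(self):
        labels, _ = dichotomize([1, 2, 3, 4, 5], "insomnia_health")
        np.testing.assert_array_equal(labels, [0.0, np.nan, np.nan, 1.0, 1.0])

    def test_out_of_range_errors(self):
        with pytest.raises(EvaluateError, match="out-of-range"):
            dichotomize([1, 7], "insomnia_health")

    def test_unknown_rule_errors(self):
        with pytest.raises(EvaluateError, match="unknown rule"):
            dichotomize([1], "nope")

    @pytest.mark.parametrize("rule,vals", [
        ("chronotype_extremes", [1, 2, 3, 4] * 10),
        ("insomnia_finrisk", [1, 2, 3] * 10),
        ("insomnia_health", [1, 2, 3, 4, 5] * 6),
    ])
    def test_partition_property(self, rule, vals):
        labels, counts = dichotomize(vals, rule)
        assert counts["case"] + counts["control"] + counts["excluded"] == len(vals)


# ---------------------------------------------------------------------------
# linear model
# ---------------------------------------------------------------------------

class TestLinearIncrementalR2:
    def test_null_prs_near_zero(self, rng):
        n = 5000
        covars = pd.DataFrame({"age": rng.uniform(20, 80, n), "sex": rng.integers(0, 2, n)})
        y = 0.01 * covars["age"].to_numpy() + rng.normal(size=n)
        prs = rng.permutation(y)  # unrelated by permutation
        rep = linear_incremental_r2(y, prs, covars)
        assert rep.incremental_r2 == pytest.approx(0.0, abs=5e-3)

    def test_exact_fit_gives_one(self, rng):
        prs = rng.normal(size=50)
        rep = linear_incremental_r2(prs, prs, None)
        assert rep.incremental_r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        n = 40
        covars = pd.DataFrame(
            {"age": rng.uniform(25, 74, n), "sex": rng.integers(0, 2, n).astype(float)}
        )
        prs = rng.normal(size=n)
        y = 0.5 * prs + 0.02 * covars["age"].to_numpy() + rng.normal(size=n)
        rep = linear_incremental_r2(y, prs, covars)

        Xb = np.column_stack([np.ones(n), covars.to_numpy()])
        Xf = np.column_stack([Xb, prs])
        bb, r2b = ols_oracle(y, Xb)
        bf, r2f = ols_oracle(y, Xf)
        assert rep.r2_base == pytest.approx(r2b, abs=1e-10)
        assert rep.r2_full == pytest.approx(r2f, abs=1e-10)
        assert rep.incremental_r2 == pytest.approx(r2f - r2b, abs=1e-10)
        assert rep.prs_coef == pytest.approx(bf[-1], abs=1e-10)

    def test_affine_prs_rescale_invariance(self, rng):
        n = 200
        prs = rng.normal(size=n)
        y = prs + rng.normal(size=n)
        covars = pd.DataFrame({"age": rng.uniform(20, 80, n)})
        a = linear_incremental_r2(y, prs, covars)
        b = linear_incremental_r2(y, 3.7 * prs - 12.0, covars)
        assert a.incremental_r2 == pytest.approx(b.incremental_r2, abs=1e-10)

    def test_collinear_errors(self, rng):
        n = 30
        age = rng.uniform(20, 80, n)
        covars = pd.DataFrame({"age": age, "age2": 2 * age})
        with pytest.raises(EvaluateError, match="collinear"):
            linear_incremental_r2(rng.normal(size=n), rng.normal(size=n), covars)

    def test_too_small_n_errors(self, rng):
        with pytest.raises(EvaluateError, match="too small"):
            linear_incremental_r2(np.ones(2), np.array([0.0, 1.0]), None)


# ---------------------------------------------------------------------------
# logistic model
# ---------------------------------------------------------------------------

class TestLogisticPseudoR2:
    def _fixture(self, rng, n=60):
        covars = pd.DataFrame(
            {"age": rng.uniform(25, 74, n), "sex": rng.integers(0, 2, n).astype(float)}
        )
        prs = rng.normal(size=n)
        eta = 0.8 * prs + 0.01 * (covars["age"].to_numpy() - 50)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        if y.min() == y.max():  # ensure both classes
            y[0] = 1 - y[0]
        return y, prs, covars

    def test_constant_prs_gives_exact_zero(self, rng):
        y, _, covars = self._fixture(rng)
        rep = logistic_pseudo_r2(y, np.full(len(y), 3.2), covars)
        assert rep.pseudo_r2 == 0.0
        assert "constant_prs" in rep.flags

    def test_nonnegative_on_converged_fits(self, rng):
        for _ in range(10):
            y, prs, covars = self._fixture(rng)
            rep = logistic_pseudo_r2(y, prs, covars)
            if rep.converged:
                assert rep.pseudo_r2 >= -1e-12
                assert rep.pseudo_r2 < 1

    def test_matches_irls_oracle(self, rng):
        y, prs, covars = self._fixture(rng)
        rep = logistic_pseudo_r2(y, prs, covars)
        n = len(y)
        Xb = np.column_stack([np.ones(n), covars.to_numpy()])
        Xf = np.column_stack([Xb, prs])
        d0, _ = irls_deviance(y, Xb)
        d1, bf = irls_deviance(y, Xf)
        assert rep.deviance_base == pytest.approx(d0, abs=1e-8)
        assert rep.deviance_full == pytest.approx(d1, abs=1e-8)
        assert rep.pseudo_r2 == pytest.approx(1 - d1 / d0, abs=1e-8)
        assert rep.prs_coef == pytest.approx(bf[-1], abs=1e-6)

    def test_affine_prs_rescale_invariance(self, rng):
        y, prs, covars = self._fixture(rng, n=200)
        a = logistic_pseudo_r2(y, prs, covars)
        b = logistic_pseudo_r2(y, -2.0 * prs + 5.0, covars)
        assert a.pseudo_r2 == pytest.approx(b.pseudo_r2, abs=1e-8)

    def test_single_class_errors(self, rng):
        with pytest.raises(EvaluateError, match="both classes"):
            logistic_pseudo_r2(np.ones(20), rng.normal(size=20), None)

    def test_perfect_separation_flagged(self):
        prs = np.linspace(-2, 2, 30)
        y = (prs > 0).astype(float)
        rep = logistic_pseudo_r2(y, prs, None)
        assert (not rep.converged) or rep.pseudo_r2 > 0.9


# ---------------------------------------------------------------------------
# group comparison and tails
# ---------------------------------------------------------------------------

class TestGroupCompare:
    def test_identical_groups(self):
        prs = np.array([1.0, 1.0, 1.0, 1.0])
        labels = np.array([1.0, 1.0, 0.0, 0.0])
        rep = group_prs_compare(prs, labels)
        assert rep.difference == 0.0
        assert rep.t_pvalue == 1.0

    def test_shifted_groups_estimate_delta(self, rng):
        n = 20000
        delta = 0.37
        prs = np.concatenate([rng.normal(0, 1, n), rng.normal(delta, 1, n)])
        labels = np.concatenate([np.zeros(n), np.ones(n)])
        rep = group_prs_compare(prs, labels)
        assert rep.difference == pytest.approx(delta, abs=4 * np.sqrt(2 / n))
        assert rep.t_pvalue < 1e-10

    def test_matches_textbook_welch(self, rng):
        a = rng.normal(0.2, 1.0, size=10)
        b = rng.normal(0.0, 2.0, size=10)
        prs = np.concatenate([a, b])
        labels = np.concatenate([np.ones(10), np.zeros(10)])
        rep = group_prs_compare(prs, labels)
        # hand formula
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = np.sqrt(va / 10 + vb / 10)
        t = (a.mean() - b.mean()) / se
        df = (va / 10 + vb / 10) ** 2 / ((va / 10) ** 2 / 9 + (vb / 10) ** 2 / 9)
        p = 2 * stats.t.sf(abs(t), df)
        assert rep.t_statistic == pytest.approx(t, abs=1e-10)
        assert rep.t_pvalue == pytest.approx(p, abs=1e-10)

    def test_small_group_errors(self, rng):
        with pytest.raises(EvaluateError, match="2 members"):
            group_prs_compare(np.arange(4.0), np.array([1.0, 0, 0, 0]))


class TestTailContrast:
    def test_constant_trait_zero_difference(self, rng):
        prs = rng.normal(size=200)
        rep = tail_contrast(prs, np.full(200, 7.5), q=0.05)
        assert rep.difference == 0.0

    def test_monotone_trait(self, rng):
        prs = rng.normal(size=500)
        rep = tail_contrast(prs, prs, q=0.05)
        assert rep.group_means["top"] > rep.group_means["bottom"]

    def test_group_sizes_nearest_rank(self, rng):
        prs = rng.normal(size=1000)  # continuous: no ties
        rep = tail_contrast(prs, rng.normal(size=1000), q=0.05)
        assert rep.group_ns == {"top": 50, "bottom": 50}

    def test_bivariate_closed_form_small(self, rng):
        # scaled-down version of the closed-form check (full size in acceptance)
        n, rho, sigma = 20000, 0.3, 1.0
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        prs, trait = z[:, 0], sigma * z[:, 1]
        rep = tail_contrast(prs, trait, q=0.05)
        lam = stats.norm.pdf(stats.norm.ppf(0.95)) / 0.05
        expected = 2 * rho * sigma * lam
        k = rep.group_ns["top"]
        tail_sd = np.sqrt(1 - (rho * lam) ** 2 + rho**2 * lam * stats.norm.ppf(0.95))
        mc_se = np.sqrt(2) * tail_sd / np.sqrt(k)
        assert rep.difference == pytest.approx(expected, abs=3 * mc_se)

    def test_q_half_closed_form(self, rng):
        # second quantile: half-vs-half difference = 2 rho sigma phi(0)/0.5
        n, rho = 40000, 0.25
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        rep = tail_contrast(z[:, 0], z[:, 1], q=0.5)
        expected = 2 * rho * stats.norm.pdf(0.0) / 0.5
        assert rep.difference == pytest.approx(expected, abs=4 / np.sqrt(n / 2))

    def test_minutes_conversion(self, rng):
        prs = rng.normal(size=400)
        trait = 7.5 + 0.5 * prs
        rep = tail_contrast(prs, trait, q=0.05)
        assert rep.difference_minutes == pytest.approx(rep.difference * 60)

    def test_degenerate_prs_errors(self):
        with pytest.raises(EvaluateError, match="degenerate"):
            tail_contrast(np.ones(100), np.arange(100.0), q=0.05)

    def test_too_small_n_errors(self, rng):
        with pytest.raises(EvaluateError, match="too small"):
            tail_contrast(rng.normal(size=10), rng.normal(size=10), q=0.05)
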