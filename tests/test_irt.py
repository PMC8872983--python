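"""IRT calibration against numerical-integration oracles, closed-form
information curves, and the three-stage reduction rules."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

from psychgen._types import ItemSpec
from psychgen.irt import (
    ReductionConfig,
    eap_scores,
    fit_irt,
    icc,
    item_information,
    reduce_items,
)
from psychgen.simulate import gen_item_responses


def _marginal_loglik_oracle(x, a, b):
    """Brute-force marginal log likelihood by adaptive quadrature."""
    total = 0.0
    for i in range(x.shape[0]):
        def integrand(theta, row=x[i]):
            p = expit(a * (theta - b))
            like = np.prod(np.where(row == 1, p, 1 - p))
            return like * norm.pdf(theta)
        val, _ = quad(integrand, -9, 9, limit=200)
        total += np.log(val)
    return total


class TestFit:
    def test_loglik_matches_quadrature_oracle(self, small_bank):
        """Fitted-model log likelihood equals independent numerical
        integration of the marginal likelihood at the fitted parameters."""
        resp = gen_item_responses(small_bank, 50, seed=21)
        fit = fit_irt(resp.accuracy, "2PL", n_quadrature=151)
        a = fit.params["a"].to_numpy()
        b = fit.params["b"].to_numpy()
        oracle = _marginal_loglik_oracle(resp.accuracy.to_numpy(), a, b)
        assert fit.loglik == pytest.approx(oracle, abs=1e-3)

    def test_em_loglik_monotone(self, small_bank):
        resp = gen_item_responses(small_bank, 400, seed=22)
        fit = fit_irt(resp.accuracy, "2PL")
        assert np.all(np.diff(fit.loglik_trace) > -1e-7)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(77)
        bank = [ItemSpec(f"i{j}", "verbal", "v",
                         a=float(rng.uniform(0.8, 2.0)),
                         b=float(rng.uniform(-2, 2))) for j in range(20)]
        resp = gen_item_responses(bank, 2000, seed=23)
        fit = fit_irt(resp.accuracy, "2PL")
        true_a = np.array([it.a for it in bank])
        true_b = np.array([it.b for it in bank])
        assert np.sqrt(np.mean((fit.params["a"] - true_a) ** 2)) < 0.15
        assert np.sqrt(np.mean((fit.params["b"] - true_b) ** 2)) < 0.12

    def test_2pl_never_worse_than_1pl(self):
        rng = np.random.default_rng(5)
        bank = [ItemSpec(f"i{j}", "verbal", "v", a=1.2,
                         b=float(rng.uniform(-1.5, 1.5))) for j in range(10)]
        resp = gen_item_responses(bank, 800, seed=24)
        f1 = fit_irt(resp.accuracy, "1PL")
        f2 = fit_irt(resp.accuracy, "2PL")
        assert f2.loglik >= f1.loglik - 1e-4
        # data generated under equal slopes: 1PL preferred by BIC
        assert f1.bic < f2.bic

    def test_information_criteria_formulas(self, small_bank):
        resp = gen_item_responses(small_bank, 200, seed=25)
        fit = fit_irt(resp.accuracy, "2PL")
        k, n = fit.n_params, fit.n_subjects
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)
        assert fit.bic == pytest.approx(-2 * fit.loglik + k * np.log(n))
        assert fit.adjusted_bic == pytest.approx(
            -2 * fit.loglik + k * np.log((n + 2) / 24))

    def test_degenerate_items_dropped(self, small_bank):
        resp = gen_item_responses(small_bank, 60, seed=26)
        acc = resp.accuracy.copy()
        acc["aced"] = 1
        with pytest.warns(UserWarning, match="all-correct"):
            fit = fit_irt(acc, "2PL")
        assert fit.dropped_items == ["aced"]
        assert "aced" not in fit.params.index

    def test_3pl_fits_with_guessing(self):
        rng = np.random.default_rng(9)
        bank = [ItemSpec(f"i{j}", "verbal", "v",
                         a=float(rng.uniform(1.0, 2.0)),
                         b=float(rng.uniform(-1, 1)), c=0.2) for j in range(8)]
        resp = gen_item_responses(bank, 1500, seed=27)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_irt(resp.accuracy, "3PL", max_iter=300)
        assert ((fit.params["c"] > 0.02) & (fit.params["c"] < 0.5)).all()

    def test_missing_responses_allowed(self, small_bank):
        resp = gen_item_responses(small_bank, 300, seed=28)
        acc = resp.accuracy.astype(float)
        acc.iloc[:50, 0] = np.nan
        fit = fit_irt(acc, "2PL")
        assert fit.n_items == 3


class TestCurves:
    def test_icc_half_at_difficulty(self, five_item_params):
        p = five_item_params
        curves = icc(p, np.array(p["b"].to_numpy()))
        for j, item in enumerate(p.index):
            assert curves.loc[item].to_numpy()[j] == pytest.approx(0.5)

    def test_peak_information_a2_over_4(self, five_item_params):
        grid = np.linspace(-4, 4, 1601)
        info = item_information(five_item_params, grid)
        for item, row in five_item_params.iterrows():
            peak = info.loc[item].max()
            assert peak == pytest.approx(row["a"] ** 2 / 4, rel=1e-3)
            assert grid[info.loc[item].to_numpy().argmax()] == pytest.approx(
                row["b"], abs=0.01)

    def test_information_matches_finite_difference_fisher(self, five_item_params):
        """Closed-form information equals the numerically differentiated
        Fisher information of the Bernoulli likelihood."""
        grid = np.linspace(-2, 2, 9)
        info = item_information(five_item_params, grid)
        eps = 1e-5
        for item, row in five_item_params.iterrows():
            a, b = row["a"], row["b"]
            for k, theta in enumerate(grid):
                p0 = expit(a * (theta - b))
                dp = (expit(a * (theta + eps - b))
                      - expit(a * (theta - eps - b))) / (2 * eps)
                fisher = dp ** 2 / (p0 * (1 - p0))
                assert info.loc[item].iloc[k] == pytest.approx(fisher, rel=1e-4)


class TestEap:
    def test_no_responses_gives_prior(self, five_item_params):
        resp = pd.DataFrame(np.full((2, 5), np.nan),
                            columns=five_item_params.index)
        scores = eap_scores(five_item_params, resp)
        np.testing.assert_allclose(scores["theta"], 0.0, atol=1e-8)
        np.testing.assert_allclose(scores["theta_sd"], 1.0, atol=1e-3)

    def test_monotone_in_number_correct(self, five_item_params):
        patterns = np.tril(np.ones((6, 5)), -1)[:, :5]
        patterns = np.vstack([np.zeros(5), np.tril(np.ones((5, 5)))])
        resp = pd.DataFrame(patterns, columns=five_item_params.index)
        theta = eap_scores(five_item_params, resp)["theta"].to_numpy()
        assert np.all(np.diff(theta) > 0)

    def test_matches_numerical_posterior(self, five_item_params):
        resp = pd.DataFrame([[1, 0, 1, 0, 1]], columns=five_item_params.index)
        est = eap_scores(five_item_params, resp, n_quadrature=101)
        a = five_item_params["a"].to_numpy()
        b = five_item_params["b"].to_numpy()
        row = resp.iloc[0].to_numpy()

        def like(theta):
            p = expit(a * (theta - b))
            return np.prod(np.where(row == 1, p, 1 - p)) * norm.pdf(theta)

        z, _ = quad(like, -9, 9)
        mean, _ = quad(lambda t: t * like(t), -9, 9)
        mean /= z
        assert est["theta"].iloc[0] == pytest.approx(mean, abs=1e-4)


_BASE_FIT = None


def _make_base_fit():
    global _BASE_FIT
    if _BASE_FIT is None:
        bank = [ItemSpec("x1", "verbal", "v", a=1.0, b=0.0),
                ItemSpec("x2", "verbal", "v", a=1.0, b=0.5),
                ItemSpec("x3", "nonverbal", "n", a=1.0, b=-0.5)]
        resp = gen_item_responses(bank, 120, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _BASE_FIT = fit_irt(resp.accuracy, "2PL", max_iter=50)
    return _BASE_FIT


def _params_frame(rows):
    df = pd.DataFrame(rows, columns=["item_id", "a", "b"]).set_index("item_id")
    df["c"] = 0.0
    df["d"] = -df["a"] * df["b"]
    return df


class TestReduction:
    def test_stage1_removes_flat_items(self):
        rows = ([(f"flat{j}", 0.05, 0.0) for j in range(5)]
                + [(f"ok{j}", 1.5, 0.0) for j in range(25)])
        params = _params_frame(rows)
        fit = dataclasses.replace(_make_base_fit(), params=params,
                                  n_items=len(params))
        domains = pd.Series("verbal", index=params.index)
        rep = reduce_items(fit, domains, ReductionConfig(stage3_domains=()))
        assert (rep.loc[[f"flat{j}" for j in range(5)], "stage"]
                == "stage1_flat").all()
        assert (rep.loc[[f"ok{j}" for j in range(25)], "stage"] == "kept").all()

    def test_stage2_low_info_and_out_of_range(self):
        rows = [("low", 0.5, 0.0), ("hard", 1.5, 3.6), ("easy", 1.5, -3.6),
                ("ok", 1.5, 0.0)]
        params = _params_frame(rows)
        fit = dataclasses.replace(_make_base_fit(), params=params,
                                  n_items=len(params))
        domains = pd.Series("verbal", index=params.index)
        rep = reduce_items(fit, domains, ReductionConfig(stage3_domains=()))
        assert rep.loc["low", "stage"] == "stage2_low_info"
        assert rep.loc["hard", "stage"] == "stage2_out_of_range"
        assert rep.loc["easy", "stage"] == "stage2_out_of_range"
        assert rep.loc["ok", "stage"] == "kept"

    def test_identical_items_tie_break_by_order(self):
        rows = [(f"dup{j:02d}", 1.5, 0.0) for j in range(30)]
        params = _params_frame(rows)
        fit = dataclasses.replace(_make_base_fit(), params=params,
                                  n_items=len(params))
        domains = pd.Series("verbal", index=params.index)
        rep = reduce_items(fit, domains,
                           ReductionConfig(quota_per_domain=20))
        kept = rep.index[rep["stage"] == "kept"].tolist()
        assert kept == [f"dup{j:02d}" for j in range(20)]
        assert (rep["stage"] == "stage3_redundant").sum() == 10

    def test_quota_shortfall_raises(self):
        rows = [(f"ok{j}", 1.5, 0.0) for j in range(10)]
        params = _params_frame(rows)
        fit = dataclasses.replace(_make_base_fit(), params=params,
                                  n_items=len(params))
        domains = pd.Series("verbal", index=params.index)
        with pytest.raises(ValueError, match="short of the quota"):
            reduce_items(fit, domains, ReductionConfig(quota_per_domain=20))

    def test_report_partitions_bank_and_reduction_idempotent(self):
        rng = np.random.default_rng(3)
        rows = ([(f"v{j:02d}", float(rng.uniform(1.2, 2.0)), float(-2 + j * 0.15))
                 for j in range(28)]
                + [(f"n{j:02d}", float(rng.uniform(1.2, 2.0)), float(-2 + j * 0.2))
                   for j in range(20)]
                + [("flat0", 0.05, 0.0), ("low0", 0.5, 0.0)])
        params = _params_frame(rows)
        fit = dataclasses.replace(_make_base_fit(), params=params,
                                  n_items=len(params))
        domains = pd.Series(["verbal"] * 28 + ["nonverbal"] * 20 + ["verbal"] * 2,
                            index=params.index)
        rep = reduce_items(fit, domains)
        assert len(rep) == len(params)
        assert set(rep["stage"].unique()) <= {
            "kept", "stage1_flat", "stage2_low_info", "stage2_out_of_range",
            "stage3_low_info", "stage3_flat_icc", "stage3_redundant"}
        kept = rep.index[rep["stage"] == "kept"]
        fit2 = dataclasses.replace(fit, params=params.loc[kept],
                                   n_items=len(kept))
        rep2 = reduce_items(fit2, domains.loc[kept])
        assert (rep2["stage"] == "kept").all()
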