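import math

import numpy as np
import pandas as pd
import pytest

from neurovote.errors import ParameterError, SeparationError
from neurovote.models import (MODEL_PREDICTORS, build_predictors, fit_logistic,
                              model_metrics, run_model_suite, table_one,
                              wald_equality)


def _frame(n=40, seed=0, beta=1.0):
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 2).astype(int)
    x = y * beta + rng.standard_normal(n)
    f = pd.DataFrame({"outcome": y, "x": x})
    return f


def _brute_force_metrics(fit):
    """Explicit likelihood sums and classification counts."""
    p = fit.fitted_prob
    y = fit.outcome
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    pbar = y.mean()
    ll0 = float(len(y) * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar)))
    n = len(y)
    mcf = 1 - ll / ll0
    nag = (1 - math.exp(2 * (ll0 - ll) / n)) / (1 - math.exp(2 * ll0 / n))
    correct = int(np.sum((p >= 0.5).astype(int) == y))
    modal = int(max(np.bincount(y)))
    lam = (correct - modal) / (n - modal)
    return ll, ll0, mcf, nag, lam


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        """A 40/29 outcome split gives intercept log(29/40) = -0.3216."""
        y = np.array([0] * 40 + [1] * 29)
        f = pd.DataFrame({"outcome": y, "z": np.zeros(69)})
        fit = fit_logistic(f, ())
        assert fit.params["const"] == pytest.approx(math.log(29 / 40), abs=1e-6)
        assert fit.loglik_model == pytest.approx(fit.loglik_null, abs=1e-8)

    def test_parameter_recovery(self):
        """Known generating model at n=500: estimate within 2 SE."""
        rng = np.random.default_rng(11)
        n = 500
        x = rng.standard_normal(n)
        eta = -0.3 + 1.2 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        f = pd.DataFrame({"outcome": y, "x": x})
        f.attrs["standardized"] = False
        fit = fit_logistic(f, ("x",))
        assert abs(fit.params["x"] - 1.2) < 2 * fit.bse["x"]
        assert abs(fit.params["const"] - (-0.3)) < 2 * fit.bse["const"]

    def test_null_coefficient_calibration(self):
        """A pure-noise predictor lies within 2 SE of zero ~95% of runs."""
        rng = np.random.default_rng(5)
        inside = 0
        n_sim = 200
        for _ in range(n_sim):
            y = np.repeat([0, 1], 25)
            x = rng.standard_normal(50)
            fit = fit_logistic(pd.DataFrame({"outcome": y, "x": x}), ("x",))
            inside += abs(fit.params["x"]) < 2 * fit.bse["x"]
        assert inside / n_sim > 0.88

    def test_separation_detected(self):
        y = np.repeat([0, 1], 10)
        f = pd.DataFrame({"outcome": y, "x": y * 10.0 - 5.0})
        with pytest.raises(SeparationError, match="penaliz"):
            fit_logistic(f, ("x",))

    def test_single_class_outcome_rejected(self):
        f = pd.DataFrame({"outcome": np.ones(10, int),
                          "x": np.arange(10.0)})
        with pytest.raises(ParameterError):
            fit_logistic(f, ("x",))


class TestMetrics:
    def test_modal_class_model_has_zero_lambda(self):
        """The intercept-only model classifies everything as the modal
        class: lambda = 0 exactly."""
        y = np.array([0] * 40 + [1] * 29)
        f = pd.DataFrame({"outcome": y})
        fit = fit_logistic(f, ())
        met = model_metrics(fit)
        assert met["lambda_adj"] == 0.0
        assert met["mcfadden"] == pytest.approx(0.0, abs=1e-10)

    def test_metrics_match_brute_force(self):
        for seed, beta in ((0, 0.8), (1, 1.6), (2, 0.2)):
            f = _frame(seed=seed, beta=beta)
            fit = fit_logistic(f, ("x",))
            met = model_metrics(fit)
            ll, ll0, mcf, nag, lam = _brute_force_metrics(fit)
            assert met["loglik_model"] == pytest.approx(ll, abs=1e-8)
            assert met["loglik_null"] == pytest.approx(ll0, abs=1e-8)
            assert met["mcfadden"] == pytest.approx(mcf, abs=1e-8)
            assert met["nagelkerke"] == pytest.approx(nag, abs=1e-8)
            assert met["lambda_adj"] == pytest.approx(lam, abs=1e-12)

    def test_metrics_invariant_to_predictor_rescaling(self):
        f = _frame(seed=3, beta=1.0)
        fit1 = fit_logistic(f, ("x",))
        f2 = f.assign(x=f["x"] * 37.5)
        fit2 = fit_logistic(f2, ("x",))
        m1, m2 = model_metrics(fit1), model_metrics(fit2)
        for k in ("mcfadden", "nagelkerke", "lambda_adj"):
            assert m1[k] == pytest.approx(m2[k], abs=1e-7)

    def test_near_perfect_classifier_approaches_one(self):
        """A nearly separating predictor drives lambda and McFadden toward
        their upper limits (an exactly perfect classifier implies complete
        separation, which the fitter rejects by design)."""
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 40)
        x = y * 3.0 + rng.standard_normal(80)
        fit = fit_logistic(pd.DataFrame({"outcome": y, "x": x}), ("x",))
        met = model_metrics(fit)
        assert met["lambda_adj"] >= 0.85
        assert met["mcfadden"] >= 0.6


class TestWald:
    def test_equal_coefficients_give_zero(self):
        f = _frame(seed=4, beta=1.0).assign(x2=lambda d: d["x"])
        # duplicate predictor columns are collinear; instead test via the
        # algebra on a hand-specified covariance
        fit = fit_logistic(_frame(seed=4, beta=1.0), ("x",))
        fit.params["y"] = fit.params["x"]
        fit.cov.loc["y", :] = 0.0
        fit.cov.loc[:, "y"] = 0.0
        fit.cov.loc["y", "y"] = fit.cov.loc["x", "x"]
        w, p = wald_equality(fit, "x", "y")
        assert w == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_specified_covariance_oracle(self):
        fit = fit_logistic(_frame(seed=4, beta=1.0), ("x",))
        fit.params["a"], fit.params["b"] = 1.5, 0.9
        for c in ("a", "b"):
            fit.cov.loc[c, :] = 0.0
            fit.cov.loc[:, c] = 0.0
        fit.cov.loc["a", "a"] = 0.04
        fit.cov.loc["b", "b"] = 0.09
        fit.cov.loc["a", "b"] = fit.cov.loc["b", "a"] = 0.01
        w, _ = wald_equality(fit, "a", "b")
        assert w == pytest.approx((1.5 - 0.9) ** 2 / (0.04 + 0.09 - 0.02),
                                  rel=1e-12)

    def test_null_calibration(self):
        """Equal true coefficients reject at ~alpha."""
        rng = np.random.default_rng(21)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            n = 120
            y = np.repeat([0, 1], n // 2)
            a = y * 0.8 + rng.standard_normal(n)
            b = y * 0.8 + rng.standard_normal(n)
            f = pd.DataFrame({"outcome": y, "a": a, "b": b})
            fit = fit_logistic(f, ("a", "b"))
            _, p = wald_equality(fit, "a", "b")
            hits += p < 0.05
        assert 0.02 <= hits / n_sim <= 0.09


class TestSuite:
    def _cohort(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        y = (np.arange(n) % 2).astype(int)
        participants = pd.DataFrame({
            "participant_id": [f"P{i:03d}" for i in range(n)],
            "vote": np.where(y == 1, "populist", "mainstream"),
            "age": rng.integers(18, 56, n),
            "gender": rng.choice(["male", "female"], n),
            "left_right": rng.integers(1, 11, n),
            "interest_politics": rng.integers(1, 6, n)})
        n400 = pd.Series(y * 1.0 + rng.standard_normal(n) * 1.0,
                         index=participants["participant_id"])
        dsc = pd.DataFrame({"participant_id": participants["participant_id"],
                            "d": rng.standard_normal(n) * 0.4})
        sri = pd.DataFrame({"participant_id": participants["participant_id"],
                            "dimension": "economy",
                            "sri": y * 80.0 + rng.standard_normal(n) * 55.0})
        return n400, dsc, sri, participants

    def test_suite_runs_identical_rows_and_nesting(self):
        n400, dsc, sri, participants = self._cohort()
        frame, _ = build_predictors(n400, dsc, sri, participants)
        suite = run_model_suite(frame)
        ns = {fit.n_obs for fit, _ in suite.values()}
        assert ns == {len(frame)}
        # nested log-likelihood ordering: 1,3 <= 4 <= 6
        ll = {mid: fit.loglik_model for mid, (fit, _) in suite.items()}
        assert ll[4] >= ll[1] - 1e-8 and ll[4] >= ll[3] - 1e-8
        assert ll[6] >= ll[4] - 1e-8
        mcf = {mid: met["mcfadden"] for mid, (_, met) in suite.items()}
        assert mcf[4] >= mcf[1] - 1e-10 and mcf[6] >= mcf[4] - 1e-10

    def test_independent_iat_gives_near_zero_lambda(self):
        n400, dsc, sri, participants = self._cohort(seed=2)
        frame, _ = build_predictors(n400, dsc, sri, participants)
        _, met = run_model_suite(frame, (2,))[2]
        assert met["lambda_adj"] <= 0.15

    def test_missing_column_aborts_with_name(self):
        n400, dsc, sri, participants = self._cohort()
        frame, _ = build_predictors(n400, dsc, sri, participants)
        with pytest.raises(ParameterError, match="sri_economy"):
            run_model_suite(frame.drop(columns="sri_economy"))

    def test_missing_sri_participant_dropped_and_logged(self):
        n400, dsc, sri, participants = self._cohort(n=30)
        sri = sri.iloc[2:]  # first two participants lack SRI
        frame, dropped = build_predictors(n400, dsc, sri, participants)
        assert len(frame) == 28
        assert set(dropped["participant_id"]) == {"P000", "P001"}
        assert (dropped["stage"] == "behav_missing").all()

    def test_join_order_independent(self):
        n400, dsc, sri, participants = self._cohort(n=30, seed=5)
        f1, _ = build_predictors(n400, dsc, sri, participants)
        shuffled = participants.sample(frac=1.0, random_state=1)
        f2, _ = build_predictors(n400.sample(frac=1.0, random_state=2),
                                 dsc.sample(frac=1.0, random_state=3),
                                 sri.sample(frac=1.0, random_state=4), shuffled)
        pd.testing.assert_frame_equal(f1, f2)

    def test_table_one_shape(self):
        n400, dsc, sri, participants = self._cohort()
        frame, _ = build_predictors(n400, dsc, sri, participants)
        t = table_one(run_model_suite(frame))
        assert list(t.columns) == [f"model_{i}" for i in range(1, 7)]
        assert "lambda_adj" in t.index and "observations" in t.index
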