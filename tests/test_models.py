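"""Unit tests for the likelihood machinery (ordinal, logistic, design)."""

import numpy as np
import pandas as pd
import pytest

from reefstress.models import BinomialLogit, ProportionalOddsLogit, build_design, removable_terms

from conftest import simulate_ordinal


class TestDesign:
    def test_continuous_and_factor(self):
        fr = pd.DataFrame({"x": [1.0, 2.0, 3.0], "g": ["a", "b", "c"]})
        X, cols = build_design(fr, ["x", "g"])
        assert cols["x"] == ["x"]
        assert cols["g"] == ["g[T.b]", "g[T.c]"]
        assert X["g[T.b]"].tolist() == [0.0, 1.0, 0.0]

    def test_interaction_products(self):
        fr = pd.DataFrame({"x": [1.0, 2.0], "t": [0.0, 1.0]})
        X, cols = build_design(fr, ["x", "t", "x:t"])
        assert X["x:t"].tolist() == [0.0, 2.0]

    def test_marginality(self):
        terms = ["a", "b", "a:b", "c"]
        assert set(removable_terms(terms)) == {"a:b", "c"}


class TestBinomialLogit:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        m = BinomialLogit().fit(pd.DataFrame(index=range(100)), y)
        assert m.coef_["Intercept"] == pytest.approx(np.log(0.3 / 0.7), abs=1e-6)

    def test_two_by_two_log_odds_ratio(self):
        # exposure x=1: 10 events / 30; x=0: 20 events / 60 -> OR = (10*40)/(20*30)
        a, b, c, d = 10, 20, 30, 40
        x = np.r_[np.ones(a + c), np.zeros(b + d)]
        y = np.r_[np.ones(a), np.zeros(c), np.ones(b), np.zeros(d)]
        m = BinomialLogit().fit(pd.DataFrame({"x": x}), y)
        assert m.coef_["x"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        m = BinomialLogit().fit(pd.DataFrame({"x": x}), x.copy())
        assert m.separation_flag_

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        for _ in range(10):
            X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
            eta = 0.3 + X["a"] - 0.5 * X["b"]
            y = (rng.uniform(size=60) < 1 / (1 + np.exp(-eta))).astype(float)
            m = BinomialLogit().fit(X, y)
            ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
            assert np.allclose(m.coef_.to_numpy(), ref.params.to_numpy(), atol=1e-5)
            assert m.loglik_ == pytest.approx(ref.llf, abs=1e-6)


class TestProportionalOdds:
    def test_intercept_only_cutpoints_are_cumulative_logits(self):
        y = np.r_[np.zeros(25), np.ones(50), np.full(25, 2)]
        m = ProportionalOddsLogit().fit(pd.DataFrame(index=range(100)), y)
        assert m.cutpoints_[0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-5)
        assert m.cutpoints_[1] == pytest.approx(np.log(0.75 / 0.25), abs=1e-5)

    def test_binary_response_rejected(self):
        with pytest.raises(ValueError, match="3 observed"):
            ProportionalOddsLogit().fit(pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}), [0, 1, 0, 1])

    def test_loglik_at_least_intercept_only(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=150)})
        y = simulate_ordinal(rng, X, [-1.0, 1.0], [0.7])
        m = ProportionalOddsLogit().fit(X, y)
        m0 = ProportionalOddsLogit().fit(pd.DataFrame(index=range(150)), y)
        assert m.loglik_ >= m0.loglik_ - 1e-9

    def test_probabilities_sum_to_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        y = simulate_ordinal(rng, X, [-1.0, 1.0], [1.0, -0.5])
        m = ProportionalOddsLogit().fit(X, y)
        P = m.predict_proba(pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"]))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()

    def test_prob_below_first_cutpoint_is_half_at_cutpoint(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=300)})
        y = simulate_ordinal(rng, X, [-1.0, 1.0], [1.0])
        m = ProportionalOddsLogit().fit(X, y)
        # at x with x*beta = theta_1, P(lowest category) = 0.5
        x_star = m.cutpoints_[0] / m.coef_["x"]
        P = m.predict_proba(pd.DataFrame({"x": [x_star]}))
        assert P[0, 0] == pytest.approx(0.5, abs=1e-10)

    def test_positive_slope_means_higher_categories(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=400)})
        y = simulate_ordinal(rng, X, [-1.0, 1.0], [1.5])
        m = ProportionalOddsLogit().fit(X, y)
        assert m.coef_["x"] > 0
        lo, hi = m.predict_proba(pd.DataFrame({"x": [-2.0]})), m.predict_proba(pd.DataFrame({"x": [2.0]}))
        assert hi[0, 2] > lo[0, 2]  # P(top category) increases with x

    def test_matches_statsmodels_ml(self, rng):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        for _ in range(10):
            n = 120
            X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
            y = simulate_ordinal(rng, X, [-0.8, 0.9], [1.0, -0.6])
            if len(np.unique(y)) < 3:
                continue
            m = ProportionalOddsLogit().fit(X, y)
            ref = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0)
            assert m.loglik_ == pytest.approx(ref.llf, abs=1e-5)
            assert np.allclose(m.coef_.to_numpy(), ref.params.to_numpy()[:2], atol=1e-4)

    def test_vcov_close_to_statsmodels(self, rng):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        n = 300
        X = pd.DataFrame({"a": rng.normal(size=n)})
        y = simulate_ordinal(rng, X, [-1.0, 1.0], [0.8])
        m = ProportionalOddsLogit().fit(X, y)
        ref = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0)
        se_ref = ref.bse.iloc[0]
        se_own = np.sqrt(m.vcov_.loc["a", "a"])
        assert se_own == pytest.approx(se_ref, rel=0.02)

    def test_parameter_recovery_beta_time(self, rng):
        """beta_time = 2.0 recovered within +-0.3 for 400 colonies x 2 years."""
        hits = 0
        reps = 60
        for _ in range(reps):
            time = np.r_[np.zeros(400), np.ones(400)]  # each colony observed both years
            X = pd.DataFrame({"time": time})
            y = simulate_ordinal(rng, X, [-1.0986, 1.0986], [2.0])
            if len(np.unique(y)) < 3:
                continue
            m = ProportionalOddsLogit().fit(X, y)
            hits += abs(m.coef_["time"] - 2.0) <= 0.3
        assert hits / reps >= 0.90
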