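"""MLE fitting, AIC comparison, and predicted-observed correlation."""

import math

import numpy as np
import pytest

import placefit as pf
from placefit.fitting import (ChoiceModelEstimator, _negloglik, aic,
                              compare_models, fit_mle,
                              predicted_observed_correlation)
from placefit.models import ParamVector, session_log_likelihood
from placefit.records import LEFT, RIGHT


def vectorized_grid_loglik(choices, rewards, alphas, betas, deltas):
    """Independent array-parallel recursion over a parameter grid.

    Returns the maximum log-likelihood over the grid.  Written directly
    from the model equations (value update on the chosen side, logistic
    choice with repetition term), not via the package's likelihood code.
    """
    A, B, D = np.meshgrid(alphas, betas, deltas, indexing="ij")
    A, B, D = A.ravel(), B.ravel(), D.ravel()
    vl = np.zeros_like(A)
    vr = np.zeros_like(A)
    ll = np.zeros_like(A)
    prev = None
    for c, r in zip(choices, rewards):
        logit = B * (vr - vl)
        if prev == RIGHT:
            logit = logit + D
        elif prev == LEFT:
            logit = logit - D
        p = 1.0 / (1.0 + np.exp(-logit))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        ll += np.log(p) if c == RIGHT else np.log(1.0 - p)
        if c == RIGHT:
            vr = vr + A * (r - vr)
        else:
            vl = vl + A * (r - vl)
        prev = c
    return ll.max()


class TestAic:
    @pytest.mark.parametrize("logl,k,expected", [(-50.0, 3, 106.0), (-50.0, 2, 104.0)])
    def test_arithmetic(self, logl, k, expected):
        assert aic(logl, k) == expected

    def test_penalty_identity(self):
        """With equal logL, RL's AIC is lower by exactly the 2-unit penalty."""
        assert aic(-30.0, 3) - aic(-30.0, 2) == 2.0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            aic(float("nan"), 2)
        with pytest.raises(ValueError):
            aic(-10.0, 0)


class TestJittedCore:
    def test_jitted_matches_scalar_reference(self, prl_session):
        """The numba objective equals the readable scalar recursion to 1e-10."""
        c, r = pf.models.trials_to_arrays(prl_session.trials)
        for params in [ParamVector("prl", 0.3, 4.0, 1.2),
                       ParamVector("prl", 0.9, 0.5, -2.0),
                       ParamVector("rl", 0.1, 7.0)]:
            logl, _ = session_log_likelihood((c, r), params)
            nll = _negloglik(c, r, params.alpha, params.beta, params.delta_or_zero)
            assert -nll == pytest.approx(logl, abs=1e-10)


class TestFitMle:
    def test_zero_trials_refused(self):
        with pytest.raises(ValueError):
            fit_mle(np.empty((0, 2), dtype=int), model="rl")

    def test_tiny_input_flagged_unreliable(self):
        X = np.array([[RIGHT, 1], [LEFT, 0]])
        fr = fit_mle(X, model="rl")
        assert not fr.reliable
        assert fr.n_trials == 2

    def test_invalid_model_tag(self):
        with pytest.raises(ValueError):
            fit_mle(np.array([[1, 1]] * 20), model="q-learning")

    def test_fair_coin_data_recovers_chance(self):
        """beta ~ 0 data: fitted logL ~ n ln(1/2) and beta not inflated."""
        rng = np.random.default_rng(7)
        n = 300
        X = np.column_stack([rng.integers(0, 2, n), rng.integers(0, 2, n)])
        fr = fit_mle(X, model="rl", seed=0)
        assert fr.logl == pytest.approx(n * math.log(0.5), abs=6.0)
        assert fr.logl >= n * math.log(0.5) - 1e-9  # MLE can only beat chance

    def test_more_starts_never_worse(self, prl_session):
        c_r = pf.models.trials_to_arrays(prl_session.trials)
        l4 = fit_mle(c_r, model="prl", n_starts=4, seed=0).logl
        l16 = fit_mle(c_r, model="prl", n_starts=16, seed=0).logl
        assert l16 >= l4 - 1e-8

    def test_grid_oracle_equivalence_20_trials(self):
        """Exhaustive grid never beats the optimiser by more than 0.05."""
        from placefit.experiments import simulate_fixed_length_session

        for seed in (0, 1, 2):
            s = simulate_fixed_length_session(0.4, 5.0, 1.5, 20, seed=seed)
            c, r = pf.models.trials_to_arrays(s.trials)
            fr = fit_mle((c, r), model="prl", seed=0)
            grid_best = vectorized_grid_loglik(
                c, r, np.arange(0, 1.0001, 0.02), np.arange(0, 20.0001, 0.2),
                np.arange(-10, 10.0001, 0.2))
            assert fr.logl >= grid_best - 0.05

    def test_recovery_bias_shrinks_with_more_trials(self):
        """RMSE of (alpha, delta) decreases over 50 -> 200 -> 800 trials."""
        from placefit.experiments import recovery_experiment

        rmses = []
        for n in (50, 200, 800):
            df = recovery_experiment(reps=12, n_trials=n, seed=5, n_starts=8)
            rmses.append(np.sqrt((df[["abs_err_alpha", "abs_err_delta"]] ** 2)
                                 .mean().mean()))
        assert rmses[0] > rmses[1] > rmses[2]


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        est = ChoiceModelEstimator(model="rl", n_starts=4, seed=3)
        params = est.get_params()
        assert params["model"] == "rl" and params["n_starts"] == 4
        est.set_params(model="prl")
        assert est.model == "prl"

    def test_fitted_attributes_and_predict(self, prl_session):
        est = ChoiceModelEstimator(model="prl", n_starts=8, seed=0)
        est.fit(prl_session.trials)
        assert 0.0 <= est.alpha_ <= 1.0
        assert est.beta_ >= 0.0
        assert est.aic_ == pytest.approx(6 - 2 * est.log_likelihood_)
        probs = est.predict_proba(prl_session.trials)
        assert len(probs) == est.n_trials_
        assert np.all((probs > 0) & (probs < 1))
        assert est.score(prl_session.trials) == pytest.approx(
            est.log_likelihood_ / est.n_trials_)

    def test_clone_compatible(self):
        from sklearn.base import clone

        est = clone(ChoiceModelEstimator(model="prl", seed=5))
        assert est.seed == 5


class TestCompareModels:
    def _mk(self, model, aic_val, n=100):
        k = 2 if model == "rl" else 3
        logl = (2 * k - aic_val) / 2
        return pf.FitResult(
            params=ParamVector(model, 0.5, 1.0, 0.0 if model == "prl" else None),
            logl=logl, aic=aic_val, n_trials=n, n_starts=1, seed=0,
            converged=True, reliable=True, predicted_probs=np.full(n, 0.5))

    def test_argmin_and_delta(self):
        cmp = compare_models(self._mk("rl", 104.0), self._mk("prl", 100.0))
        assert cmp.preferred == "prl"
        assert cmp.delta_aic == 4.0

    def test_tie_prefers_simpler_rl(self):
        cmp = compare_models(self._mk("rl", 100.0), self._mk("prl", 100.0))
        assert cmp.preferred == "rl"

    def test_mismatched_trials_rejected(self):
        with pytest.raises(ValueError):
            compare_models(self._mk("rl", 104.0, n=100), self._mk("prl", 100.0, n=99))

    def test_order_enforced(self):
        with pytest.raises(ValueError):
            compare_models(self._mk("prl", 100.0), self._mk("prl", 100.0))


class TestPredictedObservedCorrelation:
    def _fit_with_probs(self, probs):
        n = len(probs)
        return pf.FitResult(
            params=ParamVector("prl", 0.5, 1.0, 0.0), logl=0.0, aic=6.0,
            n_trials=n, n_starts=1, seed=0, converged=True, reliable=True,
            predicted_probs=np.asarray(probs, dtype=float))

    def test_constant_predictions_undefined(self):
        choices = np.array([1, 0, 1, 0])
        r, defined = predicted_observed_correlation(
            self._fit_with_probs([0.5] * 4), (choices, choices))
        assert not defined and math.isnan(r)

    def test_perfect_predictions_r_one(self):
        choices = np.array([1, 1, 0, 1])
        r, defined = predicted_observed_correlation(
            self._fit_with_probs(choices.astype(float)), (choices, choices))
        assert defined and r == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        """Textbook Pearson on choices 1,1,0,1 vs probs .8,.7,.4,.6."""
        obs = np.array([1.0, 1.0, 0.0, 1.0])
        pred = np.array([0.8, 0.7, 0.4, 0.6])
        num = np.sum((obs - obs.mean()) * (pred - pred.mean()))
        expected = num / math.sqrt(np.sum((obs - obs.mean()) ** 2)
                                   * np.sum((pred - pred.mean()) ** 2))
        r, defined = predicted_observed_correlation(
            self._fit_with_probs(pred), (obs.astype(int), obs.astype(int)))
        assert defined and r == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            predicted_observed_correlation(
                self._fit_with_probs([0.5, 0.6]), (np.array([1, 0, 1]),) * 2)
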