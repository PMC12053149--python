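"""Maximum-likelihood fitting of the RL / PRL choice models and AIC comparison.

The likelihood surface is smooth but can be multimodal in the
perseverance weight, so the fit is a bounded quasi-Newton (L-BFGS-B)
minimisation of the negative log-likelihood from 16 deterministic
quasi-random (Sobol) starting points inside the bounds
``alpha in [0, 1]``, ``beta in [0, 20]``, ``delta in [-10, 10]``.  The
beta bound is a practical identifiability cap — the logistic saturates
far below it on near-deterministic runs — and is configurable.

The hot inner loop (one likelihood evaluation per optimiser step, per
start, per session) is a numba-compiled twin of
:func:`placefit.models.session_log_likelihood`; the two are pinned
against each other in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy import optimize, stats
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .models import PROB_EPS, MODELS, ParamVector, session_log_likelihood, trials_to_arrays
from .records import RIGHT, TrialRecord

DEFAULT_BOUNDS = {"alpha": (0.0, 1.0), "beta": (0.0, 20.0), "delta": (-10.0, 10.0)}
DEFAULT_N_STARTS = 16


@njit(cache=False)
def _negloglik(choices, rewards, alpha, beta, delta):  # pragma: no cover - jitted
    vl = 0.0
    vr = 0.0
    prev = -1
    nll = 0.0
    for t in range(choices.shape[0]):
        logit = beta * (vr - vl)
        if prev == 1:
            logit += delta
        elif prev == 0:
            logit -= delta
        p = 1.0 / (1.0 + math.exp(-logit))
        if p < PROB_EPS:
            p = PROB_EPS
        elif p > 1.0 - PROB_EPS:
            p = 1.0 - PROB_EPS
        if choices[t] == 1:
            nll -= math.log(p)
        else:
            nll -= math.log(1.0 - p)
        r = rewards[t]
        if choices[t] == 1:
            vr += alpha * (r - vr)
        else:
            vl += alpha * (r - vl)
        prev = choices[t]
    return nll


def aic(logl: float, k: int) -> float:
    """Akaike information criterion, ``2 k - 2 logL``; lower is better."""
    if not math.isfinite(logl):
        raise ValueError("log-likelihood must be finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2.0 * k - 2.0 * logl


class ChoiceModelEstimator(BaseEstimator):
    """Scikit-learn style MLE estimator for the RL / PRL choice models.

    Parameters
    ----------
    model : {'rl', 'prl'}
        'rl' fits (alpha, beta); 'prl' additionally fits the perseverance
        weight delta.
    n_starts : int
        Number of Sobol multi-start points for the bounded L-BFGS-B
        optimisation.
    seed : int
        Seed of the Sobol start grid (recorded in the result; the grid is
        deterministic given the seed).
    beta_max, delta_max : float
        Box bounds: beta in [0, beta_max], delta in [-delta_max, delta_max].

    The estimator consumes either a sequence of
    :class:`~placefit.records.TrialRecord` or an ``(n, 2)`` integer array
    of ``[choice_side, reward]`` rows.  Fitted attributes follow the
    trailing-underscore convention: ``alpha_``, ``beta_``, ``delta_``
    (None for 'rl'), ``log_likelihood_``, ``aic_``, ``n_trials_``,
    ``converged_``, ``reliable_``, ``predicted_probs_``.
    """

    def __init__(self, model: str = "prl", n_starts: int = DEFAULT_N_STARTS,
                 seed: int = 0, beta_max: float = 20.0, delta_max: float = 10.0):
        self.model = model
        self.n_starts = n_starts
        self.seed = seed
        self.beta_max = beta_max
        self.delta_max = delta_max

    # -- data handling ----------------------------------------------------
    @staticmethod
    def _as_arrays(X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, tuple) and len(X) == 2:
            c, r = X
        elif len(X) and isinstance(X[0], TrialRecord):
            return trials_to_arrays(X)
        else:
            arr = np.asarray(X, dtype=np.int64)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("X must be TrialRecords or an (n, 2) array of [side, reward]")
            c, r = arr[:, 0], arr[:, 1]
        c = np.ascontiguousarray(c, dtype=np.int64)
        r = np.ascontiguousarray(r, dtype=np.int64)
        if c.size and (c.min() < 0 or c.max() > 1 or r.min() < 0 or r.max() > 1):
            raise ValueError("sides and rewards must be binary")
        return c, r

    def _bounds(self) -> list[tuple[float, float]]:
        b = [(0.0, 1.0), (0.0, self.beta_max)]
        if self.model == "prl":
            b.append((-self.delta_max, self.delta_max))
        return b

    # -- core -------------------------------------------------------------
    def fit(self, X, y=None) -> "ChoiceModelEstimator":
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        choices, rewards = self._as_arrays(X)
        n = int(choices.size)
        if n == 0:
            raise ValueError("cannot fit a choice model to 0 trials")
        k = 2 if self.model == "rl" else 3

        bounds = self._bounds()

        def nll(theta: np.ndarray) -> float:
            a, b = theta[0], theta[1]
            d = theta[2] if k == 3 else 0.0
            return _negloglik(choices, rewards, a, b, d)

        sampler = qmc.Sobol(d=k, scramble=True, seed=self.seed)
        unit = sampler.random(self.n_starts)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        starts = lo + unit * (hi - lo)

        best = None
        for x0 in starts:
            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        assert best is not None

        self.alpha_ = float(best.x[0])
        self.beta_ = float(best.x[1])
        self.delta_ = float(best.x[2]) if k == 3 else None
        self.log_likelihood_ = float(-best.fun)
        self.aic_ = aic(self.log_likelihood_, k)
        self.n_trials_ = n
        self.converged_ = bool(best.success)
        self.reliable_ = n >= max(10, 3 * k)
        _, self.predicted_probs_ = session_log_likelihood(
            (choices, rewards), self.params_)
        return self

    @property
    def params_(self) -> ParamVector:
        return ParamVector(model=self.model, alpha=self.alpha_,
                           beta=self.beta_, delta=self.delta_)

    def predict_proba(self, X) -> np.ndarray:
        """Sequential one-step-ahead P(right) along the given trials."""
        arrays = self._as_arrays(X)
        _, probs = session_log_likelihood(arrays, self.params_)
        return probs

    def score(self, X, y=None) -> float:
        """Mean per-trial log-likelihood under the fitted parameters."""
        arrays = self._as_arrays(X)
        logl, _ = session_log_likelihood(arrays, self.params_)
        return logl / max(1, len(arrays[0]))


@dataclass
class FitResult:
    """Best parameters and fit quality for one trial set."""

    params: ParamVector
    logl: float
    aic: float
    n_trials: int
    n_starts: int
    seed: int
    converged: bool
    reliable: bool
    predicted_probs: np.ndarray
    scope: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.params.model,
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "delta": self.params.delta,
            "logL": self.logl,
            "aic": self.aic,
            "n_trials": self.n_trials,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "converged": self.converged,
            "reliable": self.reliable,
            **{k: v for k, v in self.scope.items()},
        }


def fit_mle(trials, model: str = "prl", n_starts: int = DEFAULT_N_STARTS,
            seed: int = 0, scope: dict | None = None, **kwargs) -> FitResult:
    """Fit one model to one trial set by multi-start maximum likelihood.

    Fits on fewer than ``max(10, 3k)`` trials are returned flagged
    ``reliable=False`` rather than refused; 0 trials is an error.
    """
    est = ChoiceModelEstimator(model=model, n_starts=n_starts, seed=seed, **kwargs).fit(trials)
    return FitResult(
        params=est.params_, logl=est.log_likelihood_, aic=est.aic_,
        n_trials=est.n_trials_, n_starts=n_starts, seed=seed,
        converged=est.converged_, reliable=est.reliable_,
        predicted_probs=est.predicted_probs_, scope=dict(scope or {}),
    )


@dataclass
class ModelComparison:
    delta_aic: float          # AIC(RL) - AIC(PRL); positive favours PRL
    preferred: str            # 'rl' or 'prl'; ties go to the simpler RL
    aic_rl: float
    aic_prl: float


def compare_models(fit_rl: FitResult, fit_prl: FitResult) -> ModelComparison:
    """AIC comparison of the two models fitted to the same trials."""
    if fit_rl.params.model != "rl" or fit_prl.params.model != "prl":
        raise ValueError("compare_models expects (RL fit, PRL fit) in that order")
    if fit_rl.n_trials != fit_prl.n_trials:
        raise ValueError("fits must be on identical trial sets")
    d = fit_rl.aic - fit_prl.aic
    return ModelComparison(delta_aic=d, preferred="prl" if d > 0 else "rl",
                           aic_rl=fit_rl.aic, aic_prl=fit_prl.aic)


def predicted_observed_correlation(fit: FitResult, trials) -> tuple[float, bool]:
    """Pearson R between the 0/1 right-choice indicator and fitted P(right).

    Returns ``(r, defined)``; when either series is constant the
    correlation is undefined and ``(nan, False)`` is returned.
    """
    if isinstance(trials, tuple):
        choices = np.asarray(trials[0])
    else:
        choices, _ = trials_to_arrays(trials)
    probs = np.asarray(fit.predicted_probs, dtype=float)
    if len(probs) != len(choices):
        raise ValueError("prediction series and trials have different lengths")
    obs = (choices == RIGHT).astype(float)
    if len(obs) < 2 or np.ptp(obs) == 0 or np.ptp(probs) == 0:
        return float("nan"), False
    r, _ = stats.pearsonr(obs, probs)
    return float(r), True
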