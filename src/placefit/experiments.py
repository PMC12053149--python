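"""Simulation experiments: parameter recovery, AIC model selection, linkage.

These functions tie the generator and the fitter together and are used
both by the test suite and by the reproduction script: simulate choice
data from known PRL/RL parameters on the reversal task, refit, and
summarise how well truth is recovered and how often AIC prefers the
generating model class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import compare_models, fit_mle
from .metrics import phase_metrics, segment_phases
from .models import trials_to_arrays
from .records import Session
from .synth import Scenario, generate_cohort
from .task import PRLAgent, TaskConfig, run_session, test_config


def simulate_fixed_length_session(alpha: float, beta: float, delta: float,
                                  n_trials: int, seed: int,
                                  config: TaskConfig | None = None) -> Session:
    """One reversal-task session truncated at exactly ``n_trials`` trials."""
    cfg = config or test_config(
        "small", max_reversals=10**6, max_duration_s=1e9, blank_poke_rate=0.0)
    agent = PRLAgent(alpha=alpha, beta=beta, delta=delta)
    return run_session(agent, cfg, seed=seed, max_trials=n_trials)


def recovery_experiment(alpha: float = 0.4, beta: float = 5.0, delta: float = 1.5,
                        reps: int = 50, n_trials: int = 200, seed: int = 0,
                        n_starts: int = 16) -> pd.DataFrame:
    """Simulate ``reps`` sessions at known parameters and refit the PRL model.

    Returns a long table with one row per session: the truth, the
    estimates, and the absolute errors.
    """
    rows = []
    for rep in range(reps):
        s = int(np.random.SeedSequence([seed, rep, 11]).generate_state(1)[0] % (2**31))
        session = simulate_fixed_length_session(alpha, beta, delta, n_trials, s)
        fr = fit_mle(session.trials, model="prl", seed=seed, n_starts=n_starts)
        rows.append({
            "rep": rep, "n_trials": fr.n_trials, "seed": s,
            "alpha_true": alpha, "beta_true": beta, "delta_true": delta,
            "alpha_hat": fr.params.alpha, "beta_hat": fr.params.beta,
            "delta_hat": fr.params.delta,
            "abs_err_alpha": abs(fr.params.alpha - alpha),
            "abs_err_beta": abs(fr.params.beta - beta),
            "abs_err_delta": abs(fr.params.delta - delta),
            "sign_match_delta": bool(np.sign(fr.params.delta) == np.sign(delta))
            if delta != 0 else None,
            "logL": fr.logl,
        })
    return pd.DataFrame(rows)


def model_selection_experiment(delta: float, reps: int = 100, n_trials: int = 200,
                               alpha: float = 0.4, beta: float = 5.0,
                               seed: int = 0, n_starts: int = 8) -> pd.DataFrame:
    """Fit both models to data generated with the given delta (0 = RL data).

    One row per session with both AICs and the preferred model.
    """
    rows = []
    for rep in range(reps):
        s = int(np.random.SeedSequence([seed, rep, 13]).generate_state(1)[0] % (2**31))
        session = simulate_fixed_length_session(alpha, beta, delta, n_trials, s)
        arrays = trials_to_arrays(session.trials)
        fr_rl = fit_mle(arrays, model="rl", seed=seed, n_starts=n_starts)
        fr_prl = fit_mle(arrays, model="prl", seed=seed, n_starts=n_starts)
        cmp = compare_models(fr_rl, fr_prl)
        rows.append({"rep": rep, "delta_true": delta, "aic_rl": cmp.aic_rl,
                     "aic_prl": cmp.aic_prl, "delta_aic": cmp.delta_aic,
                     "preferred": cmp.preferred})
    return pd.DataFrame(rows)


def perseverance_by_delta(deltas=(-2.0, 0.0, 2.0), reps: int = 30,
                          n_trials: int = 120, alpha: float = 0.4,
                          beta: float = 5.0, seed: int = 0) -> pd.DataFrame:
    """Session-wide perseverance rate of agents generated at each delta."""
    rows = []
    for d in deltas:
        for rep in range(reps):
            s = int(np.random.SeedSequence([seed, rep, int(round(d * 1000)) % 9973, 17])
                    .generate_state(1)[0] % (2**31))
            session = simulate_fixed_length_session(alpha, beta, d, n_trials, s)
            sides = [tr.choice_side for tr in session.trials]
            pairs = list(zip(sides, sides[1:]))
            rows.append({"delta_true": d, "rep": rep,
                         "perseverance_rate": sum(a == b for a, b in pairs) / len(pairs)})
    return pd.DataFrame(rows)


def acquisition_ttc_by_treatment(seed: int = 0, n_animals: int = 11) -> pd.DataFrame:
    """Acquisition-phase TTC per session of the default CNO-vs-VEH cohort."""
    sessions, _ = generate_cohort(Scenario(n_animals=n_animals, seed=seed))
    rows = []
    for session in sessions:
        cfg = test_config(session.meta.separation)
        segs = segment_phases(session, cfg)
        acq = segs[0]
        mb = phase_metrics(acq, session)
        rows.append({"animal": session.meta.animal_id,
                     "separation": session.meta.separation,
                     "treatment": session.meta.treatment,
                     "phase": acq.label, "ttc": mb.ttc,
                     "censored": mb.censored,
                     "n_trials": mb.n_trials})
    return pd.DataFrame(rows)
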