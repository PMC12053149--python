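# placefit

Simulation and reinforcement-learning analysis of a rodent
**location-discrimination (LD) reversal task**: two cued nose-poke wells
out of eight (L1–L8, 6 cm apart), one rewarded and one not, with the
contingency reversing each time the animal makes 9 of its last 10
choices correctly. The task is the standard operant probe of
hippocampal *pattern separation* — discriminating a rewarded from an
unrewarded location that is either close by (small separation, L4–L5,
6 cm) or far apart (large separation, L2–L7, 30 cm) — and is typically
run as a crossed within-subject design (separation × a chemogenetic
treatment such as VEH vs CNO).

`placefit` is for researchers who run this task (or simulate it) and
want the complete analysis chain as tested, reusable code:

* **Task engine** — a contract-tested simulator of the contingency
  state, the 9-of-10 reversal criterion, the 6-reversal / 60-min test
  session caps and the well geometry, driven by pluggable choice agents.
* **Choice models** — the Rescorla–Wagner (RL) and Perseverance-RL (PRL)
  models. Values update by prediction error,
  `V_c ← V_c + α (r − V_c)`, and the rightward-choice probability is
  `P(right) = σ(β (V_R − V_L) + δ (C_R − C_L))`, where σ is the
  logistic, α the learning rate, β the reward sensitivity and δ the
  perseverance weight (positive = stay, negative = alternate; the
  previous-trial indicators C make the δ term ±δ after the first trial).
  The RL model is the δ = 0 special case.
* **Fitting** — multi-start bounded maximum likelihood as a
  scikit-learn-style estimator (`ChoiceModelEstimator`), AIC model
  comparison (`AIC = 2k − 2 log L`), predicted-vs-observed choice
  correlation, and parameter-recovery / model-selection experiments.
* **Behavioral metrics** — phase segmentation (Acq, R1, R2, …),
  trials-to-criterion (TTC), error proportion, perseverance rate,
  latency aggregates, blank pokes and per-well poke distributions,
  exported as tidy long-format tables for external statistics.
* **Locomotion** — pose-tracking (25 fps, 6 body parts) →
  centre-of-mass → arena-outlier removal → ≤100 ms gap interpolation →
  10-sample moving average → body speed (cm/s) per trial.
* **Synthetic cohorts** — counterbalanced animal × condition designs
  generated by PRL agents, with treatment effects encoded as parameter
  shifts, plus noisy synthetic tracking traces.

## Worked example

```python
import placefit as pf

# simulate one small-separation test session with a perseverating learner
agent = pf.PRLAgent(alpha=0.4, beta=5.0, delta=1.5)
session = pf.run_session(agent, pf.test_config("small"), seed=42)
print(len(session), session.info["reversal_count"])   # 111 6

# phase metrics
cfg = pf.test_config("small")
for seg in pf.segment_phases(session, cfg)[:3]:
    mb = pf.phase_metrics(seg, session)
    print(seg.label, mb.ttc, round(mb.error_proportion, 3))
# Acq 14 0.357
# R1 22 0.591
# R2 18 0.5

# fit both models and compare by AIC
rl = pf.fit_mle(session.trials, model="rl", seed=0)
prl = pf.fit_mle(session.trials, model="prl", seed=0)
cmp = pf.compare_models(rl, prl)
print(round(rl.aic, 2), round(prl.aic, 2), cmp.preferred)
# 40.41 39.87 prl
```

The session reached the reversal cap (6 reversals) in 111 trials; the
acquisition phase took 14 trials to criterion with 36 % errors; and the
PRL model edges out the plain RL model on AIC, i.e. the extra
perseverance parameter is worth its 2-unit penalty on this agent's
choices — as expected, since the generating agent perseverates
(δ = 1.5).

The same chain is available from a shell:

```bash
placefit simulate-cohort --out cohort/            # 44 counterbalanced sessions
placefit fit --in cohort/ --scope phase --out fits.json
placefit metrics --in cohort/ --out metrics.csv
```

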