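# Methods

## The task and its contingency engine

The location-discrimination task presents two cued wells out of eight
arranged in a row (L1–L8, 6 cm centre-to-centre); one is rewarded, one
is not, and the animal chooses by nose poke. The engine models a
session as: trial initiation at a central well (0.3 s hold), a response
with log-normal latency, sucrose reward on a correct poke (2 s
consumption) or a 3 s house-light cue plus 5 s time-out on an incorrect
one, then a 10 s inter-trial interval. Test sessions use the small
(L4–L5, 6 cm) or large (L2–L7, 30 cm) cued pair; distances are derived
from the well indices × spacing, so the medium training pairs (L1–L3
and shifts) come out at 12 cm. Pretraining-style sessions additionally
reward trial initiation with probability 0.20 and cap at 40 min.

**Reversal criterion.** The contingency reverses when the trailing
window of the current block — the last min(10, n) trials — contains at
least 9 correct and at least 9 block trials have elapsed. Under this
reading a perfect performer reverses after 9 trials, which makes the
always-correct worked example exact arithmetic (7 blocks × 9 trials).
The phrase "9 out of 10 consecutive correct" can also be read as
requiring a full 10-trial window; that stricter reading is available as
`TaskConfig(strict_window=True)` and changes only the can-fire-early
edge case at block start.

**Session termination.** A test session ends at the duration cap
(60 min) or, once 6 contingency switches have occurred, when the
criterion is met one further time: that last event completes the final
block (Acq + R1…R6 = 7 blocks, 6 switches) without triggering another
switch. This is the only reading under which "the session ends with 6
reversals completed" and "reversal count = completed blocks − 1" hold
simultaneously.

## Choice models

Both models act on the left/right choice within the cued pair (side =
position in the ordered pair; all quantities are invariant under a
consistent relabelling). The chosen side's value follows the
Rescorla–Wagner rule `V_c ← V_c + α (r − V_c)` with `r ∈ {0, 1}`; the
unchosen side does not decay (standard instrumental form; nothing in
the task motivates forgetting). The rightward-choice probability is the
logistic `P = σ(β (V_R − V_L) + δ (C_R − C_L))`, with the previous-
choice indicators making the δ term +δ after a right choice, −δ after a
left one, and 0 on the first trial. A textbook-shorthand variant of
this sigmoid with a 0.5 offset is sometimes written down; taken
literally it exceeds 1, so the package implements the plain logistic —
whose value at zero logit is exactly the chance level 0.5 the offset is
meant to express — and exposes the literal form only as a clipped debug
evaluator (`choice_probability_literal`). The sign convention is chosen
so that positive δ means perseverance (repeating the previous side) and
negative δ alternation.

Values reset to 0 and the previous-choice indicator to "none" at the
start of each *session*, never across sessions. A reversal changes the
task contingency, not the model state. When fitting per learning phase
the default likewise resets state at the phase boundary; pooling the
phase's trials with carried state is possible by fitting the whole
session and slicing the per-trial predictions.

The initiation reward (the 20 % pretraining rule) is not the outcome of
a choice and never enters the value update.

## Maximum-likelihood fitting

The session log-likelihood is the Bernoulli likelihood of each observed
side under the sequentially predicted P(right), with probabilities
clipped to [1e−9, 1 − 1e−9]. Fitting minimises the negative
log-likelihood with L-BFGS-B inside the box α ∈ [0, 1], β ∈ [0, 20],
δ ∈ [−10, 10], from 16 scrambled-Sobol start points (seeded, hence
deterministic). β is capped because the logistic saturates: on a
near-deterministic run any β above ~10 is likelihood-equivalent, and an
unbounded β is unidentifiable; the cap is configurable. The δ term
induces mild multimodality (stay-because-valuable vs
stay-because-sticky), which the multi-start absorbs; a vectorised
exhaustive grid (resolutions 0.02 / 0.2 / 0.2) cross-checks the
optimiser in the test suite and never beats it by more than 0.05 log
units on 20-trial sessions.

Fits on fewer than max(10, 3k) trials are flagged unreliable rather
than refused — phase-level trial counts can be as low as ~10 — and both
phase-level and session-level scopes are supported, the session level
being the robust default. Model comparison uses AIC = 2k − 2 log L
(k = 2 for RL, 3 for PRL); ties prefer the simpler RL model. The
predicted-observed correlation is Pearson's r between the 0/1
right-choice indicator and P(right) (identical to the point-biserial
form), returned as undefined when either series is constant.

The optimiser's inner objective is a numba-compiled copy of the
readable scalar recursion in `models.py`; a unit test pins the two to
1e−10 agreement.

## Behavioral metrics

Phases are re-derived from the choices via the reversal criterion — the
logged block indices are reconciled against the derivation and a
conflict is an error, not silently trusted. TTC is the block length
when the block completed; the censored final block of a
duration-capped session is exported as missing with a censor flag
(mixing censored and complete counts would bias phase comparisons).
The perseverance rate counts consecutive within-phase pairs with the
same choice side — matching the model's C indicators — and never spans
a reversal, where rule change and stickiness would be conflated. Blank
pokes are counted at wells never cued in the session (L1, L3, L6, L8
for either test separation); latency aggregates use the median (robust
to reaction-time skew) with the mean also exported, and missing
latencies are excluded, never imputed.

## Locomotion pipeline

Per frame, the centre of mass is the mean of the body-part estimates
with confidence ≥ 0.6 (the threshold is ordinary tracking hygiene and
configurable). Estimates outside the arena rectangle are removed, gaps
of at most 100 ms are bridged linearly (longer gaps stay invalid), and
the series is smoothed with a 10-sample centred moving average,
NaN-aware and count-normalised at the edges. Removal →
interpolation → smoothing is the default order so the boxcar never
straddles an open gap; the order is configurable. Speed is
√(Δx² + Δy²)/Δt on consecutive valid samples (first sample undefined),
and the per-trial summary is the mean of valid speeds inside
[t_start, t_end] with the coverage fraction reported; an empty overlap
is flagged missing.

## Synthetic cohorts

The generator emulates the crossed test design: each animal runs one
session per separation × treatment crossing, ordered by a 4×4 Latin
square over animals (exact day-balance when the cohort size is a
multiple of 4), defaulting to 11 animals / 44 sessions. Choices come
from PRL agents at base parameters α = 0.4, β = 5, δ = 0.5 — a fast,
clearly value-driven, mildly perseverative learner, a plausible regime
for well-trained rats on a two-alternative task — with per-animal
uniform jitter (α ± 0.05, β ± 20 %, δ ± 0.3) for between-animal
variance. The treatment effect is encoded mechanistically, not as an
outcome rewrite: under CNO the acquisition block runs at β × 0.6 and
δ − 1.0 (reduced reward sensitivity and a net shift into alternation,
δ ≈ −0.5), later blocks at base parameters, so the
acquisition-selective deficit must emerge through the generative
model. The base δ is deliberately mild: perseverance interacts with
acquisition in both directions (it prolongs an initial wrong-side run
as much as it stabilises a correct one), and only when the CNO shift
crosses zero into genuine alternation does the treatment reproduce the
alternation-driven slowing of acquisition that it is meant to encode —
an agent that deliberately switches sides cannot assemble 9-of-10
correct runs. Acquisition TTC is integer and floor-heavy (minimum 9),
so median comparisons between arms are made on a few pooled seeded
cohorts rather than a single 44-session cohort. Latencies are log-normal (median
1.5 s, σ_log 0.4) and exist only to exercise the duration cap and the
latency metrics; blank pokes are Poisson (0.1/trial) over non-cued
wells.

Tracking traces place the animal at the central well between trials,
move it to the chosen well over the trial window with smoothstep
easing, and return it during the ITI, sampling at 25 fps (0.04 s);
body parts are fixed zero-sum offsets from the trajectory plus
isotropic Gaussian jitter, so the noise-free centre of mass passes
exactly through the well centres.

What the generator does **not** emulate: within-session learning-set
effects, motivational drift, latency–accuracy coupling, posture change
at the wells, or tracking failure modes beyond white noise and
out-of-arena outliers. Passing tests therefore demonstrate that the
analysis chain is correct and internally consistent under the assumed
generative model — not that real animals obey that model.

## Problem sizes and numerical choices

The simulation experiments use: 100 sessions × 200 trials for
parameter recovery (50 each at δ = ±1.5) and per model-selection rate;
30 sessions × 120 trials per δ level for the perseverance linkage; the
11-animal default cohort for the CNO/VEH TTC comparison; 2–3 20-trial
sessions for the grid cross-check (520k grid points each). At these
sizes the full suite runs in well under a minute after JIT warm-up.
Ties: AIC ties prefer RL; equal-logit choice probability is exactly
0.5. Degenerate inputs: empty sessions give log-likelihood 0 (flagged,
not an error), zero-poke distributions and constant-series correlations
are returned flagged-undefined, and zero-trial fits are refused.

## Known limitations

* Generative parameter magnitudes for real rats are unknown; the
  defaults are package choices, and recovered values from real data
  should be interpreted relative to the fitting bounds.
* Only the two models used here are implemented — no forgetting,
  lapse, or hierarchical variants.
* The medium-separation geometry is reported as derived from the well
  indices (12 cm); protocols sometimes quote a different nominal
  distance for those pairs, and the engine deliberately keeps the
  index-derived value.
* Phase-level fits on short phases (TTC ≈ 10) are flagged unreliable;
  treat them as exploratory.
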