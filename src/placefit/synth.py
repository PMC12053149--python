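"""Synthetic cohorts: simulated sessions plus noisy tracking traces.

No animal data ship with the package, so cohorts with the statistical
structure the analysis assumes are generated here: each animal is tested
once on every crossing of separation (small, large) x treatment (VEH,
CNO) in a counterbalanced (Latin-square) day order, with choices produced
by a perseverance-RL agent at per-animal jittered parameters.  Treatment
effects are encoded as parameter shifts — by default an acquisition-phase
reduction of reward sensitivity (beta x 0.6) and of the perseverance
weight (delta - 1.0) under CNO — so any behavioral deficit emerges
through the generative model rather than being written into the
outcomes.

Tracking traces are 25-fps trajectories that move from the central
initiation well to the chosen well over each trial and back during the
inter-trial interval, with per-body-part offsets and isotropic Gaussian
jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .records import BODY_PARTS, Session, SessionMeta
from .task import (CENTRAL_WELL_XY, PRLAgent, TaskConfig, run_session,
                   test_config, well_position)

#: Default generative parameters: a moderately fast learner (alpha), a
#: clearly value-driven chooser (beta) and mild perseverance (delta).
#: The mild delta matters: the CNO acquisition shift (delta - 1.0) then
#: crosses into net alternation, the behavioral signature the treatment
#: effect encodes.
DEFAULT_PARAMS = {"alpha": 0.4, "beta": 5.0, "delta": 0.5}

#: Acquisition-only CNO effect: reduced reward sensitivity and a shift
#: toward alternation.
DEFAULT_CNO_EFFECT = {"beta_scale": 0.6, "delta_shift": -1.0}

#: Per-animal heterogeneity (uniform jitter half-widths; beta is relative).
DEFAULT_JITTER = {"alpha": 0.05, "beta_rel": 0.20, "delta": 0.3}

CONDITIONS = [("small", "VEH"), ("small", "CNO"), ("large", "VEH"), ("large", "CNO")]

# 4x4 Latin square of condition indices: cohort c tests condition
# LATIN[c][d] on day d, so each condition occupies each day position once
# across the four cohorts.
LATIN = [(0, 1, 2, 3), (1, 2, 3, 0), (2, 3, 0, 1), (3, 0, 1, 2)]


@dataclass
class Scenario:
    """Design of one synthetic cohort."""

    n_animals: int = 11
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    cno_effect: dict = field(default_factory=lambda: dict(DEFAULT_CNO_EFFECT))
    jitter: dict = field(default_factory=lambda: dict(DEFAULT_JITTER))
    seed: int = 0
    name: str = "default"

    def __post_init__(self) -> None:
        if self.n_animals <= 0:
            raise ValueError("n_animals must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def paper_default_scenario(seed: int = 0) -> Scenario:
    """11 animals x 4 conditions (44 sessions) at the default parameters."""
    return Scenario(n_animals=11, seed=seed, name="paper_default")


def _animal_params(rng: np.random.Generator, base: dict, jitter: dict) -> dict:
    return {
        "alpha": float(np.clip(base["alpha"] + rng.uniform(-1, 1) * jitter["alpha"], 0.0, 1.0)),
        "beta": float(max(0.0, base["beta"] * (1 + rng.uniform(-1, 1) * jitter["beta_rel"]))),
        "delta": float(base["delta"] + rng.uniform(-1, 1) * jitter["delta"]),
    }


def generate_cohort(scenario: Scenario) -> tuple[list[Session], pd.DataFrame]:
    """Simulate every animal x condition session; return sessions + ground truth.

    The truth table is keyed like the fitting scope (animal, separation,
    treatment, phase) and records the generative parameters in force
    during the acquisition phase ('Acq') and during all later blocks
    ('post'), which differ only under CNO.  Fully reproducible from
    ``scenario.seed``.
    """
    sessions: list[Session] = []
    truth_rows = []
    for a in range(scenario.n_animals):
        rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, a, 7919]))
        base = _animal_params(rng, scenario.params, scenario.jitter)
        animal_id = f"A{a + 1:02d}"
        order = LATIN[a % len(LATIN)]
        for day, cond_idx in enumerate(order, start=1):
            separation, treatment = CONDITIONS[cond_idx]
            acq = dict(base)
            if treatment == "CNO":
                acq["beta"] = base["beta"] * scenario.cno_effect["beta_scale"]
                acq["delta"] = base["delta"] + scenario.cno_effect["delta_shift"]
            agent = PRLAgent(
                alpha=base["alpha"], beta=base["beta"], delta=base["delta"],
                block_overrides={0: (acq["alpha"], acq["beta"], acq["delta"])},
            )
            cfg = test_config(separation)
            meta = SessionMeta(animal_id=animal_id, separation=separation,
                               treatment=treatment, test_day=day)
            seed = int(np.random.SeedSequence([scenario.seed, a, cond_idx]).generate_state(1)[0] % (2**31))
            sessions.append(run_session(agent, cfg, seed=seed, meta=meta))
            for phase, p in (("Acq", acq), ("post", base)):
                truth_rows.append({
                    "animal": animal_id, "separation": separation,
                    "treatment": treatment, "test_day": day, "phase": phase,
                    "alpha": p["alpha"], "beta": p["beta"], "delta": p["delta"],
                    "session_seed": seed,
                })
    return sessions, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# tracking traces

_PART_OFFSETS = {
    # cm offsets of each labelled part from the centre of mass; they sum
    # to zero so the noise-free part average reproduces the trajectory.
    "body_center": (0.0, 0.0),
    "left_shoulder": (-1.5, 1.0),
    "right_shoulder": (1.5, 1.0),
    "neck_base": (0.0, 2.0),
    "snout": (0.0, 4.0),
    "tail_base": (0.0, -8.0),
}

FPS = 25.0


def generate_tracking(session: Session, noise_cm: float = 0.3, seed: int = 0,
                      fps: float = FPS, config: TaskConfig | None = None) -> pd.DataFrame:
    """25-fps tracking table consistent with the session's trial windows.

    The animal sits at the central well between trials, moves to the
    chosen well over [t_start, t_end] (smoothstep easing) and returns
    during the inter-trial interval.  Each body part is the trajectory
    point plus a fixed offset plus isotropic N(0, noise_cm^2) jitter;
    with ``noise_cm = 0`` the centre of mass passes exactly through the
    well centres.
    """
    if noise_cm < 0:
        raise ValueError("noise_cm must be non-negative")
    if not session.trials:
        raise ValueError("session has no trials")
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    cx, cy = CENTRAL_WELL_XY

    # waypoints: (time, x, y)
    waypoints = [(0.0, cx, cy)]
    for tr in session.trials:
        wx, wy = well_position(tr.choice_well, config)
        waypoints.append((tr.t_start_s, cx, cy))
        waypoints.append((tr.t_end_s, wx, wy))
        waypoints.append((tr.t_end_s + 0.6 * config.iti_s, cx, cy))
    t_end = waypoints[-1][0] + 1.0
    waypoints.append((t_end, cx, cy))

    wt = np.array([w[0] for w in waypoints])
    wx = np.array([w[1] for w in waypoints])
    wy = np.array([w[2] for w in waypoints])
    keep = np.concatenate([[True], np.diff(wt) > 1e-9])
    wt, wx, wy = wt[keep], wx[keep], wy[keep]

    t = np.arange(0.0, t_end, 1.0 / fps)
    # smoothstep easing within each waypoint segment
    idx = np.clip(np.searchsorted(wt, t, side="right") - 1, 0, len(wt) - 2)
    u = (t - wt[idx]) / (wt[idx + 1] - wt[idx])
    e = u * u * (3 - 2 * u)
    x = wx[idx] + e * (wx[idx + 1] - wx[idx])
    y = wy[idx] + e * (wy[idx + 1] - wy[idx])

    cols: dict[str, np.ndarray] = {"t_s": t}
    for part in BODY_PARTS:
        ox, oy = _PART_OFFSETS[part]
        cols[part + "_x"] = x + ox + rng.normal(0, noise_cm, len(t)) if noise_cm else x + ox
        cols[part + "_y"] = y + oy + rng.normal(0, noise_cm, len(t)) if noise_cm else y + oy
        cols[part + "_conf"] = rng.uniform(0.85, 1.0, len(t))
    return pd.DataFrame(cols)
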