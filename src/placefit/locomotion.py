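"""Pose-tracking coordinates -> body-speed pipeline.

Six body parts are tracked at a nominal 25 fps.  Each frame's estimates
are averaged into a centre-of-mass (X, Y); estimates outside the arena
rectangle are treated as tracking artefacts and removed; short gaps (at
most the 100 ms interpolation window) are bridged linearly; and the
series is smoothed with a 10-sample moving average.  Body speed is the
travelled distance per second,
``sqrt(dx^2 + dy^2) / dt`` (cm/s), summarised per trial over the window
from trial start to trial end.

Order of operations is removal -> interpolation -> smoothing, so the
boxcar never averages across a still-open gap; the order is
configurable.  Gaps longer than the interpolation window stay invalid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import tracking_parts
from .records import TrialRecord
from .task import ARENA_BOUNDS

CONFIDENCE_THRESHOLD = 0.6
SMOOTH_WIDTH = 10           # frame samples
INTERP_WINDOW_S = 0.1       # maximum gap bridged by interpolation


def center_of_mass(df: pd.DataFrame,
                   confidence_threshold: float = CONFIDENCE_THRESHOLD) -> pd.DataFrame:
    """Per-frame mean of the body parts with confidence >= threshold.

    Frames with no usable part are marked invalid (NaN coordinates).
    """
    parts = tracking_parts(df)
    if not parts:
        raise ValueError("tracking table contains no body-part columns")
    xs = np.column_stack([df[p + "_x"].to_numpy(float) for p in parts])
    ys = np.column_stack([df[p + "_y"].to_numpy(float) for p in parts])
    conf = np.column_stack([df[p + "_conf"].to_numpy(float) for p in parts])
    use = (conf >= confidence_threshold) & np.isfinite(xs) & np.isfinite(ys)
    with np.errstate(invalid="ignore"):
        x = np.where(use.any(1), np.nansum(np.where(use, xs, 0.0), 1) / use.sum(1), np.nan)
        y = np.where(use.any(1), np.nansum(np.where(use, ys, 0.0), 1) / use.sum(1), np.nan)
    return pd.DataFrame({"t_s": df["t_s"].to_numpy(float), "x": x, "y": y})


def _remove_out_of_bounds(com: pd.DataFrame, bounds) -> pd.DataFrame:
    xmin, xmax, ymin, ymax = bounds
    out = ~((com["x"] >= xmin) & (com["x"] <= xmax)
            & (com["y"] >= ymin) & (com["y"] <= ymax))
    com = com.copy()
    com.loc[out.fillna(True), ["x", "y"]] = np.nan
    return com


def _interpolate_gaps(com: pd.DataFrame, max_gap_s: float) -> pd.DataFrame:
    """Linearly bridge NaN runs whose time span is <= ``max_gap_s``."""
    com = com.copy()
    t = com["t_s"].to_numpy()
    for col in ("x", "y"):
        v = com[col].to_numpy(float)
        isnan = np.isnan(v)
        if not isnan.any():
            continue
        filled = np.interp(t, t[~isnan], v[~isnan]) if (~isnan).sum() >= 2 else v
        # keep long gaps (and edge gaps, which np.interp extrapolates flat) invalid
        out = v.copy()
        i = 0
        n = len(v)
        while i < n:
            if not isnan[i]:
                i += 1
                continue
            j = i
            while j < n and isnan[j]:
                j += 1
            interior = i > 0 and j < n
            if interior and (t[j] - t[i - 1]) <= max_gap_s + 1e-12:
                out[i:j] = filled[i:j]
            i = j
        com[col] = out
    return com


def boxcar_smooth(v: np.ndarray, width: int = SMOOTH_WIDTH) -> np.ndarray:
    """Centred moving average of odd/even ``width``, NaN-aware.

    Each output sample is the mean of the valid samples in the length-
    ``width`` window centred on it ('same'-mode convolution, normalised
    by the in-window valid count; for even widths the window covers
    samples ``i - width//2 .. i + width//2 - 1``).  Samples that are
    invalid on input remain invalid.
    """
    valid = np.isfinite(v)
    num = np.convolve(np.where(valid, v, 0.0), np.ones(width), mode="same")
    den = np.convolve(valid.astype(float), np.ones(width), mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~valid] = np.nan
    return out


def preprocess_trace(df: pd.DataFrame, arena_bounds=ARENA_BOUNDS,
                     confidence_threshold: float = CONFIDENCE_THRESHOLD,
                     interp_window_s: float = INTERP_WINDOW_S,
                     smooth_width: int = SMOOTH_WIDTH,
                     order: tuple[str, ...] = ("remove", "interpolate", "smooth"),
                     ) -> pd.DataFrame:
    """Full tracking-table -> centre-of-mass pipeline.

    Returns a frame with ``t_s, x, y, valid`` on the input time base.
    """
    if len(df) < smooth_width:
        raise ValueError(f"need at least {smooth_width} frames, got {len(df)}")
    com = center_of_mass(df, confidence_threshold)
    for step in order:
        if step == "remove":
            com = _remove_out_of_bounds(com, arena_bounds)
        elif step == "interpolate":
            com = _interpolate_gaps(com, interp_window_s)
        elif step == "smooth":
            com = com.assign(x=boxcar_smooth(com["x"].to_numpy(), smooth_width),
                             y=boxcar_smooth(com["y"].to_numpy(), smooth_width))
        else:
            raise ValueError(f"unknown pipeline step {step!r}")
    com["valid"] = np.isfinite(com["x"]) & np.isfinite(com["y"])
    if not com["valid"].any():
        raise ValueError("no valid frames remain after preprocessing "
                         "(all coordinates outside the arena?)")
    return com


def compute_speed(com: pd.DataFrame) -> pd.DataFrame:
    """Instantaneous body speed sqrt(dx^2 + dy^2)/dt in cm/s.

    The first sample has no predecessor and is invalid; a sample is valid
    only when it and its predecessor both have valid coordinates.
    """
    if len(com) < 2:
        raise ValueError("need at least 2 samples to compute speed")
    t = com["t_s"].to_numpy(float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("zero or negative time step between samples")
    dx = np.diff(com["x"].to_numpy(float))
    dy = np.diff(com["y"].to_numpy(float))
    speed = np.concatenate([[np.nan], np.sqrt(dx**2 + dy**2) / dt])
    valid = np.isfinite(speed)
    if "valid" in com:
        cv = com["valid"].to_numpy(bool)
        valid &= cv & np.concatenate([[False], cv[:-1]])
    speed = np.where(valid, speed, np.nan)
    return pd.DataFrame({"t_s": t, "speed_cm_s": speed, "valid": valid})


def trial_speed_summary(speed: pd.DataFrame, trial: TrialRecord) -> dict:
    """Mean valid speed over [t_start, t_end] plus the coverage fraction.

    ``missing`` is True when the trial window does not overlap the trace
    or contains no valid sample; a zero-length window is an error.
    """
    if trial.t_end_s <= trial.t_start_s:
        raise ValueError("trial window must have positive length")
    t = speed["t_s"].to_numpy(float)
    in_win = (t >= trial.t_start_s) & (t <= trial.t_end_s)
    sel = speed.loc[in_win]
    usable = sel.loc[sel["valid"].astype(bool), "speed_cm_s"]
    n_expected = int(in_win.sum())
    if n_expected == 0 or usable.empty:
        return {"trial_index": trial.trial_index, "mean_speed_cm_s": float("nan"),
                "coverage": 0.0, "missing": True}
    return {
        "trial_index": trial.trial_index,
        "mean_speed_cm_s": float(usable.mean()),
        "coverage": float(len(usable) / n_expected),
        "missing": False,
    }


def session_speed_table(speed: pd.DataFrame, trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([trial_speed_summary(speed, tr) for tr in trials])
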