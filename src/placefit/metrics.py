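"""Phase segmentation and the task's behavioral performance measures.

A session splits into contingency blocks — the acquisition phase (Acq,
before the first reversal) and R1, R2, ... in temporal order.  Block
boundaries are re-derived from the choices via the reversal criterion,
never trusted from the log.  Per phase the package computes:

* trials to criterion (TTC): trials in the block when it completed;
  exported as missing with a censor flag for an unfinished final block,
* error proportion: incorrect choices / total choices,
* perseverance rate: fraction of consecutive within-phase trial pairs
  with the same choice *side* (left/right within the cued pair) — the
  descriptive counterpart of the PRL model's delta, so pairs never span
  a reversal,
* latency aggregates (median, robust to reaction-time skew; mean too),
* blank pokes: pokes at wells never cued in the session,
* left-choice proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import LEFT, N_WELLS, Session, TrialRecord
from .task import TaskConfig, criterion_met


class SegmentationError(ValueError):
    """Logged block indices conflict with criterion-derived boundaries."""


@dataclass
class MetricBundle:
    n_trials: int
    ttc: int | None                  # None when censored
    censored: bool
    error_proportion: float
    perseverance_rate: float | None  # None when < 2 in-pair choices
    median_latency_s: float | None
    mean_latency_s: float | None
    blank_poke_count: int
    left_choice_proportion: float


@dataclass
class PhaseSegment:
    label: str                       # 'Acq' or 'R1', 'R2', ...
    block_index: int
    trial_range: tuple[int, int]     # inclusive 1-based ordinals
    completed: bool
    trials: list[TrialRecord]

    @property
    def ttc(self) -> int | None:
        return len(self.trials) if self.completed else None


def phase_label(block_index: int) -> str:
    return "Acq" if block_index == 0 else f"R{block_index}"


def segment_phases(session: Session, config: TaskConfig,
                   reconcile: bool = True) -> list[PhaseSegment]:
    """Split a session into Acq / R1 / ... blocks by re-running the criterion.

    A block is *completed* when the criterion fired on its last trial;
    the criterion event that hits the reversal cap completes its block
    and ends the session, so only a block cut short by the duration cap
    is censored.  With ``reconcile`` (default) a mismatch between the
    derived boundaries and the logged ``block_index`` raises
    :class:`SegmentationError` naming the first divergent trial.
    """
    segments: list[PhaseSegment] = []
    history: list[bool] = []
    block = 0
    start = 0
    trials = session.trials
    n = len(trials)
    for idx, tr in enumerate(trials):
        if reconcile and tr.block_index != block:
            raise SegmentationError(
                f"trial {tr.trial_index}: logged block_index {tr.block_index} "
                f"!= derived block {block}")
        history.append(tr.correct)
        if criterion_met(history, config):
            segments.append(PhaseSegment(
                label=phase_label(block), block_index=block,
                trial_range=(trials[start].trial_index, tr.trial_index),
                completed=True, trials=trials[start:idx + 1]))
            block += 1
            start = idx + 1
            history = []
    if start < n:
        segments.append(PhaseSegment(
            label=phase_label(block), block_index=block,
            trial_range=(trials[start].trial_index, trials[-1].trial_index),
            completed=False, trials=trials[start:]))
    return segments


def phase_metrics(segment: PhaseSegment, session: Session) -> MetricBundle:
    """All MetricBundle fields for one phase (session supplies blank-well set)."""
    trials = segment.trials
    if not trials:
        raise ValueError("cannot compute metrics for an empty segment")
    n = len(trials)
    n_incorrect = sum(not tr.correct for tr in trials)

    sides = [tr.choice_side for tr in trials if tr.choice_side is not None]
    pairs = list(zip(sides, sides[1:]))
    persev = sum(a == b for a, b in pairs) / len(pairs) if pairs else None

    lats = [tr.latency_s for tr in trials if tr.latency_s is not None]
    blank_wells = session.blank_wells()
    blanks = sum(sum(1 for w in tr.blank_pokes if w in blank_wells) for tr in trials)
    left_prop = (sum(s == LEFT for s in sides) / len(sides)) if sides else float("nan")

    return MetricBundle(
        n_trials=n,
        ttc=segment.ttc,
        censored=not segment.completed,
        error_proportion=n_incorrect / n,
        perseverance_rate=persev,
        median_latency_s=float(np.median(lats)) if lats else None,
        mean_latency_s=float(np.mean(lats)) if lats else None,
        blank_poke_count=int(blanks),
        left_choice_proportion=left_prop,
    )


def poke_distribution(session: Session) -> tuple[np.ndarray, bool]:
    """Per-well probability over L1..L8 of all pokes (choices + blanks).

    Returns ``(vector, defined)``: the vector sums to 1 when any poke
    occurred; with zero pokes the unnormalized all-zero vector is
    returned with ``defined=False``.
    """
    counts = np.zeros(N_WELLS)
    for tr in session.trials:
        if 1 <= tr.choice_well <= N_WELLS:
            counts[tr.choice_well - 1] += 1
        for w in tr.blank_pokes:
            counts[w - 1] += 1
    total = counts.sum()
    if total == 0:
        return counts, False
    return counts / total, True


def session_metrics_table(session: Session, config: TaskConfig) -> pd.DataFrame:
    """Tidy long-format metrics: one row per phase x metric.

    Columns: animal, separation, treatment, test_day, phase, metric,
    value, censored — the layout external statistics packages consume.
    """
    meta = session.meta
    base = {
        "animal": meta.animal_id if meta else "",
        "separation": meta.separation if meta else "",
        "treatment": meta.treatment if meta else "",
        "test_day": meta.test_day if meta else "",
    }
    rows = []
    for seg in segment_phases(session, config):
        mb = phase_metrics(seg, session)
        for metric in ("ttc", "error_proportion", "perseverance_rate",
                       "median_latency_s", "mean_latency_s",
                       "blank_poke_count", "left_choice_proportion",
                       "n_trials"):
            rows.append({**base, "phase": seg.label, "metric": metric,
                         "value": getattr(mb, metric), "censored": mb.censored})
    return pd.DataFrame(rows)


def cohort_metrics_table(sessions: list[Session], config: TaskConfig) -> pd.DataFrame:
    return pd.concat([session_metrics_table(s, config) for s in sessions],
                     ignore_index=True)
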