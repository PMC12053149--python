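"""Readers/writers for the package's tabular formats, and session validation.

Formats
-------
Trial log: one CSV per session (UTF-8, one row per trial) with the fixed
column set ``trial_index, block_index, cue_a, cue_b, rewarded_well,
choice_well, correct, rewarded, latency_s, t_start_s, t_end_s,
blank_pokes``; ``blank_pokes`` is a semicolon-joined list of well
indices, ``latency_s`` may be empty (missing latencies are never
imputed).  Session metadata travels in a sidecar JSON
(``<stem>.meta.json``).  Writing is canonical — floats use Python's
shortest round-trip repr — so read -> write reproduces a written file
byte for byte.

Tracking: a CSV with ``t_s`` plus ``<part>_x, <part>_y, <part>_conf``
column triples per body part.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import N_WELLS, Session, SessionMeta, TrialRecord
from .task import TaskConfig, criterion_met

TRIAL_COLUMNS = [
    "trial_index", "block_index", "cue_a", "cue_b", "rewarded_well",
    "choice_well", "correct", "rewarded", "latency_s", "t_start_s",
    "t_end_s", "blank_pokes",
]


class TrialLogError(ValueError):
    """Raised when a trial log fails schema or invariant validation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_trial_log(session: Session, path, write_meta: bool = True) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(TRIAL_COLUMNS)
        for tr in session.trials:
            w.writerow([
                _fmt(tr.trial_index), _fmt(tr.block_index), _fmt(tr.cue_a),
                _fmt(tr.cue_b), _fmt(tr.rewarded_well), _fmt(tr.choice_well),
                _fmt(tr.correct), _fmt(tr.rewarded), _fmt(tr.latency_s),
                _fmt(tr.t_start_s), _fmt(tr.t_end_s),
                ";".join(str(b) for b in tr.blank_pokes),
            ])
    if write_meta and (session.meta is not None or session.info):
        meta = {}
        if session.meta is not None:
            meta.update(vars(session.meta))
        meta["info"] = session.info
        path.with_suffix(".meta.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _parse_row(row: dict, rownum: int, errors: list[str]) -> TrialRecord | None:
    def geti(col, lo=None, hi=None):
        v = int(row[col])
        if lo is not None and not (lo <= v <= hi):
            raise ValueError(f"{col}={v} outside {lo}..{hi}")
        return v

    try:
        lat = row["latency_s"]
        blank_raw = row["blank_pokes"].strip()
        blanks = [int(b) for b in blank_raw.split(";")] if blank_raw else []
        for b in blanks:
            if not 1 <= b <= N_WELLS:
                raise ValueError(f"blank poke well {b} outside 1..{N_WELLS}")
        tr = TrialRecord(
            trial_index=geti("trial_index", 1, 10**9),
            block_index=geti("block_index", 0, 10**9),
            cue_a=geti("cue_a", 1, N_WELLS),
            cue_b=geti("cue_b", 1, N_WELLS),
            rewarded_well=geti("rewarded_well", 1, N_WELLS),
            choice_well=geti("choice_well", 1, N_WELLS),
            correct=bool(int(row["correct"])),
            rewarded=bool(int(row["rewarded"])),
            latency_s=float(lat) if lat.strip() else None,
            t_start_s=float(row["t_start_s"]),
            t_end_s=float(row["t_end_s"]),
            blank_pokes=blanks,
        )
    except (KeyError, ValueError) as exc:
        errors.append(f"row {rownum}: {exc}")
        return None
    return tr


def read_trial_log(path, read_meta: bool = True) -> Session:
    """Parse a trial-log CSV (plus sidecar meta JSON when present).

    Raises :class:`TrialLogError` listing every offending row when the
    schema, a domain bound, or a per-trial invariant is violated.
    """
    path = Path(path)
    errors: list[str] = []
    trials: list[TrialRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(TRIAL_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise TrialLogError([f"missing required column(s): {sorted(missing)}"])
        for rownum, row in enumerate(reader, start=2):
            tr = _parse_row(row, rownum, errors)
            if tr is not None:
                trials.append(tr)
    if errors:
        raise TrialLogError(errors)
    trials.sort(key=lambda tr: tr.trial_index)

    meta = None
    info: dict = {}
    meta_path = path.with_suffix(".meta.json")
    if read_meta and meta_path.exists():
        raw = json.loads(meta_path.read_text(encoding="utf-8"))
        info = raw.pop("info", {})
        if raw:
            meta = SessionMeta(**raw)
    session = Session(trials=trials, meta=meta, info=info)
    violations = validate_session(session)
    if violations:
        raise TrialLogError(violations)
    return session


def validate_session(session: Session, config: TaskConfig | None = None) -> list[str]:
    """Check per-trial invariants and (optionally) config caps.

    Returns a list of human-readable violations, one per broken rule,
    each naming the trial; empty iff the session is valid.  With a
    ``config``, additionally re-derives contingency blocks via the
    reversal criterion and checks the reversal cap.
    """
    v: list[str] = []
    prev_end = None
    prev_index = 0
    for tr in session.trials:
        tag = f"trial {tr.trial_index}"
        if tr.trial_index != prev_index + 1:
            v.append(f"{tag}: non-consecutive trial_index (expected {prev_index + 1})")
        prev_index = tr.trial_index
        if tr.rewarded_well not in tr.cued_pair:
            v.append(f"{tag}: rewarded-well-not-cued")
        if tr.choice_well in tr.cued_pair:
            if tr.correct != (tr.choice_well == tr.rewarded_well):
                v.append(f"{tag}: correct-flag-mismatch")
        if tr.rewarded and not tr.correct:
            v.append(f"{tag}: reward-without-correct")
        if not tr.t_start_s < tr.t_end_s:
            v.append(f"{tag}: non-positive trial duration")
        if prev_end is not None and tr.t_start_s < prev_end:
            v.append(f"{tag}: non-monotonic time")
        prev_end = tr.t_end_s
        if tr.latency_s is not None and tr.latency_s < 0:
            v.append(f"{tag}: negative latency")

    if config is not None:
        # re-derive contingency blocks from the choices; a criterion event
        # causes a switch only when further trials follow it (the event
        # that hits the reversal cap ends the session instead)
        history: list[bool] = []
        switches = 0
        block = 0
        diverged = False
        n = len(session.trials)
        for idx, tr in enumerate(session.trials):
            if not diverged and tr.block_index != block:
                v.append(f"trial {tr.trial_index}: block_index {tr.block_index} "
                         f"disagrees with derived block {block}")
                diverged = True
            history.append(tr.correct)
            if criterion_met(history, config) and idx < n - 1:
                switches += 1
                block += 1
                history = []
        if switches > config.max_reversals:
            v.append(f"session: reversal cap exceeded "
                     f"({switches} > {config.max_reversals})")
    return v


# ---------------------------------------------------------------------------
# tracking tables

def write_tracking_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_tracking_csv(path) -> pd.DataFrame:
    """Load a tracking table; validates the t_s column and part triples."""
    df = pd.read_csv(path)
    if "t_s" not in df.columns:
        raise ValueError("tracking CSV must contain a 't_s' column")
    parts = {c[:-2] for c in df.columns if c.endswith("_x")}
    for p in parts:
        for suffix in ("_y", "_conf"):
            if p + suffix not in df.columns:
                raise ValueError(f"tracking CSV missing column {p + suffix}")
    if not np.all(np.diff(df["t_s"].to_numpy()) > 0):
        raise ValueError("tracking timestamps must be strictly increasing")
    return df


def tracking_parts(df: pd.DataFrame) -> list[str]:
    return sorted(c[:-2] for c in df.columns if c.endswith("_x"))
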