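"""Core record types for the location-discrimination task.

The task presents two cued nose-poke wells out of eight (L1..L8) arranged
in a row; one well is rewarded, the other is not, and the contingency
reverses after the animal makes 9 of the last 10 choices correctly.  These
dataclasses hold one session of that task: per-trial choices, session
metadata (separation distance, treatment), and per-frame pose-tracking
coordinates.

Conventions
-----------
* Wells are 1-based, L1..L8, matching the labels printed on the box.
* Within a cued pair ``(cue_a, cue_b)`` with ``cue_a < cue_b``, the lower
  well index is the *left* side (side code 0) and the higher the *right*
  (side code 1).
* Arena coordinates are centimetres with the origin at the front-left
  corner of the box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

N_WELLS = 8

#: Centre-to-centre distance between the wells of a cued pair, in cm,
#: for each named separation level.  Distances follow from the well
#: indices at 6-cm spacing: small = L4-L5 (6 cm), medium = e.g. L1-L3
#: (12 cm), large = L2-L7 (30 cm).
SEPARATION_CM = {"small": 6.0, "medium": 12.0, "large": 30.0}

#: Cued pairs used in the test sessions.
TEST_PAIRS = {"small": (4, 5), "large": (2, 7)}

#: Wells never cued nor rewarded in either test session; nose pokes here
#: are "blank pokes".
TEST_BLANK_WELLS = (1, 3, 6, 8)

LEFT, RIGHT = 0, 1


@dataclass
class TrialRecord:
    """One binary-choice trial.

    ``correct`` means the poked well was the currently rewarded one;
    ``rewarded`` means sucrose was actually delivered, which for choice
    outcomes coincides with ``correct`` (the 20 % initiation reward of the
    pretraining rule is tracked at session level and never appears here).
    """

    trial_index: int                 # 1-based ordinal within the session
    block_index: int                 # 0 = acquisition, n = after n-th reversal
    cue_a: int                       # lower well index of the cued pair
    cue_b: int                       # higher well index of the cued pair
    rewarded_well: int
    choice_well: int
    correct: bool
    rewarded: bool
    latency_s: float | None          # stimulus onset -> poke; None if unrecorded
    t_start_s: float
    t_end_s: float
    blank_pokes: list[int] = field(default_factory=list)

    @property
    def cued_pair(self) -> tuple[int, int]:
        return (self.cue_a, self.cue_b)

    @property
    def choice_side(self) -> int | None:
        """0 (left) / 1 (right) within the cued pair, None if off-pair."""
        if self.choice_well == self.cue_a:
            return LEFT
        if self.choice_well == self.cue_b:
            return RIGHT
        return None


@dataclass
class SessionMeta:
    """Identity of one test session in the crossed design."""

    animal_id: str
    separation: str                  # 'small' | 'medium' | 'large'
    treatment: str                   # 'VEH' | 'CNO'
    test_day: int = 1
    config_ref: str = "test"

    @property
    def separation_cm(self) -> float:
        return SEPARATION_CM[self.separation]


@dataclass
class Session:
    """Ordered trials plus metadata and engine-level counters.

    ``info`` carries quantities that are not per-trial, e.g. the number of
    trial initiations and how many of them drew the 20 % initiation reward
    during pretraining-style sessions.
    """

    trials: list[TrialRecord]
    meta: SessionMeta | None = None
    info: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def cued_pair(self) -> tuple[int, int] | None:
        return self.trials[0].cued_pair if self.trials else None

    def cued_wells(self) -> set[int]:
        """Wells that were cued at least once in this session."""
        wells: set[int] = set()
        for tr in self.trials:
            wells.update(tr.cued_pair)
        return wells

    def blank_wells(self) -> set[int]:
        """Wells never cued in this session."""
        return set(range(1, N_WELLS + 1)) - self.cued_wells()


@dataclass
class TrackingFrame:
    """Per-frame pose estimate: named body parts with confidences."""

    t: float
    xy: dict[str, tuple[float, float]]       # part -> (x, y) in cm
    confidence: dict[str, float]             # part -> [0, 1]


#: Body parts labelled for pose tracking (25 fps video).  Five are named
#: landmarks; 'tail_base' completes the six-part set used for the
#: centre-of-mass estimate.
BODY_PARTS = (
    "body_center",
    "left_shoulder",
    "right_shoulder",
    "neck_base",
    "snout",
    "tail_base",
)
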