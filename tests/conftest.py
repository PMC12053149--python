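import numpy as np
import pytest

import placefit as pf


@pytest.fixture(scope="session")
def small_cfg():
    return pf.test_config("small")


@pytest.fixture(scope="session")
def prl_session(small_cfg):
    """A realistic PRL-agent session on the small-separation test config."""
    agent = pf.PRLAgent(alpha=0.4, beta=5.0, delta=1.5)
    return pf.run_session(agent, small_cfg, seed=42)


@pytest.fixture(scope="session")
def cohort():
    sessions, truth = pf.generate_cohort(pf.Scenario(n_animals=4, seed=3))
    return sessions, truth


def make_trial(i, cue_a=4, cue_b=5, rewarded_well=4, choice_well=4,
               latency=1.0, t0=None, blanks=()):
    t0 = 20.0 * i if t0 is None else t0
    correct = choice_well == rewarded_well
    return pf.TrialRecord(
        trial_index=i, block_index=0, cue_a=cue_a, cue_b=cue_b,
        rewarded_well=rewarded_well, choice_well=choice_well,
        correct=correct, rewarded=correct, latency_s=latency,
        t_start_s=t0, t_end_s=t0 + latency, blank_pokes=list(blanks),
    )
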