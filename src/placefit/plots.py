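"""Choice-raster plot for one session.

Left/right choices per trial as dots, the currently rewarded side as a
step line, reversal points marked — the standard way a reversal session
is eyeballed.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .records import Session


def plot_choice_raster(session: Session, ax=None):
    """Plot choices (dots), rewarded side (step line) and reversals (triangles)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    trials = session.trials
    x = [tr.trial_index for tr in trials]
    choice = [tr.choice_side for tr in trials]
    rewarded_side = [tr.cued_pair.index(tr.rewarded_well) for tr in trials]
    ax.plot(x, rewarded_side, drawstyle="steps-mid", lw=1.5, alpha=0.7,
            label="rewarded side")
    ax.scatter(x, choice, s=10, color="k", zorder=3, label="choice")
    for i in range(1, len(trials)):
        if trials[i].block_index != trials[i - 1].block_index:
            ax.scatter([trials[i].trial_index], [1.1], marker="v", color="k")
    ax.set_yticks([0, 1], ["left", "right"])
    ax.set_ylim(-0.3, 1.3)
    ax.set_xlabel("trial")
    if session.meta:
        ax.set_title(f"{session.meta.animal_id} {session.meta.separation}/"
                     f"{session.meta.treatment}")
    ax.legend(loc="lower right", fontsize=7)
    return ax
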