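"""Reference cohort parameters for mouse rest/activity analysis.

Published cohort-mean bout lengths (minutes) for C57BL/6 mice recorded with
passive-infrared sensors in 10-s bins, under light-dark T-cycles (LD, pooled
over T = 22/24/26 h) and constant darkness (DD, subjective day/night defined
by cosine fitting).  These means anchor the synthetic-data generator and the
analytic consistency checks; the bin-level transition probabilities follow
from them through the mean-bout relation of the two-state Markov model.
"""

from __future__ import annotations

BIN_SECONDS_DEFAULT = 10

#: Cohort-mean bout lengths in minutes, by lighting group and phase.
REFERENCE_BOUT_MIN: dict[str, dict[str, dict[str, float]]] = {
    "LD": {
        "DAY": {"rest": 4.50, "activity": 0.54},
        "NIGHT": {"rest": 1.75, "activity": 0.75},
    },
    "DD": {
        "DAY": {"rest": 4.05, "activity": 0.55},
        "NIGHT": {"rest": 2.68, "activity": 0.67},
    },
}

#: Study cohort composition: number of animals per housing condition.
STUDY_COHORTS: dict[str, int] = {"LD22": 8, "LD24": 16, "LD26": 8, "DD": 16}


def exit_prob_from_mean_bout(mean_bout_min: float, bin_seconds: int = BIN_SECONDS_DEFAULT) -> float:
    """Per-bin exit probability implied by a mean bout length in minutes.

    A state with per-bin exit probability ``p`` has geometric dwell times with
    mean ``1/p`` bins, i.e. ``bin_seconds / (60 p)`` minutes.  At 10-s bins
    this is the familiar ``1/(6 p)``.
    """
    if mean_bout_min <= 0:
        raise ValueError("mean bout length must be positive")
    return bin_seconds / (60.0 * mean_bout_min)


def mean_bout_min_from_prob(prob: float, bin_seconds: int = BIN_SECONDS_DEFAULT) -> float:
    """Mean bout length in minutes implied by a per-bin exit probability."""
    if not 0 < prob <= 1:
        raise ValueError("exit probability must lie in (0, 1]")
    return bin_seconds / (60.0 * prob)


def reference_rates(group: str, bin_seconds: int = BIN_SECONDS_DEFAULT) -> dict[str, tuple[float, float]]:
    """Per-phase ``(alpha, beta)`` implied by the reference bout means.

    ``alpha`` is the rest-to-activity probability (exit from rest), ``beta``
    the activity-to-rest probability (exit from activity); ``group`` is
    ``"LD"`` or ``"DD"``.
    """
    table = REFERENCE_BOUT_MIN[group]
    return {
        phase: (
            exit_prob_from_mean_bout(cells["rest"], bin_seconds),
            exit_prob_from_mean_bout(cells["activity"], bin_seconds),
        )
        for phase, cells in table.items()
    }
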