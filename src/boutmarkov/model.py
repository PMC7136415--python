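"""Two-state (rest/activity) Markov model with phase-dependent parameters.

The behavioral state of bin ``n+1`` depends only on the state of bin ``n``
and on the circadian phase of bin ``n``: with probability ``alpha(X)`` a
resting animal starts moving in the next bin, with probability ``beta(X)``
an active animal stops.  Both parameters may differ between DAY and NIGHT
(subjective day/night in constant darkness), so a record yields four
probabilities.  Maximum-likelihood estimation reduces to transition
counting:

    alpha(X) = #(R -> A | phase X) / #(R -> anything | phase X)
    beta(X)  = #(A -> R | phase X) / #(A -> anything | phase X)

A transition between bins ``n`` and ``n+1`` is attributed to the phase of
bin ``n`` (the conditioning variable), and pairs spanning a recording gap
are never counted.  Dwell times in each state are geometric, so the mean
bout lengths in minutes are ``bin_seconds/(60 alpha)`` for rest and
``bin_seconds/(60 beta)`` for activity (``1/(6 alpha)`` and ``1/(6 beta)``
at 10-s bins), and the stationary fraction of time spent active in a phase
is ``alpha/(alpha + beta)``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .records import (
    ACTIVE,
    DAY,
    NIGHT,
    PHASE_NAMES,
    REST,
    EncodedSequence,
    ValidationError,
)


class EstimationWarning(UserWarning):
    """A parameter could not be estimated (zero-count denominator)."""


@dataclasses.dataclass(frozen=True)
class TransitionCounts:
    """Phase-resolved 2x2 transition-count table.

    ``table[phase, s_from, s_to]`` counts adjacent-bin pairs with origin
    state ``s_from`` under ``phase`` followed by ``s_to``.
    """

    table: np.ndarray

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=np.int64)
        if table.shape != (2, 2, 2):
            raise ValidationError("transition table must have shape (2, 2, 2)")
        if (table < 0).any():
            raise ValidationError("transition counts must be non-negative")
        object.__setattr__(self, "table", table)

    def n(self, phase: int, s_from: int, s_to: int) -> int:
        return int(self.table[phase, s_from, s_to])

    def n_rr(self, phase: int) -> int:
        return self.n(phase, REST, REST)

    def n_ra(self, phase: int) -> int:
        return self.n(phase, REST, ACTIVE)

    def n_ar(self, phase: int) -> int:
        return self.n(phase, ACTIVE, REST)

    def n_aa(self, phase: int) -> int:
        return self.n(phase, ACTIVE, ACTIVE)

    @property
    def total_pairs(self) -> int:
        return int(self.table.sum())

    def __add__(self, other: "TransitionCounts") -> "TransitionCounts":
        return TransitionCounts(self.table + other.table)


def count_transitions(seq: EncodedSequence) -> TransitionCounts:
    """Count adjacent-bin state transitions, resolved by origin-bin phase.

    Pairs spanning a gap are excluded; every other adjacent pair contributes
    exactly one count, so the table total equals the number of valid pairs.
    """
    if seq.n_bins < 2:
        raise ValidationError("at least two bins are required to count transitions")
    s = seq.states
    keep = ~seq.gap_after[:-1]
    table = np.zeros((2, 2, 2), dtype=np.int64)
    np.add.at(table, (seq.phase[:-1][keep], s[:-1][keep], s[1:][keep]), 1)
    return TransitionCounts(table)


def geometric_bout_pmf(prob: float, k) -> np.ndarray | float:
    """Geometric bout-length pmf: P(length = k bins) = (1-prob)^(k-1) prob.

    ``prob`` is the per-bin exit probability of the state; the distribution
    is supported on k >= 1 with mean 1/prob bins.
    """
    if not 0 < prob <= 1:
        raise ValueError("exit probability must lie in (0, 1]")
    k_arr = np.asarray(k)
    if np.any(k_arr < 1) or np.any(k_arr != np.floor(k_arr)):
        raise ValueError("bout length k must be a positive integer")
    out = stats.geom.pmf(k_arr, prob)
    return float(out) if np.isscalar(k) or k_arr.ndim == 0 else out


class TwoStateMarkov:
    """Phase-conditional two-state Markov model bound to one encoded sequence.

    Parameters
    ----------
    seq : EncodedSequence
        The animal's A/R states with per-bin DAY/NIGHT labels.

    Examples
    --------
    >>> model = TwoStateMarkov(seq)
    >>> res = model.fit()
    >>> res.mean_rest_bout_min[DAY]
    """

    def __init__(self, seq: EncodedSequence):
        if seq.n_bins < 2:
            raise ValidationError("sequence too short to fit a Markov model")
        self.seq = seq
        self.bin_seconds = seq.bin_seconds

    @classmethod
    def from_record(cls, record, phase=None) -> "TwoStateMarkov":
        """Build from a raw count record: encode A/R and label phases.

        ``phase`` may be a PhaseAssignment/label array; when omitted, light
        flags are used for LD records and a cosinor fit for DD records.
        """
        from .phase import assign_phase
        from .records import encode

        if phase is None:
            phase = assign_phase(record)
        return cls(encode(record, phase))

    def fit(self) -> "TwoStateMarkovResults":
        counts = count_transitions(self.seq)
        return TwoStateMarkovResults(counts, self.bin_seconds, model=self)


def _safe_ratio(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.full(2, np.nan)
    for ph in (DAY, NIGHT):
        if den[ph] > 0:
            out[ph] = num[ph] / den[ph]
        else:
            warnings.warn(
                f"{what} undefined for phase {PHASE_NAMES[ph]}: no qualifying "
                "transitions; estimate reported as NaN",
                EstimationWarning,
                stacklevel=3,
            )
    return out


class TwoStateMarkovResults:
    """Fitted transition probabilities and the bout summaries they imply.

    Attributes
    ----------
    alpha, beta : ndarray, shape (2,)
        Rest->activity and activity->rest probabilities indexed by phase
        (0 = DAY, 1 = NIGHT).  NaN with an :class:`EstimationWarning` when a
        phase has no qualifying transitions.
    bse_alpha, bse_beta : ndarray
        Binomial standard errors of the estimates.
    counts : TransitionCounts
    """

    def __init__(self, counts: TransitionCounts, bin_seconds: int, model: TwoStateMarkov | None = None):
        self.counts = counts
        self.bin_seconds = int(bin_seconds)
        self.model = model
        t = counts.table.astype(float)
        n_from_r = t[:, REST, :].sum(axis=1)
        n_from_a = t[:, ACTIVE, :].sum(axis=1)
        self.alpha = _safe_ratio(t[:, REST, ACTIVE], n_from_r, "alpha")
        self.beta = _safe_ratio(t[:, ACTIVE, REST], n_from_a, "beta")
        with np.errstate(invalid="ignore", divide="ignore"):
            self.bse_alpha = np.sqrt(self.alpha * (1 - self.alpha) / n_from_r)
            self.bse_beta = np.sqrt(self.beta * (1 - self.beta) / n_from_a)
        self.nobs = counts.total_pairs
        self._n_from = np.stack((n_from_r, n_from_a))

    # -- derived summaries -------------------------------------------------
    @property
    def mean_rest_bout_min(self) -> np.ndarray:
        """Model-implied mean rest-bout length per phase, minutes."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.bin_seconds / (60.0 * self.alpha)

    @property
    def mean_activity_bout_min(self) -> np.ndarray:
        """Model-implied mean activity-bout length per phase, minutes."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.bin_seconds / (60.0 * self.beta)

    @property
    def average_activity(self) -> np.ndarray:
        """Stationary fraction of time active per phase: alpha/(alpha+beta)."""
        with np.errstate(invalid="ignore"):
            return self.alpha / (self.alpha + self.beta)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Normal-approximation confidence intervals for alpha and beta."""
        z = stats.norm.ppf(0.5 + level / 2)
        rows = []
        for name, est, se in (("alpha", self.alpha, self.bse_alpha), ("beta", self.beta, self.bse_beta)):
            for ph in (DAY, NIGHT):
                rows.append(
                    {
                        "param": name,
                        "phase": PHASE_NAMES[ph],
                        "estimate": est[ph],
                        "lower": est[ph] - z * se[ph],
                        "upper": est[ph] + z * se[ph],
                    }
                )
        return pd.DataFrame(rows)

    def params_frame(self) -> pd.DataFrame:
        """Per-phase parameter and summary table."""
        rows = []
        for ph in (DAY, NIGHT):
            rows.append(
                {
                    "phase": PHASE_NAMES[ph],
                    "alpha": self.alpha[ph],
                    "beta": self.beta[ph],
                    "se_alpha": self.bse_alpha[ph],
                    "se_beta": self.bse_beta[ph],
                    "mean_rest_bout_min": self.mean_rest_bout_min[ph],
                    "mean_activity_bout_min": self.mean_activity_bout_min[ph],
                    "average_activity": self.average_activity[ph],
                    "n_pairs_from_rest": int(self._n_from[REST, ph]),
                    "n_pairs_from_activity": int(self._n_from[ACTIVE, ph]),
                }
            )
        return pd.DataFrame(rows).set_index("phase")

    def to_dict(self) -> dict:
        """JSON-serializable summary (per-phase parameters and counts)."""
        out: dict = {"bin_seconds": self.bin_seconds, "n_pairs": self.nobs, "phases": {}}
        if self.model is not None:
            out["animal_id"] = self.model.seq.animal_id
            out["condition"] = self.model.seq.condition
        for ph in (DAY, NIGHT):
            name = PHASE_NAMES[ph]
            out["phases"][name] = {
                "alpha": _float_or_none(self.alpha[ph]),
                "beta": _float_or_none(self.beta[ph]),
                "mean_rest_bout_min": _float_or_none(self.mean_rest_bout_min[ph]),
                "mean_activity_bout_min": _float_or_none(self.mean_activity_bout_min[ph]),
                "average_activity": _float_or_none(self.average_activity[ph]),
                "counts": {
                    "n_rr": self.counts.n_rr(ph),
                    "n_ra": self.counts.n_ra(ph),
                    "n_ar": self.counts.n_ar(ph),
                    "n_aa": self.counts.n_aa(ph),
                },
            }
        return out

    def summary(self) -> str:
        """Plain-text fit summary in the style of a regression results table."""
        lines = [
            "       Two-State Rest/Activity Markov Model",
            "=" * 74,
            f"No. transition pairs: {self.nobs:>10d}    bin width: {self.bin_seconds} s",
            "-" * 74,
            f"{'phase':<7}{'alpha':>9}{'(se)':>9}{'beta':>9}{'(se)':>9}"
            f"{'rest[min]':>10}{'act[min]':>10}{'activity':>10}",
            "-" * 74,
        ]
        for ph in (DAY, NIGHT):
            lines.append(
                f"{PHASE_NAMES[ph]:<7}"
                f"{self.alpha[ph]:>9.4f}{self.bse_alpha[ph]:>9.4f}"
                f"{self.beta[ph]:>9.4f}{self.bse_beta[ph]:>9.4f}"
                f"{self.mean_rest_bout_min[ph]:>10.2f}"
                f"{self.mean_activity_bout_min[ph]:>10.2f}"
                f"{self.average_activity[ph]:>10.3f}"
            )
        lines.append("=" * 74)
        lines.append("rest[min] = bin/(60 alpha); act[min] = bin/(60 beta); "
                     "activity = alpha/(alpha+beta)")
        return "\n".join(lines)

    # -- simulation and diagnostics ---------------------------------------
    def simulate(self, phase=None, n_bins: int | None = None, seed=None,
                 initial_state: str = "stationary") -> EncodedSequence:
        """Simulate a sequence from the fitted parameters.

        By default reuses the phase track (and bin width) of the data the
        model was fit to; pass ``phase`` (per-bin labels) to override.
        """
        from .simulate import simulate_sequence

        if phase is None:
            if self.model is None:
                raise ValidationError("no bound sequence; supply a phase track")
            phase = self.model.seq.phase
        phase = np.asarray(phase)
        if n_bins is not None:
            phase = phase[:n_bins]
        return simulate_sequence(
            self.alpha, self.beta, phase,
            seed=seed, initial_state=initial_state, bin_seconds=self.bin_seconds,
        )

    def bouts(self):
        """Bouts extracted from the bound sequence."""
        from .bouts import extract_bouts

        if self.model is None:
            raise ValidationError("results are not bound to a sequence")
        return extract_bouts(self.model.seq)

    def split_half(self):
        from .diagnostics import split_half_stability

        if self.model is None:
            raise ValidationError("results are not bound to a sequence")
        return split_half_stability(self.model.seq)

    def cmi_bits(self, per_phase: bool = False):
        from .diagnostics import conditional_mutual_information

        if self.model is None:
            raise ValidationError("results are not bound to a sequence")
        return conditional_mutual_information(self.model.seq, per_phase=per_phase)

    def bout_table(self, phase: int, state: int, include_truncated: bool = False):
        from .diagnostics import bout_distribution_comparison

        return bout_distribution_comparison(self.bouts(), self, phase, state,
                                            include_truncated=include_truncated)


def _float_or_none(x: float) -> float | None:
    return None if np.isnan(x) else float(x)


def fit_markov(counts: TransitionCounts, bin_seconds: int = 10) -> TwoStateMarkovResults:
    """Results from a transition-count table alone (no bound sequence)."""
    return TwoStateMarkovResults(counts, bin_seconds)
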