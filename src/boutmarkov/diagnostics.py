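"""Model-validity checks.

Three diagnostics probe the assumptions behind the two-state Markov model:

* **Split-half stability** — if behavior is stationary within each phase,
  transition probabilities estimated from the first and second halves of a
  recording should agree; across a cohort the two halves should correlate
  strongly.
* **Conditional mutual information (CMI)** — the Markov property says the
  next state is independent of the previous state given the current one:
  I(S_{n+1}; S_{n-1} | S_n) should be near zero.  A plug-in estimate from
  empirical triple frequencies is used, in bits.
* **Bout-length distribution** — the model implies geometric bout lengths;
  the observed histogram of non-truncated bouts is tabulated against the
  geometric pmf at the fitted exit probability.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bouts import Bout, bout_lengths
from .model import (
    EstimationWarning,
    TwoStateMarkov,
    TwoStateMarkovResults,
    geometric_bout_pmf,
)
from .records import DAY, NIGHT, PHASE_NAMES, STATE_CHARS, EncodedSequence, ValidationError


@dataclasses.dataclass
class SplitHalfResult:
    """Independent fits to the first and second halves of one recording."""

    first: TwoStateMarkovResults
    second: TwoStateMarkovResults
    split_bin: int

    def table(self) -> pd.DataFrame:
        rows = []
        for name in ("alpha", "beta"):
            for ph in (DAY, NIGHT):
                rows.append(
                    {
                        "param": name,
                        "phase": PHASE_NAMES[ph],
                        "first_half": getattr(self.first, name)[ph],
                        "second_half": getattr(self.second, name)[ph],
                    }
                )
        return pd.DataFrame(rows)


def _subsequence(seq: EncodedSequence, start: int, stop: int) -> EncodedSequence:
    gap = seq.gap_after[start:stop].copy()
    if stop - start >= 1:
        gap[-1] = False
    return EncodedSequence(
        animal_id=seq.animal_id,
        bin_seconds=seq.bin_seconds,
        states=seq.states[start:stop],
        phase=seq.phase[start:stop],
        gap_after=gap,
        condition=seq.condition,
    )


def split_half_stability(seq: EncodedSequence) -> SplitHalfResult:
    """Fit the model separately to each half of the recording (midpoint split).

    Phases absent from a half yield NaN estimates with an
    :class:`EstimationWarning` rather than an error.
    """
    if seq.n_bins < 4:
        warnings.warn(
            "sequence too short for a meaningful split-half check",
            EstimationWarning,
            stacklevel=2,
        )
    mid = seq.n_bins // 2
    first = TwoStateMarkov(_subsequence(seq, 0, max(mid, 2))).fit()
    second = TwoStateMarkov(_subsequence(seq, min(mid, seq.n_bins - 2), seq.n_bins)).fit()
    return SplitHalfResult(first=first, second=second, split_bin=mid)


def split_half_correlation(seqs: Iterable[EncodedSequence]) -> dict:
    """Across-animal Pearson correlation of first- vs second-half estimates.

    Estimates are pooled over animals and phases, separately for alpha and
    beta (each animal contributes one day and one night estimate).
    """
    firsts = {"alpha": [], "beta": []}
    seconds = {"alpha": [], "beta": []}
    n_animals = 0
    for seq in seqs:
        n_animals += 1
        half = split_half_stability(seq)
        for name in ("alpha", "beta"):
            for ph in (DAY, NIGHT):
                firsts[name].append(getattr(half.first, name)[ph])
                seconds[name].append(getattr(half.second, name)[ph])
    out: dict = {"n_animals": n_animals}
    for name in ("alpha", "beta"):
        x = np.asarray(firsts[name])
        y = np.asarray(seconds[name])
        ok = np.isfinite(x) & np.isfinite(y)
        out[name] = float(np.corrcoef(x[ok], y[ok])[0, 1]) if ok.sum() >= 2 else np.nan
        out[f"n_pairs_{name}"] = int(ok.sum())
    return out


def _triple_counts(seq: EncodedSequence, phase: int | None = None) -> np.ndarray:
    s = seq.states
    valid = ~seq.gap_after[:-2] & ~seq.gap_after[1:-1]
    if phase is not None:
        valid = valid & (seq.phase[1:-1] == phase)
    counts = np.zeros((2, 2, 2))
    np.add.at(counts, (s[:-2][valid], s[1:-1][valid], s[2:][valid]), 1)
    return counts


def _cmi_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return np.nan
    p_abc = counts / n  # indices: (prev, current, next)
    p_b = p_abc.sum(axis=(0, 2))
    p_ab = p_abc.sum(axis=2)
    p_bc = p_abc.sum(axis=0)
    cmi = 0.0
    for a in range(2):
        for b in range(2):
            for c in range(2):
                p = p_abc[a, b, c]
                if p > 0:
                    cmi += p * np.log2(p * p_b[b] / (p_ab[a, b] * p_bc[b, c]))
    return float(cmi)


def conditional_mutual_information(seq: EncodedSequence, per_phase: bool = False):
    """Plug-in estimate of I(S_{n+1}; S_{n-1} | S_n), in bits.

    Triples spanning a gap are excluded; zero-count cells contribute zero.
    Non-negative up to floating-point round-off; near zero when the sequence
    is first-order Markov.  With ``per_phase=True`` returns a dict with the
    overall value and one value per phase of the middle bin.
    """
    if seq.n_bins < 3:
        raise ValidationError("at least three bins are required for the CMI check")
    overall = _cmi_from_counts(_triple_counts(seq))
    if not per_phase:
        return overall
    return {
        "overall": overall,
        "DAY": _cmi_from_counts(_triple_counts(seq, DAY)),
        "NIGHT": _cmi_from_counts(_triple_counts(seq, NIGHT)),
    }


@dataclasses.dataclass
class BoutLengthTable:
    """Observed vs model-predicted bout-length distribution for one cell."""

    state: int
    phase: int
    lengths: np.ndarray  # 1..max observed length, bins
    observed: np.ndarray  # normalized histogram
    predicted: np.ndarray  # geometric pmf at the fitted exit probability
    predicted_tail_mass: float  # model mass beyond max observed length
    n_bouts: int
    exit_prob: float

    @property
    def empty(self) -> bool:
        return self.n_bouts == 0

    def total_variation(self) -> float:
        """TV distance between observed and predicted (incl. predicted tail)."""
        return 0.5 * (
            float(np.abs(self.observed - self.predicted).sum()) + self.predicted_tail_mass
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"length_bins": self.lengths, "observed": self.observed, "predicted": self.predicted}
        )


def bout_distribution_comparison(
    bouts: Sequence[Bout],
    fit: TwoStateMarkovResults,
    phase: int,
    state: int,
    include_truncated: bool = False,
) -> BoutLengthTable:
    """Tabulate observed bout lengths against the fitted geometric law.

    Truncated bouts are excluded by default (their lengths are censored).
    Returns an empty-table sentinel when no bout qualifies.
    """
    exit_prob = float((fit.beta if state == 1 else fit.alpha)[phase])
    lengths = bout_lengths(bouts, state=state, phase=phase, include_truncated=include_truncated)
    if lengths.size == 0:
        return BoutLengthTable(
            state=state, phase=phase,
            lengths=np.array([], dtype=int), observed=np.array([]),
            predicted=np.array([]), predicted_tail_mass=np.nan,
            n_bouts=0, exit_prob=exit_prob,
        )
    kmax = int(lengths.max())
    support = np.arange(1, kmax + 1)
    observed = np.bincount(lengths, minlength=kmax + 1)[1:] / lengths.size
    if np.isnan(exit_prob):
        predicted = np.full(kmax, np.nan)
        tail = np.nan
    else:
        predicted = np.asarray(geometric_bout_pmf(exit_prob, support))
        tail = float((1 - exit_prob) ** kmax)
    return BoutLengthTable(
        state=state,
        phase=phase,
        lengths=support,
        observed=observed,
        predicted=predicted,
        predicted_tail_mass=tail,
        n_bouts=int(lengths.size),
        exit_prob=exit_prob,
    )


@dataclasses.dataclass
class DiagnosticsReport:
    """Bundle of the three validity checks for one animal."""

    split_half: SplitHalfResult
    cmi_bits: dict
    distribution_tables: dict  # (phase_name, state_char) -> BoutLengthTable

    def to_dict(self) -> dict:
        out = {
            "cmi_bits": {k: (None if np.isnan(v) else float(v)) for k, v in self.cmi_bits.items()},
            "split_half": self.split_half.table().to_dict(orient="records"),
            "bout_tables": {},
        }
        for key, tab in self.distribution_tables.items():
            out["bout_tables"]["/".join(key)] = {
                "n_bouts": tab.n_bouts,
                "exit_prob": None if np.isnan(tab.exit_prob) else tab.exit_prob,
                "total_variation": None if tab.empty else tab.total_variation(),
            }
        return out


def diagnose(seq: EncodedSequence) -> DiagnosticsReport:
    """Run all diagnostics for one encoded sequence."""
    from .bouts import extract_bouts

    res = TwoStateMarkov(seq).fit()
    bouts = extract_bouts(seq)
    tables = {}
    for ph in (DAY, NIGHT):
        for st in (0, 1):
            tables[(PHASE_NAMES[ph], STATE_CHARS[st])] = bout_distribution_comparison(
                bouts, res, ph, st
            )
    return DiagnosticsReport(
        split_half=split_half_stability(seq),
        cmi_bits=conditional_mutual_information(seq, per_phase=True),
        distribution_tables=tables,
    )
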