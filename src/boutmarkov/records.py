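"""Core containers: binned activity records and encoded A/R sequences.

The primary coordinate is the 0-based bin index; runs of bins are half-open
intervals ``[start, start + length)``.  Missing stretches of recording are
kept as *gap markers*: ``gap_after[i]`` is True when bins ``i`` and ``i+1``
are not contiguous in time, and no transition, bout or state triple is ever
counted across such a break.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Sequence

import numpy as np

# Behavioral states (per bin).
REST, ACTIVE = 0, 1
STATE_CHARS = ("R", "A")

# Circadian phases (per bin); subjective day/night under DD.
DAY, NIGHT = 0, 1
PHASE_NAMES = ("DAY", "NIGHT")

LIGHT_ON, LIGHT_OFF, LIGHT_NONE = "L", "D", ""

CONDITIONS = ("LD22", "LD24", "LD26", "DD")
CONDITION_PERIOD_H: dict[str, float | None] = {
    "LD22": 22.0,
    "LD24": 24.0,
    "LD26": 26.0,
    "DD": None,
}


class ValidationError(ValueError):
    """Raised when a record or sequence violates its structural invariants."""


def _check_gap_after(gap_after, n_bins: int) -> np.ndarray:
    if gap_after is None:
        return np.zeros(n_bins, dtype=bool)
    gap_after = np.asarray(gap_after, dtype=bool)
    if gap_after.shape != (n_bins,):
        raise ValidationError("gap_after must have one entry per bin")
    if n_bins and gap_after[-1]:
        raise ValidationError("gap_after[-1] is meaningless (no following bin)")
    return gap_after


def _segments(gap_after: np.ndarray) -> Iterator[tuple[int, int]]:
    """Yield half-open ``(start, stop)`` index ranges of gap-free runs."""
    n = len(gap_after)
    start = 0
    for i in np.flatnonzero(gap_after):
        yield start, int(i) + 1
        start = int(i) + 1
    if start < n:
        yield start, n


@dataclasses.dataclass(eq=False)
class ActivityRecord:
    """One animal's binned activity-count series.

    Parameters
    ----------
    counts : array of int
        Non-negative activity counts, one per bin.
    light : sequence of str
        Per-bin light flag: ``"L"`` (lights on), ``"D"`` (lights off) or
        ``""`` (no lighting information; constant darkness).
    condition : str
        Housing condition, one of ``LD22``, ``LD24``, ``LD26``, ``DD``.
    times_h : array of float, optional
        Bin start times in hours.  Defaults to uniform spacing at
        ``bin_seconds``; non-uniform spacing defines gaps.
    """

    animal_id: str
    counts: np.ndarray
    light: np.ndarray
    condition: str = "DD"
    bin_seconds: int = 10
    start_time_h: float = 0.0
    times_h: np.ndarray | None = None
    gap_after: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 1:
            raise ValidationError("counts must be a non-empty 1-d sequence")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64, casting="unsafe")
            if not np.array_equal(as_int, counts):
                raise ValidationError("counts must be integers")
            counts = as_int
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

        light = np.asarray(self.light, dtype="U1")
        if light.shape != counts.shape:
            raise ValidationError("light and counts must have identical length")
        bad = ~np.isin(light, (LIGHT_ON, LIGHT_OFF, LIGHT_NONE))
        if bad.any():
            raise ValidationError(f"invalid light flag {light[bad][0]!r}")
        has_none = (light == LIGHT_NONE).any()
        has_ld = (light != LIGHT_NONE).any()
        if has_none and has_ld:
            raise ValidationError("mixed L/D and empty light flags in one record")
        self.light = light

        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.condition == "DD" and has_ld:
            raise ValidationError("DD record must not carry L/D flags")
        if self.condition != "DD" and has_none:
            raise ValidationError(f"{self.condition} record must carry L/D flags for every bin")

        if int(self.bin_seconds) <= 0:
            raise ValidationError("bin_seconds must be positive")
        self.bin_seconds = int(self.bin_seconds)

        bin_h = self.bin_seconds / 3600.0
        if self.times_h is None:
            gap = _check_gap_after(self.gap_after, self.n_bins)
            times = self.start_time_h + np.arange(self.n_bins, dtype=float) * bin_h
            # shift segment starts so bins after a gap leave at least one missing bin
            if gap.any():
                offsets = np.concatenate(([0.0], np.cumsum(gap[:-1]) * bin_h))
                times = times + offsets
            self.times_h = times
            self.gap_after = gap
        else:
            times = np.asarray(self.times_h, dtype=float)
            if times.shape != counts.shape:
                raise ValidationError("times_h must have one entry per bin")
            diffs = np.diff(times)
            if (diffs <= 0).any():
                raise ValidationError("times_h must be strictly increasing")
            self.times_h = times
            if self.gap_after is None:
                gap = np.zeros(self.n_bins, dtype=bool)
                gap[:-1] = diffs > 1.5 * bin_h
                self.gap_after = gap
            else:
                self.gap_after = _check_gap_after(self.gap_after, self.n_bins)

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def duration_h(self) -> float:
        """Recorded span in hours (including gaps)."""
        return float(self.times_h[-1] - self.times_h[0]) + self.bin_seconds / 3600.0

    def segments(self) -> Iterator[tuple[int, int]]:
        return _segments(self.gap_after)


@dataclasses.dataclass
class EncodedSequence:
    """Binary behavioral-state sequence with per-bin circadian phase.

    ``states`` holds 0 (rest, ``R``) / 1 (activity, ``A``); ``phase`` holds
    0 (``DAY``) / 1 (``NIGHT``), subjective phases under DD.
    """

    animal_id: str
    bin_seconds: int
    states: np.ndarray
    phase: np.ndarray
    gap_after: np.ndarray | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        states = np.asarray(self.states)
        phase = np.asarray(self.phase)
        if states.ndim != 1 or states.size < 1:
            raise ValidationError("states must be a non-empty 1-d sequence")
        if states.dtype.kind in "US":
            states = np.asarray([STATE_CHARS.index(s) for s in states])
        if phase.dtype.kind in "US":
            phase = np.asarray([PHASE_NAMES.index(p) for p in phase])
        if phase.shape != states.shape:
            raise ValidationError("states and phase must have identical length")
        if not np.isin(states, (REST, ACTIVE)).all():
            raise ValidationError("states must be 0/R or 1/A")
        if not np.isin(phase, (DAY, NIGHT)).all():
            raise ValidationError("phase must be 0/DAY or 1/NIGHT")
        self.states = states.astype(np.uint8)
        self.phase = phase.astype(np.uint8)
        if int(self.bin_seconds) <= 0:
            raise ValidationError("bin_seconds must be positive")
        self.bin_seconds = int(self.bin_seconds)
        self.gap_after = _check_gap_after(self.gap_after, self.n_bins)
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")

    @property
    def n_bins(self) -> int:
        return int(self.states.size)

    def segments(self) -> Iterator[tuple[int, int]]:
        return _segments(self.gap_after)

    def state_chars(self) -> np.ndarray:
        return np.array(STATE_CHARS, dtype="U1")[self.states]

    def phase_names(self) -> np.ndarray:
        return np.array(PHASE_NAMES, dtype="U5")[self.phase]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EncodedSequence):
            return NotImplemented
        return (
            self.animal_id == other.animal_id
            and self.bin_seconds == other.bin_seconds
            and self.condition == other.condition
            and np.array_equal(self.states, other.states)
            and np.array_equal(self.phase, other.phase)
            and np.array_equal(self.gap_after, other.gap_after)
        )


def states_from_counts(counts: Sequence[int] | np.ndarray) -> np.ndarray:
    """Threshold counts at zero: positive count -> ACTIVE, zero -> REST."""
    return (np.asarray(counts) > 0).astype(np.uint8)


def encode(record: ActivityRecord, phase) -> EncodedSequence:
    """Encode an :class:`ActivityRecord` into an A/R sequence.

    ``phase`` may be a per-bin label array (ints or ``DAY``/``NIGHT`` names)
    or a :class:`~boutmarkov.phase.PhaseAssignment`.
    """
    labels = getattr(phase, "labels", phase)
    labels = np.asarray(labels)
    if labels.shape != record.counts.shape:
        raise ValidationError("phase labels must have one entry per bin")
    return EncodedSequence(
        animal_id=record.animal_id,
        bin_seconds=record.bin_seconds,
        states=states_from_counts(record.counts),
        phase=labels,
        gap_after=record.gap_after.copy(),
        condition=record.condition,
    )
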