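"""Bout extraction: maximal runs of one behavioral state.

A bout is one or more contiguous bins of the same state.  Bouts never span
recording gaps; within each gap-free segment rest and activity bouts
strictly alternate, so their counts in any contiguous interval differ by at
most one.  Bouts touching a segment edge (record start/end or a gap) are
flagged ``truncated``: their observed length is a lower bound, which is why
empirical bout-length histograms exclude them by default.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .records import EncodedSequence


@dataclasses.dataclass(frozen=True)
class Bout:
    state: int  # REST or ACTIVE
    start_bin: int
    length_bins: int
    phase: int  # phase label of the starting bin
    truncated: bool


def extract_bouts(seq: EncodedSequence) -> list[Bout]:
    """Run-length encode the sequence into bouts, segment by segment."""
    out: list[Bout] = []
    s = seq.states
    for seg_start, seg_stop in seq.segments():
        seg = s[seg_start:seg_stop]
        # run boundaries within the segment
        change = np.flatnonzero(np.diff(seg)) + 1
        starts = np.concatenate(([0], change))
        stops = np.concatenate((change, [len(seg)]))
        last = len(starts) - 1
        for i, (a, b) in enumerate(zip(starts, stops)):
            out.append(
                Bout(
                    state=int(seg[a]),
                    start_bin=seg_start + int(a),
                    length_bins=int(b - a),
                    phase=int(seq.phase[seg_start + int(a)]),
                    truncated=(i == 0) or (i == last),
                )
            )
    return out


def _segment_key(bouts: Sequence[Bout]) -> np.ndarray:
    """Group label per bout: bouts are in the same segment iff contiguous."""
    if not bouts:
        return np.array([], dtype=int)
    key = np.zeros(len(bouts), dtype=int)
    for i in range(1, len(bouts)):
        prev = bouts[i - 1]
        contiguous = prev.start_bin + prev.length_bins == bouts[i].start_bin
        key[i] = key[i - 1] + (0 if contiguous else 1)
    return key


def count_bouts(bouts: Iterable[Bout], phase: int | None = None) -> int:
    """Total number of bouts starting in ``phase`` (all phases when None).

    Because rest and activity alternate, only the total is meaningful; the
    per-state counts within each contiguous segment are checked to differ by
    at most one.
    """
    bouts = list(bouts)
    keys = _segment_key(bouts)
    for key in np.unique(keys):
        seg = [b for b, k in zip(bouts, keys) if k == key]
        n_a = sum(b.state == 1 for b in seg)
        n_r = len(seg) - n_a
        if abs(n_a - n_r) > 1:
            raise AssertionError("rest/activity bout counts differ by more than one")
    if phase is None:
        return len(bouts)
    return sum(b.phase == phase for b in bouts)


def bout_lengths(
    bouts: Iterable[Bout],
    state: int,
    phase: int | None = None,
    include_truncated: bool = False,
) -> np.ndarray:
    """Lengths (bins) of qualifying bouts, truncated ones excluded by default."""
    return np.array(
        [
            b.length_bins
            for b in bouts
            if b.state == state
            and (phase is None or b.phase == phase)
            and (include_truncated or not b.truncated)
        ],
        dtype=int,
    )
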