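"""Reading and writing the on-disk dialects.

Activity records are delimited text with one row per bin and columns
``time`` (hours), ``light`` (``L``/``D``, empty for constant darkness) and
``count`` — the shape of a minimal ClockLab-style export.  Encoded sequences
round-trip through a CSV with ``#``-prefixed metadata header lines.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .records import (
    CONDITION_PERIOD_H,
    LIGHT_NONE,
    ActivityRecord,
    EncodedSequence,
    PHASE_NAMES,
    STATE_CHARS,
    ValidationError,
)


class ParseError(ValueError):
    """Malformed input file; carries the 1-based file line where parsing failed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _numeric_column(raw: pd.Series, name: str) -> np.ndarray:
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"could not parse {name} value {raw.iloc[row]!r}", line=row + 2
        )  # +2: header row + 1-based
    return values.to_numpy()


def read_activity_record(
    path,
    *,
    delimiter: str = ",",
    time_col: str = "time",
    light_col: str = "light",
    count_col: str = "count",
    condition: str | None = None,
    animal_id: str | None = None,
    bin_seconds: int | None = None,
) -> ActivityRecord:
    """Read one animal's binned record from delimited text.

    The time column is in hours.  Bin spacing is checked for uniformity;
    spacings larger than 1.5x the bin width are recorded as gaps, never
    silently bridged.  An absent/empty light column marks a DD record.  When
    ``condition`` is not given it defaults to ``DD`` without light flags and
    ``LD24`` with them.
    """
    table = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, skipinitialspace=True)
    for col in (time_col, count_col):
        if col not in table.columns:
            raise ParseError(f"missing required column {col!r}")
    if table.shape[0] < 1:
        raise ParseError("file contains no data rows")

    times_h = _numeric_column(table[time_col], "time")
    counts = _numeric_column(table[count_col], "count")
    if not np.array_equal(counts, np.round(counts)):
        row = int(np.flatnonzero(counts != np.round(counts))[0])
        raise ValidationError(f"non-integer count at data row {row + 1}")
    if (counts < 0).any():
        raise ValidationError("negative activity count")

    if light_col in table.columns:
        light = table[light_col].str.strip().to_numpy(dtype="U1")
    else:
        light = np.full(len(counts), LIGHT_NONE, dtype="U1")

    diffs = np.diff(times_h)
    if (diffs <= 0).any():
        row = int(np.flatnonzero(diffs <= 0)[0])
        raise ParseError("time column must be strictly increasing", line=row + 3)
    if bin_seconds is None:
        bin_seconds = int(round(float(np.median(diffs)) * 3600)) if len(diffs) else 10

    if condition is None:
        condition = "DD" if (light == LIGHT_NONE).all() else "LD24"

    if animal_id is None:
        animal_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]

    return ActivityRecord(
        animal_id=animal_id,
        counts=counts.astype(np.int64),
        light=light,
        condition=condition,
        bin_seconds=bin_seconds,
        start_time_h=float(times_h[0]),
        times_h=times_h,
    )


def write_encoded(seq: EncodedSequence, path) -> None:
    """Write an encoded sequence as CSV with ``#`` metadata header lines.

    Output is deterministic: identical sequences produce byte-identical files.
    """
    meta = {
        "animal_id": seq.animal_id,
        "bin_seconds": seq.bin_seconds,
        "condition": seq.condition,
    }
    states = seq.state_chars()
    phases = seq.phase_names()
    with open(path, "w", newline="") as fh:
        fh.write(f"# boutmarkov-encoded {json.dumps(meta, sort_keys=True)}\n")
        fh.write("bin,state,phase,gap_after\n")
        for i in range(seq.n_bins):
            fh.write(f"{i},{states[i]},{phases[i]},{int(seq.gap_after[i])}\n")


def read_encoded(path) -> EncodedSequence:
    """Read a sequence written by :func:`write_encoded`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# boutmarkov-encoded "):
            raise ParseError("missing boutmarkov-encoded metadata header", line=1)
        meta = json.loads(header[len("# boutmarkov-encoded "):])
        table = pd.read_csv(fh)
    states = table["state"].map({c: i for i, c in enumerate(STATE_CHARS)})
    phase = table["phase"].map({p: i for i, p in enumerate(PHASE_NAMES)})
    if states.isna().any() or phase.isna().any():
        raise ParseError("unrecognized state or phase symbol")
    return EncodedSequence(
        animal_id=meta["animal_id"],
        bin_seconds=int(meta["bin_seconds"]),
        states=states.to_numpy(dtype=np.uint8),
        phase=phase.to_numpy(dtype=np.uint8),
        gap_after=table["gap_after"].to_numpy(dtype=bool),
        condition=meta.get("condition"),
    )


def nominal_period_h(condition: str) -> float | None:
    """Nominal T-cycle period for a condition (None for DD)."""
    return CONDITION_PERIOD_H[condition]
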