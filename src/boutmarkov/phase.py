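"""Circadian phase labeling.

Under a light-dark cycle the phase of every bin is given directly by the
light flags.  Under constant darkness the subjective day and night must be
inferred from the behavior itself: a cosinor (mean + cosine + sine) is fit
to the raw activity counts on a grid of candidate free-running periods, the
period maximizing variance explained is kept, and subjective *night* is the
half-cycle window centered on the acrophase — the nocturnal convention that
the activity peak lies in subjective night.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .records import (
    DAY,
    LIGHT_NONE,
    LIGHT_ON,
    NIGHT,
    ActivityRecord,
    CONDITION_PERIOD_H,
    ValidationError,
)

#: Default candidate free-running periods, hours: brackets mouse tau.
PERIOD_MIN_H, PERIOD_MAX_H, PERIOD_STEP_H = 20.0, 28.0, 0.1


class DegenerateFitError(RuntimeError):
    """Cosine fit is undefined: no variance or no rhythmic amplitude."""


@dataclasses.dataclass(eq=False)
class PhaseAssignment:
    """Per-bin DAY/NIGHT labels plus how they were obtained."""

    labels: np.ndarray
    method: str  # "light" or "cosine"
    period_h: float | None
    acrophase_h: float | None = None
    fit_quality: float | None = None
    period_grid: np.ndarray | None = None
    r2_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.method not in ("light", "cosine"):
            raise ValidationError(f"unknown phase method {self.method!r}")
        if self.method == "cosine" and not (PERIOD_MIN_H <= self.period_h <= PERIOD_MAX_H):
            raise ValidationError("fitted period outside the candidate range")

    @property
    def night_fraction(self) -> float:
        return float(np.mean(self.labels == NIGHT))


def label_from_light(record: ActivityRecord) -> PhaseAssignment:
    """DAY where lights are on (``L``), NIGHT where off (``D``)."""
    if (record.light == LIGHT_NONE).any():
        raise ValidationError(
            "record has no light flags; use fit_cosine_phase for DD records"
        )
    labels = np.where(record.light == LIGHT_ON, DAY, NIGHT).astype(np.uint8)
    return PhaseAssignment(
        labels=labels,
        method="light",
        period_h=CONDITION_PERIOD_H.get(record.condition),
    )


def fit_cosine_phase(
    record: ActivityRecord,
    period_min_h: float = PERIOD_MIN_H,
    period_max_h: float = PERIOD_MAX_H,
    period_step_h: float = PERIOD_STEP_H,
) -> PhaseAssignment:
    """Fit a cosinor to raw counts and label subjective day/night.

    For each candidate period ``T`` the model ``m + a cos(2 pi t/T) +
    b sin(2 pi t/T)`` is fit by exact linear least squares; the period with
    the highest coefficient of determination wins.  Subjective NIGHT is the
    half-period window centered on the acrophase, tiled periodically.

    Requires at least four cycles of the longest candidate period (the
    cohort inclusion rule) and a non-degenerate rhythm (rejects all-zero or
    constant counts).
    """
    t = record.times_h - record.times_h[0]
    y = record.counts.astype(float)
    span_h = record.duration_h
    if span_h < 4 * period_max_h:
        raise ValidationError(
            f"record spans {span_h:.1f} h; at least four cycles of the longest "
            f"candidate period ({4 * period_max_h:.0f} h) are required"
        )
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise DegenerateFitError("counts have zero variance; cosine fit undefined")

    periods = np.arange(period_min_h, period_max_h + 0.5 * period_step_h, period_step_h)
    r2 = np.empty(len(periods))
    coef = np.empty((len(periods), 3))
    for i, period in enumerate(periods):
        w = 2.0 * np.pi / period
        design = np.column_stack((np.ones_like(t), np.cos(w * t), np.sin(w * t)))
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        r2[i] = 1.0 - float(resid @ resid) / sst
        coef[i] = beta
    best = int(np.argmax(r2))
    period = float(periods[best])
    _, a, b = coef[best]
    amplitude = float(np.hypot(a, b))
    if amplitude <= 1e-9 * max(1.0, float(np.abs(y).max())):
        raise DegenerateFitError("fitted cosine amplitude is zero; no rhythm to phase")
    acrophase = float(np.arctan2(b, a) / (2.0 * np.pi / period) % period)

    offset = (t - acrophase) % period
    labels = np.where(
        (offset < period / 4) | (offset >= 3 * period / 4), NIGHT, DAY
    ).astype(np.uint8)
    return PhaseAssignment(
        labels=labels,
        method="cosine",
        period_h=period,
        acrophase_h=acrophase,
        fit_quality=float(r2[best]),
        period_grid=periods,
        r2_grid=r2,
    )


def assign_phase(record: ActivityRecord, method: str | None = None) -> PhaseAssignment:
    """Dispatch: light flags for LD records, cosine fit for DD."""
    if method is None:
        method = "cosine" if record.condition == "DD" else "light"
    if method == "light":
        return label_from_light(record)
    if method == "cosine":
        return fit_cosine_phase(record)
    raise ValidationError(f"unknown phase method {method!r}")
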