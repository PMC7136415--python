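"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator is the stand-in for unreleased recordings: each animal is a
phase-switched two-state Markov chain at 10-s bins, with per-animal
parameters drawn lognormally around cohort means, under an LD T-cycle
(equal light and dark halves) or constant darkness with a free-running
period near 24 h.  Cohort composition defaults mirror the study: 8/16/8
animals at T = 22/24/26 h plus 16 in DD, each recorded for a week.

Everything is reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .params import REFERENCE_BOUT_MIN, STUDY_COHORTS, exit_prob_from_mean_bout
from .records import (
    ACTIVE,
    CONDITION_PERIOD_H,
    CONDITIONS,
    DAY,
    NIGHT,
    REST,
    EncodedSequence,
    ValidationError,
)


def _per_phase(value) -> np.ndarray:
    """Normalize a probability spec (scalar, (day, night) pair, or mapping)."""
    if isinstance(value, dict):
        value = [value[k] for k in (sorted(value) if set(value) <= {0, 1} else ("DAY", "NIGHT"))]
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 2)
    if arr.shape != (2,):
        raise ValidationError("expected a scalar or per-phase (DAY, NIGHT) pair")
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValidationError("transition probabilities must lie in [0, 1]")
    return arr


def ld_phase_track(n_bins: int, period_h: float, bin_seconds: int = 10,
                   lights_on_first: bool = True) -> np.ndarray:
    """Per-bin DAY/NIGHT labels for a T-cycle with equal light and dark."""
    half_bins = int(round(period_h * 3600 / (2 * bin_seconds)))
    if half_bins < 1:
        raise ValidationError("period too short for the bin width")
    first, second = (DAY, NIGHT) if lights_on_first else (NIGHT, DAY)
    cycle = np.concatenate(
        (np.full(half_bins, first, np.uint8), np.full(half_bins, second, np.uint8))
    )
    reps = int(np.ceil(n_bins / cycle.size))
    return np.tile(cycle, reps)[:n_bins]


def dd_phase_track(n_bins: int, period_h: float, bin_seconds: int = 10,
                   start_phase: int = DAY) -> np.ndarray:
    """Subjective day/night labels tiled at the free-running period."""
    return ld_phase_track(n_bins, period_h, bin_seconds,
                          lights_on_first=(start_phase == DAY))


def simulate_sequence(
    alpha,
    beta,
    phase,
    seed=None,
    initial_state: str | int = "stationary",
    bin_seconds: int = 10,
    animal_id: str = "sim",
    condition: str | None = None,
) -> EncodedSequence:
    """Simulate a phase-switched two-state Markov chain.

    The transition out of bin ``n`` is governed by the phase of bin ``n``,
    matching the estimator's conditioning.  ``initial_state`` may be
    ``"stationary"`` (draw S_0 with P(A) = alpha/(alpha+beta) of the first
    bin's phase), ``"rest"``/``"activity"``, or an explicit 0/1.
    """
    alpha = _per_phase(alpha)
    beta = _per_phase(beta)
    phase = np.asarray(phase, dtype=np.uint8)
    n = phase.size
    if n < 1:
        raise ValidationError("phase track must cover at least one bin")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    u = rng.random(n)
    if isinstance(initial_state, str):
        key = initial_state.lower()
        if key == "stationary":
            ph0 = int(phase[0])
            denom = alpha[ph0] + beta[ph0]
            p_active = alpha[ph0] / denom if denom > 0 else 0.5
            state = ACTIVE if u[0] < p_active else REST
        elif key in ("rest", "r"):
            state = REST
        elif key in ("activity", "active", "a"):
            state = ACTIVE
        else:
            raise ValidationError(f"unknown initial_state {initial_state!r}")
    else:
        state = int(initial_state)
        if state not in (REST, ACTIVE):
            raise ValidationError("initial_state must be REST(0) or ACTIVE(1)")

    # p_switch[i]: probability of leaving the current state during bin i,
    # which depends on the state, so resolve per step in a tight loop.
    pa = alpha[phase].tolist()
    pb = beta[phase].tolist()
    uu = u.tolist()
    out = [0] * n
    out[0] = state
    for i in range(n - 1):
        if state == ACTIVE:
            if uu[i + 1] < pb[i]:
                state = REST
        else:
            if uu[i + 1] < pa[i]:
                state = ACTIVE
        out[i + 1] = state
    return EncodedSequence(
        animal_id=animal_id,
        bin_seconds=bin_seconds,
        states=np.asarray(out, dtype=np.uint8),
        phase=phase,
        condition=condition,
    )


@dataclasses.dataclass
class SimulationConfig:
    """Cohort-level generating conditions.

    ``record_days`` is measured in 24-h days (total duration =
    ``record_days * 24`` h) and must give at least four cycles of the
    condition's period — the study's inclusion rule.  ``inter_animal_cv``
    is the lognormal coefficient of variation applied independently to each
    animal's alpha and beta.

    LD cohorts admit only entrained animals, as the study design requires:
    a draw whose implied day/night average-activity ratio exceeds
    ``entrainment_fold_max`` (day activity not clearly below night) is
    rejected and redrawn.  The default 0.6 is lenient relative to the
    reported cohort ratios (~0.35-0.40); set to None to disable.
    """

    seed: int
    n_animals: int
    condition: str
    alpha_day: float
    beta_day: float
    alpha_night: float
    beta_night: float
    record_days: float = 7.0
    bin_seconds: int = 10
    inter_animal_cv: float = 0.2
    dd_period_h: float = 23.8
    dd_period_sd_h: float = 0.15
    initial_state: str = "stationary"
    entrainment_fold_max: float | None = 0.6

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        for name in ("alpha_day", "beta_day", "alpha_night", "beta_night"):
            p = getattr(self, name)
            if not 0 < p < 1:
                raise ValidationError(f"{name}={p} must lie in (0, 1)")
        if self.n_animals < 1:
            raise ValidationError("n_animals must be at least 1")
        if self.inter_animal_cv < 0:
            raise ValidationError("inter_animal_cv must be non-negative")
        period = CONDITION_PERIOD_H[self.condition] or self.dd_period_h
        if self.record_days * 24.0 < 4 * period:
            raise ValidationError(
                "record must span at least four cycles of the condition period"
            )

    @property
    def n_bins(self) -> int:
        return int(round(self.record_days * 24 * 3600 / self.bin_seconds))


def default_config(condition: str, n_animals: int | None = None, seed: int = 0,
                   **overrides) -> SimulationConfig:
    """Config at the reference cohort parameters for a condition."""
    group = "DD" if condition == "DD" else "LD"
    ref = REFERENCE_BOUT_MIN[group]
    bin_seconds = int(overrides.pop("bin_seconds", 10))
    return SimulationConfig(
        seed=seed,
        n_animals=STUDY_COHORTS[condition] if n_animals is None else n_animals,
        condition=condition,
        alpha_day=exit_prob_from_mean_bout(ref["DAY"]["rest"], bin_seconds),
        beta_day=exit_prob_from_mean_bout(ref["DAY"]["activity"], bin_seconds),
        alpha_night=exit_prob_from_mean_bout(ref["NIGHT"]["rest"], bin_seconds),
        beta_night=exit_prob_from_mean_bout(ref["NIGHT"]["activity"], bin_seconds),
        bin_seconds=bin_seconds,
        **overrides,
    )


@dataclasses.dataclass
class CohortSim:
    """Simulated cohort: sequences plus the generating truths per animal."""

    sequences: list[EncodedSequence]
    truths: pd.DataFrame
    config: SimulationConfig | None = None


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and cv; clipped to (0,1)."""
    if cv == 0:
        return np.full(size, mean)
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean) - sigma**2 / 2
    draws = rng.lognormal(mu, sigma, size)
    return np.clip(draws, 1e-9, 1 - 1e-9)


def _draw_animal_params(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """One animal's (alpha_day, alpha_night, beta_day, beta_night).

    LD draws are rejected (and redrawn) while the implied day/night
    average-activity ratio is not clearly below one — the entrainment
    requirement for inclusion.
    """
    cv = config.inter_animal_cv
    check_entrainment = (
        config.condition != "DD"
        and config.entrainment_fold_max is not None
        and cv > 0
    )
    while True:
        ad = _lognormal_around(rng, config.alpha_day, cv, 1)[0]
        an = _lognormal_around(rng, config.alpha_night, cv, 1)[0]
        bd = _lognormal_around(rng, config.beta_day, cv, 1)[0]
        bn = _lognormal_around(rng, config.beta_night, cv, 1)[0]
        if not check_entrainment:
            return np.array([ad, an, bd, bn])
        fold = (ad / (ad + bd)) / (an / (an + bn))
        if fold < config.entrainment_fold_max:
            return np.array([ad, an, bd, bn])


def simulate_cohort(config: SimulationConfig) -> CohortSim:
    """Simulate one condition's cohort, returning data and truths."""
    ss = np.random.SeedSequence(config.seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    animal_streams = ss.spawn(config.n_animals + 1)[1:]

    n = config.n_animals
    params = np.array([_draw_animal_params(param_rng, config) for _ in range(n)])
    alpha = params[:, :2]
    beta = params[:, 2:]
    nominal = CONDITION_PERIOD_H[config.condition]
    if nominal is None:
        periods = config.dd_period_h + config.dd_period_sd_h * param_rng.standard_normal(n)
    else:
        periods = np.full(n, nominal)

    sequences = []
    rows = []
    for i in range(n):
        animal_id = f"{config.condition}_{i + 1:02d}"
        if nominal is None:
            phase = dd_phase_track(config.n_bins, periods[i], config.bin_seconds)
        else:
            phase = ld_phase_track(config.n_bins, periods[i], config.bin_seconds)
        seq = simulate_sequence(
            alpha[i],
            beta[i],
            phase,
            seed=np.random.default_rng(animal_streams[i]),
            initial_state=config.initial_state,
            bin_seconds=config.bin_seconds,
            animal_id=animal_id,
            condition=config.condition,
        )
        sequences.append(seq)
        rows.append(
            {
                "animal_id": animal_id,
                "condition": config.condition,
                "alpha_day": alpha[i, DAY],
                "alpha_night": alpha[i, NIGHT],
                "beta_day": beta[i, DAY],
                "beta_night": beta[i, NIGHT],
                "period_h": periods[i],
            }
        )
    return CohortSim(sequences=sequences, truths=pd.DataFrame(rows), config=config)


def simulate_study(seed: int = 0, record_days: float = 7.0,
                   inter_animal_cv: float = 0.2) -> CohortSim:
    """Simulate the full study composition: 8 + 16 + 8 LD animals + 16 DD."""
    child = np.random.SeedSequence(seed).generate_state(len(STUDY_COHORTS)) % (2**31)
    sequences: list[EncodedSequence] = []
    truths = []
    for sub_seed, condition in zip(child, STUDY_COHORTS):
        cohort = simulate_cohort(
            default_config(
                condition,
                seed=int(sub_seed),
                record_days=record_days,
                inter_animal_cv=inter_animal_cv,
            )
        )
        sequences.extend(cohort.sequences)
        truths.append(cohort.truths)
    return CohortSim(sequences=sequences, truths=pd.concat(truths, ignore_index=True))
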