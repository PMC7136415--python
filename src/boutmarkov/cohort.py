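"""Cohort-level summaries: fold changes, ratios and bootstrap intervals.

All cohort aggregation is multiplicative: per-animal quantities (mean bout
lengths, average activity, bout counts) are summarized by geometric means,
day/night contrasts by within-animal ratios, and 95% confidence intervals
by a seeded animal-level nonparametric bootstrap (2000 resamples).  This
preserves the estimands of the study design — paired fold changes with
intervals — while staying self-contained.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .bouts import count_bouts, extract_bouts
from .model import TwoStateMarkovResults
from .records import DAY, NIGHT, PHASE_NAMES, ValidationError

N_BOOT_DEFAULT = 2000

#: Per-animal, per-phase quantities summarized at the cohort level.
QUANTITIES = ("average_activity", "mean_rest_bout_min", "mean_activity_bout_min", "total_bouts")


def per_animal_table(
    fits: Sequence[TwoStateMarkovResults],
    conditions: Sequence[str] | None = None,
    animal_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format table: one row per animal x phase with model summaries.

    ``conditions``/``animal_ids`` default to the metadata of the sequence
    each fit is bound to.
    """
    rows = []
    for i, fit in enumerate(fits):
        seq = fit.model.seq if fit.model is not None else None
        condition = conditions[i] if conditions is not None else (seq.condition if seq else None)
        animal = animal_ids[i] if animal_ids is not None else (seq.animal_id if seq else f"animal_{i}")
        if condition is None:
            raise ValidationError("condition unknown; pass conditions explicitly")
        bouts = extract_bouts(seq) if seq is not None else None
        for ph in (DAY, NIGHT):
            rows.append(
                {
                    "animal_id": animal,
                    "condition": condition,
                    "group": "DD" if condition == "DD" else "LD",
                    "phase": PHASE_NAMES[ph],
                    "average_activity": fit.average_activity[ph],
                    "mean_rest_bout_min": fit.mean_rest_bout_min[ph],
                    "mean_activity_bout_min": fit.mean_activity_bout_min[ph],
                    "total_bouts": count_bouts(bouts, ph) if bouts is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _geo_point_ci(log_values: np.ndarray, rng: np.random.Generator, n_boot: int):
    """Geometric mean and bootstrap percentile CI from per-animal logs."""
    log_values = log_values[np.isfinite(log_values)]
    n = log_values.size
    if n == 0:
        return np.nan, np.nan, np.nan, 0
    point = float(np.exp(log_values.mean()))
    idx = rng.integers(0, n, size=(n_boot, n))
    reps = np.exp(log_values[idx].mean(axis=1))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, float(lo), float(hi), n


@dataclasses.dataclass
class CohortSummary:
    """Cohort summaries: per-animal values plus derived contrast tables."""

    per_animal: pd.DataFrame
    fold_day_night: pd.DataFrame  # quantity x condition group: day/night ratio
    rest_activity_ratio: pd.DataFrame  # phase x group: rest/activity bout ratio
    dd_ld_contrast: pd.DataFrame  # quantity: DD fold / pooled-LD fold
    n_boot: int
    seed: int


def _wide(per_animal: pd.DataFrame, quantity: str) -> pd.DataFrame:
    wide = per_animal.pivot_table(
        index=["animal_id", "condition", "group"], columns="phase", values=quantity,
        dropna=False,
    )
    for name in PHASE_NAMES:  # keep both phases even when all-NaN
        if name not in wide.columns:
            wide[name] = np.nan
    return wide.reset_index()


def _groups(per_animal: pd.DataFrame):
    """(label, mask) pairs: each condition, pooled LD, and all."""
    out = []
    for cond in pd.unique(per_animal["condition"]):
        out.append((cond, per_animal["condition"] == cond))
    if (per_animal["group"] == "LD").any() and per_animal[per_animal["group"] == "LD"]["condition"].nunique() > 1:
        out.append(("LD", per_animal["group"] == "LD"))
    return out


def summarize_cohort(
    fits: Sequence[TwoStateMarkovResults],
    conditions: Sequence[str] | None = None,
    animal_ids: Sequence[str] | None = None,
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
) -> CohortSummary:
    """Aggregate per-animal Markov fits into cohort contrast tables.

    Requires at least two animals.  Per-animal entries that are undefined
    (NaN from empty phases) are excluded, with the effective n reported in
    each table row.
    """
    if len(fits) < 2:
        raise ValidationError("cohort summaries require at least two animals")
    per_animal = per_animal_table(fits, conditions, animal_ids)
    rng = np.random.default_rng(seed)

    fold_rows = []
    for quantity in QUANTITIES:
        wide = _wide(per_animal, quantity)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_ratio = np.log(wide["DAY"].to_numpy() / wide["NIGHT"].to_numpy())
        for label, mask in _groups(per_animal):
            sel = wide["condition"].eq(label) if label != "LD" else wide["group"].eq("LD")
            point, lo, hi, n = _geo_point_ci(log_ratio[sel.to_numpy()], rng, n_boot)
            fold_rows.append(
                {
                    "quantity": quantity,
                    "group": label,
                    "fold_day_night": point,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n_animals": n,
                }
            )
    fold_day_night = pd.DataFrame(fold_rows)

    ratio_rows = []
    rest = _wide(per_animal, "mean_rest_bout_min")
    act = _wide(per_animal, "mean_activity_bout_min")
    for phase in PHASE_NAMES:
        with np.errstate(divide="ignore", invalid="ignore"):
            log_ratio = np.log(rest[phase].to_numpy() / act[phase].to_numpy())
        for label, mask in _groups(per_animal):
            sel = rest["condition"].eq(label) if label != "LD" else rest["group"].eq("LD")
            point, lo, hi, n = _geo_point_ci(log_ratio[sel.to_numpy()], rng, n_boot)
            ratio_rows.append(
                {
                    "phase": phase,
                    "group": label,
                    "rest_activity_ratio": point,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n_animals": n,
                }
            )
    rest_activity_ratio = pd.DataFrame(ratio_rows)

    contrast_rows = []
    has_both = (per_animal["group"] == "DD").any() and (per_animal["group"] == "LD").any()
    if has_both:
        for quantity in QUANTITIES:
            wide = _wide(per_animal, quantity)
            with np.errstate(divide="ignore", invalid="ignore"):
                log_ratio = np.log(wide["DAY"].to_numpy() / wide["NIGHT"].to_numpy())
            dd = log_ratio[wide["group"].eq("DD").to_numpy()]
            ld = log_ratio[wide["group"].eq("LD").to_numpy()]
            dd = dd[np.isfinite(dd)]
            ld = ld[np.isfinite(ld)]
            if dd.size == 0 or ld.size == 0:
                continue
            point = float(np.exp(dd.mean() - ld.mean()))
            reps = np.exp(
                dd[rng.integers(0, dd.size, size=(n_boot, dd.size))].mean(axis=1)
                - ld[rng.integers(0, ld.size, size=(n_boot, ld.size))].mean(axis=1)
            )
            lo, hi = np.percentile(reps, [2.5, 97.5])
            contrast_rows.append(
                {
                    "quantity": quantity,
                    "dd_over_ld_fold_ratio": point,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "n_dd": int(dd.size),
                    "n_ld": int(ld.size),
                }
            )
    dd_ld_contrast = pd.DataFrame(
        contrast_rows,
        columns=["quantity", "dd_over_ld_fold_ratio", "ci_low", "ci_high", "n_dd", "n_ld"],
    )

    return CohortSummary(
        per_animal=per_animal,
        fold_day_night=fold_day_night,
        rest_activity_ratio=rest_activity_ratio,
        dd_ld_contrast=dd_ld_contrast,
        n_boot=n_boot,
        seed=seed,
    )


def night_day_activity_report(summary: CohortSummary) -> pd.DataFrame:
    """Day/night average-activity fold per condition, with disjoint-CI flags.

    A condition is flagged when its CI excludes the point estimate of every
    other condition and vice versa (a conservative screen for differing
    day-night modulation).
    """
    table = summary.fold_day_night.query("quantity == 'average_activity'").copy()
    table = table[~table["group"].isin(["LD"])].reset_index(drop=True)
    flags = []
    for i, row in table.iterrows():
        others = table.drop(index=i)
        disjoint = bool(
            ((others["ci_high"] < row["ci_low"]) | (others["ci_low"] > row["ci_high"])).all()
        ) if len(others) else False
        flags.append(disjoint)
    table["ci_disjoint_from_others"] = flags
    return table.drop(columns="quantity")
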