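"""Data preparation for chart construction.

Covers WHO BMI grouping, the early/mid/late measurement-window selection,
gain computation, the week-0 variance nudge, the +20 kg positivity offset and
the uncomplicated-pregnancy subset filter.

The week-0 nudge exists because every woman's gain at 0 weeks is identically
zero (weight at week 0 *is* the pre-pregnancy weight); a distributional fit
cannot accommodate a zero-variance outcome, so the zero is replaced by a
Gaussian draw whose variance equals that of the difference of two independent
dial weighings (2 * 0.70^2 = 0.98 kg^2).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort_io import CohortTable, WeightObservation, WomanRecord

__all__ = [
    "BMIGroup",
    "GainRecord",
    "ShiftedGainRecord",
    "GainTable",
    "MEASUREMENT_ERROR_SD",
    "GAIN_OFFSET_KG",
    "WINDOWS",
    "nudge_variance",
    "classify_bmi",
    "select_window_measurements",
    "build_gain_table",
    "apply_nudge",
    "apply_offset",
    "filter_uncomplicated",
]

#: sd of a single dial weight measurement, kg
MEASUREMENT_ERROR_SD = 0.70

#: offset added to gains before fitting so the outcome is strictly positive
GAIN_OFFSET_KG = 20.0

#: (target week, window lower bound, window upper bound) for early/mid/late
WINDOWS = {
    "early": (13.0, 6.0, 19.9),
    "mid": (26.0, 20.0, 31.9),
    "late": (40.0, 32.0, 45.0),
}


def nudge_variance() -> float:
    """Variance of the week-0 gain nudge, kg^2.

    A gain is the difference of two weighings, each with measurement sd
    0.70 kg, so the variance is 0.70^2 + 0.70^2.
    """
    return MEASUREMENT_ERROR_SD**2 + MEASUREMENT_ERROR_SD**2


class BMIGroup(enum.Enum):
    """WHO pre-pregnancy BMI classes (kg/m^2), partitioning (0, inf)."""

    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE1 = "obese1"
    OBESE2 = "obese2"
    OBESE3 = "obese3"


# half-open [lower, upper) boundaries; printed one-decimal ranges like
# "18.5-24.9" leave gaps on a continuum, so 24.95 must still classify
_BMI_EDGES: list[tuple[float, BMIGroup]] = [
    (18.5, BMIGroup.UNDERWEIGHT),
    (25.0, BMIGroup.NORMAL),
    (30.0, BMIGroup.OVERWEIGHT),
    (35.0, BMIGroup.OBESE1),
    (40.0, BMIGroup.OBESE2),
    (math.inf, BMIGroup.OBESE3),
]

#: BMI interval [low, high) per group, for simulation and documentation
BMI_BOUNDS: dict[BMIGroup, tuple[float, float]] = {
    BMIGroup.UNDERWEIGHT: (12.0, 18.5),
    BMIGroup.NORMAL: (18.5, 25.0),
    BMIGroup.OVERWEIGHT: (25.0, 30.0),
    BMIGroup.OBESE1: (30.0, 35.0),
    BMIGroup.OBESE2: (35.0, 40.0),
    BMIGroup.OBESE3: (40.0, math.inf),
}


def classify_bmi(bmi: float) -> BMIGroup:
    """Map a pre-pregnancy BMI (kg/m^2) to its WHO group."""
    if not bmi > 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    for upper, group in _BMI_EDGES:
        if bmi < upper:
            return group
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class GainRecord:
    """One (woman, gestational age, gain) row of the long-format fit table."""

    woman_id: str
    gestational_age: float
    gain: float  # kg, may be negative
    bmi_group: BMIGroup
    is_week0: bool = False


@dataclass(frozen=True)
class ShiftedGainRecord(GainRecord):
    """GainRecord with the fit outcome ``y = gain + 20`` (kg, > 0)."""

    y: float = float("nan")


@dataclass
class GainTable:
    """Gain records plus the per-reason exclusion tally from their build."""

    records: list[GainRecord]
    exclusions: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def select_window_measurements(
    record: WomanRecord,
) -> dict[str, WeightObservation]:
    """Pick at most one observation per early/mid/late pregnancy window.

    Each window keeps the observation closest to its target week (13, 26,
    40); ties go to the earlier observation; the week-0 row never enters a
    window.  Empty windows simply yield no entry.
    """
    picked: dict[str, WeightObservation] = {}
    for name, (target, lo, hi) in WINDOWS.items():
        best = None
        best_key = None
        for obs in record.observations:
            if obs.gestational_age <= 0:
                continue
            if not (lo <= obs.gestational_age <= hi):
                continue
            key = (abs(obs.gestational_age - target), obs.gestational_age)
            if best_key is None or key < best_key:
                best, best_key = obs, key
        if best is not None:
            picked[name] = best
    return picked


def build_gain_table(cohort: CohortTable) -> GainTable:
    """Long-format gain table: one week-0 row plus one row per filled window.

    Gain is the weight at a gestational age minus the pre-pregnancy weight.
    Women without height (no BMI, hence no group) are excluded and counted.
    """
    records: list[GainRecord] = []
    excl = {"missing_height": 0}
    for woman in cohort.records:
        if woman.height is None or not woman.height > 0:
            excl["missing_height"] += 1
            continue
        bmi = woman.prepregnancy_weight / woman.height**2
        group = classify_bmi(bmi)
        records.append(
            GainRecord(woman.woman_id, 0.0, 0.0, group, is_week0=True)
        )
        for obs in select_window_measurements(woman).values():
            records.append(
                GainRecord(
                    woman.woman_id,
                    obs.gestational_age,
                    obs.weight - woman.prepregnancy_weight,
                    group,
                )
            )
    return GainTable(records, excl)


def apply_nudge(records: list[GainRecord], seed: int) -> list[GainRecord]:
    """Replace each week-0 zero gain by a draw from N(0, 0.98 kg^2).

    Reproducible for a given seed; non-week-0 rows pass through untouched.
    """
    rng = np.random.default_rng(seed)
    sd = math.sqrt(nudge_variance())
    out = []
    for rec in records:
        if rec.is_week0:
            out.append(replace(rec, gain=float(rng.normal(0.0, sd))))
        else:
            out.append(rec)
    return out


def apply_offset(
    records: list[GainRecord],
) -> tuple[list[ShiftedGainRecord], int]:
    """Shift gains by +20 kg to the strictly positive fit scale.

    Returns the shifted records and the count of rows dropped because
    ``gain + 20 <= 0`` (the distribution cannot represent them).
    """
    out: list[ShiftedGainRecord] = []
    dropped = 0
    for rec in records:
        y = rec.gain + GAIN_OFFSET_KG
        if y <= 0:
            dropped += 1
            continue
        out.append(
            ShiftedGainRecord(
                rec.woman_id,
                rec.gestational_age,
                rec.gain,
                rec.bmi_group,
                rec.is_week0,
                y=y,
            )
        )
    return out, dropped


def filter_uncomplicated(cohort: CohortTable) -> CohortTable:
    """Subset of women with all four complication flags known and False.

    Unknown flags exclude a woman from this subset only — she stays in the
    full table used for the main charts.
    """
    kept = [
        w
        for w in cohort.records
        if all(v is False for v in w.complication_flags.values())
    ]
    return CohortTable(
        records=kept, provenance=f"{cohort.provenance} [uncomplicated subset]"
    )
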