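"""Tabular I/O for the chart pipeline.

Reads and writes the cohort CSV (long format, one row per weight
observation), the week-indexed BCT parameter grid CSV and the centile table
CSV.  All formats are comma-separated UTF-8 with a header row and decimal
points; units are fixed at kg / m / decimal weeks — no unit auto-detection.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "WeightObservation",
    "WomanRecord",
    "CohortTable",
    "RejectionReport",
    "COHORT_COLUMNS",
    "FLAG_COLUMNS",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_parameter_grid",
    "write_parameter_grid",
    "write_centile_table",
]

#: mandatory cohort CSV columns (canonical names)
COHORT_COLUMNS = [
    "woman_id",
    "prepregnancy_weight_kg",
    "height_m",
    "ga_weeks",
    "weight_kg",
]

#: optional complication-flag columns -> canonical flag names
FLAG_COLUMNS = {
    "hypertensive": "hypertensive_disorder",
    "diabetic": "diabetic_disorder",
    "preterm": "preterm_birth",
    "sga_lga": "sga_or_lga",
}

FLAG_NAMES = list(FLAG_COLUMNS.values())

GA_RANGE = (0.0, 45.0)
WEIGHT_RANGE = (25.0, 250.0)  # exclusive plausibility screen, kg


@dataclass(frozen=True)
class WeightObservation:
    """One weight measurement: gestational age (decimal weeks) and kg."""

    gestational_age: float
    weight: float


@dataclass
class WomanRecord:
    """One woman's anthropometrics, complication flags and observations.

    ``complication_flags`` maps each of the four flag names to True, False
    or None (unknown).  After loading, the observation list always contains
    an implied week-0 row whose weight is the pre-pregnancy weight.
    """

    woman_id: str
    prepregnancy_weight: float
    height: float | None
    complication_flags: dict[str, bool | None] = field(
        default_factory=lambda: {name: None for name in FLAG_NAMES}
    )
    observations: list[WeightObservation] = field(default_factory=list)

    @property
    def bmi(self) -> float | None:
        if self.height is None or self.height <= 0:
            return None
        return self.prepregnancy_weight / self.height**2


@dataclass
class CohortTable:
    """Validated collection of WomanRecords with unique ids."""

    records: list[WomanRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [w.woman_id for w in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("woman_id must be unique within a cohort table")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class RejectionReport:
    """Per-reason tally (and row detail) of data not retained on load."""

    counts: dict[str, int] = field(default_factory=dict)
    rows: dict[str, list[int]] = field(default_factory=dict)

    def add(self, reason: str, row_index: int | None = None) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1
        if row_index is not None:
            self.rows.setdefault(reason, []).append(row_index)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _parse_flag(value) -> bool | None:
    if pd.isna(value):
        return None
    if isinstance(value, str):
        v = value.strip().lower()
        if v in {"", "na", "nan", "unknown"}:
            return None
        if v in {"1", "true", "t", "yes"}:
            return True
        if v in {"0", "false", "f", "no"}:
            return False
        raise ValueError(f"unparseable complication flag value: {value!r}")
    return bool(int(value))


def read_cohort_csv(
    path, schema_config: dict[str, str] | None = None
) -> tuple[CohortTable, RejectionReport]:
    """Load a long-format cohort CSV into a validated CohortTable.

    ``schema_config`` maps canonical column names to the file's column names
    (identity for unmapped columns).  Week-0 rows are materialized from the
    pre-pregnancy weight; rows failing the plausibility screens and women
    without a pre-pregnancy weight go to the rejection report, never
    silently dropped.
    """
    rename = {v: k for k, v in (schema_config or {}).items()}
    df = pd.read_csv(path)
    df = df.rename(columns=rename)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing mandatory columns: {missing}")

    report = RejectionReport()
    if df.empty:
        warnings.warn(f"cohort file {path} contains no rows", stacklevel=2)
        return CohortTable([], provenance=str(path)), report

    records: list[WomanRecord] = []
    for woman_id, rows in df.groupby("woman_id", sort=True):
        first = rows.iloc[0]
        pre_w = first["prepregnancy_weight_kg"]
        if pd.isna(pre_w):
            report.add("missing_prepregnancy_weight")
            continue
        pre_w = float(pre_w)
        height = None if pd.isna(first["height_m"]) else float(first["height_m"])
        flags = {name: None for name in FLAG_NAMES}
        for col, name in FLAG_COLUMNS.items():
            if col in rows.columns:
                flags[name] = _parse_flag(first[col])
        obs = [WeightObservation(0.0, pre_w)]
        for idx, row in rows.iterrows():
            ga, w = row["ga_weeks"], row["weight_kg"]
            if pd.isna(ga) or pd.isna(w):
                report.add("missing_ga_or_weight", idx)
                continue
            ga, w = float(ga), float(w)
            if ga == 0.0:
                # week-0 comes from the pre-pregnancy column, authoritative
                report.add("week0_replaced", idx)
                continue
            if not (GA_RANGE[0] <= ga <= GA_RANGE[1]):
                report.add("gestational_age_out_of_range", idx)
                continue
            if not (WEIGHT_RANGE[0] < w < WEIGHT_RANGE[1]):
                report.add("weight_implausible", idx)
                continue
            obs.append(WeightObservation(ga, w))
        records.append(
            WomanRecord(str(woman_id), pre_w, height, flags, obs)
        )
    return CohortTable(records, provenance=str(path)), report


def write_cohort_csv(cohort: CohortTable, path) -> None:
    """Write a CohortTable back to the long cohort CSV format.

    Materialized week-0 rows are not written (they are implied by the
    pre-pregnancy weight column), so read(write(t)) round-trips.
    """
    rows = []
    for w in cohort.records:
        flags = {
            col: ("" if w.complication_flags[name] is None
                  else int(w.complication_flags[name]))
            for col, name in FLAG_COLUMNS.items()
        }
        for obs in w.observations:
            if obs.gestational_age == 0.0:
                continue
            rows.append(
                {
                    "woman_id": w.woman_id,
                    "prepregnancy_weight_kg": f"{w.prepregnancy_weight:.10g}",
                    "height_m": "" if w.height is None else f"{w.height:.10g}",
                    "ga_weeks": f"{obs.gestational_age:.10g}",
                    "weight_kg": f"{obs.weight:.10g}",
                    **flags,
                }
            )
    cols = COHORT_COLUMNS + list(FLAG_COLUMNS)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_parameter_grid(grid, path) -> None:
    """Write a week-indexed BCT parameter grid as CSV.

    One BMI group per file; the group is recorded in a leading comment line
    ``# bmi_group: <label>``.  Full precision (>= 10 significant digits) so
    the round trip is an identity.
    """
    weeks = [week for week, _ in grid.rows]
    if any(b <= a for a, b in zip(weeks, weeks[1:])):
        raise ValueError("parameter grid weeks must be strictly increasing")
    buf = io.StringIO()
    buf.write(f"# bmi_group: {grid.bmi_group.value}\n")
    buf.write("week,mu,sigma,nu,tau\n")
    for week, p in grid.rows:
        buf.write(
            f"{week},{p.mu:.12g},{p.sigma:.12g},{p.nu:.12g},{p.tau:.12g}\n"
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_parameter_grid(path):
    """Read a parameter grid CSV written by :func:`write_parameter_grid`."""
    from .bct import BCTParams
    from .charts import ParameterGrid
    from .preprocess import BMIGroup

    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError("parameter grid file must start with '# bmi_group: ...'")
    label = lines[0].split(":", 1)[1].strip()
    group = BMIGroup(label)
    df = pd.read_csv(io.StringIO("\n".join(lines[1:])))
    weeks = df["week"].tolist()
    if len(set(weeks)) != len(weeks):
        raise ValueError("duplicate week rows in parameter grid")
    if any(b <= a for a, b in zip(weeks, weeks[1:])):
        raise ValueError("parameter grid weeks must be strictly increasing")
    if (df["sigma"] <= 0).any() or (df["tau"] <= 0).any():
        raise ValueError("sigma and tau must be positive in a parameter grid")
    rows = [
        (int(r.week), BCTParams(r.mu, r.sigma, r.nu, r.tau))
        for r in df.itertuples()
    ]
    return ParameterGrid(bmi_group=group, rows=rows)


def write_centile_table(table, path) -> None:
    """Write a centile table as CSV (week, p2.3, p16, p50, p84, p97.7; 2 dp)."""
    labels = table.labels
    header = "week," + ",".join(f"p{lab:g}" for lab in labels)
    lines = [f"# bmi_group: {table.bmi_group.value}", header]
    for week, vals in table.rows:
        lines.append(f"{week}," + ",".join(f"{v:.2f}" for v in vals))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
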