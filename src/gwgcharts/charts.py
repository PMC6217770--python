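"""Chart deliverables: parameter grids, centile curves, z-score calculator,
and IOM adequacy classification.

The parameter grid — BCT (mu, sigma, nu, tau) at integer weeks 0..42 — is
the exchange format between a fitted chart and the calculator: a user's
z-score at an exact (decimal) gestational age is obtained by linearly
interpolating each parameter between the two bracketing integer weeks and
evaluating the BCT machinery on ``y = gain + 20``.  Interpolating the
parameters rather than the quantiles keeps the calculator and the centile
curves mutually consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import bct
from .bct import BCTParams
from .preprocess import GAIN_OFFSET_KG, BMIGroup
from .smooth_fit import FittedChart, predict_params

__all__ = [
    "ParameterGrid",
    "CentileTable",
    "GRID_WEEKS",
    "SD_LABELS",
    "export_parameter_grid",
    "centile_curve",
    "build_centile_table",
    "gain_to_zscore",
    "zscore_to_gain",
    "iom_classify",
    "IOM_RANGES",
]

#: integer weeks covered by an exported grid
GRID_WEEKS = range(0, 43)

#: percentile labels and the SD (normal-equivalent z) values defining them
SD_LABELS: dict[float, float] = {2.3: -2.0, 16.0: -1.0, 50.0: 0.0,
                                 84.0: 1.0, 97.7: 2.0}

#: 2009 Institute of Medicine adequate total-gain ranges [low, high], kg;
#: the three obesity grades share one range
IOM_RANGES: dict[BMIGroup, tuple[float, float]] = {
    BMIGroup.UNDERWEIGHT: (12.5, 18.0),
    BMIGroup.NORMAL: (11.5, 16.0),
    BMIGroup.OVERWEIGHT: (7.0, 11.5),
    BMIGroup.OBESE1: (5.0, 9.0),
    BMIGroup.OBESE2: (5.0, 9.0),
    BMIGroup.OBESE3: (5.0, 9.0),
}


@dataclass
class ParameterGrid:
    """Week-indexed BCT parameters for one BMI group."""

    bmi_group: BMIGroup
    rows: list[tuple[int, BCTParams]]

    def __post_init__(self) -> None:
        weeks = [w for w, _ in self.rows]
        if weeks != list(range(weeks[0], weeks[0] + len(weeks))):
            raise ValueError("grid weeks must be consecutive integers")

    @property
    def weeks(self) -> list[int]:
        return [w for w, _ in self.rows]

    def params_at_week(self, week: int) -> BCTParams:
        first = self.rows[0][0]
        return self.rows[week - first][1]


@dataclass
class CentileTable:
    """Gain (kg) by week for a fixed set of percentile labels."""

    bmi_group: BMIGroup
    labels: tuple[float, ...]
    rows: list[tuple[int, tuple[float, ...]]]

    def __post_init__(self) -> None:
        for week, vals in self.rows:
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"crossing centiles at week {week}")


def export_parameter_grid(chart: FittedChart) -> ParameterGrid:
    """Evaluate the fitted curves at integer weeks 0..42."""
    if not chart.converged:
        warnings.warn(
            "exporting a parameter grid from a non-converged fit",
            stacklevel=2,
        )
    rows = [(week, predict_params(chart, float(week))) for week in GRID_WEEKS]
    return ParameterGrid(bmi_group=chart.bmi_group, rows=rows)


def _prob_for_label(percentile: float) -> float:
    if not (0.0 < percentile < 100.0):
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    if percentile in SD_LABELS:
        # chart labels are defined by round SD values on the normal scale
        return float(stats.norm.cdf(SD_LABELS[percentile]))
    return percentile / 100.0


def centile_curve(grid: ParameterGrid, percentile: float) -> dict[int, float]:
    """Gain (kg) at the given percentile for every week of the grid."""
    prob = _prob_for_label(percentile)
    return {
        week: bct.bct_quantile(prob, p) - GAIN_OFFSET_KG
        for week, p in grid.rows
    }


def build_centile_table(
    grid: ParameterGrid, labels: tuple[float, ...] = (2.3, 16.0, 50.0, 84.0, 97.7)
) -> CentileTable:
    curves = {lab: centile_curve(grid, lab) for lab in labels}
    rows = [
        (week, tuple(curves[lab][week] for lab in labels))
        for week in grid.weeks
    ]
    return CentileTable(bmi_group=grid.bmi_group, labels=tuple(labels), rows=rows)


def _interpolate_params(grid: ParameterGrid, ga: float) -> BCTParams:
    """Per-parameter linear interpolation at an exact gestational age.

    Beyond the grid the terminal pair of weeks is extrapolated linearly,
    with a warning; at integer weeks the grid values are returned exactly.
    """
    if not (0.0 <= ga <= 45.0):
        raise ValueError(f"gestational age {ga} outside [0, 45] weeks")
    weeks = grid.weeks
    first, last = weeks[0], weeks[-1]
    if ga < first or ga > last:
        warnings.warn(
            f"gestational age {ga} outside the grid range "
            f"[{first}, {last}]; extrapolating parameters linearly",
            stacklevel=3,
        )
        lo, hi = (first, first + 1) if ga < first else (last - 1, last)
    else:
        lo = min(int(np.floor(ga)), last - 1)
        hi = lo + 1
    p_lo = grid.params_at_week(lo)
    p_hi = grid.params_at_week(hi)
    frac = (ga - lo) / (hi - lo)
    vals = {
        name: getattr(p_lo, name) + frac * (getattr(p_hi, name) - getattr(p_lo, name))
        for name in ("mu", "sigma", "nu", "tau")
    }
    return BCTParams(**vals)


def gain_to_zscore(
    gain: float, ga: float, group: BMIGroup, grid: ParameterGrid
) -> dict[str, float]:
    """z-scores and percentile for an observed gain at an exact age.

    Returns ``z_raw`` (the t-scale Box-Cox transform), ``z_normal`` (the
    normal-equivalent z defining the chart's SD lines) and ``percentile``.
    """
    if group is not grid.bmi_group:
        raise ValueError(
            f"grid is for {grid.bmi_group.value}, not {group.value}"
        )
    y = gain + GAIN_OFFSET_KG
    if y <= 0:
        raise ValueError(
            f"gain {gain} kg implies y = gain + 20 = {y} <= 0; the model "
            "is defined only for shifted gains > 0"
        )
    p = _interpolate_params(grid, ga)
    z_normal = bct.normalized_residual(y, p)
    return {
        "z_raw": bct.bct_transform(y, p),
        "z_normal": z_normal,
        "percentile": 100.0 * float(stats.norm.cdf(z_normal)),
    }


def zscore_to_gain(
    z_normal: float, ga: float, group: BMIGroup, grid: ParameterGrid
) -> float:
    """Gain (kg) whose normal-equivalent z equals ``z_normal`` — the exact
    inverse of :func:`gain_to_zscore` under the same interpolation rule."""
    if group is not grid.bmi_group:
        raise ValueError(
            f"grid is for {grid.bmi_group.value}, not {group.value}"
        )
    p = _interpolate_params(grid, ga)
    prob = float(stats.norm.cdf(z_normal))
    prob = min(max(prob, 1e-15), 1 - 1e-15)
    return bct.bct_quantile(prob, p) - GAIN_OFFSET_KG


def iom_classify(total_gain: float, group: BMIGroup) -> str:
    """Classify a total gain against the IOM adequate range (closed)."""
    low, high = IOM_RANGES[group]
    if total_gain < low:
        return "insufficient"
    if total_gain > high:
        return "excessive"
    return "adequate"
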