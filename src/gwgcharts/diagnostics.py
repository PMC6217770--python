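"""Model-adequacy diagnostics: worm plots, Q statistics, centile coverage,
BIC comparison and subgroup-consistency screening.

All diagnostics operate on the normal-equivalent quantile residuals
(Phi^-1 of the fitted CDF at each observation), which are standard normal
when the chart describes the data correctly, and are pure functions of
their inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .charts import SD_LABELS, ParameterGrid
from .preprocess import GAIN_OFFSET_KG, ShiftedGainRecord, nudge_variance
from .smooth_fit import FittedChart, LinearBaselineFit

__all__ = [
    "WormBin",
    "QStat",
    "DiagnosticsReport",
    "chart_residuals",
    "worm_plot_data",
    "q_statistics",
    "centile_coverage",
    "compare_bic",
    "subgroup_median_spread",
]


@dataclass
class WormBin:
    """Detrended QQ data for one gestational-age bin."""

    ga_range: tuple[float, float]
    n: int
    theoretical: np.ndarray  # standard-normal order-statistic medians
    deviation: np.ndarray  # empirical minus theoretical quantile
    band: np.ndarray  # 95% pointwise band half-widths


@dataclass
class QStat:
    """One moment's Q statistic across gestational-age groups."""

    moment: str
    statistic: float
    df: float
    p_value: float | None
    group_sizes: list[int]


@dataclass
class DiagnosticsReport:
    worm_bins: list[WormBin] = field(default_factory=list)
    q_stats: dict[str, QStat] = field(default_factory=dict)
    coverage: dict[float, float] = field(default_factory=dict)
    delta_bic: float | None = None


def chart_residuals(
    data: list[ShiftedGainRecord], grid: ParameterGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Normal-equivalent residuals of observations against a fitted grid.

    Vectorized: parameters are linearly interpolated per observation with
    the same rule as the z-score calculator (terminal-pair extrapolation
    beyond the grid), then Phi^-1 of the BCT CDF is taken.
    """
    ga = np.array([r.gestational_age for r in data], dtype=float)
    y = np.array([r.y for r in data], dtype=float)
    weeks = np.asarray(grid.weeks, dtype=float)
    par = {
        name: np.array([getattr(p, name) for _, p in grid.rows])
        for name in ("mu", "sigma", "nu", "tau")
    }
    idx = np.clip(np.floor(ga - weeks[0]).astype(int), 0, len(weeks) - 2)
    frac = (ga - weeks[0]) - idx  # may fall outside [0, 1] -> extrapolation
    vals = {
        name: arr[idx] + frac * (arr[idx + 1] - arr[idx])
        for name, arr in par.items()
    }
    from .smooth_fit import _zscore

    zt = _zscore(y, vals["mu"], vals["sigma"], vals["nu"])
    nu, sigma, tau = vals["nu"], vals["sigma"], vals["tau"]
    small = np.abs(nu) <= 1e-6
    c = 1.0 / (sigma * np.where(small, 1.0, np.abs(nu)))
    mass = np.where(small, 1.0, stats.t.cdf(c, df=tau))
    lower = np.where((nu > 0) & ~small, stats.t.cdf(-c, df=tau), 0.0)
    cdf = np.clip((stats.t.cdf(zt, df=tau) - lower) / mass, 1e-15, 1 - 1e-15)
    return stats.norm.ppf(cdf), ga


def _equal_count_bins(ga: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Index groups of roughly equal size, ordered by gestational age.

    Week-0 rows are a point mass in age; when they exceed 10% of the data
    they form their own bin and the rest is split into ``n_bins - 1``.
    """
    order = np.argsort(ga, kind="stable")
    idx_groups: list[np.ndarray] = []
    week0 = np.flatnonzero(ga == 0.0)
    rest = order[~np.isin(order, week0)]
    if week0.size > 0.1 * ga.size and n_bins > 1:
        idx_groups.append(week0)
        n_bins -= 1
    else:
        rest = order
    idx_groups.extend(np.array_split(rest, n_bins))
    return [g for g in idx_groups if g.size]


def worm_plot_data(
    z_normal, ga, n_bins: int = 8
) -> list[WormBin]:
    """Per-age-bin detrended QQ data with 95% pointwise bands.

    Within each equal-count bin the ordered residuals are paired with
    standard-normal order-statistic medians (Blom positions); a flat worm
    inside the band means the residuals are locally standard normal.
    """
    z = np.asarray(z_normal, dtype=float)
    ga = np.asarray(ga, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("residuals must be finite")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    bins = []
    for idx in _equal_count_bins(ga, n_bins):
        zi = np.sort(z[idx])
        n = zi.size
        if n < 20:
            warnings.warn(
                f"worm-plot bin with only {n} points; interpret with care",
                stacklevel=2,
            )
        p = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
        theo = stats.norm.ppf(p)
        band = 1.96 * np.sqrt(p * (1 - p) / n) / stats.norm.pdf(theo)
        bins.append(
            WormBin(
                ga_range=(float(ga[idx].min()), float(ga[idx].max())),
                n=n,
                theoretical=theo,
                deviation=zi - theo,
                band=band,
            )
        )
    return bins


def q_statistics(
    z_normal,
    ga,
    n_groups: int = 8,
    fitted_df: dict[str, float] | None = None,
) -> dict[str, QStat]:
    """Royston-Wright-style Q statistics per residual moment.

    Residuals are split into ``n_groups`` equal-count age groups; per group
    the standardized departure of the mean, variance, skewness and kurtosis
    from standard-normal expectation is computed (mean via m*sqrt(n),
    variance via the Wilson-Hilferty cube-root transform, skewness and
    kurtosis via the D'Agostino z-transformations), and Q is the sum of
    squared departures, referred to chi-square with ``n_groups`` minus the
    effective df the corresponding fitted curve absorbed (floored at 1).
    """
    z = np.asarray(z_normal, dtype=float)
    ga = np.asarray(ga, dtype=float)
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    fitted_df = fitted_df or {}
    groups = _equal_count_bins(ga, n_groups)
    sizes = [g.size for g in groups]

    u: dict[str, list[float]] = {m: [] for m in
                                 ("mean", "variance", "skewness", "kurtosis")}
    small = False
    for idx in groups:
        zi = z[idx]
        n = zi.size
        if n < 10:
            small = True
            continue
        u["mean"].append(float(np.mean(zi)) * np.sqrt(n))
        d = n - 1
        v = float(np.var(zi, ddof=1))
        u["variance"].append(
            (v ** (1 / 3) - (1 - 2 / (9 * d))) / np.sqrt(2 / (9 * d))
        )
        with np.errstate(all="ignore"):
            # undefined for (near-)constant groups; recorded as nan
            u["skewness"].append(float(stats.skewtest(zi).statistic))
            u["kurtosis"].append(float(stats.kurtosistest(zi).statistic))

    curve_for = {"mean": "mu", "variance": "sigma",
                 "skewness": "nu", "kurtosis": "tau"}
    out: dict[str, QStat] = {}
    for moment, us in u.items():
        q = float(np.sum(np.square(us)))
        df = max(len(groups) - fitted_df.get(curve_for[moment], 0.0), 1.0)
        p = (
            None
            if small or not np.isfinite(q)
            else float(stats.chi2.sf(q, df))
        )
        out[moment] = QStat(moment, q, df, p, sizes)
    return out


def centile_coverage(
    data: list[ShiftedGainRecord],
    grid: ParameterGrid,
    labels: tuple[float, ...] = (2.3, 16.0, 50.0, 84.0, 97.7),
) -> dict[float, float]:
    """Fraction of observations falling below each nominal centile curve.

    Close agreement with the nominal probabilities (0.023, 0.16, ...) is
    the "fitted centiles" criterion used for model selection.
    """
    z, _ = chart_residuals(data, grid)
    cover = {}
    for lab in labels:
        z_cut = SD_LABELS.get(lab)
        prob = stats.norm.cdf(z_cut) if z_cut is not None else lab / 100.0
        cover[lab] = float(np.mean(stats.norm.cdf(z) < prob))
    return cover


def compare_bic(chart: FittedChart, baseline: LinearBaselineFit) -> float:
    """BIC difference (linear minus chart); positive favors the chart."""
    if chart.n_observations != baseline.n:
        raise ValueError(
            f"chart was fit to {chart.n_observations} observations but the "
            f"baseline to {baseline.n}; BIC comparison requires the same data"
        )
    return float(baseline.bic - chart.bic)


def subgroup_median_spread(
    charts: list[FittedChart], weeks=range(0, 43)
) -> tuple[float, bool]:
    """Across-subgroup variance of fitted median gains, and whether its
    maximum over weeks stays below the 0.98 kg^2 measurement-error variance.

    A spread below measurement error means subgroup charts (e.g. per
    cohort or country) are practically indistinguishable.
    """
    from .smooth_fit import predict_params

    if len(charts) < 2:
        raise ValueError("need at least two subgroup charts")
    spreads = []
    for week in weeks:
        med = [predict_params(c, float(week)).mu - GAIN_OFFSET_KG for c in charts]
        spreads.append(float(np.var(med, ddof=1)))
    max_spread = max(spreads)
    return max_spread, max_spread < nudge_variance()
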