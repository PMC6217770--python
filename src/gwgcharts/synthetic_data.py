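"""Synthetic pregnancy cohorts with the structure the chart pipeline assumes.

The generator emulates the study design behind the charts: per-woman
pre-pregnancy BMI inside one of the six WHO groups, at most one weight
measurement per early/mid/late pregnancy window, skewed non-linear gain
trajectories whose cross-sectional distribution at every age is exactly
Box-Cox t, a dial measurement error of 0.70 kg on every observed weight,
and binary complication flags.  The truth median curve per group is
anchored at the published group medians at 20 and 40 weeks, with zero gain
at conception and an early-pregnancy lag (the gain rate is lower in the
first half of pregnancy than the second).

Within-woman tracking comes from a single woman-level uniform shared across
her windows, which induces realistic correlation between repeated weights
while keeping each cross-sectional margin exactly BCT — matching the
cross-sectional modeling assumption of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from . import bct
from .bct import BCTParams
from .cohort_io import FLAG_NAMES, CohortTable, WeightObservation, WomanRecord
from .preprocess import (
    BMI_BOUNDS,
    GAIN_OFFSET_KG,
    MEASUREMENT_ERROR_SD,
    BMIGroup,
)

__all__ = [
    "SyntheticTruth",
    "SyntheticConfig",
    "TABLE_MEDIANS",
    "default_truth",
    "simulate_cohort",
    "simulate_iom_mix",
]

#: published all-women median gain (kg) at 20 and 40 weeks per BMI group —
#: the anchors every default truth curve interpolates
TABLE_MEDIANS: dict[BMIGroup, tuple[float, float]] = {
    BMIGroup.UNDERWEIGHT: (4.20, 14.20),
    BMIGroup.NORMAL: (3.90, 14.49),
    BMIGroup.OVERWEIGHT: (3.35, 13.86),
    BMIGroup.OBESE1: (1.95, 11.19),
    BMIGroup.OBESE2: (0.93, 8.73),
    BMIGroup.OBESE3: (-0.35, 6.27),
}

#: simulation cap for the unbounded obesity-grade-3 BMI class
_OBESE3_BMI_CAP = 50.0

#: GA sampling windows (lo, hi) for early/mid/late observations
_WINDOW_RANGES = {"early": (6.0, 19.9), "mid": (20.0, 31.9), "late": (32.0, 42.0)}


@dataclass
class SyntheticTruth:
    """Ground-truth parameter curves generating one group's gains."""

    bmi_group: BMIGroup
    mu_curve: object  # callable weeks -> median gain (kg)
    sigma: float = 0.06
    nu: float = 0.8
    tau: float = 12.0
    anchors: tuple[tuple[float, float], ...] = ()

    def params_at(self, t: float) -> BCTParams:
        """BCT parameters of the shifted gain y = gain + 20 at age t."""
        return BCTParams(
            mu=float(self.mu_curve(t)) + GAIN_OFFSET_KG,
            sigma=self.sigma,
            nu=self.nu,
            tau=self.tau,
        )

    def median_gain(self, t: float) -> float:
        return float(self.mu_curve(t))


@dataclass
class SyntheticConfig:
    """Cohort design: sizes, observation schedule, noise and flags."""

    n_women: int = 1000
    window_missingness: dict[str, float] = field(
        default_factory=lambda: {"early": 0.0, "mid": 0.0, "late": 0.0}
    )
    measurement_error_sd: float = MEASUREMENT_ERROR_SD
    complication_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "hypertensive_disorder": 0.08,
            "diabetic_disorder": 0.05,
            "preterm_birth": 0.06,
            "sga_or_lga": 0.20,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_women < 1:
            raise ValueError("n_women must be >= 1")
        probs = list(self.window_missingness.values()) + list(
            self.complication_prevalence.values()
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")


def default_truth(group: BMIGroup) -> SyntheticTruth:
    """Truth curves anchored at the published group medians.

    The median curve is a shape-preserving cubic through (0 wk, 0 kg) and
    the 20- and 40-week anchors, with the derivative at conception set to
    half the 0-20-week secant slope (early-pregnancy lag) and a linear
    continuation past 40 weeks.  S/L/T are constants: sigma 0.06, nu 0.8,
    tau 12 — invented but realistic magnitudes, config-exposed; recovery
    tests assert recovery of whatever truth is configured.
    """
    m20, m40 = TABLE_MEDIANS[group]
    s1 = (m20 - 0.0) / 20.0
    s2 = (m40 - m20) / 20.0
    d0 = 0.5 * s1
    # harmonic-mean derivative at 20 wk keeps the curve shape-preserving
    d20 = 2.0 * s1 * s2 / (s1 + s2) if s1 * s2 > 0 else 0.0
    d40 = s2
    x = np.array([0.0, 20.0, 40.0, 45.0])
    yv = np.array([0.0, m20, m40, m40 + 5.0 * s2])
    dy = np.array([d0, d20, d40, s2])
    spline = CubicHermiteSpline(x, yv, dy)
    return SyntheticTruth(
        bmi_group=group,
        mu_curve=spline,
        anchors=((0.0, 0.0), (20.0, m20), (40.0, m40)),
    )


def _truth_quantile_gain(truth: SyntheticTruth, u: np.ndarray, ga: np.ndarray):
    """Vectorized gain quantile across ages (constant S/L/T per truth)."""
    from scipy import stats

    mu = np.array([truth.mu_curve(g) for g in np.atleast_1d(ga)]) + GAIN_OFFSET_KG
    sigma, nu, tau = truth.sigma, truth.nu, truth.tau
    if abs(nu) > 1e-6:
        c = 1.0 / (sigma * abs(nu))
        mass = stats.t.cdf(c, df=tau)
        lower = stats.t.cdf(-c, df=tau) if nu > 0 else 0.0
        z = stats.t.ppf(lower + u * mass, df=tau)
        y = mu * np.power(1.0 + sigma * nu * z, 1.0 / nu)
    else:
        y = mu * np.exp(sigma * stats.t.ppf(u, df=tau))
    return y - GAIN_OFFSET_KG


def simulate_cohort(
    config: SyntheticConfig,
    truths: dict[BMIGroup, SyntheticTruth] | None = None,
    groups: list[BMIGroup] | None = None,
) -> CohortTable:
    """Simulate ``n_women`` per requested group, reproducibly by seed.

    Per woman: BMI uniform within her group's interval, height normal
    (1.65 m, sd 0.07) truncated to [1.40, 1.95], pre-pregnancy weight =
    BMI * height^2; per non-missing window one gestational age is drawn and
    the true gain is the BCT quantile of her shared woman-level uniform at
    that age; observed weight adds a fresh N(0, 0.70^2) dial error.
    """
    groups = groups or [BMIGroup.NORMAL]
    truths = truths or {g: default_truth(g) for g in groups}
    rng = np.random.default_rng(config.seed)
    records: list[WomanRecord] = []
    n = config.n_women
    for group in groups:
        truth = truths[group]
        lo, hi = BMI_BOUNDS[group]
        hi = min(hi, _OBESE3_BMI_CAP)
        bmi = rng.uniform(lo, hi, n)
        height = np.clip(rng.normal(1.65, 0.07, n), 1.40, 1.95)
        pre_weight = bmi * height**2
        u = rng.uniform(size=n)  # one latent trajectory level per woman
        window_obs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for name, (wlo, whi) in _WINDOW_RANGES.items():
            present = rng.uniform(size=n) >= config.window_missingness.get(name, 0.0)
            ga = rng.uniform(wlo, whi, n)
            err = rng.normal(0.0, config.measurement_error_sd, n)
            gain = _truth_quantile_gain(truth, u, ga)
            window_obs[name] = (present, ga, pre_weight + gain + err)
        flags_draw = {
            name: rng.uniform(size=n) < config.complication_prevalence.get(name, 0.0)
            for name in FLAG_NAMES
        }
        for i in range(n):
            obs = [WeightObservation(0.0, float(pre_weight[i]))]
            for name in _WINDOW_RANGES:
                present, ga, w = window_obs[name]
                if present[i]:
                    obs.append(WeightObservation(float(ga[i]), float(w[i])))
            records.append(
                WomanRecord(
                    f"{group.value}-{i:06d}",
                    float(pre_weight[i]),
                    float(height[i]),
                    {name: bool(flags_draw[name][i]) for name in FLAG_NAMES},
                    obs,
                )
            )
    return CohortTable(records, provenance=f"synthetic(seed={config.seed})")


def simulate_iom_mix(
    config: SyntheticConfig,
    targets: dict[BMIGroup, tuple[float, float, float]],
) -> CohortTable:
    """Cohort whose total-gain adequacy proportions match given targets.

    ``targets`` maps a group to (insufficient, adequate, excessive)
    proportions.  Women receive a single 40-week observation; total gains
    are drawn from the group truth at 40 weeks, rejection-sampled into the
    IOM category assigned to each woman, so realized proportions match the
    targets to within rounding (< 2%).  Measurement error is off so the
    classification of each woman is exact.
    """
    from .charts import IOM_RANGES, iom_classify

    rng = np.random.default_rng(config.seed)
    records = []
    for group, props in targets.items():
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"target proportions for {group} must sum to 1")
        truth = default_truth(group)
        p40 = truth.params_at(40.0)
        low, high = IOM_RANGES[group]
        # feasibility: each targeted category must have mass under the truth
        mass = {
            "insufficient": bct.bct_cdf(low + GAIN_OFFSET_KG, p40),
            "adequate": (
                bct.bct_cdf(high + GAIN_OFFSET_KG, p40)
                - bct.bct_cdf(low + GAIN_OFFSET_KG, p40)
            ),
        }
        mass["excessive"] = 1.0 - mass["insufficient"] - mass["adequate"]
        counts = np.round(np.array(props) * config.n_women).astype(int)
        counts[-1] = config.n_women - counts[:-1].sum()
        cats = ["insufficient", "adequate", "excessive"]
        for cat, cnt in zip(cats, counts):
            if cnt > 0 and mass[cat] < 1e-12:
                raise ValueError(
                    f"{cat} gains are outside the truth support for "
                    f"{group.value}; targets are infeasible"
                )
        i = 0
        for cat, cnt in zip(cats, counts):
            for _ in range(cnt):
                gain = None
                for _attempt in range(100000):
                    g = bct.bct_quantile(rng.uniform(), p40) - GAIN_OFFSET_KG
                    if iom_classify(g, group) == cat:
                        gain = g
                        break
                if gain is None:  # pragma: no cover
                    raise RuntimeError(
                        f"could not sample a {cat} gain for {group.value}"
                    )
                lo, hi = BMI_BOUNDS[group]
                bmi = rng.uniform(lo, min(hi, _OBESE3_BMI_CAP))
                height = float(np.clip(rng.normal(1.65, 0.07), 1.40, 1.95))
                pre_weight = bmi * height**2
                records.append(
                    WomanRecord(
                        f"{group.value}-iom-{i:06d}",
                        float(pre_weight),
                        height,
                        {name: False for name in FLAG_NAMES},
                        [
                            WeightObservation(0.0, float(pre_weight)),
                            WeightObservation(40.0, float(pre_weight + gain)),
                        ],
                    )
                )
                i += 1
    return CohortTable(records, provenance=f"synthetic-iom(seed={config.seed})")
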