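"""Penalized-likelihood fitting of the four BCT parameter curves.

Each distributional parameter is a smooth function of gestational age:
the median curve M(t) is an unpenalized degree-3 B-spline regression with
specified internal breakpoints; the S (variation), L (skewness) and T
(kurtosis) curves are cubic penalized splines whose smoothing constants are
chosen so the trace of the smoother matrix equals the requested effective
degrees of freedom.  Links are identity for mu and nu, log for sigma and
tau, so sigma(t) > 0 and tau(t) > 0 hold by construction.

Fitting follows the Rigby-Stasinopoulos backfitting scheme: cycling over
the four parameters, each update forms the adjusted dependent variable from
the score of the log-likelihood on the link scale and solves one penalized
weighted least-squares problem, holding the other curves fixed.  Every
update is guarded by step-halving on the penalized objective (deviance plus
quadratic penalties), so the objective is non-increasing by construction.
Data are modeled cross-sectionally: repeated observations of one woman
enter as independent rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from scipy.interpolate import BSpline

from .bct import BCTParams
from .preprocess import BMIGroup, GainRecord, ShiftedGainRecord

__all__ = [
    "MCurveSpec",
    "SmoothCurveSpec",
    "ModelSpec",
    "FittedChart",
    "LinearBaselineFit",
    "build_design",
    "fit_penalized_wls",
    "fit_gamlss_bct",
    "fit_linear_baseline",
    "predict_params",
]

#: gestational-age domain of every fitted curve, weeks
DOMAIN = (0.0, 45.0)

_NU_EPS = 1e-6
PARAM_NAMES = ("mu", "sigma", "nu", "tau")
#: fixed link map; identity for mu/nu, log for sigma/tau
LINKS = {"mu": "identity", "sigma": "log", "nu": "identity", "tau": "log"}

# evaluation-time guard rails on the link scale
_ETA_BOUNDS = {
    "mu": (1e-2, 1e3),
    "sigma": (np.log(1e-4), np.log(2.0)),
    "nu": (-8.0, 8.0),
    "tau": (np.log(0.2), np.log(1e6)),
}


@dataclass(frozen=True)
class MCurveSpec:
    """Unpenalized B-spline regression spec for the median curve."""

    degree: int = 3
    internal_breakpoints: tuple[float, ...] = (12.0, 20.0, 28.0, 34.0)

    def __post_init__(self) -> None:
        bp = self.internal_breakpoints
        if any(b <= a for a, b in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if any(not (DOMAIN[0] < b < DOMAIN[1]) for b in bp):
            raise ValueError(f"breakpoints must lie inside {DOMAIN}")

    @property
    def dimension(self) -> int:
        return len(self.internal_breakpoints) + self.degree + 1


@dataclass(frozen=True)
class SmoothCurveSpec:
    """Cubic penalized-spline spec with fixed effective df.

    ``df == 1`` degenerates to a constant curve (intercept only), the
    infinite-penalty limit of a first-order roughness penalty; ``df == 2``
    is the affine null space of the second-order penalty.
    """

    df: float = 3.0
    n_interior_knots: int = 13

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")

    @property
    def dimension(self) -> int:
        if self.df <= 1.0:
            return 1
        return self.n_interior_knots + 4


@dataclass(frozen=True)
class ModelSpec:
    """Curve shapes, links and convergence control for one chart fit."""

    m_curve: MCurveSpec = MCurveSpec()
    s_curve: SmoothCurveSpec = SmoothCurveSpec(df=3.0)
    l_curve: SmoothCurveSpec = SmoothCurveSpec(df=2.0)
    t_curve: SmoothCurveSpec = SmoothCurveSpec(df=2.0)
    tol: float = 1e-3
    max_outer_iterations: int = 50

    def curve(self, param: str):
        return {
            "mu": self.m_curve,
            "sigma": self.s_curve,
            "nu": self.l_curve,
            "tau": self.t_curve,
        }[param]


@dataclass
class _Curve:
    """Fitted representation of one parameter curve."""

    knots: np.ndarray
    degree: int
    beta: np.ndarray
    lam: float
    df: float
    info: np.ndarray | None = None  # B'WB at convergence
    penalty: np.ndarray | None = None

    def design(self, t: np.ndarray) -> np.ndarray:
        t = np.clip(np.asarray(t, dtype=float), DOMAIN[0], DOMAIN[1])
        # nudge the right edge inside so the last basis row is well defined
        t = np.minimum(t, DOMAIN[1] - 1e-9)
        return BSpline.design_matrix(t, self.knots, self.degree).toarray()

    def eta(self, t: np.ndarray) -> np.ndarray:
        return self.design(t) @ self.beta


@dataclass
class FittedChart:
    """Per-BMI-group fitted BCT parameter curves plus fit metadata."""

    bmi_group: BMIGroup
    spec: ModelSpec
    curves: dict[str, _Curve]
    global_deviance: float
    effective_df_total: float
    bic: float
    n_observations: int
    nudge_seed: int | None
    converged: bool
    iterations: int
    deviance_path: list[float] = field(default_factory=list)
    objective_path: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class LinearBaselineFit:
    """Simple straight-line Gaussian fit of gain on gestational age."""

    intercept: float
    slope: float
    residual_sd: float
    bic: float
    n: int


def _knot_vector(interior: np.ndarray, degree: int) -> np.ndarray:
    return np.concatenate(
        [
            np.repeat(DOMAIN[0], degree + 1),
            np.asarray(interior, dtype=float),
            np.repeat(DOMAIN[1], degree + 1),
        ]
    )


def _curvature_penalty(knots: np.ndarray, degree: int) -> np.ndarray:
    """Exact Gram matrix of basis second derivatives over the domain.

    The null space is exactly the affine functions, whatever the knot
    layout.  B'' of a cubic B-spline is piecewise linear, so per-interval
    Simpson quadrature integrates the products exactly.
    """
    dim = len(knots) - degree - 1
    eye = np.eye(dim)
    d2 = [BSpline(knots, eye[j], degree).derivative(2) for j in range(dim)]
    pen = np.zeros((dim, dim))
    for a, b in zip(*(lambda u: (u[:-1], u[1:]))(np.unique(knots))):
        pts = np.array([a, 0.5 * (a + b), min(b, DOMAIN[1] - 1e-9)])
        wts = (b - a) / 6.0 * np.array([1.0, 4.0, 1.0])
        v = np.array([[f(p) for f in d2] for p in pts])
        pen += v.T @ (wts[:, None] * v)
    return pen


def _curve_skeleton(curve_spec) -> tuple[np.ndarray, int, int, np.ndarray]:
    """(knot vector, degree, dimension, penalty matrix) for a curve spec."""
    if isinstance(curve_spec, MCurveSpec):
        knots = _knot_vector(
            np.asarray(curve_spec.internal_breakpoints), curve_spec.degree
        )
        dim = curve_spec.dimension
        return knots, curve_spec.degree, dim, np.zeros((dim, dim))
    if isinstance(curve_spec, SmoothCurveSpec):
        if curve_spec.df <= 1.0:
            # constant curve: one degree-0 basis function over the domain
            return _knot_vector(np.array([]), 0), 0, 1, np.zeros((1, 1))
        interior = np.linspace(
            DOMAIN[0], DOMAIN[1], curve_spec.n_interior_knots + 2
        )[1:-1]
        dim = curve_spec.dimension
        knots = _knot_vector(interior, 3)
        return knots, 3, dim, _curvature_penalty(knots, 3)
    raise TypeError(f"unknown curve spec {type(curve_spec)}")


def build_design(t_values, curve_spec):
    """Basis matrix and penalty matrix for one curve at the data ages.

    B-spline regression branch: the penalty is zero and the basis is a
    partition of unity.  Penalized-spline branch: equally spaced interior
    knots over the domain with an integrated-squared-second-derivative
    penalty, whose null space is exactly the affine functions; the actual
    smoothing constant is chosen at fit time to hit the requested df.
    """
    t = np.asarray(t_values, dtype=float)
    if np.any((t < DOMAIN[0]) | (t > DOMAIN[1])):
        raise ValueError(f"gestational ages must lie within {DOMAIN}")
    if isinstance(curve_spec, MCurveSpec) and curve_spec.internal_breakpoints:
        bp = np.asarray(curve_spec.internal_breakpoints)
        if t.size and (bp.min() < t.min() or bp.max() > t.max()):
            warnings.warn(
                "internal breakpoints fall outside the observed "
                "gestational-age range", stacklevel=2,
            )
    knots, degree, dim, penalty = _curve_skeleton(curve_spec)
    if np.unique(t).size < dim:
        raise ValueError(
            f"need at least {dim} distinct gestational ages for a "
            f"{dim}-dimensional basis, got {np.unique(t).size}"
        )
    basis = _Curve(knots, degree, np.zeros(dim), 0.0, float(dim)).design(t)
    return basis, penalty


def _edf(btwb: np.ndarray, penalty: np.ndarray, lam: float) -> float:
    ridge = 1e-9 * np.eye(btwb.shape[0])
    return float(
        np.trace(np.linalg.solve(btwb + lam * penalty + ridge, btwb))
    )


def _select_lambda(btwb: np.ndarray, penalty: np.ndarray, df: float) -> float:
    """Smoothing constant with trace of the smoother equal to ``df``."""
    if not penalty.any():
        return 0.0
    scale = np.trace(btwb) / max(np.trace(penalty), 1e-12)
    lo, hi = np.log(scale) - 25.0, np.log(scale) + 25.0
    if _edf(btwb, penalty, np.exp(hi)) >= df:
        return float(np.exp(hi))
    if _edf(btwb, penalty, np.exp(lo)) <= df:
        return float(np.exp(lo))
    loglam = optimize.brentq(
        lambda ll: _edf(btwb, penalty, np.exp(ll)) - df, lo, hi, xtol=1e-6
    )
    return float(np.exp(loglam))


def fit_penalized_wls(basis, penalty, z, w, df):
    """Penalized weighted least squares at a requested effective df.

    Returns (coefficients, smoothing constant, achieved df).  With a zero
    penalty this is plain weighted regression and df is the basis dimension.
    """
    w = np.asarray(w, dtype=float)
    btwb = basis.T @ (basis * w[:, None])
    lam = _select_lambda(btwb, penalty, df)
    ridge = 1e-9 * np.eye(btwb.shape[0])
    beta = np.linalg.solve(
        btwb + lam * penalty + ridge, basis.T @ (w * np.asarray(z))
    )
    achieved = _edf(btwb, penalty, lam)
    return beta, lam, achieved


# ---------------------------------------------------------------------------
# vectorized BCT log-likelihood and scores (per-observation parameters)


def _zscore(y, mu, sigma, nu):
    ratio = y / mu
    small = np.abs(nu) <= _NU_EPS
    nu_safe = np.where(small, 1.0, nu)
    z_pow = (ratio**nu - 1.0) / (nu_safe * sigma)
    z_log = np.log(ratio) / sigma
    return np.where(small, z_log, z_pow)


def _log_trunc_mass(sigma, nu, tau):
    # normalizer is T(c) with c = 1/(sigma*|nu|) for either sign of nu
    small = np.abs(nu) <= _NU_EPS
    nu_safe = np.where(small, 1.0, np.abs(nu))
    c = 1.0 / (sigma * nu_safe)
    mass = np.where(small, 1.0, stats.t.cdf(c, df=tau))
    return np.log(np.clip(mass, 1e-300, None))


def _loglik(y, mu, sigma, nu, tau):
    z = _zscore(y, mu, sigma, nu)
    logjac = (nu - 1.0) * np.log(y) - nu * np.log(mu) - np.log(sigma)
    return (
        logjac
        + stats.t.logpdf(z, df=tau)
        - _log_trunc_mass(sigma, nu, tau)
    )


def _deviance(y, mu, sigma, nu, tau) -> float:
    ll = _loglik(y, mu, sigma, nu, tau)
    if not np.all(np.isfinite(ll)):
        bad = int(np.argmax(~np.isfinite(ll)))
        raise FloatingPointError(
            f"non-finite log-likelihood at observation {bad} "
            f"(y={y[bad]:.4g}); check that all y = gain + 20 are positive"
        )
    return float(-2.0 * np.sum(ll))


def _scores(y, mu, sigma, nu, tau):
    """First derivatives of the log-likelihood on each link scale.

    Truncation-mass derivatives are omitted (they are ~1e-10 for fitted
    parameter magnitudes); step-halving on the exact objective keeps the
    iteration honest regardless.
    """
    z = _zscore(y, mu, sigma, nu)
    w_t = (tau + 1.0) / (tau + z**2)
    dldm = w_t * z / (mu * sigma) + (nu / mu) * (w_t * z**2 - 1.0)
    dlds = (w_t * z**2 - 1.0) / sigma

    logym = np.log(y / mu)
    small = np.abs(nu) <= 1e-3
    nu_safe = np.where(small, 1.0, nu)
    dldv = (w_t * z**2) / nu_safe - logym * (
        w_t * z**2 + (w_t * z) / (sigma * nu_safe) - 1.0
    )
    if np.any(small):
        h = 1e-4
        fd = (
            _loglik(y, mu, sigma, nu + h, tau)
            - _loglik(y, mu, sigma, nu - h, tau)
        ) / (2 * h)
        dldv = np.where(small, fd, dldv)

    dldt = (
        0.5 * (special.digamma((tau + 1.0) / 2) - special.digamma(tau / 2))
        - 0.5 / tau
        - 0.5 * np.log1p(z**2 / tau)
        + w_t * z**2 / (2.0 * tau)
    )

    u = {
        "mu": dldm,  # identity link
        "sigma": dlds * sigma,  # log link
        "nu": dldv,
        "tau": dldt * tau,
    }
    w = {
        "mu": (tau + 1.0) / ((tau + 3.0) * mu**2 * sigma**2),
        "sigma": 2.0 * tau / (tau + 3.0) * np.ones_like(z),
        "nu": u["nu"] ** 2,
        "tau": u["tau"] ** 2,
    }
    # stabilize quasi-info weights away from zero
    for name in ("nu", "tau"):
        w[name] = w[name] + 1e-3 * float(np.mean(w[name])) + 1e-8
    return u, w


def _theta_from_eta(eta: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for name, e in eta.items():
        lo, hi = _ETA_BOUNDS[name]
        e = np.clip(e, lo, hi)
        out[name] = np.exp(e) if LINKS[name] == "log" else e
    return out


def fit_gamlss_bct(
    data: list[ShiftedGainRecord],
    spec: ModelSpec | None = None,
    nudge_seed: int | None = None,
) -> FittedChart:
    """Fit the four BCT parameter curves to one BMI group's shifted gains.

    ``data`` must already carry the +20 kg offset (``y > 0``) and the
    nudged week-0 rows.  The returned chart records convergence honestly:
    if the deviance has not stabilized within the iteration budget the
    chart comes back with ``converged=False`` and the deviance path intact.
    """
    spec = spec or ModelSpec()
    if not data:
        raise ValueError("no observations supplied")
    groups = {r.bmi_group for r in data}
    if len(groups) != 1:
        raise ValueError(f"records span multiple BMI groups: {groups}")
    (group,) = groups
    t = np.array([r.gestational_age for r in data], dtype=float)
    y = np.array([r.y for r in data], dtype=float)
    if np.any(y <= 0):
        bad = int(np.argmax(y <= 0))
        raise ValueError(
            f"record {data[bad].woman_id} at {t[bad]:.1f} weeks has "
            f"y = {y[bad]:.3f} <= 0; apply_offset must drop such rows"
        )
    n = y.size
    n_weeks = np.unique(np.round(t)).size
    if n < 200 or n_weeks < 20:
        raise ValueError(
            f"refusing to fit a distributional chart to n={n} observations "
            f"over {n_weeks} distinct weeks; need >= 200 observations "
            "spanning >= 20 distinct weeks for stable S/L/T curves"
        )

    bases: dict[str, np.ndarray] = {}
    penalties: dict[str, np.ndarray] = {}
    curves: dict[str, _Curve] = {}
    for name in PARAM_NAMES:
        cspec = spec.curve(name)
        bases[name], penalties[name] = build_design(t, cspec)
        knots, degree, dim, _ = _curve_skeleton(cspec)
        curves[name] = _Curve(knots, degree, np.zeros(dim), 0.0, 0.0)

    # warm start: median curve from a plain least-squares fit of y,
    # constant S/L/T on the link scale (B-splines sum to one, so a
    # constant coefficient vector gives a constant curve)
    beta0, _, _ = fit_penalized_wls(
        bases["mu"], penalties["mu"], y, np.ones(n), spec.m_curve.dimension
    )
    curves["mu"].beta = beta0
    resid = y - bases["mu"] @ beta0
    mad = float(np.median(np.abs(resid))) * 1.4826
    sigma0 = float(np.clip(mad / float(np.median(y)), 0.01, 0.5))
    curves["sigma"].beta = np.full(curves["sigma"].beta.size, np.log(sigma0))
    curves["nu"].beta = np.full(curves["nu"].beta.size, 1.0)
    curves["tau"].beta = np.full(curves["tau"].beta.size, np.log(10.0))

    df_request = {
        "mu": float(spec.m_curve.dimension),
        "sigma": spec.s_curve.df,
        "nu": spec.l_curve.df,
        "tau": spec.t_curve.df,
    }
    n_freeze = 3  # smoothing constants re-selected during the first cycles

    def current_eta():
        return {name: bases[name] @ curves[name].beta for name in PARAM_NAMES}

    def objective(theta) -> float:
        dev = _deviance(y, theta["mu"], theta["sigma"], theta["nu"], theta["tau"])
        pen = sum(
            curves[p].lam * curves[p].beta @ penalties[p] @ curves[p].beta
            for p in PARAM_NAMES
        )
        return dev + pen

    eta = current_eta()
    theta = _theta_from_eta(eta)
    deviance_path = [_deviance(y, theta["mu"], theta["sigma"], theta["nu"], theta["tau"])]
    objective_path: list[float] = []
    converged = False
    iterations = 0

    for outer in range(1, spec.max_outer_iterations + 1):
        iterations = outer
        for name in PARAM_NAMES:
            eta = current_eta()
            theta = _theta_from_eta(eta)
            u, w = _scores(y, theta["mu"], theta["sigma"], theta["nu"], theta["tau"])
            # no per-observation clipping of the ratio: the weight floor
            # bounds it, and clipping would bias the aggregate step
            wi = np.clip(w[name], 1e-10, 1e10)
            zwork = eta[name] + u[name] / wi
            btwb = bases[name].T @ (bases[name] * wi[:, None])
            if outer <= n_freeze:
                lam = _select_lambda(btwb, penalties[name], df_request[name])
                curves[name].lam = lam
                curves[name].df = _edf(btwb, penalties[name], lam)
            lam = curves[name].lam
            ridge = 1e-9 * np.eye(btwb.shape[0])
            beta_new = np.linalg.solve(
                btwb + lam * penalties[name] + ridge,
                bases[name].T @ (wi * zwork),
            )
            # step-halving on the penalized objective
            beta_old = curves[name].beta.copy()
            obj_old = objective(_theta_from_eta(current_eta()))
            alpha = 1.0
            for _ in range(12):
                curves[name].beta = beta_old + alpha * (beta_new - beta_old)
                try:
                    obj_new = objective(_theta_from_eta(current_eta()))
                except FloatingPointError:
                    obj_new = np.inf
                if obj_new <= obj_old + 1e-10:
                    break
                alpha *= 0.5
            else:
                curves[name].beta = beta_old
        theta = _theta_from_eta(current_eta())
        dev = _deviance(y, theta["mu"], theta["sigma"], theta["nu"], theta["tau"])
        deviance_path.append(dev)
        if outer > n_freeze:
            objective_path.append(objective(theta))
        if abs(deviance_path[-2] - deviance_path[-1]) < spec.tol and outer > n_freeze:
            converged = True
            break

    # unpenalized mu curve spends its full basis dimension
    curves["mu"].df = df_request["mu"]
    edf_total = sum(curves[p].df for p in PARAM_NAMES)
    # store the converged information matrices for pointwise SEs
    theta = _theta_from_eta(current_eta())
    _, w_fin = _scores(y, theta["mu"], theta["sigma"], theta["nu"], theta["tau"])
    for name in PARAM_NAMES:
        wi = np.clip(w_fin[name], 1e-10, 1e10)
        curves[name].info = bases[name].T @ (bases[name] * wi[:, None])
        curves[name].penalty = penalties[name]
    dev = deviance_path[-1]
    bic = dev + np.log(n) * edf_total
    return FittedChart(
        bmi_group=group,
        spec=spec,
        curves=curves,
        global_deviance=dev,
        effective_df_total=edf_total,
        bic=float(bic),
        n_observations=n,
        nudge_seed=nudge_seed,
        converged=converged,
        iterations=iterations,
        deviance_path=deviance_path,
        objective_path=objective_path,
    )


def predict_params(chart: FittedChart, t: float) -> BCTParams:
    """Evaluate the fitted curves at one gestational age (weeks)."""
    if not (DOMAIN[0] <= t <= DOMAIN[1]):
        raise ValueError(f"gestational age {t} outside domain {DOMAIN}")
    ta = np.array([float(t)])
    eta = {name: chart.curves[name].eta(ta) for name in PARAM_NAMES}
    theta = _theta_from_eta(eta)
    return BCTParams(
        mu=float(theta["mu"][0]),
        sigma=float(theta["sigma"][0]),
        nu=float(theta["nu"][0]),
        tau=float(theta["tau"][0]),
    )


def curve_standard_error(chart: FittedChart, param: str, t) -> np.ndarray:
    """Approximate pointwise standard error of a fitted link-scale curve.

    Uses the sandwich of the penalized information at convergence,
    Var(eta) = X (B'WB + lam P)^-1 B'WB (B'WB + lam P)^-1 X'.
    """
    c = chart.curves[param]
    if c.info is None:
        raise ValueError("chart carries no information matrices")
    x = c.design(np.atleast_1d(np.asarray(t, dtype=float)))
    a = c.info + c.lam * c.penalty + 1e-9 * np.eye(c.info.shape[0])
    ainv_b = np.linalg.solve(a, c.info)
    cov = np.linalg.solve(a, ainv_b.T).T  # A^-1 B'WB A^-1
    var = np.einsum("ij,jk,ik->i", x, cov, x)
    return np.sqrt(np.clip(var, 0.0, None))


def predict_median_gain(chart: FittedChart, t: float) -> float:
    """Fitted median weight gain (kg) at ``t`` weeks (mu(t) - 20)."""
    from .preprocess import GAIN_OFFSET_KG

    return predict_params(chart, t).mu - GAIN_OFFSET_KG


def fit_linear_baseline(data: list[GainRecord]) -> LinearBaselineFit:
    """Straight-line Gaussian fit of gain on gestational age.

    The comparison baseline for the BIC check; bic uses the Gaussian
    maximum likelihood with 3 parameters (intercept, slope, variance).
    """
    import statsmodels.api as sm

    if len(data) < 3:
        raise ValueError("need at least 3 observations")
    t = np.array([r.gestational_age for r in data], dtype=float)
    g = np.array([r.gain for r in data], dtype=float)
    if np.unique(t).size < 2:
        raise ValueError("degenerate design: all gestational ages identical")
    res = sm.OLS(g, sm.add_constant(t)).fit()
    n = t.size
    rss = float(np.sum(res.resid**2))
    if rss <= 0:
        bic = -np.inf
    else:
        bic = n * np.log(rss / n) + n * (np.log(2 * np.pi) + 1) + 3 * np.log(n)
    return LinearBaselineFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        residual_sd=float(np.sqrt(rss / n)),
        bic=float(bic),
        n=n,
    )
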