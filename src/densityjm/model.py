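"""Core joint-model quantities.

The longitudinal submodel is a natural-cubic-spline mixed-effects model for
square-root dense area with Gaussian measurement error,

    y_ij = m_i(t_ij) + e_ij,      e_ij ~ N(0, sigma^2),
    m_i(t) = x_i(t)' beta + z_i(t)' b_i + u_i' delta,   b_i ~ N(0, D),

with 13 fixed effects (intercept, three spline terms, and spline-by-MHT and
spline-by-menopausal-status interactions), four baseline covariate effects
delta (BMI, MHT former, MHT current, postmenopausal), and a 4-dimensional
random effect (intercept + three spline coefficients).

The event submodel is a proportional-hazards model on model time
t = age - 40 with penalized-spline log baseline hazard,

    h_i(t) = h0(t) exp(gamma' w_i + f(m_i(t), b_i, alpha)),

where w_i = (BMI, MHT former, MHT current, FH yes, FH missing) and f is one
of three association structures: the current value alpha * m_i(t), the
current value and slope alpha1 * m_i(t) + alpha2 * m_i'(t), or the
cumulative value alpha * int_{t0}^{t} m_i(s) ds.

Subjects enter the risk set at their second screen (delayed entry); the
event likelihood conditions on survival to entry, so only the hazard on
[entry, exit] contributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .splines import (
    BaselineHazardSpec,
    SplineSpec,
    bspline_basis,
    natural_cubic_basis,
    natural_cubic_basis_derivative,
    natural_cubic_basis_integral,
    quadrature_breakpoints,
)

__all__ = [
    "MHT_LEVELS",
    "MP_LEVELS",
    "FH_LEVELS",
    "ASSOCIATION_STRUCTURES",
    "SubjectRecord",
    "LongitudinalRecord",
    "LongitudinalParams",
    "SurvivalParams",
    "fixed_design_row",
    "random_design_row",
    "baseline_covariate_vector",
    "hazard_covariate_vector",
    "trajectory_value",
    "trajectory_slope",
    "trajectory_cumulative",
    "log_hazard",
    "cumulative_hazard",
    "subject_log_likelihood",
]

MHT_LEVELS = ("never", "former", "current")
MP_LEVELS = ("pre", "post")
FH_LEVELS = ("no", "yes", "missing")
ASSOCIATION_STRUCTURES = ("current_value", "value_and_slope", "cumulative")

MAX_MODEL_TIME = 40.0  # follow-up ends at age 80

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(15)


@dataclass(frozen=True)
class SubjectRecord:
    """One-row-per-woman survival and baseline-covariate record.

    Times are model time (years since age 40); entry is the second screen.
    """

    id: int | str
    entry_time: float
    exit_time: float
    event: int
    bmi: float
    mht: str
    mp: str
    fh: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.entry_time < self.exit_time <= MAX_MODEL_TIME):
            raise ValueError(
                f"subject {self.id}: require 0 <= entry < exit <= {MAX_MODEL_TIME}, "
                f"got entry={self.entry_time}, exit={self.exit_time}"
            )
        if self.event not in (0, 1):
            raise ValueError(f"subject {self.id}: event must be 0/1")
        if self.mht not in MHT_LEVELS:
            raise ValueError(f"subject {self.id}: unknown MHT level {self.mht!r}")
        if self.mp not in MP_LEVELS:
            raise ValueError(f"subject {self.id}: unknown MP level {self.mp!r}")
        if self.fh not in FH_LEVELS:
            raise ValueError(f"subject {self.id}: unknown FH level {self.fh!r}")


@dataclass(frozen=True)
class LongitudinalRecord:
    """One mammographic density measurement: model time and sqrt dense area."""

    id: int | str
    t: float
    y: float


@dataclass
class LongitudinalParams:
    """Parameters of the longitudinal submodel.

    beta: 13 fixed effects (intercept, 3 spline, 9 spline-by-covariate);
    delta: baseline effects (BMI, MHT former, MHT current, MP post);
    sigma: residual SD of the measurement error (sqrt cm^2 scale);
    D: 4x4 covariance of the random intercept + spline coefficients.
    """

    beta: np.ndarray
    delta: np.ndarray
    sigma: float
    D: np.ndarray
    spline: SplineSpec = field(default_factory=SplineSpec)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        nb = self.spline.n_basis
        if self.beta.shape != (1 + 4 * nb,):
            raise ValueError(f"beta must have length {1 + 4 * nb}")
        if self.delta.shape != (4,):
            raise ValueError("delta must have length 4")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.D.shape != (1 + nb, 1 + nb) or not np.allclose(self.D, self.D.T):
            raise ValueError("D must be symmetric with dimension 1 + n_basis")
        np.linalg.cholesky(self.D)  # raises if not positive definite


@dataclass
class SurvivalParams:
    """Parameters of the event submodel.

    gamma: log hazard ratios for (BMI, MHT former, MHT current, FH yes,
    FH missing); assoc selects the association structure; alpha holds one
    coefficient (or two for value_and_slope); baseline_coefs are the log
    baseline hazard B-spline coefficients with difference-penalty weight
    ``smoothing``; t0 is the lower limit of the cumulative integral.
    """

    gamma: np.ndarray
    assoc: str
    alpha: np.ndarray
    baseline_coefs: np.ndarray
    smoothing: float = 1.0
    t0: float = 0.0
    baseline: BaselineHazardSpec = field(default_factory=BaselineHazardSpec)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.baseline_coefs = np.asarray(self.baseline_coefs, dtype=float)
        if self.assoc not in ASSOCIATION_STRUCTURES:
            raise ValueError(f"unknown association structure {self.assoc!r}")
        n_alpha = 2 if self.assoc == "value_and_slope" else 1
        if self.alpha.shape != (n_alpha,):
            raise ValueError(
                f"association {self.assoc!r} requires {n_alpha} alpha coefficient(s)"
            )
        if self.gamma.shape != (5,):
            raise ValueError("gamma must have length 5")
        if self.baseline_coefs.shape != (self.baseline.n_basis,):
            raise ValueError("baseline_coefs must match the baseline basis size")
        if self.smoothing <= 0:
            raise ValueError("smoothing must be positive")
        if not (0.0 <= self.t0 <= MAX_MODEL_TIME):
            raise ValueError("t0 must lie in the follow-up window")


def _dummies(level: str, levels: tuple[str, ...]) -> np.ndarray:
    if level not in levels:
        raise ValueError(f"unknown category {level!r}; expected one of {levels}")
    return np.array([level == l for l in levels[1:]], dtype=float)


def fixed_design_row(t, mht: str, mp: str, spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """Fixed-effects design row(s) x_i(t) of the trajectory model.

    Layout: [1, B1, B2, B3, B*MHT_former (3), B*MHT_current (3), B*MP_post (3)].
    Accepts scalar or array t; the covariate axis is last.
    """
    mht1, mht2 = _dummies(mht, MHT_LEVELS)
    (mp1,) = _dummies(mp, MP_LEVELS)
    B = natural_cubic_basis(t, spec)
    one = np.ones(B.shape[:-1] + (1,))
    return np.concatenate([one, B, B * mht1, B * mht2, B * mp1], axis=-1)


def random_design_row(t, spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """Random-effects design row(s) z_i(t): intercept plus the spline basis."""
    B = natural_cubic_basis(t, spec)
    one = np.ones(B.shape[:-1] + (1,))
    return np.concatenate([one, B], axis=-1)


def baseline_covariate_vector(subject: SubjectRecord) -> np.ndarray:
    """u_i = (BMI, MHT former, MHT current, MP post) for the delta term."""
    return np.concatenate(
        [[subject.bmi], _dummies(subject.mht, MHT_LEVELS), _dummies(subject.mp, MP_LEVELS)]
    )


def hazard_covariate_vector(subject: SubjectRecord) -> np.ndarray:
    """w_i = (BMI, MHT former, MHT current, FH yes, FH missing) for gamma."""
    return np.concatenate(
        [[subject.bmi], _dummies(subject.mht, MHT_LEVELS), _dummies(subject.fh, FH_LEVELS)]
    )


def trajectory_value(t, subject: SubjectRecord, params: LongitudinalParams, b) -> np.ndarray:
    """Latent sqrt-density m_i(t) = x_i(t)'beta + z_i(t)'b + u_i'delta."""
    b = np.asarray(b, dtype=float)
    x = fixed_design_row(t, subject.mht, subject.mp, params.spline)
    z = random_design_row(t, params.spline)
    u = baseline_covariate_vector(subject)
    return x @ params.beta + z @ b + u @ params.delta


def trajectory_slope(t, subject: SubjectRecord, params: LongitudinalParams, b) -> np.ndarray:
    """Rate of change m_i'(t); the baseline covariate term is constant in t."""
    b = np.asarray(b, dtype=float)
    dB = natural_cubic_basis_derivative(t, params.spline)
    mht1, mht2 = _dummies(subject.mht, MHT_LEVELS)
    (mp1,) = _dummies(subject.mp, MP_LEVELS)
    zero = np.zeros(dB.shape[:-1] + (1,))
    dx = np.concatenate([zero, dB, dB * mht1, dB * mht2, dB * mp1], axis=-1)
    dz = np.concatenate([zero, dB], axis=-1)
    return dx @ params.beta + dz @ b


def trajectory_cumulative(
    t, subject: SubjectRecord, params: LongitudinalParams, b, t0: float = 0.0
) -> np.ndarray:
    """Accumulated latent density int_{t0}^{t} m_i(s) ds (closed form)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < t0):
        raise ValueError("trajectory_cumulative requires t >= t0")
    b = np.asarray(b, dtype=float)
    IB = natural_cubic_basis_integral(t0, t_arr, params.spline)
    mht1, mht2 = _dummies(subject.mht, MHT_LEVELS)
    (mp1,) = _dummies(subject.mp, MP_LEVELS)
    span = np.asarray(t_arr - t0, dtype=float)[..., None]
    ix = np.concatenate([span, IB, IB * mht1, IB * mht2, IB * mp1], axis=-1)
    iz = np.concatenate([span, IB], axis=-1)
    u = baseline_covariate_vector(subject)
    const = (t_arr - t0) * (u @ params.delta)
    return ix @ params.beta + iz @ b + const


def _association(t, subject, long_params, surv_params, b):
    a = surv_params.alpha
    if surv_params.assoc == "current_value":
        return a[0] * trajectory_value(t, subject, long_params, b)
    if surv_params.assoc == "value_and_slope":
        return a[0] * trajectory_value(t, subject, long_params, b) + a[1] * trajectory_slope(
            t, subject, long_params, b
        )
    return a[0] * trajectory_cumulative(t, subject, long_params, b, surv_params.t0)


def log_hazard(
    t,
    subject: SubjectRecord,
    long_params: LongitudinalParams,
    surv_params: SurvivalParams,
    b,
) -> np.ndarray:
    """log h_i(t) = log h0(t) + gamma'w_i + f(m_i(t), b_i, alpha)."""
    w = hazard_covariate_vector(subject)
    log_h0 = bspline_basis(t, surv_params.baseline) @ surv_params.baseline_coefs
    return log_h0 + w @ surv_params.gamma + _association(t, subject, long_params, surv_params, b)


def _gl_segments(a: float, bnd: float, breaks: np.ndarray):
    """15-node Gauss-Legendre nodes/weights on [a, bnd], split at spline knots."""
    cuts = np.concatenate(([a], breaks[(breaks > a) & (breaks < bnd)], [bnd]))
    lo, hi = cuts[:-1], cuts[1:]
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    nodes = (mid[:, None] + half[:, None] * _GL_NODES).ravel()
    weights = (half[:, None] * _GL_WEIGHTS).ravel()
    return nodes, weights


def cumulative_hazard(
    a: float,
    bnd: float,
    subject: SubjectRecord,
    long_params: LongitudinalParams,
    surv_params: SurvivalParams,
    b,
) -> float:
    """int_a^bnd h_i(s) ds by fixed-order Gauss-Legendre quadrature.

    The integration interval is split at the spline knots (where the
    integrand loses smoothness) with 15 nodes per segment; the inner
    cumulative-density integral is analytic, so no nested quadrature occurs.
    """
    if a > bnd:
        raise ValueError("cumulative_hazard requires a <= bnd")
    if a == bnd:
        return 0.0
    breaks = quadrature_breakpoints(long_params.spline, surv_params.baseline)
    nodes, weights = _gl_segments(a, bnd, breaks)
    lh = log_hazard(nodes, subject, long_params, surv_params, b)
    if not np.all(np.isfinite(lh)):
        raise ValueError("non-finite log hazard encountered")
    return float(weights @ np.exp(lh))


def subject_log_likelihood(
    subject: SubjectRecord,
    measurements,
    long_params: LongitudinalParams,
    surv_params: SurvivalParams,
    b,
) -> float:
    """Joint log likelihood contribution of one subject, conditional on b.

    Sum of Gaussian measurement terms plus the delayed-entry event term
    event * log h_i(exit) - int_{entry}^{exit} h_i(s) ds (the survival part
    conditions on being event-free at entry).
    """
    ll = 0.0
    if len(measurements):
        for rec in measurements:
            if rec.id != subject.id:
                raise ValueError("measurement does not belong to this subject")
        ts = np.array([rec.t for rec in measurements])
        ys = np.array([rec.y for rec in measurements])
        m = trajectory_value(ts, subject, long_params, b)
        s2 = long_params.sigma**2
        ll += float(np.sum(-0.5 * np.log(2.0 * np.pi * s2) - 0.5 * (ys - m) ** 2 / s2))
    if subject.event:
        ll += float(log_hazard(subject.exit_time, subject, long_params, surv_params, b))
    ll -= cumulative_hazard(
        subject.entry_time, subject.exit_time, subject, long_params, surv_params, b
    )
    return ll
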