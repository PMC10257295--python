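"""Spline bases for the density trajectory and the baseline hazard.

Two bases live here:

* a 3-column **natural cubic spline** basis for the population and
  subject-level density trajectories (interior knots at ages 50 and 55,
  boundary knots at ages 43 and 65, linear beyond the boundaries), with
  exact derivatives and closed-form integrals;
* a **cubic B-spline** basis with a difference penalty (P-spline) for the
  log baseline hazard over the screening age window 40-80.

All evaluation is on the model time scale t = age - 40 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline, CubicSpline, PPoly

__all__ = [
    "SplineSpec",
    "BaselineHazardSpec",
    "natural_cubic_basis",
    "natural_cubic_basis_derivative",
    "natural_cubic_basis_integral",
    "bspline_basis",
    "difference_penalty",
    "quadrature_breakpoints",
]

_PAD = 1.0  # width of the explicit linear tail segments (extrapolation
# beyond them remains exact: PPoly extends the linear/quadratic end pieces)


@dataclass(frozen=True)
class SplineSpec:
    """Knot configuration for the natural cubic trajectory basis.

    Knots are given on the age scale (years) and converted internally to
    model time ``t = age - time_origin``.  The basis has
    ``len(interior_knots) + 1`` columns (3 with the defaults); the model
    intercept is *not* part of the basis.
    """

    interior_knots: tuple[float, ...] = (50.0, 55.0)
    boundary_knots: tuple[float, float] = (43.0, 65.0)
    time_origin: float = 40.0

    def __post_init__(self) -> None:
        knots = (self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1])
        if not all(a < b for a, b in zip(knots, knots[1:])):
            raise ValueError(
                "knots must be strictly increasing with interior knots inside "
                f"the boundary knots, got {knots}"
            )

    @property
    def knots_model_time(self) -> np.ndarray:
        """All knots (boundary, interior, boundary) as model time."""
        return np.asarray(
            (self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1]),
            dtype=float,
        ) - self.time_origin

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + 1


@dataclass(frozen=True)
class BaselineHazardSpec:
    """Penalized B-spline (P-spline) configuration for the log baseline hazard.

    The basis covers model time ``knot_range`` = [0, 40] (ages 40-80) with
    ``n_basis`` cubic B-spline columns on equally spaced knots and an
    order-``penalty_order`` difference penalty on the coefficients.
    """

    n_basis: int = 8
    degree: int = 3
    knot_range: tuple[float, float] = (0.0, 40.0)
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.n_basis <= self.degree:
            raise ValueError("n_basis must exceed the spline degree")
        if self.penalty_order >= self.n_basis:
            raise ValueError("penalty_order must be smaller than n_basis")
        if not self.knot_range[0] < self.knot_range[1]:
            raise ValueError("knot_range must be an increasing interval")

    @property
    def knot_vector(self) -> np.ndarray:
        """Clamped knot vector on model time."""
        lo, hi = self.knot_range
        n_interior = self.n_basis - self.degree - 1
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        return np.concatenate(
            [np.full(self.degree + 1, lo), interior, np.full(self.degree + 1, hi)]
        )

    @property
    def interior_knots(self) -> np.ndarray:
        n_interior = self.n_basis - self.degree - 1
        return np.linspace(*self.knot_range, n_interior + 2)[1:-1]


def _extend_linear(pp: PPoly) -> PPoly:
    """Append explicit linear tail segments so extrapolation is linear."""
    lo, hi = pp.x[0], pp.x[-1]
    dpp = pp.derivative()
    v_lo, s_lo = float(pp(lo)), float(dpp(lo))
    v_hi, s_hi = float(pp(hi)), float(dpp(hi))
    x = np.concatenate([[lo - _PAD], pp.x, [hi + _PAD]])
    k = pp.c.shape[0]
    c = np.zeros((k, pp.c.shape[1] + 2))
    c[:, 1:-1] = pp.c
    # left tail: value and slope matched at lo, local coordinate t - (lo - PAD)
    c[-2, 0] = s_lo
    c[-1, 0] = v_lo - _PAD * s_lo
    # right tail: local coordinate t - hi
    c[-2, -1] = s_hi
    c[-1, -1] = v_hi
    return PPoly(c, x, extrapolate=True)


class _NaturalBasis:
    """Cardinal natural cubic splines at the non-leading knots.

    Column k interpolates the indicator of knot k+1 under natural boundary
    conditions (zero second derivative at the boundary knots) and is
    extended linearly beyond them.  Together with the constant these
    columns span the natural cubic spline space on the given knots.
    """

    def __init__(self, spec: SplineSpec) -> None:
        knots = spec.knots_model_time
        cols = []
        for j in range(1, len(knots)):
            e = np.zeros(len(knots))
            e[j] = 1.0
            cs = CubicSpline(knots, e, bc_type="natural")
            cols.append(_extend_linear(PPoly(cs.c, cs.x)))
        self.columns = cols
        self.derivatives = [c.derivative() for c in cols]
        self.antiderivatives = [c.antiderivative() for c in cols]

    def value(self, t):
        t = np.asarray(t, dtype=float)
        return np.stack([c(t) for c in self.columns], axis=-1)

    def deriv(self, t):
        t = np.asarray(t, dtype=float)
        return np.stack([d(t) for d in self.derivatives], axis=-1)

    def integral(self, a, b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        return np.stack([f(b) - f(a) for f in self.antiderivatives], axis=-1)


@lru_cache(maxsize=8)
def _natural_basis(spec: SplineSpec) -> _NaturalBasis:
    return _NaturalBasis(spec)


def natural_cubic_basis(t, spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """Evaluate the natural cubic trajectory basis at model time ``t``.

    Returns an array with a trailing axis of length ``spec.n_basis`` (3 for
    the default knots).  Each column is C2 inside the boundary knots and
    exactly linear outside them.
    """
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    return _natural_basis(spec).value(t)


def natural_cubic_basis_derivative(t, spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """First derivative of each trajectory basis column at model time ``t``."""
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    return _natural_basis(spec).deriv(t)


def natural_cubic_basis_integral(a, b, spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """Exact integral of each basis column over [a, b] (model time).

    Computed from the piecewise-polynomial antiderivative; no quadrature.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if np.any(a_arr > b_arr):
        raise ValueError("integration requires a <= b")
    return _natural_basis(spec).integral(a_arr, b_arr)


@lru_cache(maxsize=8)
def _bspline_elements(spec: BaselineHazardSpec) -> tuple[BSpline, ...]:
    kv = spec.knot_vector
    return tuple(
        BSpline.basis_element(kv[i : i + spec.degree + 2], extrapolate=False)
        for i in range(spec.n_basis)
    )


def bspline_basis(t, spec: BaselineHazardSpec = BaselineHazardSpec()) -> np.ndarray:
    """Baseline-hazard B-spline basis at model time ``t``, clamped to its range.

    Values are nonnegative and sum to 1 at every t (partition of unity).
    """
    lo, hi = spec.knot_range
    t = np.clip(np.asarray(t, dtype=float), lo, hi)
    out = np.stack(
        [np.nan_to_num(el(t), nan=0.0) for el in _bspline_elements(spec)], axis=-1
    )
    # basis_element treats the right endpoint as outside the half-open support
    at_hi = np.asarray(t == hi)
    if np.any(at_hi):
        out[..., at_hi, :] = 0.0
        out[..., at_hi, -1] = 1.0
    return out


def difference_penalty(spec: BaselineHazardSpec = BaselineHazardSpec()) -> np.ndarray:
    """P-spline roughness penalty K = D'D for order-d differences.

    Symmetric positive semi-definite with rank ``n_basis - penalty_order``;
    polynomial coefficient sequences of degree < d are unpenalized.
    """
    d = np.diff(np.eye(spec.n_basis), spec.penalty_order, axis=0)
    return d.T @ d


def quadrature_breakpoints(
    spline_spec: SplineSpec = SplineSpec(),
    baseline_spec: BaselineHazardSpec = BaselineHazardSpec(),
) -> np.ndarray:
    """Sorted union of all knot locations (model time) where the hazard
    integrand loses smoothness; used to segment Gauss-Legendre panels."""
    pts = np.concatenate(
        [spline_spec.knots_model_time, baseline_spec.interior_knots, baseline_spec.knot_range]
    )
    return np.unique(pts)
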