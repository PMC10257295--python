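"""Vectorized joint-model likelihood over a cohort.

Precomputes every design quantity that is fixed during MCMC — longitudinal
design matrices, Gauss-Legendre quadrature nodes on each subject's at-risk
interval [entry, exit] (segmented at the spline knots), and the association
design at the nodes and exit times — so that a full log-likelihood
evaluation reduces to a handful of matrix products.

The association term is expressed uniformly for all three structures: each
alpha component multiplies a functional of the trajectory that is linear in
(beta, b, u'delta),

    F_j(t) = AX_j(t)' beta + AZ_j(t)' b_i + c_j(t) * u_i' delta,

with (AX, AZ, c) = (x(t), z(t), 1) for the current value, the derivative
design with c = 0 for the slope, and the integrated design with
c = t - t0 for the cumulative structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import FH_LEVELS, MHT_LEVELS, MP_LEVELS
from .splines import (
    BaselineHazardSpec,
    SplineSpec,
    bspline_basis,
    natural_cubic_basis,
    natural_cubic_basis_derivative,
    natural_cubic_basis_integral,
    quadrature_breakpoints,
)

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(15)

LOG_2PI = float(np.log(2.0 * np.pi))


def _dummy_cols(series: pd.Series, levels) -> np.ndarray:
    vals = series.to_numpy()
    return np.stack([(vals == l).astype(float) for l in levels[1:]], axis=1)


class CohortLikelihood:
    """Fixed data + design arrays for fast repeated likelihood evaluation."""

    def __init__(
        self,
        subjects: pd.DataFrame,
        longitudinal: pd.DataFrame,
        assoc: str = "current_value",
        t0: float = 0.0,
        spline_spec: SplineSpec | None = None,
        baseline_spec: BaselineHazardSpec | None = None,
    ) -> None:
        self.spline_spec = spline_spec or SplineSpec()
        self.baseline_spec = baseline_spec or BaselineHazardSpec()
        self.assoc = assoc
        self.t0 = float(t0)

        subjects = subjects.reset_index(drop=True)
        self.subject_ids = subjects["id"].to_numpy()
        self.n = len(subjects)
        idx_of = {sid: k for k, sid in enumerate(self.subject_ids)}

        self.entry = subjects["entry"].to_numpy(dtype=float)
        self.exit = subjects["exit"].to_numpy(dtype=float)
        self.events = subjects["event"].to_numpy(dtype=float)
        self.n_events = int(self.events.sum())

        mht_d = _dummy_cols(subjects["mht"], MHT_LEVELS)
        mp_d = _dummy_cols(subjects["mp"], MP_LEVELS)
        fh_d = _dummy_cols(subjects["fh"], FH_LEVELS)
        bmi = subjects["bmi"].to_numpy(dtype=float)
        self.U = np.column_stack([bmi, mht_d, mp_d])  # delta design
        self.W = np.column_stack([bmi, mht_d, fh_d])  # gamma design

        # --- longitudinal design -------------------------------------------------
        self.obs_sub = np.array([idx_of[i] for i in longitudinal["id"]], dtype=np.intp)
        self.y = longitudinal["y"].to_numpy(dtype=float)
        t_obs = longitudinal["t"].to_numpy(dtype=float)
        self.n_obs = len(self.y)
        self.X = self._fixed_design(t_obs, self.obs_sub, mht_d, mp_d)
        self.Z = self._random_design(t_obs)
        self.obs_count = np.bincount(self.obs_sub, minlength=self.n).astype(float)
        dim_b = self.Z.shape[1]
        self.SZZ = np.zeros((self.n, dim_b, dim_b))
        np.add.at(self.SZZ, self.obs_sub, self.Z[:, :, None] * self.Z[:, None, :])
        # combined design for the (beta, delta) conditional proposal
        self.A = np.column_stack([self.X, self.U[self.obs_sub]])
        self.AtA = self.A.T @ self.A

        # --- quadrature nodes on [entry, exit], segmented at spline knots --------
        breaks = quadrature_breakpoints(self.spline_spec, self.baseline_spec)
        nodes, weights, subj = [], [], []
        for k in range(self.n):
            a, bnd = self.entry[k], self.exit[k]
            cuts = np.concatenate(([a], breaks[(breaks > a) & (breaks < bnd)], [bnd]))
            half = 0.5 * np.diff(cuts)
            mid = 0.5 * (cuts[:-1] + cuts[1:])
            nodes.append((mid[:, None] + half[:, None] * _GL_NODES).ravel())
            weights.append((half[:, None] * _GL_WEIGHTS).ravel())
            subj.append(np.full(15 * len(half), k, dtype=np.intp))
        self.q_t = np.concatenate(nodes)
        self.q_w = np.concatenate(weights)
        self.q_sub = np.concatenate(subj)

        self.Bq = bspline_basis(self.q_t, self.baseline_spec)
        self.Be = bspline_basis(self.exit, self.baseline_spec)

        # --- association designs -------------------------------------------------
        terms = {
            "current_value": ("value",),
            "value_and_slope": ("value", "slope"),
            "cumulative": ("cumulative",),
        }[assoc]
        self.n_alpha = len(terms)
        self.AXq, self.AZq, self.cq = [], [], []
        self.AXe, self.AZe, self.ce = [], [], []
        for term in terms:
            for t_arr, sub, store_x, store_z, store_c in (
                (self.q_t, self.q_sub, self.AXq, self.AZq, self.cq),
                (self.exit, np.arange(self.n), self.AXe, self.AZe, self.ce),
            ):
                ax, az, c = self._assoc_design(term, t_arr, sub, mht_d, mp_d)
                store_x.append(ax)
                store_z.append(az)
                store_c.append(c)

    # ------------------------------------------------------------------ designs
    def _fixed_design(self, t, sub, mht_d, mp_d, basis=natural_cubic_basis):
        B = basis(t, self.spline_spec)
        one = np.ones((len(t), 1))
        m1 = mht_d[sub, 0:1]
        m2 = mht_d[sub, 1:2]
        p1 = mp_d[sub, 0:1]
        return np.concatenate([one, B, B * m1, B * m2, B * p1], axis=1)

    def _random_design(self, t, basis=natural_cubic_basis):
        B = basis(t, self.spline_spec)
        return np.concatenate([np.ones((len(t), 1)), B], axis=1)

    def _assoc_design(self, term, t, sub, mht_d, mp_d):
        if term == "value":
            return (
                self._fixed_design(t, sub, mht_d, mp_d),
                self._random_design(t),
                np.ones(len(t)),
            )
        if term == "slope":
            dB = natural_cubic_basis_derivative(t, self.spline_spec)
            zero = np.zeros((len(t), 1))
            m1 = mht_d[sub, 0:1]
            m2 = mht_d[sub, 1:2]
            p1 = mp_d[sub, 0:1]
            ax = np.concatenate([zero, dB, dB * m1, dB * m2, dB * p1], axis=1)
            az = np.concatenate([zero, dB], axis=1)
            return ax, az, np.zeros(len(t))
        # cumulative
        IB = natural_cubic_basis_integral(self.t0, t, self.spline_spec)
        span = (t - self.t0)[:, None]
        m1 = mht_d[sub, 0:1]
        m2 = mht_d[sub, 1:2]
        p1 = mp_d[sub, 0:1]
        ax = np.concatenate([span, IB, IB * m1, IB * m2, IB * p1], axis=1)
        az = np.concatenate([span, IB], axis=1)
        return ax, az, (t - self.t0).copy()

    # --------------------------------------------------------------- evaluation
    def assoc_functionals(self, beta, delta, b):
        """Per-term trajectory functionals at quadrature nodes and exits."""
        ud = self.U @ delta
        Mq = [
            ax @ beta + np.einsum("ij,ij->i", az, b[self.q_sub]) + c * ud[self.q_sub]
            for ax, az, c in zip(self.AXq, self.AZq, self.cq)
        ]
        Me = [
            ax @ beta + np.einsum("ij,ij->i", az, b) + c * ud
            for ax, az, c in zip(self.AXe, self.AZe, self.ce)
        ]
        return Mq, Me

    def survival_loglik_parts(self, Mq, Me, alpha, gamma, theta):
        """Per-subject event log-likelihood given cached functionals."""
        eta = self.W @ gamma
        fq = sum(a * m for a, m in zip(alpha, Mq))
        fe = sum(a * m for a, m in zip(alpha, Me))
        lhq = self.Bq @ theta + eta[self.q_sub] + fq
        cum = np.bincount(self.q_sub, weights=self.q_w * np.exp(lhq), minlength=self.n)
        lhe = self.Be @ theta + eta + fe
        return self.events * lhe - cum

    def longitudinal_loglik_parts(self, beta, delta, sigma, b):
        """Per-subject Gaussian measurement log-likelihood."""
        resid = self.residuals(beta, delta, b)
        rss = np.bincount(self.obs_sub, weights=resid**2, minlength=self.n)
        return -0.5 * self.obs_count * (LOG_2PI + 2.0 * np.log(sigma)) - 0.5 * rss / sigma**2

    def residuals(self, beta, delta, b):
        mu = self.X @ beta + np.einsum("ij,ij->i", self.Z, b[self.obs_sub])
        mu += (self.U @ delta)[self.obs_sub]
        return self.y - mu

    def loglik_parts(self, beta, delta, sigma, b, alpha, gamma, theta):
        """(longitudinal, survival) per-subject log-likelihood vectors."""
        Mq, Me = self.assoc_functionals(beta, delta, b)
        return (
            self.longitudinal_loglik_parts(beta, delta, sigma, b),
            self.survival_loglik_parts(Mq, Me, alpha, gamma, theta),
        )

    def total_loglik(self, beta, delta, sigma, b, alpha, gamma, theta) -> float:
        lo, su = self.loglik_parts(beta, delta, sigma, b, alpha, gamma, theta)
        return float(lo.sum() + su.sum())
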