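"""Model core: design rows, trajectory functionals, hazard and likelihood."""

import numpy as np
import pytest
from scipy.integrate import quad

from densityjm import defaults
from densityjm.model import (
    LongitudinalParams,
    LongitudinalRecord,
    SubjectRecord,
    SurvivalParams,
    cumulative_hazard,
    fixed_design_row,
    hazard_covariate_vector,
    baseline_covariate_vector,
    log_hazard,
    random_design_row,
    subject_log_likelihood,
    trajectory_cumulative,
    trajectory_slope,
    trajectory_value,
)
from densityjm.splines import natural_cubic_basis


def constant_long_params(level: float, sigma: float = 0.5) -> LongitudinalParams:
    beta = np.zeros(13)
    beta[0] = level
    return LongitudinalParams(beta=beta, delta=np.zeros(4), sigma=sigma, D=np.eye(4))


def surv(assoc="current_value", alpha=(0.2,), intercept=-4.0, slope=0.0, t0=0.0):
    return defaults.survival_params(
        assoc=assoc, alpha=alpha, baseline_intercept=intercept, baseline_slope=slope, t0=t0
    )


class TestTypes:
    def test_subject_invariants_enforced(self):
        with pytest.raises(ValueError):
            SubjectRecord(id=1, entry_time=5.0, exit_time=4.0, event=0,
                          bmi=25.0, mht="never", mp="pre", fh="no")
        with pytest.raises(ValueError):
            SubjectRecord(id=1, entry_time=1.0, exit_time=45.0, event=0,
                          bmi=25.0, mht="never", mp="pre", fh="no")
        with pytest.raises(ValueError):
            SubjectRecord(id=1, entry_time=1.0, exit_time=5.0, event=0,
                          bmi=25.0, mht="sometimes", mp="pre", fh="no")

    def test_param_shape_validation(self):
        with pytest.raises(ValueError):
            LongitudinalParams(beta=np.zeros(12), delta=np.zeros(4), sigma=1.0, D=np.eye(4))
        with pytest.raises(ValueError):
            LongitudinalParams(beta=np.zeros(13), delta=np.zeros(4), sigma=1.0,
                               D=-np.eye(4))  # not PD
        with pytest.raises(ValueError):
            SurvivalParams(gamma=np.zeros(5), assoc="value_and_slope", alpha=[0.1],
                           baseline_coefs=np.zeros(8))
        with pytest.raises(ValueError):
            SurvivalParams(gamma=np.zeros(5), assoc="sigmoid", alpha=[0.1],
                           baseline_coefs=np.zeros(8))


class TestDesignRows:
    def test_reference_levels_zero_interactions(self, spline_spec):
        row = fixed_design_row(7.3, "never", "pre", spline_spec)
        assert row.shape == (13,)
        assert np.allclose(row[4:], 0.0)

    def test_dummy_coding_blocks(self, spline_spec):
        t = 11.0
        B = natural_cubic_basis(t, spline_spec)
        row = fixed_design_row(t, "current", "pre", spline_spec)
        assert np.allclose(row[4:7], 0.0)       # former block
        assert np.allclose(row[7:10], B)        # current block
        assert np.allclose(row[10:13], 0.0)     # MP block
        row = fixed_design_row(t, "former", "post", spline_spec)
        assert np.allclose(row[4:7], B) and np.allclose(row[10:13], B)

    def test_random_row_shares_basis_with_fixed_row(self, spline_spec):
        for t in (0.0, 9.0, 23.0, 39.0):
            assert np.allclose(random_design_row(t, spline_spec),
                               fixed_design_row(t, "former", "post", spline_spec)[:4])

    def test_unknown_category_rejected(self, spline_spec):
        with pytest.raises(ValueError):
            fixed_design_row(5.0, "unknown", "pre", spline_spec)

    def test_covariate_vectors(self, subject):
        assert np.allclose(baseline_covariate_vector(subject), [24.0, 1, 0, 1])
        assert np.allclose(hazard_covariate_vector(subject), [24.0, 1, 0, 1, 0])


class TestTrajectory:
    def test_constant_trajectory(self, subject):
        p = constant_long_params(7.5)
        t = np.linspace(0, 40, 9)
        assert np.allclose(trajectory_value(t, subject, p, np.zeros(4)), 7.5)
        assert np.allclose(trajectory_slope(t, subject, p, np.zeros(4)), 0.0)

    def test_dot_product_oracle(self, subject, long_params, spline_spec):
        """Explicit dot-product recomputation on random parameter draws."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            t = rng.uniform(0, 40)
            b = rng.normal(size=4)
            expected = (
                fixed_design_row(t, subject.mht, subject.mp, spline_spec) @ long_params.beta
                + random_design_row(t, spline_spec) @ b
                + baseline_covariate_vector(subject) @ long_params.delta
            )
            assert trajectory_value(t, subject, long_params, b) == pytest.approx(expected)

    def test_random_intercept_shift(self, subject, long_params):
        b = np.array([0.3, -0.1, 0.2, 0.05])
        shifted = b + np.array([1.7, 0, 0, 0])
        t = np.linspace(0, 40, 7)
        assert np.allclose(
            trajectory_value(t, subject, long_params, shifted)
            - trajectory_value(t, subject, long_params, b),
            1.7,
        )

    def test_slope_finite_difference_oracle(self, subject, long_params):
        rng = np.random.default_rng(9)
        b = rng.normal(size=4)
        h = 1e-6
        for t in rng.uniform(0.5, 39.5, 10):
            fd = (trajectory_value(t + h, subject, long_params, b)
                  - trajectory_value(t - h, subject, long_params, b)) / (2 * h)
            assert trajectory_slope(t, subject, long_params, b) == pytest.approx(fd, abs=1e-6)

    def test_slope_constant_beyond_boundary_knots(self, subject, long_params):
        b = np.array([0.1, 0.2, -0.3, 0.4])
        s = [trajectory_slope(t, subject, long_params, b) for t in (26.0, 31.0, 39.0)]
        assert np.allclose(s[0], s[1]) and np.allclose(s[1], s[2])


class TestCumulativeTrajectory:
    def test_zero_at_t0_and_constant_closed_form(self, subject):
        p = constant_long_params(3.25)
        assert trajectory_cumulative(5.0, subject, p, np.zeros(4), t0=5.0) == pytest.approx(0.0)
        assert trajectory_cumulative(17.0, subject, p, np.zeros(4), t0=5.0) == pytest.approx(
            3.25 * 12.0, abs=1e-10
        )

    def test_quadrature_oracle(self, subject, long_params):
        rng = np.random.default_rng(10)
        b = rng.normal(size=4)
        for _ in range(5):
            t0, t = np.sort(rng.uniform(0, 40, 2))
            q, _ = quad(lambda s: trajectory_value(s, subject, long_params, b), t0, t,
                        points=[3, 10, 15, 25], limit=200)
            got = trajectory_cumulative(t, subject, long_params, b, t0=t0)
            assert got == pytest.approx(q, abs=1e-8)

    def test_requires_t_at_least_t0(self, subject, long_params):
        with pytest.raises(ValueError):
            trajectory_cumulative(3.0, subject, long_params, np.zeros(4), t0=5.0)


class TestLogHazard:
    def test_zero_alpha_removes_association(self, subject, long_params):
        sp = surv(alpha=(0.0,))
        rng = np.random.default_rng(11)
        for t in (2.0, 17.0, 33.0):
            base = log_hazard(t, subject, long_params, sp, np.zeros(4))
            for _ in range(3):
                assert log_hazard(t, subject, long_params, sp, rng.normal(size=4)) \
                    == pytest.approx(base)

    def test_cumulative_association_linear_growth(self, subject):
        """With flat trajectories differing by c, the log-hazard gap grows
        as alpha * c * (t - t0)."""
        sp = surv(assoc="cumulative", alpha=(0.05,), t0=0.0)
        pa = constant_long_params(4.0)
        pb = constant_long_params(6.5)
        for t in (5.0, 15.0, 30.0):
            gap = (log_hazard(t, subject, pb, sp, np.zeros(4))
                   - log_hazard(t, subject, pa, sp, np.zeros(4)))
            assert gap == pytest.approx(0.05 * 2.5 * t, abs=1e-10)

    def test_current_value_intercept_linearity(self, subject, long_params):
        sp = surv(alpha=(0.2,))
        b = np.array([0.5, -0.2, 0.1, 0.3])
        b_shift = b + np.array([1.3, 0, 0, 0])
        for t in (4.0, 21.0, 36.0):
            diff = (log_hazard(t, subject, long_params, sp, b_shift)
                    - log_hazard(t, subject, long_params, sp, b))
            assert diff == pytest.approx(0.2 * 1.3)

    def test_alpha_assoc_mismatch_rejected(self):
        with pytest.raises(ValueError):
            surv(assoc="current_value", alpha=(0.1, 0.2))


class TestCumulativeHazard:
    def test_empty_interval_and_monotonicity(self, subject, long_params):
        sp = surv()
        b = np.zeros(4)
        assert cumulative_hazard(5.0, 5.0, subject, long_params, sp, b) == 0.0
        vals = [cumulative_hazard(2.0, t, subject, long_params, sp, b)
                for t in (5.0, 10.0, 20.0, 40.0)]
        assert np.all(np.diff(vals) > 0)

    def test_reversed_interval_rejected(self, subject, long_params):
        with pytest.raises(ValueError):
            cumulative_hazard(9.0, 3.0, subject, long_params, surv(), np.zeros(4))

    @pytest.mark.parametrize("assoc,alpha", [
        ("current_value", (0.2,)),
        ("value_and_slope", (0.15, -0.8)),
        ("cumulative", (0.01,)),
    ])
    def test_trapezoid_oracle(self, subject, long_params, assoc, alpha):
        """10,000-panel trapezoid agreement to 1e-6 relative, all structures."""
        rng = np.random.default_rng(13)
        sp = surv(assoc=assoc, alpha=alpha, slope=0.02)
        for _ in range(7):
            a, bnd = np.sort(rng.uniform(0.0, 40.0, 2))
            b = 0.3 * rng.normal(size=4)
            grid = np.linspace(a, bnd, 10001)
            h = np.exp(log_hazard(grid, subject, long_params, sp, b))
            trap = np.trapezoid(h, grid)
            got = cumulative_hazard(a, bnd, subject, long_params, sp, b)
            assert got == pytest.approx(trap, rel=1e-6)


class TestSubjectLogLikelihood:
    def test_survival_only_contribution(self, subject, long_params):
        sp = surv()
        b = np.zeros(4)
        censored = SubjectRecord(id=1, entry_time=12.0, exit_time=20.0, event=0,
                                 bmi=24.0, mht="former", mp="post", fh="yes")
        ll = subject_log_likelihood(censored, [], long_params, sp, b)
        assert ll == pytest.approx(
            -cumulative_hazard(12.0, 20.0, censored, long_params, sp, b)
        )

    def test_gaussian_normalizer(self, subject):
        """With y on the trajectory, doubling sigma lowers the longitudinal
        term by n log 2."""
        p1 = constant_long_params(5.0, sigma=0.4)
        p2 = constant_long_params(5.0, sigma=0.8)
        sp = surv(alpha=(0.0,))
        meas = [LongitudinalRecord(id=1, t=t, y=5.0) for t in (2.0, 6.0, 13.0)]
        ll1 = subject_log_likelihood(subject, meas, p1, sp, np.zeros(4))
        ll2 = subject_log_likelihood(subject, meas, p2, sp, np.zeros(4))
        assert ll1 - ll2 == pytest.approx(3 * np.log(2.0))

    def test_naive_reimplementation_oracle(self, long_params):
        """Straight-line recomputation (normal pdf + event term + hazard
        integral by brute-force quadrature) on random subjects."""
        from scipy.stats import norm

        rng = np.random.default_rng(14)
        sp = surv(assoc="value_and_slope", alpha=(0.1, -0.4), slope=0.01)
        for i in range(10):
            entry, exit_ = np.sort(rng.uniform(1.0, 39.0, 2))
            subj = SubjectRecord(
                id=i, entry_time=entry, exit_time=exit_, event=int(rng.uniform() < 0.5),
                bmi=float(rng.uniform(18, 35)),
                mht=rng.choice(["never", "former", "current"]),
                mp=rng.choice(["pre", "post"]), fh=rng.choice(["no", "yes", "missing"]),
            )
            b = 0.4 * rng.normal(size=4)
            meas = [LongitudinalRecord(id=i, t=float(t), y=float(rng.normal(4, 2)))
                    for t in rng.uniform(0, exit_, 3)]
            naive = sum(
                norm.logpdf(r.y, trajectory_value(r.t, subj, long_params, b),
                            long_params.sigma)
                for r in meas
            )
            if subj.event:
                naive += log_hazard(exit_, subj, long_params, sp, b)
            grid = np.linspace(entry, exit_, 20001)
            naive -= np.trapezoid(np.exp(log_hazard(grid, subj, long_params, sp, b)), grid)
            got = subject_log_likelihood(subj, meas, long_params, sp, b)
            assert got == pytest.approx(naive, rel=1e-5, abs=1e-5)

    def test_foreign_measurement_rejected(self, subject, long_params):
        with pytest.raises(ValueError):
            subject_log_likelihood(
                subject, [LongitudinalRecord(id=999, t=1.0, y=4.0)],
                long_params, surv(), np.zeros(4),
            )


class TestLikelihoodInvariants:
    def test_left_truncation_ignores_pre_entry_hazard(self, long_params):
        """Perturbing baseline coefficients whose B-spline support ends
        before the entry time leaves the likelihood unchanged."""
        subj = SubjectRecord(id=1, entry_time=20.0, exit_time=30.0, event=1,
                             bmi=26.0, mht="never", mp="post", fh="no")
        sp = surv()
        b = np.array([0.2, -0.1, 0.3, 0.0])
        ll = subject_log_likelihood(subj, [], long_params, sp, b)
        coefs = sp.baseline_coefs.copy()
        coefs[0] += 5.0  # support [0, 8], entirely before entry at 20
        sp2 = SurvivalParams(gamma=sp.gamma, assoc=sp.assoc, alpha=sp.alpha,
                             baseline_coefs=coefs, smoothing=sp.smoothing, t0=sp.t0)
        assert subject_log_likelihood(subj, [], long_params, sp2, b) == pytest.approx(
            ll, abs=1e-12
        )

    def test_value_and_slope_nests_current_value(self, subject, long_params):
        """alpha2 = 0 reproduces the current-value log likelihood exactly."""
        b = np.array([0.4, -0.2, 0.1, 0.3])
        meas = [LongitudinalRecord(id=1, t=t, y=4.0 + 0.1 * t) for t in (1.0, 5.0, 9.0)]
        sp1 = surv(assoc="current_value", alpha=(0.17,))
        sp2 = surv(assoc="value_and_slope", alpha=(0.17, 0.0))
        ll1 = subject_log_likelihood(subject, meas, long_params, sp1, b)
        ll2 = subject_log_likelihood(subject, meas, long_params, sp2, b)
        assert ll2 == pytest.approx(ll1, abs=1e-12)

    def test_cohort_likelihood_is_sum_of_subject_contributions(self, small_cohort, long_params):
        from densityjm.inference import cohort_log_likelihood

        subjects, longitudinal, _ = small_cohort
        sp = surv()
        rng = np.random.default_rng(15)
        b = 0.3 * rng.normal(size=(len(subjects), 4))
        total = cohort_log_likelihood(subjects, longitudinal, long_params, sp, b)
        by_hand = 0.0
        for k, row in subjects.reset_index(drop=True).iterrows():
            subj = SubjectRecord(id=row.id, entry_time=row.entry, exit_time=row.exit,
                                 event=int(row.event), bmi=row.bmi, mht=row.mht,
                                 mp=row.mp, fh=row.fh)
            meas = [LongitudinalRecord(id=row.id, t=r.t, y=r.y)
                    for r in longitudinal[longitudinal.id == row.id].itertuples()]
            by_hand += subject_log_likelihood(subj, meas, long_params, sp, b[k])
        assert total == pytest.approx(by_hand, rel=1e-12)
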