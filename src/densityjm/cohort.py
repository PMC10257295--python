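"""Synthetic screening-cohort generator.

Emulates the structure of a population-based mammography screening cohort:
women aged 40-74 at baseline, screens every 18-24 months, follow-up to age
80 (administratively censored a fixed number of years after baseline),
delayed entry into the risk set at the second screen, covariate marginals
matching the cohort's baseline table, spline trajectories of square-root
dense area with measurement error, and diagnosis times drawn exactly from
the joint model's hazard by inverse-transform sampling — so the simulator
and the likelihood share one hazard code path and estimation is testable by
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from . import defaults
from .model import (
    FH_LEVELS,
    MAX_MODEL_TIME,
    MHT_LEVELS,
    MP_LEVELS,
    LongitudinalParams,
    SubjectRecord,
    SurvivalParams,
    cumulative_hazard,
    trajectory_value,
)

__all__ = [
    "SimulationConfig",
    "COVARIATE_MARGINALS",
    "simulate_covariates",
    "simulate_visits",
    "simulate_trajectory_and_measurements",
    "simulate_event_time",
    "simulate_cohort",
]

# Baseline covariate marginals of the emulated cohort ("All" column):
# MHT never/former/current, menopausal status pre/post, family history
# no/yes/missing, and BMI mean/SD (truncated to a plausible range).
COVARIATE_MARGINALS = {
    "mht": dict(zip(MHT_LEVELS, (0.821, 0.142, 0.037))),
    "mp": dict(zip(MP_LEVELS, (0.486, 0.514))),
    "fh": dict(zip(FH_LEVELS, (0.840, 0.134, 0.026))),
    "bmi_mean": 25.2,
    "bmi_sd": 4.2,
    "bmi_range": (15.0, 50.0),
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate the screening cohort: baseline ages uniform on 40-74,
    18-24 months between screens, administrative censoring 6 years after
    baseline (mean follow-up near the cohort's 5.4 years), follow-up capped
    at age 80, and truth parameters shaped like the cohort estimates with an
    event fraction near 1.3%.
    """

    n_subjects: int
    seed: int
    long_params: LongitudinalParams = field(default_factory=defaults.longitudinal_params)
    surv_params: SurvivalParams = field(default_factory=defaults.survival_params)
    baseline_age_range: tuple[float, float] = (40.0, 74.0)
    visit_gap_range: tuple[float, float] = (1.5, 2.0)
    max_age: float = 80.0
    admin_followup: float = 6.0
    age_linked_mp: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        lo, hi = self.visit_gap_range
        if not (0.0 < lo <= hi < self.max_age - 40.0):
            raise ValueError("visit_gap_range must lie within (0, max_age - 40)")


@lru_cache(maxsize=4)
def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose [lo, hi]-truncated normal has the target mean."""

    def gap(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return truncnorm.mean(a, b, loc=mu, scale=sd) - target_mean

    return brentq(gap, target_mean - 3.0, target_mean + 3.0)


def simulate_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw baseline covariates and baseline ages for all subjects.

    BMI is truncated normal; MHT, MP and FH are categorical with the
    cohort's marginal proportions; baseline age is uniform.  With
    ``age_linked_mp`` the postmenopausal probability instead follows a
    logistic curve in age centred at 51 years (a realism option; the
    default, matching the model, draws MP independently of age).
    """
    n = config.n_subjects
    m = COVARIATE_MARGINALS
    lo, hi = m["bmi_range"]
    loc = _truncnorm_loc(m["bmi_mean"], m["bmi_sd"], lo, hi)
    a = (lo - loc) / m["bmi_sd"]
    b = (hi - loc) / m["bmi_sd"]
    bmi = truncnorm.rvs(a, b, loc=loc, scale=m["bmi_sd"], size=n, random_state=rng)
    mht = rng.choice(MHT_LEVELS, size=n, p=[m["mht"][l] for l in MHT_LEVELS])
    fh = rng.choice(FH_LEVELS, size=n, p=[m["fh"][l] for l in FH_LEVELS])
    age = rng.uniform(*config.baseline_age_range, size=n)
    if config.age_linked_mp:
        p_post = 1.0 / (1.0 + np.exp(-(age - 51.0)))
        mp = np.where(rng.uniform(size=n) < p_post, "post", "pre")
    else:
        mp = rng.choice(MP_LEVELS, size=n, p=[m["mp"][l] for l in MP_LEVELS])
    return pd.DataFrame(
        {"baseline_age": age, "bmi": bmi, "mht": mht, "mp": mp, "fh": fh}
    )


def simulate_visits(
    baseline_age: float, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Screening visit times (model time), first at baseline, gaps 18-24 months.

    Visits stop at min(max_age, baseline_age + admin_followup).  Returns an
    empty array when the window cannot contain a second screen (the cohort
    excludes women without longitudinal follow-up; entry is the second
    screen).
    """
    horizon = min(config.max_age, baseline_age + config.admin_followup) - 40.0
    t = baseline_age - 40.0
    visits = [t]
    while True:
        t = t + rng.uniform(*config.visit_gap_range)
        if t > horizon:
            break
        visits.append(t)
    if len(visits) < 2:
        return np.empty(0)
    return np.asarray(visits)


def simulate_trajectory_and_measurements(
    subject: SubjectRecord,
    visits: np.ndarray,
    long_params: LongitudinalParams,
    rng: np.random.Generator,
):
    """Draw b ~ N(0, D) and noisy sqrt-density measurements at the visits.

    Measured values are the latent trajectory plus N(0, sigma^2) noise,
    recorded untruncated (the Gaussian error model permits small negative
    observations on the square-root scale).
    """
    dim = long_params.D.shape[0]
    L = np.linalg.cholesky(long_params.D)
    b = L @ rng.standard_normal(dim)
    m = trajectory_value(np.asarray(visits, dtype=float), subject, long_params, b)
    y = m + long_params.sigma * rng.standard_normal(len(visits))
    return b, y


def simulate_event_time(
    subject: SubjectRecord,
    long_params: LongitudinalParams,
    surv_params: SurvivalParams,
    b: np.ndarray,
    censor_time: float,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Draw (exit_time, event) by inverting the cumulative hazard from entry.

    Solves H_i(entry, T) = E with E ~ Exponential(1) by root bracketing to
    1e-8 years; the draw is conditional on survival to entry, matching the
    left-truncated likelihood.  If no event occurs by age 80 or before the
    censoring time, the subject is censored.
    """
    entry = subject.entry_time
    e_draw = rng.exponential()

    def shifted(t: float) -> float:
        return cumulative_hazard(entry, t, subject, long_params, surv_params, b) - e_draw

    total = shifted(MAX_MODEL_TIME)
    if not np.isfinite(total):
        raise ValueError("non-finite cumulative hazard; check parameters")
    if total <= 0.0:  # survives past age 80
        return censor_time, 0
    t_event = brentq(shifted, entry, MAX_MODEL_TIME, xtol=1e-8)
    if t_event < censor_time:
        return float(t_event), 1
    return censor_time, 0


def simulate_cohort(config: SimulationConfig):
    """Generate a full cohort: (subjects, longitudinal, truth).

    Returns two data frames — one row per subject (model-time entry/exit)
    and one row per measurement — plus a dictionary of the generating
    parameters and seed, written alongside the data for recovery tests.
    Fully reproducible given the seed.
    """
    rng = np.random.default_rng(config.seed)
    cov = simulate_covariates(config, rng)
    subj_rows = []
    long_rows = []
    for i in range(config.n_subjects):
        row = cov.iloc[i]
        visits = simulate_visits(row.baseline_age, config, rng)
        while visits.size == 0:  # redraw: window cannot hold a second screen
            new_age = rng.uniform(*config.baseline_age_range)
            cov.loc[cov.index[i], "baseline_age"] = new_age
            visits = simulate_visits(new_age, config, rng)
            row = cov.iloc[i]
        entry = float(visits[1])
        censor = min(config.max_age, row.baseline_age + config.admin_followup) - 40.0
        censor = min(censor, MAX_MODEL_TIME)
        shell = SubjectRecord(
            id=i,
            entry_time=entry,
            exit_time=censor,
            event=0,
            bmi=float(row.bmi),
            mht=str(row.mht),
            mp=str(row.mp),
            fh=str(row.fh),
        )
        b, y = simulate_trajectory_and_measurements(shell, visits, config.long_params, rng)
        exit_time, event = simulate_event_time(
            shell, config.long_params, config.surv_params, b, censor, rng
        )
        subj_rows.append(
            dict(
                id=i,
                entry=entry,
                exit=exit_time,
                event=event,
                bmi=float(row.bmi),
                mht=str(row.mht),
                mp=str(row.mp),
                fh=str(row.fh),
                baseline_age=float(row.baseline_age),
            )
        )
        keep = visits <= exit_time + 1e-12
        for t, yv in zip(visits[keep], y[keep]):
            long_rows.append(dict(id=i, t=float(t), y=float(yv)))
    subjects = pd.DataFrame(subj_rows)
    longitudinal = pd.DataFrame(long_rows)
    truth = {
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "beta": config.long_params.beta.tolist(),
        "delta": config.long_params.delta.tolist(),
        "sigma": config.long_params.sigma,
        "D": config.long_params.D.tolist(),
        "gamma": config.surv_params.gamma.tolist(),
        "assoc": config.surv_params.assoc,
        "alpha": config.surv_params.alpha.tolist(),
        "baseline_coefs": config.surv_params.baseline_coefs.tolist(),
        "t0": config.surv_params.t0,
        "admin_followup": config.admin_followup,
        "visit_gap_range": list(config.visit_gap_range),
        "baseline_age_range": list(config.baseline_age_range),
    }
    return subjects, longitudinal, truth
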