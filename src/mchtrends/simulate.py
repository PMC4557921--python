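"""Synthetic truths, surveys, populations, and birth histories.

The generator is the pipeline's testbed: it produces data with exactly the
statistical structure the estimator assumes — smooth logit-scale true trends
with zone and state random intercepts and slopes, binomial survey sampling
inflated by a design effect, sparse irregular survey years, and birth
histories with piecewise-constant age-specific hazards — together with the
realized truth, so recovery and interval-coverage tests need no external
data.

Defaults mirror the real application: 37 states in 6 zones, an annual
2000-2013 grid, six survey sources at irregular years (three full-history,
two recent-birth, one malaria-survey-like), 500 respondents per state per
survey with a design effect of 1.5, and under-5 mortality declining from
roughly 180 to 130 deaths per 1,000 live births nationally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import geography
from .prior import build_time_basis
from .transforms import clamp, from_logit
from .u5m import AGE_SEGMENTS

__all__ = [
    "SurveyPlanEntry", "SimConfig", "simulate_truth", "simulate_surveys",
    "simulate_population", "simulate_birth_histories", "u5m_truth",
    "simulate_bundle",
]


@dataclass(frozen=True)
class SurveyPlanEntry:
    source_id: str
    year: int
    family: str = "full-history"   # or "recent-birth-only"


DEFAULT_SURVEY_PLAN: tuple[SurveyPlanEntry, ...] = (
    SurveyPlanEntry("dhs-like-2003", 2003, "full-history"),
    SurveyPlanEntry("mics-like-2007", 2007, "recent-birth-only"),
    SurveyPlanEntry("dhs-like-2008", 2008, "full-history"),
    SurveyPlanEntry("mis-like-2010", 2010, "recent-birth-only"),
    SurveyPlanEntry("mics-like-2011", 2011, "recent-birth-only"),
    SurveyPlanEntry("dhs-like-2013", 2013, "full-history"),
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator."""

    n_states: int = 37
    n_zones: int = 6
    years: tuple = (2000, 2013)            # inclusive range
    truth_basis: str = "ncs1"              # "linear" or "ncs1"
    alpha: float = -0.8
    beta: tuple = (0.16, 0.06)             # per (unit-SD) basis column
    sd_u_s: float = 0.30
    sd_u_z: float = 0.30
    # slope SDs per standardized basis column (columns have unit SD over the
    # grid, so these are logit-scale trajectory perturbations)
    sd_b_s: float = 0.08
    sd_b_z: float = 0.08
    sd_eps: float = 0.10                   # residual SD of the model-equation
                                           # generator (simulate_prior_dataset)
    survey_plan: tuple = DEFAULT_SURVEY_PLAN
    n_per_state: int = 500
    design_effect: float = 1.5
    # birth histories; full-birth-history files are large (thousands of
    # births per state per survey in DHS-scale data)
    n_children_per_state: int = 2000
    q5_start: float = 0.18                 # national 5q0 in the first year
    q5_end: float = 0.13                   # ... and the last year
    sd_state_loghaz: float = 0.15
    seed: Optional[int] = None

    # relative age profile of the monthly hazard over the standard segments
    hazard_profile: tuple = (0.030, 0.006, 0.004, 0.002, 0.0012, 0.0008, 0.0006)

    def __post_init__(self):
        if self.design_effect < 1:
            raise ValueError("design effect must be >= 1")
        for sd in (self.sd_u_s, self.sd_u_z, self.sd_b_s, self.sd_b_z,
                   self.sd_eps):
            if sd < 0:
                raise ValueError("SDs must be non-negative")
        if self.n_states < self.n_zones:
            raise ValueError("need at least one state per zone")

    @property
    def year_grid(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    def state_zone(self) -> dict[str, str]:
        """States partitioned into zones; real names when sizes match."""
        if self.n_states == 37 and self.n_zones == 6:
            return dict(geography.STATE_ZONE)
        states = [f"State{i:02d}" for i in range(self.n_states)]
        return {s: f"Zone{i % self.n_zones}" for i, s in enumerate(states)}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def simulate_truth(config: SimConfig, seed=None):
    """True proportions per (state, year) plus the realized effects.

    truth_{s,t} = invlogit(alpha + T(beta + b_s + b_z) + u_s + u_z).
    Returns (truth DataFrame with columns state, zone, year, y_true, p_true;
    effects dict with the realized random effects).
    """
    rng = _rng(seed if seed is not None else config.seed)
    state_zone = config.state_zone()
    states = sorted(state_zone)
    zones = sorted(set(state_zone.values()))
    basis = build_time_basis(config.year_grid, config.truth_basis)
    k = basis.k
    beta = np.asarray(config.beta, float)[:k]

    T = basis.design(config.year_grid)
    u_s = {s: rng.normal(0.0, config.sd_u_s) for s in states}
    u_z = {z: rng.normal(0.0, config.sd_u_z) for z in zones}
    b_s = {s: rng.normal(0.0, config.sd_b_s, size=k) for s in states}
    b_z = {z: rng.normal(0.0, config.sd_b_z, size=k) for z in zones}
    rows = []
    for s in states:
        z = state_zone[s]
        y = (config.alpha + u_s[s] + u_z[z]
             + T @ (beta + b_s[s] + b_z[z]))
        for yr, yy in zip(config.year_grid, y):
            rows.append(dict(state=s, zone=z, year=int(yr),
                             y_true=float(yy), p_true=float(from_logit(yy))))
    truth = pd.DataFrame(rows)
    effects = dict(u_s=u_s, u_z=u_z, b_s=b_s, b_z=b_z,
                   alpha=config.alpha, beta=beta, basis=basis)
    return truth, effects


def simulate_surveys(
    truth: pd.DataFrame,
    config: SimConfig,
    seed=None,
    plan: Optional[Sequence[SurveyPlanEntry]] = None,
) -> pd.DataFrame:
    """Survey estimates around the truth: binomial sampling with a design
    effect.

    Per survey-state-year: n_eff = n / deff; successes ~ Binomial(n_eff,
    truth); p_hat = successes / n_eff with var_p = p_hat(1-p_hat)/n_eff,
    clamped into [0.001, 0.999].
    """
    rng = _rng(seed if seed is not None else config.seed)
    plan = list(plan if plan is not None else config.survey_plan)
    n_eff = max(int(round(config.n_per_state / config.design_effect)), 2)
    truth_idx = truth.set_index(["state", "year"])
    rows = []
    for entry in plan:
        for (state, year), rec in truth_idx.iterrows():
            if year != entry.year:
                continue
            p = rec["p_true"]
            successes = rng.binomial(n_eff, p)
            p_hat = successes / n_eff
            p_c = float(clamp(p_hat))
            var_p = p_c * (1.0 - p_c) / n_eff
            rows.append(dict(
                indicator="synthetic", state=state, zone=rec["zone"],
                year=int(year), p=p_c, var_p=var_p,
                source_id=entry.source_id, flags="",
            ))
    return pd.DataFrame(rows)


def simulate_prior_dataset(
    config: SimConfig,
    seed=None,
    re_structure: frozenset = frozenset({"u_s", "u_z", "b_s", "b_z"}),
    survey_years: Sequence[int] = (2003, 2007, 2008, 2010, 2011, 2013),
    sd_slope: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Logit-scale observations drawn directly from the stage-1 model
    equation (normal errors, equal slope variance per basis column).

    This is the generative twin of the prior: y = alpha + T(beta + b_s +
    b_z) + u_s + u_z + eps, with every requested random term IID mean-zero —
    the oracle for parameter-recovery tests of the fitting machinery,
    bypassing survey sampling.

    Returns (data with columns state, zone, year, y; truth dict).
    """
    rng = _rng(seed if seed is not None else config.seed)
    state_zone = config.state_zone()
    states = sorted(state_zone)
    zones = sorted(set(state_zone.values()))
    basis = build_time_basis(config.year_grid, config.truth_basis)
    k = basis.k
    beta = np.asarray(config.beta, float)[:k]
    u_s = {s: rng.normal(0, config.sd_u_s) if "u_s" in re_structure else 0.0
           for s in states}
    u_z = {z: rng.normal(0, config.sd_u_z) if "u_z" in re_structure else 0.0
           for z in zones}
    b_s = {s: rng.normal(0, sd_slope, k) if "b_s" in re_structure
           else np.zeros(k) for s in states}
    b_z = {z: rng.normal(0, sd_slope, k) if "b_z" in re_structure
           else np.zeros(k) for z in zones}
    rows = []
    T = basis.design(np.asarray(survey_years))
    for s in states:
        z = state_zone[s]
        mu = (config.alpha + u_s[s] + u_z[z] + T @ (beta + b_s[s] + b_z[z]))
        y = mu + rng.normal(0, config.sd_eps, len(survey_years))
        for yr, yy in zip(survey_years, y):
            rows.append(dict(state=s, zone=z, year=int(yr), y=float(yy)))
    truth = dict(alpha=config.alpha, beta=beta, u_s=u_s, u_z=u_z, b_s=b_s,
                 b_z=b_z, sd_slope=sd_slope, sd_eps=config.sd_eps)
    return pd.DataFrame(rows), truth


def simulate_population(config: SimConfig, seed=None) -> pd.DataFrame:
    """State-year populations and live births.

    Lognormal state sizes (median ~4 million, substantial skew), 2.5% annual
    growth, and live births at a ~4% crude birth rate with mild state
    variation.
    """
    rng = _rng(seed if seed is not None else config.seed)
    state_zone = config.state_zone()
    states = sorted(state_zone)
    base = rng.lognormal(mean=np.log(4e6), sigma=0.5, size=len(states))
    cbr = rng.normal(0.040, 0.004, size=len(states)).clip(0.02, 0.06)
    rows = []
    for i, s in enumerate(states):
        for yr in config.year_grid:
            pop = base[i] * 1.025 ** (yr - config.years[0])
            rows.append(dict(state=s, year=int(yr),
                             population=float(pop),
                             live_births=float(pop * cbr[i])))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# birth histories

def _hazard_scale(config: SimConfig, year, state_factor=1.0):
    """Cumulative-hazard scale factor(s) at calendar time(s) ``year``."""
    y0, y1 = config.years
    frac = np.clip((np.asarray(year, float) - y0) / max(y1 - y0, 1), 0.0, 1.0)
    q5 = config.q5_start + frac * (config.q5_end - config.q5_start)
    widths = np.array([a1 - a0 for a0, a1 in AGE_SEGMENTS], float)
    profile = np.asarray(config.hazard_profile, float)
    return -np.log(1.0 - q5) * state_factor / float(np.dot(profile, widths))


def _hazards_for_year(config: SimConfig, year: float,
                      state_factor: float = 1.0) -> np.ndarray:
    """Monthly hazards by age segment at a given calendar time.

    Hazards trend with the calendar year of exposure (not the birth cohort),
    so the period measure 5q0(t) = 1 - exp(-sum_a m_a(t) w_a) is exactly the
    quantity the synthetic-cohort estimator targets. The relative age
    profile is scaled so 5q0 interpolates linearly between q5_start and
    q5_end over the study years.
    """
    return np.asarray(config.hazard_profile, float) * _hazard_scale(
        config, year, state_factor
    )


def u5m_truth(config: SimConfig, seed=None) -> pd.DataFrame:
    """True period 5q0 per (state, calendar year) implied by the hazard
    schedule, including the realized state hazard factors."""
    rng = _rng(seed if seed is not None else config.seed)
    state_zone = config.state_zone()
    states = sorted(state_zone)
    factors = np.exp(rng.normal(0.0, config.sd_state_loghaz, len(states)))
    widths = np.array([a1 - a0 for a0, a1 in AGE_SEGMENTS], float)
    rows = []
    for f, s in zip(factors, states):
        for yr in config.year_grid:
            m = _hazards_for_year(config, yr, f)
            q5 = 1.0 - np.exp(-float(np.dot(m, widths)))
            rows.append(dict(state=s, year=int(yr), q5_true=q5,
                             hazard_factor=float(f)))
    return pd.DataFrame(rows)


def simulate_birth_histories(
    config: SimConfig,
    seed=None,
    survey_years: Sequence[int] = (2003, 2008, 2013),
    cohort_span: int = 15,
    state_factors: Optional[dict] = None,
) -> pd.DataFrame:
    """Complete birth histories with piecewise-constant age hazards.

    Children get birth dates uniform over the ``cohort_span`` years before
    each survey; survival is simulated segment by segment, each segment
    using the calendar-year hazards at its midpoint; censoring is at the
    survey date. Deaths never exceed censoring ages by construction.
    """
    rng = _rng(seed if seed is not None else config.seed)
    state_zone = config.state_zone()
    states = sorted(state_zone)
    if state_factors is None:
        state_factors = {
            s: float(f) for s, f in zip(
                states,
                np.exp(rng.normal(0.0, config.sd_state_loghaz, len(states))),
            )
        }
    n = config.n_children_per_state
    profile = np.asarray(config.hazard_profile, float)
    seg_a0 = np.array([a0 for a0, _ in AGE_SEGMENTS], float)
    seg_a1 = np.array([a1 for _, a1 in AGE_SEGMENTS], float)
    frames = []
    for sy in survey_years:
        survey_time = sy + 0.5
        sid = f"bh-survey-{sy}"
        for s in states:
            birth_time = survey_time - rng.uniform(0.0, cohort_span, size=n)
            birth_year = np.floor(birth_time).astype(int)
            censor = (survey_time - birth_time) * 12.0
            age_death = np.full(n, np.nan)
            alive = np.ones(n, dtype=bool)
            for j in range(len(AGE_SEGMENTS)):
                w = seg_a1[j] - seg_a0[j]
                seg_mid_time = birth_time + (seg_a0[j] + seg_a1[j]) / 24.0
                m = profile[j] * _hazard_scale(
                    config, seg_mid_time, state_factors[s]
                )
                p_die = 1.0 - np.exp(-m * w)
                u = rng.random(n)
                dies = alive & (u < p_die)
                # given u < p_die, u is uniform on (0, p_die) so -ln(1-u)/m
                # is the truncated-exponential time within the segment
                with np.errstate(divide="ignore", invalid="ignore"):
                    t_in = np.where(m > 0, -np.log(1.0 - u) / m, 0.0)
                age_death[dies] = seg_a0[j] + t_in[dies]
                alive &= ~dies
            died = ~np.isnan(age_death) & (age_death < censor)
            month = np.clip(((birth_time - birth_year) * 12 + 0.5).astype(int),
                            1, 12)
            frames.append(pd.DataFrame({
                "survey_id": sid, "state": s, "zone": state_zone[s],
                "weight": 1.0,
                "birth_ym": [f"{y}-{mo:02d}" for y, mo in zip(birth_year, month)],
                "birth_time": birth_time,
                "died_flag": died.astype(int),
                "age_death_months": np.where(died, age_death, np.nan),
                "censor_age_months": censor,
            }))
    return pd.concat(frames, ignore_index=True)


def simulate_bundle(config: SimConfig, seed=None) -> dict:
    """The full synthetic input bundle keyed by table name."""
    rng = _rng(seed if seed is not None else config.seed)
    truth, effects = simulate_truth(config, rng)
    estimates = simulate_surveys(truth, config, rng)
    population = simulate_population(config, rng)
    histories = simulate_birth_histories(config, rng)
    return dict(truth=truth, effects=effects, estimates=estimates,
                population=population, birth_histories=histories)
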