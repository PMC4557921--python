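"""Under-5 mortality (5q0) from complete birth histories.

5q0 — the probability a live-born child dies before age 5, conventionally
reported per 1,000 live births — is estimated per source and calendar year by
a synthetic-cohort life table over the standard age segments 0, 1-5, 6-11,
12-23, 24-35, 36-47 and 48-59 months: within a period, each segment's
weighted occurrence/exposure rate is converted to a segment death
probability, and the segment survival probabilities multiply into the cohort
probability q5 = 1 - prod_a (1 - q_a).

Source-year estimates are then smoothed on the logit scale with a one-knot
natural cubic spline plus IID state and survey (source) random intercepts,
and finally scaled so the births-weighted national series matches an external
reference series (a generic scale-to-reference operation).

Only complete birth histories are supported; summary-history conversion is a
non-goal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .prior import build_time_basis
from .transforms import clamp, from_logit, to_logit

__all__ = [
    "AGE_SEGMENTS", "MortalityEstimate", "cbh_5q0", "tabulate_u5m",
    "U5mTrendFit", "fit_u5m_trend", "scale_to_reference",
]

#: (start, end) in months of age; the canonical birth-history segments
AGE_SEGMENTS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 6), (6, 12), (12, 24), (24, 36), (36, 48), (48, 60),
)


@dataclass(frozen=True)
class MortalityEstimate:
    state: str
    period: int
    q5: float
    variance: float
    source_id: str

    def __post_init__(self):
        if not (0 < self.q5 < 1):
            raise ValueError("q5 must lie in (0, 1)")


def parse_birth_time(birth_ym) -> np.ndarray:
    """Decimal birth time from 'YYYY-MM' strings (mid-month convention)."""
    s = pd.Series(birth_ym).astype(str)
    parts = s.str.split("-", expand=True)
    year = parts[0].astype(float)
    month = parts[1].astype(float)
    return (year + (month - 0.5) / 12.0).to_numpy()


def _segment_rates(
    histories: pd.DataFrame,
    period: int,
    age_segments: Sequence[tuple[int, int]],
):
    """Weighted deaths, squared-weight deaths and person-months of exposure
    per age segment within the calendar period [period, period+1)."""
    if "birth_time" in histories.columns:
        b = histories["birth_time"].to_numpy(float)
    else:
        b = parse_birth_time(histories["birth_ym"])
    w = histories["weight"].to_numpy(float)
    died = histories["died_flag"].to_numpy().astype(bool)
    age_death = histories["age_death_months"].to_numpy(float)
    censor = histories["censor_age_months"].to_numpy(float)
    end_age = np.where(died, age_death, censor)

    t0, t1 = float(period), float(period) + 1.0
    D = np.zeros(len(age_segments))
    D2 = np.zeros(len(age_segments))
    PM = np.zeros(len(age_segments))
    PM_obs = np.zeros(len(age_segments))
    for i, (a0, a1) in enumerate(age_segments):
        # calendar window during which each child occupies this age segment,
        # truncated at death/censoring
        seg_start = b + a0 / 12.0
        seg_end = b + np.minimum(a1, end_age) / 12.0
        lo = np.maximum(seg_start, t0)
        hi = np.minimum(seg_end, t1)
        months = np.maximum(hi - lo, 0.0) * 12.0
        PM[i] = float(np.dot(w, months))
        # design exposure: truncated by censoring only, not by death — used
        # to distinguish structural truncation from mortality
        obs_end = b + np.minimum(a1, censor) / 12.0
        hi_obs = np.minimum(obs_end, t1)
        PM_obs[i] = float(np.dot(w, np.maximum(hi_obs - lo, 0.0) * 12.0))
        in_seg = died & (age_death >= a0) & (age_death < a1) & (age_death < censor)
        death_time = b + age_death / 12.0
        in_period = (death_time >= t0) & (death_time < t1)
        sel = in_seg & in_period
        D[i] = float(w[sel].sum())
        D2[i] = float((w[sel] ** 2).sum())
    return D, D2, PM, PM_obs


def cbh_5q0(
    histories: pd.DataFrame,
    period: int,
    age_segments: Sequence[tuple[int, int]] = AGE_SEGMENTS,
) -> Optional[MortalityEstimate]:
    """Synthetic-cohort 5q0 for one calendar year.

    Segment monthly rates m_a = deaths_a / person-months_a convert to segment
    probabilities q_a = 1 - exp(-m_a * width_a); q5 = 1 - prod (1 - q_a).
    The variance sums weighted-Poisson segment contributions on the
    log-survival scale and is delta-transformed back to the q5 scale.

    Returns None unless every age segment has positive exposure under the
    observation design (censoring only): a cohort probability built from a
    truncated age range (e.g. periods at the edge of a source's reporting
    horizon, where only young children are under observation) would be
    structurally biased downward. Segments emptied by mortality itself do
    not suppress the estimate. q5 is clamped into [0.001, 0.999].
    """
    if histories.empty:
        raise ValueError("no birth histories supplied")
    state = histories["state"].iloc[0] if histories["state"].nunique() == 1 \
        else "all"
    source = histories["survey_id"].iloc[0] \
        if histories["survey_id"].nunique() == 1 else "pooled"
    D, D2, PM, PM_obs = _segment_rates(histories, period, age_segments)
    if not np.all(PM_obs > 0):
        return None
    widths = np.array([a1 - a0 for a0, a1 in age_segments], dtype=float)
    ok = PM > 0
    m = np.zeros_like(PM)
    m[ok] = D[ok] / PM[ok]
    log_surv = -np.sum(m * widths)
    q5 = 1.0 - np.exp(log_surv)
    # var(m_a) ~ sum(w^2 over deaths) / PM^2; log-survival variance adds
    # widths^2 * var(m_a) across segments
    var_log_s = np.zeros_like(PM)
    var_log_s[ok] = (widths[ok] ** 2) * D2[ok] / PM[ok] ** 2
    var_q5 = float(np.exp(2 * log_surv) * var_log_s.sum())
    q5_c = float(clamp(q5))
    if var_q5 <= 0:
        # no observed deaths: binomial floor at the clamped level
        var_q5 = q5_c * (1 - q5_c) / max(PM.sum() / widths.sum(), 1.0)
    return MortalityEstimate(state=state, period=int(period), q5=q5_c,
                             variance=var_q5, source_id=source)


def tabulate_u5m(
    histories: pd.DataFrame,
    periods: Sequence[int],
    age_segments: Sequence[tuple[int, int]] = AGE_SEGMENTS,
) -> pd.DataFrame:
    """Per (source, state, period) 5q0 estimates as a DataFrame."""
    if "birth_time" not in histories.columns:
        histories = histories.assign(
            birth_time=parse_birth_time(histories["birth_ym"])
        )
    rows = []
    for (src, state), g in histories.groupby(["survey_id", "state"]):
        for period in periods:
            est = cbh_5q0(g, period, age_segments)
            if est is not None:
                rows.append(dict(
                    source_id=src, state=state,
                    zone=g["zone"].iloc[0] if "zone" in g else "",
                    year=est.period, q5=est.q5, var_q5=est.variance,
                ))
    return pd.DataFrame(rows)


@dataclass
class U5mTrendFit:
    """Smoothed annual state 5q0 series with parametric-bootstrap draws."""

    years: np.ndarray
    states: list
    q5: pd.DataFrame          # long: state, year, q5 (point estimate)
    draws: dict               # state -> years x n_draws matrix, q5 scale
    source_effects: dict
    state_effects: dict


def fit_u5m_trend(
    estimates: pd.DataFrame,
    year_grid: Sequence[int],
    n_draws: int = 1000,
    seed=None,
) -> U5mTrendFit:
    """One-knot natural-spline logit trend with state and survey random
    intercepts; uncertainty via parametric-bootstrap draws of the fixed
    effects around their REML estimates.

    ``estimates`` needs columns state, year, q5, var_q5, source_id.
    """
    if estimates["source_id"].nunique() < 2:
        warnings.warn(
            "single source: survey random intercept fixed at 0", UserWarning
        )
    df = estimates.copy().reset_index(drop=True)
    df["y"] = to_logit(df["q5"].to_numpy())
    basis = build_time_basis(year_grid, "ncs1")
    cols = basis.column_names()
    T = basis.design(df["year"])
    for j, c in enumerate(cols):
        df[c] = T[:, j]
    df["_one"] = 1

    vc = {}
    if df["state"].nunique() > 1:
        vc["state"] = "0 + C(state)"
    if df["source_id"].nunique() > 1:
        vc["source"] = "0 + C(source_id)"
    fe_formula = "y ~ " + " + ".join(cols)
    fe_names = ["Intercept"] + cols
    if vc:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(
                fe_formula, groups="_one", vc_formula=vc, data=df
            )
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        fe = res.fe_params
        # GLS covariance (X' V^-1 X)^-1 at the estimated variance
        # components; the observed-information covariance can be invalid at
        # boundary solutions
        n = len(df)
        V = float(res.scale) * np.eye(n)
        for name, s2 in zip(model.exog_vc.names, np.asarray(res.vcomp)):
            col = "state" if name == "state" else "source_id"
            Z = pd.get_dummies(df[col]).to_numpy(float)
            V += float(s2) * (Z @ Z.T)
        X = np.column_stack([np.ones(n)] + [df[c].to_numpy() for c in cols])
        Vi_X = np.linalg.solve(V, X)
        cov_fe = np.linalg.inv(X.T @ Vi_X)
        ser = res.random_effects[list(res.random_effects)[0]]
        state_eff = {
            s: float(ser.get(f"state[C(state)[{s}]]", 0.0))
            for s in df["state"].unique()
        }
        source_eff = {
            s: float(ser.get(f"source[C(source_id)[{s}]]", 0.0))
            for s in df["source_id"].unique()
        }
    else:
        res = sm.OLS.from_formula(fe_formula, data=df).fit()
        fe = res.params
        cov_fe = np.asarray(res.cov_params().loc[fe_names, fe_names])
        state_eff = {s: 0.0 for s in df["state"].unique()}
        source_eff = {s: 0.0 for s in df["source_id"].unique()}

    fe_vec = np.array([fe[n] for n in fe_names])
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    # symmetrize + jitter-stabilize the REML covariance before factorization
    cov_fe = 0.5 * (cov_fe + cov_fe.T)
    jitter = 1e-12 * max(float(np.diag(cov_fe).max()), 1e-12)
    L = None
    for _ in range(10):
        try:
            L = np.linalg.cholesky(cov_fe + jitter * np.eye(len(fe_vec)))
            break
        except np.linalg.LinAlgError:
            jitter *= 10
    if L is None:
        raise np.linalg.LinAlgError("fixed-effect covariance not PSD")
    fe_draws = fe_vec + rng.standard_normal((n_draws, len(fe_vec))) @ L.T

    years = np.asarray(sorted(set(int(y) for y in year_grid)))
    Tg = np.column_stack([np.ones(len(years)), basis.design(years)])
    states = sorted(df["state"].unique())
    draws = {}
    point_rows = []
    for s in states:
        logit_mu = Tg @ fe_vec + state_eff[s]
        logit_draws = Tg @ fe_draws.T + state_eff[s]
        draws[s] = from_logit(logit_draws)
        for y, v in zip(years, from_logit(logit_mu)):
            point_rows.append(dict(state=s, year=int(y), q5=float(v)))
    return U5mTrendFit(
        years=years, states=states,
        q5=pd.DataFrame(point_rows), draws=draws,
        source_effects=source_eff, state_effects=state_eff,
    )


def scale_to_reference(
    trend: U5mTrendFit,
    pops: pd.DataFrame,
    reference: pd.DataFrame,
    weight_basis: str = "live_births",
) -> tuple[U5mTrendFit, pd.Series]:
    """Multiplicatively scale state 5q0 series to a national reference.

    Per year t, the factor r_t = reference_t / (births-weighted national
    aggregate of state point estimates); every state's point estimate and
    every draw is multiplied by r_t, so the re-aggregated national point
    series equals the reference exactly. Between-state ratios within each
    year are preserved.

    ``reference`` has columns year, q5. Returns the scaled trend and the
    factor series indexed by year.
    """
    from .aggregate import normalized_weights

    years = trend.years
    W = normalized_weights(pops, trend.states, years, weight_basis)
    wide = trend.q5.pivot(index="year", columns="state", values="q5") \
        .loc[years, trend.states]
    nat = (W.values * wide.values).sum(axis=1)
    if np.any(nat <= 0):
        raise ValueError("national aggregate is zero; cannot scale")
    ref = reference.set_index("year")["q5"].reindex(years)
    if ref.isna().any():
        raise ValueError("reference series does not cover the year grid")
    factors = pd.Series(ref.to_numpy() / nat, index=years, name="factor")

    scaled_q5 = trend.q5.copy()
    fmap = factors.to_dict()
    scaled_q5["q5"] = [
        q * fmap[y] for q, y in zip(scaled_q5["q5"], scaled_q5["year"])
    ]
    scaled_draws = {
        s: trend.draws[s] * factors.to_numpy()[:, None] for s in trend.states
    }
    out = U5mTrendFit(
        years=years, states=trend.states, q5=scaled_q5, draws=scaled_draws,
        source_effects=trend.source_effects, state_effects=trend.state_effects,
    )
    return out, factors
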