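"""Benchmark experiments: published-estimate arithmetic and simulation
studies of estimator calibration.

These routines re-run the package's own machinery under the default study
conditions and measure how well it does — interval calibration, fixed-effect
recovery, cross-validated basis selection, the birth-history estimator
against its closed form, and the scale-to-reference conservation law. They
back both the acceptance checks and the reproducibility script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aggregate import paired_gap, range_gap, relative_decline
from .gpr import GPConfig, gp_condition, matern_kernel
from .model import CoverageTrendModel
from .prior import PriorSpec, cv_select, fit_prior
from .simulate import (SimConfig, simulate_birth_histories,
                       simulate_population, simulate_prior_dataset,
                       simulate_surveys, simulate_truth)
from .u5m import cbh_5q0, fit_u5m_trend, scale_to_reference, tabulate_u5m

YEAR_GRID = tuple(range(2000, 2014))

#: Published point estimates for Nigeria used to exercise the benchmarking
#: arithmetic. Under-5 mortality is in deaths per 1,000 live births;
#: coverages are in percent.
PUBLISHED = {
    "u5m_national": {2000: 184.0, 2013: 128.0},
    "u5m_states_2000": {"Lagos": 96.0, "Zamfara": 302.0},
    "u5m_states_2013": {"Edo": 72.0, "Zamfara": 209.0},
    "lagos_2013": {"dpt3": 88.0, "opv3": 69.0},
    "ifd_2013": {"Imo": 91.0, "Zamfara": 5.0},
    "itn_own": {"level_2009": 14.0, "goal_2013": 80.0},
}

#: default stage-1 specification for simulation studies: the state/zone
#: intercept hierarchy, leaving state-specific slope deviations to the GP
SIM_SPEC = PriorSpec("ncs1", frozenset({"u_s", "u_z"}))


def published_identities() -> dict[str, float]:
    """The benchmarking arithmetic applied to the published estimates."""
    u5m = PUBLISHED["u5m_national"]
    _, _, gap_2000 = range_gap(PUBLISHED["u5m_states_2000"])
    _, _, gap_2013 = range_gap(PUBLISHED["u5m_states_2013"])
    _, _, ifd_gap = range_gap(PUBLISHED["ifd_2013"])
    return {
        "u5m_national_decline_pct": round(
            relative_decline(u5m[2000], u5m[2013])
        ),
        "u5m_state_range_2000": gap_2000,
        "u5m_state_range_2013": gap_2013,
        "lagos_dpt3_minus_opv3_pp": paired_gap(
            PUBLISHED["lagos_2013"]["dpt3"], PUBLISHED["lagos_2013"]["opv3"]
        ),
        "ifd_state_range_2013_pp": ifd_gap,
        "itn_goal_gap_2009_pp": paired_gap(
            PUBLISHED["itn_own"]["goal_2013"],
            PUBLISHED["itn_own"]["level_2009"],
        ),
    }


def gpr_oracle_error(seed: int = 0, n_trials: int = 20) -> float:
    """Worst deviation of gp_condition from brute-force conditioning of the
    dense multivariate normal, over random <=10-point problems."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        n_grid = int(rng.integers(4, 11))
        grid = 2000 + np.sort(rng.choice(20, n_grid, replace=False)).astype(float)
        config = GPConfig(
            nu=float(rng.choice([0.5, 1.5, 2.5])),
            length_scale=float(rng.uniform(2, 8)),
            amplitude=float(rng.uniform(0.2, 2.0)),
        )
        mu0 = rng.normal(0, 1, n_grid)
        n_obs = int(rng.integers(1, n_grid))
        obs_t = np.sort(rng.choice(grid, n_obs, replace=False))
        obs_y = rng.normal(0, 1, n_obs)
        obs_var = rng.uniform(0.01, 1.0, n_obs)
        mean, cov = gp_condition(grid, mu0, obs_t, obs_y, obs_var, config)
        # dense oracle over the joint (grid, obs) normal
        allt = np.concatenate([grid, obs_t])
        K = matern_kernel(np.subtract.outer(allt, allt), config.nu,
                          config.length_scale, config.amplitude**2)
        mu_obs = np.interp(obs_t, grid, mu0)
        K_oo = K[n_grid:, n_grid:] + np.diag(obs_var)
        K_go = K[:n_grid, n_grid:]
        sol = np.linalg.solve(K_oo, obs_y - mu_obs)
        mean_o = mu0 + K_go @ sol
        cov_o = K[:n_grid, :n_grid] - K_go @ np.linalg.solve(K_oo, K_go.T)
        worst = max(worst,
                    float(np.abs(mean - mean_o).max()),
                    float(np.abs(cov - cov_o).max()))
    return worst


def interval_coverage(n_reps: int = 200, seed: int = 0) -> dict:
    """Pooled fraction of state-years whose 95% interval covers the truth,
    across replicates of the full two-stage pipeline at default conditions."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig()
    hits = 0
    total = 0
    for _ in range(n_reps):
        truth, _ = simulate_truth(cfg, rng)
        est = simulate_surveys(truth, cfg, rng)
        res = CoverageTrendModel(est, year_grid=YEAR_GRID).fit(
            spec=SIM_SPEC, seed=int(rng.integers(2**31))
        )
        m = res.summaries.merge(truth, on=["state", "year"])
        hits += int(((m["p_true"] >= m["lower"])
                     & (m["p_true"] <= m["upper"])).sum())
        total += len(m)
    return {"coverage_pct": 100.0 * hits / total, "n_state_years": total}


def fixed_effect_recovery(n_reps: int = 200, seed: int = 0) -> dict:
    """Bias z-scores of the fully loaded REML fit's fixed effects against
    the generating values, and variance-component accuracy."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig()
    spec = PriorSpec("ncs1", frozenset({"u_s", "u_z", "b_s", "b_z"}))
    sd_slope = 0.05
    estimates, vcomps = [], []
    for _ in range(n_reps):
        d, truth = simulate_prior_dataset(cfg, rng, sd_slope=sd_slope)
        f = fit_prior(d, spec, year_grid=YEAR_GRID)
        estimates.append([f.alpha, *f.beta])
        vcomps.append([f.variance_components[k] for k in
                       ("sigma2_eps", "sigma2_u_z", "sigma2_u_s",
                        "sigma2_b_s", "sigma2_b_z")])
    E = np.asarray(estimates)
    true_fe = np.array([cfg.alpha, *cfg.beta])
    mc_se = E.std(axis=0, ddof=1) / np.sqrt(n_reps)
    z = (E.mean(axis=0) - true_fe) / mc_se
    true_vc = np.array([cfg.sd_eps**2, cfg.sd_u_z**2, cfg.sd_u_s**2,
                        sd_slope**2, sd_slope**2])
    vc_ratio = np.asarray(vcomps).mean(axis=0) / true_vc
    return {
        "max_abs_z": float(np.abs(z).max()),
        "z": z.tolist(),
        "vc_mean_ratio": vc_ratio.tolist(),
        "vc_max_rel_err": float(np.abs(vc_ratio - 1).max()),
        "n_reps": n_reps,
    }


def cv_basis_selection(n_runs: int = 50, cv_reps: int = 20,
                       seed: int = 0) -> dict:
    """How often hold-out CV picks the spline family when the truth has
    strong curvature."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(beta=(0.05, 0.30), sd_b_s=0.03, sd_b_z=0.03)
    specs = [PriorSpec("linear", frozenset({"u_s"})),
             PriorSpec("ncs1", frozenset({"u_s"})),
             PriorSpec("linear", frozenset({"u_s", "u_z"})),
             PriorSpec("ncs1", frozenset({"u_s", "u_z"}))]
    wins = 0
    for _ in range(n_runs):
        truth, _ = simulate_truth(cfg, rng)
        est = simulate_surveys(truth, cfg, rng)
        d = est[["state", "zone", "year"]].copy()
        from .transforms import to_logit
        d["y"], _ = to_logit(est["p"].to_numpy(), est["var_p"].to_numpy())
        cv = cv_select(d, specs, reps=cv_reps,
                       seed=int(rng.integers(2**31)), year_grid=YEAR_GRID)
        wins += cv.selected.basis == "ncs1"
    return {"ncs1_selected_pct": 100.0 * wins / n_runs, "n_runs": n_runs}


def constant_hazard_check(n_children: int = 50_000, seed: int = 0,
                          lam: float = 0.002) -> dict:
    """cbh_5q0 on constant-hazard children vs the closed form
    1 - exp(-60 lambda)."""
    rng = np.random.default_rng(seed)
    survey_time, span = 2010.5, 10.0
    b = survey_time - rng.uniform(0, span, n_children)
    t_death = rng.exponential(1 / lam, n_children)
    censor = (survey_time - b) * 12
    died = (t_death < 60) & (t_death < censor)
    h = pd.DataFrame({
        "survey_id": "svy", "state": "X", "zone": "Z", "weight": 1.0,
        "birth_time": b, "birth_ym": "2000-01",
        "died_flag": died.astype(int),
        "age_death_months": np.where(died, t_death, np.nan),
        "censor_age_months": censor,
    })
    est = cbh_5q0(h, 2005)
    expected = 1 - np.exp(-60 * lam)
    mc_se = float(np.sqrt(expected * (1 - expected) / (n_children / 2)))
    return {"q5": est.q5, "expected": expected, "mc_se": mc_se,
            "abs_err": abs(est.q5 - expected), "n": n_children}


def scaling_conservation(seed: int = 0) -> dict:
    """Max deviation of the re-aggregated national 5q0 from the reference
    after scale_to_reference."""
    cfg = SimConfig(n_states=8, n_zones=4, n_children_per_state=1500)
    hist = simulate_birth_histories(cfg, seed)
    tab = tabulate_u5m(hist, YEAR_GRID)
    trend = fit_u5m_trend(tab, YEAR_GRID, n_draws=100, seed=seed + 1)
    pop = simulate_population(cfg, seed + 2)
    ref = pd.DataFrame({"year": list(YEAR_GRID),
                        "q5": np.linspace(0.184, 0.128, len(YEAR_GRID))})
    scaled, _ = scale_to_reference(trend, pop, ref)
    wide = scaled.q5.pivot(index="year", columns="state", values="q5")
    w = pop.pivot(index="year", columns="state", values="live_births")
    w = w.div(w.sum(axis=1), axis=0).loc[wide.index, wide.columns]
    nat = (wide * w).sum(axis=1).to_numpy()
    return {"max_abs_err": float(np.abs(nat - ref["q5"].to_numpy()).max())}


def aggregation_invariants(seed: int = 0) -> dict:
    """Constant conservation and commutation of aggregation with
    summarization, measured as worst-case deviations."""
    from .aggregate import composite_coverage, national_aggregate
    from .gpr import PosteriorDraws, summarize_draws
    from .indicators import CompositeSpec
    from .transforms import from_logit, to_logit

    rng = np.random.default_rng(seed)
    years = np.asarray(YEAR_GRID)
    states = [f"S{i}" for i in range(5)]
    pops = pd.DataFrame([
        dict(state=s, year=int(y), population=float(rng.uniform(1e6, 8e6)),
             live_births=1.0)
        for s in states for y in years
    ])
    const = {s: PosteriorDraws(s, years, np.full((len(years), 1000),
                                                 to_logit(0.42)))
             for s in states}
    nat_const = national_aggregate(const, pops)
    err_const = float(np.abs(from_logit(nat_const.draws) - 0.42).max())

    sd = {s: PosteriorDraws(s, years, rng.normal(0, 1, (len(years), 1000)))
          for s in states}
    nat = national_aggregate(sd, pops)
    s_after = summarize_draws(nat)
    wide = pops.pivot(index="year", columns="state", values="population")
    W = wide.div(wide.sum(axis=1), axis=0)[states].to_numpy()
    agg = np.einsum("sy,syd->yd", W.T,
                    np.stack([from_logit(sd[s].draws) for s in states]))
    s_pre = summarize_draws(PosteriorDraws("national", years, to_logit(agg)))
    err_commute = float(
        np.abs(s_after[["median", "lower", "upper"]].to_numpy()
               - s_pre[["median", "lower", "upper"]].to_numpy()).max()
    )

    spec = CompositeSpec.default()
    vals = {m: rng.uniform(0.05, 0.95, (3, 200)) for m in spec.members}
    comp = composite_coverage(vals, spec)
    err_bounds = float(max(-comp.min(), comp.max() - 1, 0.0))
    return {"constant_conservation_err": err_const,
            "commutation_err": err_commute,
            "composite_bounds_err": err_bounds}
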