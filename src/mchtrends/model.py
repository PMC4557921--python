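"""Model/Results facade over the two-stage estimator.

:class:`CoverageTrendModel` is built from a table of state-year survey
estimates for one indicator; :meth:`~CoverageTrendModel.fit` runs
cross-validated stage-1 specification selection, fits the mixed-effects
logit prior, smooths each state with the Matern GP, and (when a population
table is supplied) aggregates to a national trend at the draw level. The
returned :class:`CoverageTrendResults` carries the selected specification,
the prior fit, per-state posterior draws and summaries, and a printable
``summary()``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aggregate import national_aggregate
from .gpr import GPConfig, PosteriorDraws, smooth_state, summarize_draws
from .prior import (CVResult, PriorFit, PriorSpec, cv_select, enumerate_specs,
                    fit_prior)
from .tabulate import active_estimates
from .transforms import to_logit

__all__ = ["CoverageTrendModel", "CoverageTrendResults"]


class CoverageTrendModel:
    """Two-stage small-area trend model for one indicator.

    Parameters
    ----------
    estimates : DataFrame
        State-year survey estimates with columns state, zone, year, p,
        var_p, source_id, flags. Rows flagged ``excluded`` never enter the
        fit.
    population : DataFrame, optional
        Columns state, year, population (and/or live_births); enables
        national aggregation.
    year_grid : sequence of int
        Annual estimation grid (default 2000-2013).
    gp_config : GPConfig
        Matern hyperparameters; an unset amplitude is derived from the
        stage-1 residual scale at fit time.
    """

    def __init__(
        self,
        estimates: pd.DataFrame,
        population: Optional[pd.DataFrame] = None,
        year_grid: Sequence[int] = tuple(range(2000, 2014)),
        gp_config: GPConfig = GPConfig(),
    ):
        est = active_estimates(estimates).reset_index(drop=True)
        if est.empty:
            raise ValueError("no non-excluded estimates")
        self.estimates = est
        self.population = population
        self.year_grid = np.asarray(sorted(set(int(y) for y in year_grid)))
        self.gp_config = gp_config
        data = est[["state", "zone", "year"]].copy()
        y, var_y = to_logit(est["p"].to_numpy(), est["var_p"].to_numpy())
        data["y"] = y
        data["var_y"] = var_y
        self.data = data

    @classmethod
    def from_dataframe(cls, estimates: pd.DataFrame, **kw) -> "CoverageTrendModel":
        return cls(estimates, **kw)

    def fit(
        self,
        spec: Optional[PriorSpec] = None,
        specs: Optional[Sequence[PriorSpec]] = None,
        holdout_frac: float = 0.20,
        cv_reps: int = 100,
        seed=None,
        weight_basis: str = "population",
    ) -> "CoverageTrendResults":
        """Run both stages and return results.

        When ``spec`` is given, cross-validation is skipped; otherwise the
        candidate list (default: all 14) is scored by repeated 20% hold-out
        RMSE and the winner refitted on all data.
        """
        rng = np.random.default_rng(seed)
        cv_result = None
        if spec is None:
            cv_result = cv_select(
                self.data, specs=specs or enumerate_specs(),
                holdout_frac=holdout_frac, reps=cv_reps,
                seed=int(rng.integers(2**31)), year_grid=self.year_grid,
            )
            spec = cv_result.selected
        prior_fit = fit_prior(self.data, spec, year_grid=self.year_grid)

        config = self.gp_config
        if config.amplitude is None:
            config = config.with_amplitude_from_residuals(prior_fit.resid)

        draws: dict[str, PosteriorDraws] = {}
        summaries = []
        for state in sorted(self.data["state"].unique()):
            obs = self.data[self.data["state"] == state]
            prior_mean = prior_fit.predict(state, self.year_grid)
            pdraws = smooth_state(
                state, self.year_grid, prior_mean, obs, config, rng=rng
            )
            draws[state] = pdraws
            summaries.append(summarize_draws(pdraws, strict=False))

        national_draws = national_summary = None
        if self.population is not None:
            national_draws = national_aggregate(
                draws, self.population, weight_basis=weight_basis
            )
            national_summary = summarize_draws(national_draws, strict=False)

        return CoverageTrendResults(
            model=self, spec=spec, cv_result=cv_result, prior_fit=prior_fit,
            gp_config=config, draws=draws,
            summaries=pd.concat(summaries, ignore_index=True),
            national_draws=national_draws, national_summary=national_summary,
        )


class CoverageTrendResults:
    """Fitted two-stage trend estimates for one indicator."""

    def __init__(self, model, spec, cv_result, prior_fit, gp_config, draws,
                 summaries, national_draws=None, national_summary=None):
        self.model: CoverageTrendModel = model
        self.spec: PriorSpec = spec
        self.cv_result: Optional[CVResult] = cv_result
        self.prior_fit: PriorFit = prior_fit
        self.gp_config: GPConfig = gp_config
        self.draws: dict[str, PosteriorDraws] = draws
        self.summaries: pd.DataFrame = summaries
        self.national_draws: Optional[PosteriorDraws] = national_draws
        self.national_summary: Optional[pd.DataFrame] = national_summary

    @property
    def states(self) -> list[str]:
        return sorted(self.draws)

    def state_summary(self, state: str) -> pd.DataFrame:
        return self.summaries[self.summaries["state"] == state].reset_index(
            drop=True
        )

    def median_table(self) -> pd.DataFrame:
        """Wide year x state table of posterior medians (proportion scale)."""
        return self.summaries.pivot(index="year", columns="state",
                                    values="median")

    def summary(self) -> str:
        """Printable fit summary."""
        lines = [
            "Two-stage coverage trend model",
            "=" * 46,
            f"states:            {len(self.states)}",
            f"observations:      {len(self.model.data)}",
            f"year grid:         {self.model.year_grid[0]}-{self.model.year_grid[-1]}",
            f"selected spec:     {self.spec.id}"
            + ("  (by 20% hold-out CV)" if self.cv_result is not None else ""),
            f"residual SD:       {self.prior_fit.sigma_eps:.4f} (logit)",
            f"GP amplitude:      {self.gp_config.amplitude:.4f} (logit SD)",
            f"GP kernel:         Matern nu={self.gp_config.nu}, "
            f"length scale {self.gp_config.length_scale} y",
            f"posterior draws:   {next(iter(self.draws.values())).n_draws}",
        ]
        if self.prior_fit.variance_components:
            lines.append("variance components:")
            for k, v in sorted(self.prior_fit.variance_components.items()):
                lines.append(f"  {k:<18} {v:.5f}")
        if self.national_summary is not None:
            first = self.national_summary.iloc[0]
            last = self.national_summary.iloc[-1]
            lines.append(
                f"national trend:    {100 * first['median']:.1f}% "
                f"({int(first['year'])}) -> {100 * last['median']:.1f}% "
                f"({int(last['year'])})"
            )
        return "\n".join(lines)

    def plot(self, state: str, ax=None):
        """Plot one state's data, posterior median and 95% band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.state_summary(state)
        ax.fill_between(s["year"], s["lower"], s["upper"], alpha=0.25,
                        label="95% interval")
        ax.plot(s["year"], s["median"], label="posterior median")
        obs = self.model.estimates[self.model.estimates["state"] == state]
        ax.scatter(obs["year"], obs["p"], s=15, color="k", zorder=3,
                   label="survey estimates")
        ax.set_xlabel("year")
        ax.set_ylabel("proportion")
        ax.set_title(state)
        ax.legend()
        return ax
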