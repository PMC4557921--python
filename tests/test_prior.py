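"""Stage-1 mixed-effects prior: basis, enumeration, fitting, CV selection."""

import numpy as np
import pandas as pd
import patsy
import pytest

from mchtrends.prior import (PriorSpec, build_time_basis, cv_select,
                             enumerate_specs, fit_prior, predict_prior)
from mchtrends.simulate import SimConfig, simulate_prior_dataset

GRID = list(range(2000, 2014))


class TestTimeBasis:
    def test_linear_centering(self):
        b = build_time_basis(GRID, "linear")
        col = b.design([2006.5])[0]
        assert col[0] == pytest.approx(0.0, abs=1e-12)
        assert b.design(GRID).shape == (14, 1)

    def test_ncs_column_space_matches_patsy_cr(self):
        """The 2-column spline spans the same space as patsy's natural
        cubic regression spline with the same knots (independent oracle)."""
        x = np.linspace(2000, 2013, 27)
        b = build_time_basis(GRID, "ncs1")
        mine = np.column_stack([np.ones(len(x)), b.design(x)])
        cr = patsy.dmatrix(
            "cr(x, knots=[2006.5], lower_bound=2000, upper_bound=2013) - 1",
            {"x": x}, return_type="matrix",
        )
        cr = np.asarray(cr)
        resid = cr - mine @ np.linalg.lstsq(mine, cr, rcond=None)[0]
        assert np.abs(resid).max() < 1e-9
        # and conversely
        resid2 = mine - cr @ np.linalg.lstsq(cr, mine, rcond=None)[0]
        assert np.abs(resid2).max() < 1e-9

    def test_natural_boundary_is_linear(self):
        """Beyond the boundary knots the spline continues linearly: second
        differences vanish."""
        b = build_time_basis(GRID, "ncs1")
        for xs in (np.arange(2014, 2020), np.arange(1994, 2000)):
            B = b.design(xs)
            d2 = np.diff(B, n=2, axis=0)
            assert np.abs(d2).max() < 1e-8

    def test_too_few_years(self):
        with pytest.raises(ValueError):
            build_time_basis([2005], "linear")
        with pytest.raises(ValueError):
            build_time_basis([2005, 2008], "ncs1")


class TestSpecEnumeration:
    def test_fourteen_specs_stable_order(self):
        specs = enumerate_specs()
        assert len(specs) == 14
        assert specs == enumerate_specs()
        ids = [s.id for s in specs]
        assert len(set(ids)) == 14
        assert "linear~none" in ids                       # pure OLS member
        assert "ncs1~u_s+u_z+b_s+b_z" in ids              # fully loaded

    def test_slope_requires_intercept(self):
        with pytest.raises(ValueError):
            PriorSpec("linear", frozenset({"b_s"}))
        with pytest.raises(ValueError):
            PriorSpec("ncs1", frozenset({"u_z", "b_s"}))


def _line_data(states=("A",), zone="Z1", years=GRID, alpha=2.0, slope=0.1):
    b = build_time_basis(years, "linear")
    rows = []
    for s in states:
        t = b.design(years)[:, 0]
        for yr, tt in zip(years, t):
            rows.append(dict(state=s, zone=zone, year=yr,
                             y=alpha + slope * tt))
    return pd.DataFrame(rows)


class TestFitPrior:
    def test_noise_free_line_recovered_exactly(self):
        d = _line_data()
        f = fit_prior(d, PriorSpec("linear"), year_grid=GRID)
        assert f.alpha == pytest.approx(2.0, abs=1e-8)
        assert f.beta[0] == pytest.approx(0.1, abs=1e-8)

    def test_intercept_only_data(self):
        d = _line_data(slope=0.0, alpha=1.3)
        f = fit_prior(d, PriorSpec("linear"), year_grid=GRID)
        assert f.alpha == pytest.approx(1.3, abs=1e-8)
        assert f.beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_ols_matches_closed_form(self, rng):
        d = _line_data(states=("A", "B"))
        d["y"] = d["y"] + rng.normal(0, 0.3, len(d))
        f = fit_prior(d, PriorSpec("ncs1"), year_grid=GRID)
        b = build_time_basis(GRID, "ncs1")
        X = np.column_stack([np.ones(len(d)), b.design(d["year"])])
        coef, *_ = np.linalg.lstsq(X, d["y"].to_numpy(), rcond=None)
        assert f.alpha == pytest.approx(coef[0], abs=1e-8)
        np.testing.assert_allclose(f.beta, coef[1:], atol=1e-8)

    def test_predict_matches_component_assembly(self, rng):
        cfg = SimConfig()
        d, _ = simulate_prior_dataset(cfg, rng)
        spec = PriorSpec("ncs1", frozenset({"u_s", "u_z", "b_s", "b_z"}))
        f = fit_prior(d, spec, year_grid=GRID)
        state = d["state"].iloc[0]
        zone = d["zone"].iloc[0]
        T = f.basis.design(GRID)
        manual = (f.alpha + f.u_s[state] + f.u_z[zone]
                  + T @ (f.beta + f.b_s[state] + f.b_z[zone]))
        np.testing.assert_allclose(predict_prior(f, state, GRID), manual,
                                   atol=1e-10)

    def test_random_effects_explain_residual_structure(self, rng):
        """Including the extracted effects shrinks residuals to ~sigma_eps,
        validating the component extraction from the REML fit."""
        cfg = SimConfig()
        d, _ = simulate_prior_dataset(cfg, rng)
        spec = PriorSpec("ncs1", frozenset({"u_s", "u_z"}))
        f = fit_prior(d, spec, year_grid=GRID)
        resid_sd = np.std(d["y"].to_numpy() - f.predict_rows(d))
        assert resid_sd < 0.6 * d["y"].std()
        assert resid_sd == pytest.approx(f.sigma_eps, rel=0.5)

    def test_single_zone_fixes_zone_terms(self, rng):
        d = _line_data(states=("A", "B", "C"))
        d["y"] += rng.normal(0, 0.1, len(d))
        spec = PriorSpec("linear", frozenset({"u_s", "u_z"}))
        with pytest.warns(UserWarning, match="single zone"):
            f = fit_prior(d, spec, year_grid=GRID)
        assert all(v == 0 for v in f.u_z.values()) or not f.u_z

    def test_unknown_state_prediction_raises(self):
        d = _line_data(states=("A", "B"))
        f = fit_prior(d, PriorSpec("linear", frozenset({"u_s"})),
                      year_grid=GRID)
        with pytest.raises(KeyError):
            f.predict("nowhere", GRID)

    def test_mixed_fit_matches_lme4(self, tmp_path, rng):
        """Cross-check REML estimates against R's lme4 on one dataset."""
        cfg = SimConfig(n_states=12, n_zones=4)
        d, _ = simulate_prior_dataset(
            cfg, rng, re_structure=frozenset({"u_s"}),
        )
        f = fit_prior(d, PriorSpec("linear", frozenset({"u_s"})),
                      year_grid=GRID)
        csv = tmp_path / "d.csv"
        b = build_time_basis(GRID, "linear")
        d = d.assign(tb1=b.design(d["year"])[:, 0])
        d.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- lmer(y ~ tb1 + (1 | state), data = d, REML = TRUE)\n"
            "cat(fixef(m), sigma(m), as.numeric(VarCorr(m)$state), sep=',')\n"
        )
        import subprocess
        try:
            out = subprocess.run(
                ["Rscript", str(script)], capture_output=True, text=True,
                timeout=120, check=True,
            ).stdout
        except (FileNotFoundError, subprocess.CalledProcessError):
            pytest.skip("Rscript/lme4 unavailable")
        alpha_r, beta_r, sigma_r, var_us_r = map(float, out.split(","))
        assert f.alpha == pytest.approx(alpha_r, rel=1e-4)
        assert f.beta[0] == pytest.approx(beta_r, rel=1e-4)
        assert f.sigma_eps == pytest.approx(sigma_r, rel=1e-3)
        assert f.variance_components["sigma2_u_s"] == pytest.approx(
            var_us_r, rel=1e-2
        )


@pytest.fixture(scope="module")
def noisy_data():
    cfg = SimConfig(n_states=12, n_zones=4)
    d, _ = simulate_prior_dataset(cfg, 55, re_structure=frozenset({"u_s"}))
    return d


class TestCvSelect:
    def test_bit_reproducible(self, noisy_data):
        specs = [PriorSpec("linear", frozenset({"u_s"})),
                 PriorSpec("ncs1", frozenset({"u_s"}))]
        a = cv_select(noisy_data, specs, reps=5, seed=9, year_grid=GRID)
        b = cv_select(noisy_data, specs, reps=5, seed=9, year_grid=GRID)
        pd.testing.assert_frame_equal(a.rmse, b.rmse)
        assert a.selected == b.selected

    def test_rmse_of_perfect_predictor_is_zero(self):
        d = _line_data(states=("A", "B", "C", "D"))
        cv = cv_select(d, [PriorSpec("linear")], reps=5, seed=1,
                       year_grid=GRID)
        assert cv.table["mean_rmse"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_rmse_formula(self):
        from mchtrends.prior import _rmse
        assert _rmse(np.array([3.0, 4.0])) == pytest.approx(
            np.sqrt((9 + 16) / 2)
        )

    def test_nested_specs_never_increase_in_sample_fit(self, noisy_data):
        """Adding random effects cannot worsen in-sample RMSE."""
        rmses = {}
        for re in [frozenset(), frozenset({"u_s"}),
                   frozenset({"u_s", "b_s"})]:
            f = fit_prior(noisy_data, PriorSpec("linear", re), year_grid=GRID)
            resid = noisy_data["y"].to_numpy() - f.predict_rows(noisy_data)
            rmses[len(re)] = np.sqrt(np.mean(resid**2))
        assert rmses[1] <= rmses[0] + 1e-8
        assert rmses[2] <= rmses[1] + 1e-8

    def test_tie_break_prefers_parsimony(self):
        d = _line_data(states=("A", "B", "C", "D", "E"))
        specs = [PriorSpec("ncs1", frozenset({"u_s"})),
                 PriorSpec("linear", frozenset())]
        cv = cv_select(d, specs, reps=4, seed=3, year_grid=GRID)
        # noise-free line: every spec predicts perfectly; the simpler and
        # linear one must win the tie
        assert cv.selected == PriorSpec("linear", frozenset())
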