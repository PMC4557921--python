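"""Stage 1: the mixed-effects logit prior over state-level time trends.

The systematic component is a fixed effect on time, entered either linearly
or through the two basis columns of a natural cubic spline with a single
interior knot. Random components are IID mean-zero intercepts and slopes at
the state and geopolitical-zone levels. On the logit scale, for state s in
zone z at year t:

    y_{s,t} = alpha + T (beta + b_s + b_z) + u_s + u_z + eps_{s,t}

where T is the time basis row, beta the fixed time coefficients, b_s / b_z
IID random slopes, u_s / u_z IID random intercepts, and eps_{s,t} a normal
error. Slopes are only admitted alongside the intercept at the same level,
giving 7 random structures x 2 bases = 14 candidate specifications.

Model selection is by cross-validation: the specification with the lowest
mean RMSE of logit-scale predictions over repeated 20% random hold-outs
wins. Mixed specifications are fitted by REML (statsmodels MixedLM, with the
state/zone structure encoded as variance components so every random term is
IID with its own single variance); the empty random structure is ordinary
least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TimeBasis", "build_time_basis", "PriorSpec", "enumerate_specs",
    "PriorFit", "fit_prior", "predict_prior", "CVResult", "cv_select",
    "PriorConvergenceError",
]

RE_TERMS = ("u_s", "u_z", "b_s", "b_z")

#: the 7 admissible random structures (slope requires same-level intercept)
RE_LATTICE: tuple[frozenset, ...] = tuple(
    frozenset(s) for s in (
        (), ("u_s",), ("u_z",), ("u_s", "u_z"),
        ("u_s", "b_s"), ("u_s", "u_z", "b_s"),
        ("u_s", "u_z", "b_s", "b_z"),
    )
)


class PriorConvergenceError(RuntimeError):
    """Raised when a specification fails to produce a usable fit."""

    def __init__(self, spec: "PriorSpec", msg: str = ""):
        self.spec = spec
        super().__init__(f"prior fit failed for {spec.id}: {msg}")


# ---------------------------------------------------------------------------
# time basis

class TimeBasis:
    """Centered, standardized time design; reproducible at prediction time.

    ``linear`` is a single year column centered at the mean of the build
    grid. ``ncs1`` spans the 2-column natural cubic spline space with
    interior knot at the median build year and boundary knots at its min/max
    (linear beyond the boundaries). Columns are centered at their build-grid
    means and scaled to unit build-grid SD, so IID random slopes with a
    shared variance perturb trajectories by comparable magnitudes on every
    column.
    """

    def __init__(self, kind: str, years: Sequence[int]):
        years = np.asarray(sorted(set(int(y) for y in years)), dtype=float)
        if kind == "linear":
            if years.size < 2:
                raise ValueError("linear basis needs >= 2 distinct years")
        elif kind == "ncs1":
            if years.size < 3:
                raise ValueError("ncs1 basis needs >= 3 distinct years")
        else:
            raise ValueError(f"unknown basis kind {kind!r}")
        self.kind = kind
        self.build_years = years
        if kind == "ncs1":
            self.knots = (years.min(), float(np.median(years)), years.max())
        else:
            self.knots = None
        raw = self._raw(years)
        self._center = raw.mean(axis=0)
        self._scale = raw.std(axis=0)
        if np.any(self._scale <= 0):
            raise ValueError("degenerate time basis (constant column)")

    @property
    def k(self) -> int:
        return 1 if self.kind == "linear" else 2

    def _raw(self, years) -> np.ndarray:
        x = np.asarray(years, dtype=float)
        if self.kind == "linear":
            return x[:, None]
        lo, mid, hi = self.knots

        def d(knot):
            return (np.maximum(x - knot, 0.0) ** 3
                    - np.maximum(x - hi, 0.0) ** 3) / (hi - knot)

        return np.column_stack([x, d(lo) - d(mid)])

    def design(self, years) -> np.ndarray:
        """Centered, standardized basis matrix, one row per year."""
        return (self._raw(years) - self._center) / self._scale

    def column_names(self) -> list[str]:
        return [f"tb{j + 1}" for j in range(self.k)]


def build_time_basis(years: Sequence[int], basis: str) -> TimeBasis:
    """Construct the time basis of the given kind from observed years."""
    return TimeBasis(basis, years)


# ---------------------------------------------------------------------------
# specifications

@dataclass(frozen=True)
class PriorSpec:
    """One candidate specification: a basis and a random-effects structure."""

    basis: str
    re_structure: frozenset = frozenset()

    def __post_init__(self):
        if self.basis not in ("linear", "ncs1"):
            raise ValueError(f"unknown basis {self.basis!r}")
        re = frozenset(self.re_structure)
        object.__setattr__(self, "re_structure", re)
        if not re <= set(RE_TERMS):
            raise ValueError(f"unknown random terms {re - set(RE_TERMS)}")
        if "b_s" in re and "u_s" not in re:
            raise ValueError("b_s requires u_s")
        if "b_z" in re and "u_z" not in re:
            raise ValueError("b_z requires u_z")

    @property
    def id(self) -> str:
        terms = [t for t in RE_TERMS if t in self.re_structure]
        return f"{self.basis}~{'+'.join(terms) if terms else 'none'}"

    @property
    def n_random_terms(self) -> int:
        return len(self.re_structure)


def enumerate_specs() -> list[PriorSpec]:
    """All 14 candidate specifications, in stable order."""
    return [
        PriorSpec(basis=b, re_structure=re)
        for b in ("linear", "ncs1")
        for re in RE_LATTICE
    ]


# ---------------------------------------------------------------------------
# fitting

@dataclass
class PriorFit:
    """A fitted stage-1 specification.

    Random-effect dictionaries map state/zone labels to realized (posterior
    mean) effects; labels absent from the fitting data get zero effects at
    prediction time.
    """

    spec: PriorSpec
    basis: TimeBasis
    alpha: float
    beta: np.ndarray
    u_s: dict = field(default_factory=dict)
    u_z: dict = field(default_factory=dict)
    b_s: dict = field(default_factory=dict)
    b_z: dict = field(default_factory=dict)
    sigma_eps: float = float("nan")
    variance_components: dict = field(default_factory=dict)
    state_zone: dict = field(default_factory=dict)
    converged: bool = True
    resid: Optional[np.ndarray] = None

    def predict(self, state: str, years, zone: Optional[str] = None
                ) -> np.ndarray:
        """Mean-function values alpha + T(beta + b_s + b_z) + u_s + u_z.

        A state not seen in fitting is an error unless its ``zone`` is
        supplied, in which case the state effects are zero and the zone
        effects apply (used when cross-validation holds out all of a
        state's observations).
        """
        if self.state_zone and state not in self.state_zone:
            if zone is None:
                raise KeyError(f"unknown state {state!r}")
        else:
            zone = self.state_zone.get(state)
        T = self.basis.design(years)
        coef = self.beta.copy()
        coef += self.b_s.get(state, 0.0)
        if zone is not None:
            coef = coef + self.b_z.get(zone, 0.0)
        level = self.alpha + self.u_s.get(state, 0.0)
        if zone is not None:
            level += self.u_z.get(zone, 0.0)
        return level + T @ coef

    def predict_rows(self, df: pd.DataFrame) -> np.ndarray:
        """Vectorized prediction for rows carrying state, zone and year."""
        zones = df["zone"] if "zone" in df.columns else [None] * len(df)
        out = np.empty(len(df))
        for i, (state, zone, year) in enumerate(
            zip(df["state"], zones, df["year"])
        ):
            out[i] = self.predict(state, [year], zone=zone)[0]
        return out


def _vc_formulas(spec_re: frozenset, cols: list[str]) -> dict:
    tb = " + ".join(cols)
    vc = {}
    if "u_z" in spec_re and "u_s" in spec_re:
        vc["u_s"] = "0 + C(state)"
    if "b_s" in spec_re:
        if "u_z" in spec_re:
            vc["b_s"] = " + ".join(f"0 + C(state):{c}" for c in cols)
        else:
            vc["b_s"] = f"0 + {tb}"
    if "b_z" in spec_re:
        vc["b_z"] = f"0 + {tb}"
    return vc


def fit_prior(
    data: pd.DataFrame,
    spec: PriorSpec,
    year_grid: Optional[Sequence[int]] = None,
) -> PriorFit:
    """Fit one specification to logit-scale estimates.

    ``data`` needs columns state, zone, year, y. The time basis is built from
    ``year_grid`` when given (so prediction spans the full estimation grid)
    and otherwise from the observed years. REML for mixed specifications,
    OLS for the empty random structure.
    """
    if data.empty:
        raise ValueError("no data to fit")
    data = data.reset_index(drop=True)
    basis = build_time_basis(
        year_grid if year_grid is not None else data["year"], spec.basis
    )
    cols = basis.column_names()
    df = data[["state", "zone", "year", "y"]].copy()
    T = basis.design(df["year"])
    for j, c in enumerate(cols):
        df[c] = T[:, j]

    spec_re = set(spec.re_structure)
    # degenerate hierarchies: a single observed zone cannot identify zone
    # terms; fix them at zero
    if {"u_z", "b_z"} & spec_re and df["zone"].nunique() < 2:
        warnings.warn(
            "single zone in data: zone random terms fixed at 0", UserWarning
        )
        spec_re -= {"u_z", "b_z"}
    if {"u_s", "b_s"} & spec_re and df["state"].nunique() < 2:
        warnings.warn(
            "single state in data: state random terms fixed at 0", UserWarning
        )
        spec_re -= {"u_s", "b_s"}

    fe_formula = "y ~ " + " + ".join(cols)
    state_zone = dict(zip(df["state"], df["zone"]))
    k = basis.k

    if not spec_re:
        res = sm.OLS.from_formula(fe_formula, data=df).fit()
        fe = res.params
        fit = PriorFit(
            spec=spec, basis=basis, alpha=float(fe["Intercept"]),
            beta=np.array([fe[c] for c in cols]),
            sigma_eps=float(np.sqrt(res.scale)),
            state_zone=state_zone, resid=np.asarray(res.resid),
        )
        return fit

    by_zone = "u_z" in spec_re
    groups = "zone" if by_zone else "state"
    vc = _vc_formulas(frozenset(spec_re), cols)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(
                fe_formula, groups=groups, re_formula="1",
                vc_formula=vc or None, data=df,
            )
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise PriorConvergenceError(spec, str(exc)) from exc
    fe = res.fe_params
    if not np.all(np.isfinite(fe.values)):
        raise PriorConvergenceError(spec, "non-finite fixed effects")

    fit = PriorFit(
        spec=spec, basis=basis, alpha=float(fe["Intercept"]),
        beta=np.array([fe[c] for c in cols]),
        sigma_eps=float(np.sqrt(res.scale)),
        state_zone=state_zone,
    )
    # variance components by term
    fit.variance_components = {
        "sigma2_eps": float(res.scale),
        f"sigma2_{'u_z' if by_zone else 'u_s'}": float(np.asarray(res.cov_re)[0, 0]),
    }
    for name, v in zip(model.exog_vc.names, np.asarray(res.vcomp)):
        fit.variance_components[f"sigma2_{name}"] = float(v)

    # realized random effects, parsed from the per-group series; a variance
    # component estimated at the zero boundary can make BLUP prediction
    # singular, in which case the effects are (numerically) zero
    states = sorted(df["state"].unique())
    zones = sorted(df["zone"].unique())
    try:
        re_all = res.random_effects
    except (ValueError, np.linalg.LinAlgError):
        re_all = None
    if re_all is None:
        for s in states:
            if "u_s" in spec_re:
                fit.u_s[s] = 0.0
            if "b_s" in spec_re:
                fit.b_s[s] = np.zeros(k)
        for z in zones:
            if "u_z" in spec_re:
                fit.u_z[z] = 0.0
            if "b_z" in spec_re:
                fit.b_z[z] = np.zeros(k)
    elif by_zone:
        for z in zones:
            ser = re_all[z]
            fit.u_z[z] = float(ser.iloc[0])
            if "b_z" in spec_re:
                fit.b_z[z] = np.array(
                    [float(ser.get(f"b_z[{c}]", 0.0)) for c in cols]
                )
        if "u_s" in spec_re:
            for s in states:
                z = state_zone[s]
                ser = re_all[z]
                fit.u_s[s] = float(ser.get(f"u_s[C(state)[{s}]]", 0.0))
                if "b_s" in spec_re:
                    fit.b_s[s] = np.array(
                        [float(ser.get(f"b_s[C(state)[{s}]:{c}]", 0.0))
                         for c in cols]
                    )
    else:
        for s in states:
            ser = re_all[s]
            fit.u_s[s] = float(ser.iloc[0])
            if "b_s" in spec_re:
                fit.b_s[s] = np.array(
                    [float(ser.get(f"b_s[{c}]", 0.0)) for c in cols]
                )
    fit.resid = df["y"].to_numpy() - fit.predict_rows(df)
    fit.converged = bool(getattr(res, "converged", True))
    return fit


def predict_prior(fit: PriorFit, state: str, years) -> np.ndarray:
    """Functional form of :meth:`PriorFit.predict`."""
    return fit.predict(state, years)


# ---------------------------------------------------------------------------
# cross-validated model selection

@dataclass
class CVResult:
    """Hold-out cross-validation outcome over candidate specifications."""

    table: pd.DataFrame                 # spec_id, mean_rmse, n_converged, selected
    rmse: pd.DataFrame                  # replicate x spec_id matrix
    selected: PriorSpec

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _rmse(resid: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(resid))))


def cv_select(
    data: pd.DataFrame,
    specs: Optional[Sequence[PriorSpec]] = None,
    holdout_frac: float = 0.20,
    reps: int = 100,
    seed: Optional[int] = None,
    year_grid: Optional[Sequence[int]] = None,
) -> CVResult:
    """Select the specification with the lowest mean hold-out RMSE.

    Each replicate holds out ``holdout_frac`` of the observations uniformly
    at random, fits every specification to the remainder, and scores
    logit-scale RMSE on the held-out set. Replicates where a specification
    fails to converge do not count toward its mean. Ties break toward fewer
    random terms, then the linear basis.
    """
    if specs is None:
        specs = enumerate_specs()
    data = data.reset_index(drop=True)
    n = len(data)
    n_test = max(1, int(round(holdout_frac * n)))
    if n_test >= n:
        raise ValueError("holdout leaves no training data")
    rng = np.random.default_rng(seed)

    rmse = np.full((reps, len(specs)), np.nan)
    for r in range(reps):
        test_idx = rng.choice(n, size=n_test, replace=False)
        test_mask = np.zeros(n, dtype=bool)
        test_mask[test_idx] = True
        train, test = data[~test_mask], data[test_mask]
        for j, spec in enumerate(specs):
            try:
                fit = fit_prior(train, spec, year_grid=year_grid)
            except PriorConvergenceError:
                continue
            pred = fit.predict_rows(test)
            rmse[r, j] = _rmse(test["y"].to_numpy() - pred)

    spec_ids = [s.id for s in specs]
    rmse_df = pd.DataFrame(rmse, columns=spec_ids)
    n_conv = rmse_df.notna().sum(axis=0)
    mean_rmse = rmse_df.mean(axis=0, skipna=True)
    if mean_rmse.isna().all():
        raise PriorConvergenceError(
            specs[0], "no specification converged in any replicate"
        )

    order = sorted(
        range(len(specs)),
        key=lambda j: (
            np.inf if np.isnan(mean_rmse.iloc[j]) else mean_rmse.iloc[j],
            specs[j].n_random_terms,
            0 if specs[j].basis == "linear" else 1,
            j,
        ),
    )
    best = order[0]
    table = pd.DataFrame({
        "spec_id": spec_ids,
        "mean_rmse": mean_rmse.values,
        "n_converged": n_conv.values,
        "selected": [j == best for j in range(len(specs))],
    })
    return CVResult(table=table, rmse=rmse_df, selected=specs[best])
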