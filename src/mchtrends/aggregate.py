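"""National aggregation, the composite coverage index, and benchmarking
arithmetic (ranges, gaps, declines).

National trends are population-weighted means of state values computed at
the draw level and on the proportion scale (weighted means of proportions
are the estimand; averaging logits would bias). The composite coverage index
is the equally weighted mean of 11 intervention coverages, with wasting
entering as its complement.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .gpr import PosteriorDraws
from .indicators import CompositeSpec
from .transforms import from_logit, to_logit

__all__ = [
    "normalized_weights", "national_aggregate", "composite_coverage",
    "range_gap", "paired_gap", "relative_decline",
]


def normalized_weights(
    pops: pd.DataFrame,
    states,
    years,
    weight_basis: str = "population",
) -> pd.DataFrame:
    """Per-year weights w_{s,t} = pop_{s,t} / sum_s pop_{s,t}.

    ``pops`` has columns state, year and a value column named by
    ``weight_basis`` ("population" or "live_births").
    """
    if weight_basis not in pops.columns:
        raise ValueError(f"population table lacks column {weight_basis!r}")
    sub = pops[pops["state"].isin(states) & pops["year"].isin(years)]
    wide = sub.pivot(index="year", columns="state", values=weight_basis)
    missing = set(states) - set(wide.columns)
    if missing or wide.isna().any().any() or len(wide) != len(set(years)):
        raise ValueError(
            f"population table incomplete on the grid (missing: {sorted(missing)})"
        )
    if (wide.values <= 0).any():
        raise ValueError("population values must be positive")
    return wide.div(wide.sum(axis=1), axis=0).loc[sorted(set(years)), list(states)]


def national_aggregate(
    state_draws: Mapping[str, PosteriorDraws],
    pops: pd.DataFrame,
    weight_basis: str = "population",
) -> PosteriorDraws:
    """Population-weighted national draws from state draws.

    Aggregation happens per (year, draw index) on the proportion scale; the
    result is re-logit-transformed for storage, like any other draw matrix.
    """
    if not state_draws:
        raise ValueError("no state draws")
    states = sorted(state_draws)
    ref = state_draws[states[0]]
    years = np.asarray(ref.years)
    n_draws = ref.n_draws
    for s in states:
        d = state_draws[s]
        if not np.array_equal(np.asarray(d.years), years) or d.n_draws != n_draws:
            raise ValueError(f"state {s} has a mismatched grid or draw count")
    W = normalized_weights(pops, states, years, weight_basis).to_numpy()
    # stack: state x year x draw on the proportion scale, then weighted sum
    # over states with per-year weights
    P = np.stack([from_logit(state_draws[s].draws) for s in states])
    nat_p = np.einsum("sy,syd->yd", W.T, P)
    nat_p = np.clip(nat_p, 1e-12, 1 - 1e-12)
    return PosteriorDraws(state="national", years=years, draws=to_logit(nat_p))


def composite_coverage(
    indicator_values: Mapping[str, object],
    spec: Optional[CompositeSpec] = None,
):
    """Equally weighted composite of the 11 member interventions.

    Values may be scalars or aligned draw arrays; complement-transformed
    members (wasting) enter as 1 - value. Applied per draw when given draw
    matrices, so the composite carries uncertainty.
    """
    if spec is None:
        spec = CompositeSpec.default()
    missing = [m for m in spec.members if m not in indicator_values]
    if missing:
        raise KeyError(f"composite missing members: {missing}")
    parts = []
    for m in spec.members:
        v = np.asarray(indicator_values[m], dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"member {m!r} outside [0, 1]")
        if spec.transforms.get(m, "identity") == "complement":
            v = 1.0 - v
        parts.append(v)
    out = np.mean(np.broadcast_arrays(*parts), axis=0)
    return float(out) if out.ndim == 0 else out


def range_gap(values: Mapping[str, float]) -> tuple[str, str, float]:
    """Extremal units and max - min on the reported scale.

    Returns (max unit, min unit, difference).
    """
    if not values:
        raise ValueError("empty map")
    hi = max(values, key=lambda k: values[k])
    lo = min(values, key=lambda k: values[k])
    return hi, lo, values[hi] - values[lo]


def paired_gap(value_a: float, value_b: float) -> float:
    """Signed difference a - b (percentage points when inputs are percents)."""
    return value_a - value_b


def relative_decline(v_start: float, v_end: float) -> float:
    """Percent decline 100 * (v_start - v_end) / v_start."""
    if v_start <= 0:
        raise ValueError("v_start must be positive")
    return 100.0 * (v_start - v_end) / v_start
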