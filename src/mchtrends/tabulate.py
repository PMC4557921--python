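"""Survey tabulation and harmonization.

Turns microdata-like records (one row per respondent or child) into
comparable state-year estimates, applying the rules that make heterogeneous
survey instruments commensurable:

* design-weighted tabulation of proportions with a ratio-estimator variance;
* attribution of retrospective birth-linked indicators to the child's birth
  year, with recall windows per source family (6 years for full birth-history
  instruments, 2 years for most-recent-birth instruments);
* a card-only immunization crosswalk (scaling card-only coverage by the
  average card-to-total ratio observed in surveys that record both);
* near-zero pseudo-observations for years before a malaria intervention was
  formally adopted;
* configuration-driven exclusion flagging.

Tabulated estimates live in a pandas DataFrame with columns
``indicator, state, zone, year, p, var_p, source_id, flags``; ``flags`` is a
``|``-separated string drawn from {card_only_adjusted, imputed_pre_policy,
excluded}.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .indicators import IndicatorDefinition
from .transforms import CLAMP_HI, PSEUDO_P, PSEUDO_VAR, clamp

logger = logging.getLogger(__name__)

ESTIMATE_COLUMNS = [
    "indicator", "state", "zone", "year", "p", "var_p", "source_id", "flags",
]

FLAG_CARD = "card_only_adjusted"
FLAG_IMPUTED = "imputed_pre_policy"
FLAG_EXCLUDED = "excluded"

#: recall window (years before the survey) per source family
_WINDOWS = {"full-history": 6, "recent-birth-only": 2}


def add_flag(flags: pd.Series, flag: str, where=None) -> pd.Series:
    """Append ``flag`` to the ``|``-separated flag strings (idempotent)."""
    flags = flags.fillna("").astype(str)
    mask = pd.Series(True, index=flags.index) if where is None else where

    def _add(s: str) -> str:
        parts = [x for x in s.split("|") if x]
        if flag not in parts:
            parts.append(flag)
        return "|".join(parts)

    out = flags.copy()
    out[mask] = flags[mask].map(_add)
    return out


def has_flag(flags: pd.Series, flag: str) -> pd.Series:
    return flags.fillna("").astype(str).str.split("|").map(lambda xs: flag in xs)


def active_estimates(estimates: pd.DataFrame) -> pd.DataFrame:
    """Estimates eligible for model fitting (excluded rows removed)."""
    return estimates[~has_flag(estimates["flags"], FLAG_EXCLUDED)]


def weighted_tabulate(
    records: pd.DataFrame,
    indicator: IndicatorDefinition,
    source_id: Optional[str] = None,
) -> pd.DataFrame:
    """Design-weighted state-year tabulation of a 0/1 outcome.

    For each (state, event_year) group: p = sum(w*o)/sum(w) and the
    ratio-estimator variance var_p = sum(w^2 (o - p)^2) / (sum w)^2, which
    reduces to p(1-p)/n under equal weights. Degenerate all-0/all-1 cells
    fall back to a binomial variance at the clamped proportion with the Kish
    effective sample size, so var_p stays positive.

    Proportions are clamped into [0.001, 0.999] before storage.
    """
    required = {"survey_id", "state", "zone", "weight", "outcome", "event_year"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if records["survey_id"].nunique() > 1:
        raise ValueError("weighted_tabulate expects records from one survey")
    if len(records) and not (records["weight"] > 0).any():
        raise ValueError("all sampling weights are zero or negative")
    if source_id is None:
        source_id = str(records["survey_id"].iloc[0]) if len(records) else ""

    rows = []
    for (state, zone, year), g in records.groupby(
        ["state", "zone", "event_year"], sort=True
    ):
        w = g["weight"].to_numpy(float)
        o = g["outcome"].to_numpy(float)
        ok = w > 0
        w, o = w[ok], o[ok]
        if w.size == 0:
            continue
        sw = w.sum()
        p = float(np.dot(w, o) / sw)
        var_p = float(np.dot(w**2, (o - p) ** 2) / sw**2)
        p_c = float(clamp(p))
        if var_p <= 0:
            n_eff = sw**2 / np.dot(w, w)
            var_p = p_c * (1.0 - p_c) / n_eff
        rows.append(
            dict(indicator=indicator.id, state=state, zone=zone,
                 year=int(year), p=p_c, var_p=var_p,
                 source_id=source_id, flags="")
        )
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def attribute_event_year(
    records: pd.DataFrame, indicator: IndicatorDefinition
) -> tuple[pd.DataFrame, int]:
    """Assign each record's event year per the indicator's attribution rule.

    Birth-year indicators (ANC1/ANC4/SBA/IFD) take the child's birth year;
    records with a missing birth year are dropped and counted. All other
    indicators take the survey year.

    Returns the records with an ``event_year`` column and the drop count.
    """
    out = records.copy()
    if indicator.attribution == "birth-year":
        if "birth_year" not in out.columns:
            raise ValueError("birth-year attribution requires a birth_year column")
        missing = out["birth_year"].isna()
        n_dropped = int(missing.sum())
        if n_dropped:
            logger.info(
                "%s: dropped %d records with missing birth year",
                indicator.id, n_dropped,
            )
        out = out[~missing].copy()
        out["event_year"] = out["birth_year"].astype(int)
    else:
        n_dropped = 0
        out["event_year"] = out["survey_year"].astype(int)
    return out, n_dropped


def window_filter(records: pd.DataFrame, source_family: str) -> pd.DataFrame:
    """Keep births within the source family's recall window.

    Full-history instruments record every recent birth and support a 6-year
    window; most-recent-birth instruments are population-representative only
    within 2 years of the survey date.
    """
    if source_family not in _WINDOWS:
        raise ValueError(f"unknown source family {source_family!r}")
    if records.empty:
        return records.copy()
    lag = records["survey_year"] - records["event_year"]
    return records[(lag >= 0) & (lag <= _WINDOWS[source_family])].copy()


def estimate_crosswalk_ratio(
    paired_estimates: Iterable[tuple[float, float]]
) -> float:
    """Average total/card-only coverage ratio from paired-evidence surveys."""
    pairs = list(paired_estimates)
    if not pairs:
        raise ValueError("need at least one (card_only, total) pair")
    ratios = []
    for card_only, total in pairs:
        if not (0 < card_only < 1) or not (0 < total < 1):
            raise ValueError(
                f"pair ({card_only}, {total}) outside (0, 1)"
            )
        ratios.append(total / card_only)
    return float(np.mean(ratios))


def card_crosswalk(estimates: pd.DataFrame, ratio: float) -> pd.DataFrame:
    """Scale card-only immunization estimates up to total-coverage scale.

    p' = min(ratio * p, 0.999); var_p scales by ratio^2; rows are flagged
    ``card_only_adjusted``.
    """
    if ratio <= 0:
        raise ValueError("crosswalk ratio must be positive")
    out = estimates.copy()
    out["p"] = np.minimum(out["p"] * ratio, CLAMP_HI)
    out["var_p"] = out["var_p"] * ratio**2
    out["flags"] = add_flag(out["flags"], FLAG_CARD)
    return out


def impute_pre_policy(
    indicator: IndicatorDefinition,
    states: Sequence[str],
    year_grid: Sequence[int],
    state_zone: dict,
    policy_years: Optional[dict] = None,
) -> pd.DataFrame:
    """Near-zero pseudo-observations for years before policy adoption.

    Emits p = 0.0001 (0.01% coverage) with a tiny fixed variance for every
    grid year strictly before the indicator's policy start year, flagged
    ``imputed_pre_policy``. ``policy_years`` optionally overrides the start
    year per state (used for phased interventions such as IRS).
    """
    if indicator.policy_start_year is None and not policy_years:
        raise ValueError(
            f"indicator {indicator.id!r} has no policy start year"
        )
    rows = []
    for state in states:
        start = indicator.policy_start_year
        if policy_years and state in policy_years:
            start = policy_years[state]
        if start is None:
            continue
        for year in year_grid:
            if year < start:
                rows.append(
                    dict(indicator=indicator.id, state=state,
                         zone=state_zone[state], year=int(year),
                         p=PSEUDO_P, var_p=PSEUDO_VAR,
                         source_id="pre-policy-imputation",
                         flags=FLAG_IMPUTED)
                )
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def flag_exclusions(
    estimates: pd.DataFrame,
    exclusion_list: Iterable[tuple[str, str, str]],
) -> pd.DataFrame:
    """Flag estimates named in an explicit (indicator, state, source) list.

    Exclusions are judgement-based (documented sampling problems,
    implausibility against nearby points) and therefore configuration-driven,
    never auto-detected. The resulting exclusion fraction is logged.
    """
    out = estimates.copy()
    excl = set(exclusion_list)
    if excl:
        key = list(zip(out["indicator"], out["state"], out["source_id"]))
        mask = pd.Series([k in excl for k in key], index=out.index)
        out["flags"] = add_flag(out["flags"], FLAG_EXCLUDED, where=mask)
        frac = mask.mean() if len(out) else 0.0
        logger.info("flagged %d/%d estimates as excluded (%.1f%%)",
                    int(mask.sum()), len(out), 100 * frac)
    return out
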