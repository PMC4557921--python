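"""Tabulation, harmonization and logit-transform behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mchtrends.indicators import (DEFAULT_REGISTRY, CompositeSpec,
                                  get_indicator, registry_by_id)
from mchtrends.geography import STATE_ZONE, ZONES
from mchtrends.tabulate import (FLAG_EXCLUDED, FLAG_IMPUTED, active_estimates,
                                attribute_event_year, card_crosswalk,
                                estimate_crosswalk_ratio, flag_exclusions,
                                has_flag, impute_pre_policy, weighted_tabulate,
                                window_filter)
from mchtrends.transforms import from_logit, to_logit


def _records(outcomes, weights=None, state="Lagos", year=2008):
    n = len(outcomes)
    return pd.DataFrame({
        "survey_id": "svy", "state": state, "zone": STATE_ZONE.get(state, "Z"),
        "weight": weights if weights is not None else np.ones(n),
        "outcome": outcomes, "event_year": year,
    })


class TestRegistry:
    def test_registry_invariants(self):
        reg = registry_by_id()
        assert len(reg) == 20
        composite = [d for d in DEFAULT_REGISTRY if d.composite_member]
        assert len(composite) == 11
        # policy years only on the malaria interventions with documented
        # adoption dates
        with_policy = {d.id for d in DEFAULT_REGISTRY
                       if d.policy_start_year is not None}
        assert with_policy == {"itn_own", "itn_irs", "iptp2", "act"}
        # birth-year attribution for the retrospective birth-linked set
        birth_year = {d.id for d in DEFAULT_REGISTRY
                      if d.attribution == "birth-year"}
        assert birth_year == {"anc1", "anc4", "sba", "ifd"}

    def test_wasting_enters_composite_as_complement(self):
        spec = CompositeSpec.default()
        assert spec.transforms["wasting"] == "complement"
        assert all(spec.transforms[m] == "identity"
                   for m in spec.members if m != "wasting")

    def test_geography(self):
        assert len(STATE_ZONE) == 37
        assert set(STATE_ZONE.values()) == set(ZONES)


class TestWeightedTabulate:
    @pytest.mark.parametrize(
        "outcomes,weights,expected_p",
        [
            ([1, 0, 1, 1], None, 0.75),            # unweighted mean
            ([1, 0], [3.0, 1.0], 0.75),            # weighted hand evaluation
        ],
    )
    def test_point_estimates(self, outcomes, weights, expected_p):
        est = weighted_tabulate(_records(outcomes, weights),
                                get_indicator("measles"))
        assert len(est) == 1
        assert est["p"].iloc[0] == pytest.approx(expected_p)

    def test_variance_matches_binomial_oracle(self, rng):
        n = 200
        outcomes = rng.binomial(1, 0.4, n)
        est = weighted_tabulate(_records(outcomes), get_indicator("measles"))
        p = est["p"].iloc[0]
        assert est["var_p"].iloc[0] == pytest.approx(p * (1 - p) / n, rel=0.10)

    def test_mean_variance_calibration(self, rng):
        """Mean tabulated var_p across many surveys tracks p(1-p)/n."""
        p_true, n = 0.3, 500
        vars_ = []
        for _ in range(300):
            outcomes = rng.binomial(1, p_true, n)
            est = weighted_tabulate(_records(outcomes),
                                    get_indicator("measles"))
            vars_.append(est["var_p"].iloc[0])
        assert np.mean(vars_) == pytest.approx(p_true * (1 - p_true) / n,
                                               rel=0.05)

    def test_weight_rescaling_invariance(self, rng):
        outcomes = rng.binomial(1, 0.6, 50)
        weights = rng.uniform(0.5, 3.0, 50)
        a = weighted_tabulate(_records(outcomes, weights),
                              get_indicator("measles"))
        b = weighted_tabulate(_records(outcomes, weights * 7.3),
                              get_indicator("measles"))
        assert a["p"].iloc[0] == pytest.approx(b["p"].iloc[0], abs=1e-12)
        assert a["var_p"].iloc[0] == pytest.approx(b["var_p"].iloc[0],
                                                   rel=1e-10)

    def test_degenerate_cells(self):
        # all-one outcomes clamp to 0.999 and keep a positive variance
        est = weighted_tabulate(_records([1, 1, 1, 1]),
                                get_indicator("measles"))
        assert est["p"].iloc[0] == 0.999
        assert est["var_p"].iloc[0] > 0
        with pytest.raises(ValueError, match="weights"):
            weighted_tabulate(_records([1, 0], [0.0, 0.0]),
                              get_indicator("measles"))
        empty = weighted_tabulate(_records([]), get_indicator("measles"))
        assert empty.empty


class TestAttributionAndWindows:
    def test_birth_year_attribution(self):
        rec = pd.DataFrame({
            "survey_id": "dhs", "state": "Kano", "zone": "North West",
            "weight": 1.0, "outcome": [1, 0, 1],
            "survey_year": 2008, "birth_year": [2005.0, 2007.0, np.nan],
        })
        out, dropped = attribute_event_year(rec, get_indicator("sba"))
        assert dropped == 1
        assert out["event_year"].tolist() == [2005, 2007]

    def test_survey_year_attribution(self):
        rec = pd.DataFrame({
            "survey_id": "mis", "state": "Kano", "zone": "North West",
            "weight": 1.0, "outcome": [1], "survey_year": 2010,
        })
        out, dropped = attribute_event_year(rec, get_indicator("itn_own"))
        assert dropped == 0
        assert out["event_year"].tolist() == [2010]

    @pytest.mark.parametrize(
        "family,survey_year,kept,dropped",
        [
            ("full-history", 2013, 2007, 2006),
            ("recent-birth-only", 2011, 2009, 2008),
        ],
    )
    def test_recall_windows(self, family, survey_year, kept, dropped):
        rec = pd.DataFrame({
            "survey_id": "s", "state": "Oyo", "zone": "South West",
            "weight": 1.0, "outcome": 1, "survey_year": survey_year,
            "event_year": [kept, dropped],
        })
        out = window_filter(rec, family)
        assert out["event_year"].tolist() == [kept]

    def test_window_filter_empty(self):
        rec = pd.DataFrame(columns=["survey_year", "event_year"])
        assert window_filter(rec, "full-history").empty


class TestCrosswalk:
    def test_ratio_from_pairs(self):
        assert estimate_crosswalk_ratio([(0.5, 0.6), (0.4, 0.48)]) == \
            pytest.approx(1.2)
        assert estimate_crosswalk_ratio([(0.5, 0.5)]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            estimate_crosswalk_ratio([])
        with pytest.raises(ValueError):
            estimate_crosswalk_ratio([(0.0, 0.5)])

    def test_card_adjustment(self):
        est = pd.DataFrame({
            "indicator": "measles", "state": "Oyo", "zone": "South West",
            "year": 2007, "p": [0.40, 0.90], "var_p": 0.001,
            "source_id": "mics", "flags": "",
        })
        out = card_crosswalk(est, 1.2)
        assert out["p"].tolist() == pytest.approx([0.48, 0.999])
        assert out["var_p"].iloc[0] == pytest.approx(0.001 * 1.44)
        assert has_flag(out["flags"], "card_only_adjusted").all()
        # identity ratio changes nothing but the flag
        out1 = card_crosswalk(est, 1.0)
        assert out1["p"].tolist() == pytest.approx([0.40, 0.90])
        with pytest.raises(ValueError):
            card_crosswalk(est, 0.0)


class TestPrePolicyImputation:
    def test_pseudo_observations(self):
        grid = range(1998, 2014)
        states = ["Kano", "Oyo"]
        out = impute_pre_policy(get_indicator("itn_own"), states, grid,
                                STATE_ZONE)
        # ITN ownership: 0.01% before 2000
        assert set(out["year"]) == {1998, 1999}
        assert (out["p"] == 0.0001).all()
        assert has_flag(out["flags"], FLAG_IMPUTED).all()
        out2 = impute_pre_policy(get_indicator("iptp2"), states, grid,
                                 STATE_ZONE)
        assert out2["year"].max() == 2000       # policy year 2001 excluded
        assert 2005 not in set(out2["year"])
        with pytest.raises(ValueError):
            impute_pre_policy(get_indicator("measles"), states, grid,
                              STATE_ZONE)

    def test_per_state_policy_years(self):
        out = impute_pre_policy(
            get_indicator("itn_irs"), ["Kano", "Oyo"], range(1999, 2006),
            STATE_ZONE, policy_years={"Kano": 2004},
        )
        kano = out[out["state"] == "Kano"]
        oyo = out[out["state"] == "Oyo"]
        assert kano["year"].max() == 2003
        assert oyo["year"].max() == 1999


class TestExclusions:
    def test_flagging_and_filtering(self):
        est = pd.DataFrame({
            "indicator": "measles", "state": ["Kano", "Oyo"],
            "zone": "z", "year": 2007, "p": 0.4, "var_p": 0.001,
            "source_id": ["svyA", "svyB"], "flags": "",
        })
        out = flag_exclusions(est, [("measles", "Kano", "svyA")])
        assert has_flag(out["flags"], FLAG_EXCLUDED).tolist() == [True, False]
        assert len(active_estimates(out)) == 1
        unchanged = flag_exclusions(est, [])
        assert not has_flag(unchanged["flags"], FLAG_EXCLUDED).any()


class TestLogitTransforms:
    def test_examples(self):
        assert to_logit(0.5) == pytest.approx(0.0)
        _, var_y = to_logit(0.5, 0.01)
        assert var_y == pytest.approx(0.16)
        y = to_logit(0.73)
        assert y == pytest.approx(0.9946, abs=1e-4)
        assert from_logit(y) == pytest.approx(0.73)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            to_logit(0.0)
        with pytest.raises(ValueError):
            to_logit(1.0)

    @given(p=st.floats(0.001, 0.999), var_p=st.floats(1e-8, 0.25))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_roundtrip(self, p, var_p):
        y, var_y = to_logit(p, var_p)
        p2, var_p2 = from_logit(y, var_y)
        assert p2 == pytest.approx(p, rel=1e-10)
        assert var_p2 == pytest.approx(var_p, rel=1e-10)
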