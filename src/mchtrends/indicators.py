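"""Indicator registry for the maternal and child health (MCH) benchmarking
pipeline.

Each indicator is a survey-measurable proportion (or, for under-5 mortality, a
probability of death) tracked per state and year. The registry records, per
indicator:

* the denominator population the proportion refers to;
* whether survey responses are attributed to the survey year or to the birth
  year of the index child (antenatal care, skilled birth attendance and
  in-facility delivery are retrospective over recent births, so their
  estimates belong to the birth year);
* an optional policy start year for malaria interventions — before formal
  adoption, coverage is treated as known-near-zero (0.01%) rather than
  unobserved;
* membership in the 11-component composite coverage index, and the transform
  applied on entry (wasting prevalence enters as its complement, "not
  wasted").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

DENOMINATORS = frozenset(
    {"households", "children-u5", "children-12-59m", "women-15-49", "births"}
)
ATTRIBUTIONS = frozenset({"survey-year", "birth-year"})
TRANSFORMS = frozenset({"identity", "complement"})


@dataclass(frozen=True)
class IndicatorDefinition:
    """Definition of one MCH indicator."""

    id: str
    label: str
    denominator: str
    attribution: str = "survey-year"
    policy_start_year: Optional[int] = None
    composite_member: bool = False
    composite_transform: str = "identity"

    def __post_init__(self) -> None:
        if self.denominator not in DENOMINATORS:
            raise ValueError(f"unknown denominator {self.denominator!r}")
        if self.attribution not in ATTRIBUTIONS:
            raise ValueError(f"unknown attribution {self.attribution!r}")
        if self.composite_transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.composite_transform!r}")


def _mk(*args, **kw) -> IndicatorDefinition:
    return IndicatorDefinition(*args, **kw)


#: The 20 tracked indicators. Policy start years apply only to malaria
#: interventions with documented adoption dates (IPTp2 in national guidelines
#: from 2001 accounting for possible earlier use, ACTs as first-line treatment
#: from 2004, ITN ownership from 2000, IRS phased from 2000).
DEFAULT_REGISTRY: tuple[IndicatorDefinition, ...] = (
    # health outcomes
    _mk("u5m", "Under-5 mortality (5q0)", "births"),
    _mk("underweight", "Children under 5 underweight", "children-u5"),
    _mk("wasting", "Prevalence of wasting among children under 5",
        "children-u5", composite_member=True, composite_transform="complement"),
    _mk("stunting", "Prevalence of stunting among children under 5",
        "children-u5"),
    # malaria interventions
    _mk("itn_own", "Household ownership of ITNs", "households",
        policy_start_year=2000),
    _mk("itn_use", "ITN use by children under 5", "children-u5"),
    _mk("itn_irs", "Household ITN ownership or receipt of IRS", "households",
        policy_start_year=2000, composite_member=True),
    _mk("iptp2", "IPTp2 during pregnancy", "women-15-49",
        policy_start_year=2001, composite_member=True),
    _mk("act", "Febrile children under 5 receiving ACTs", "children-u5",
        policy_start_year=2004, composite_member=True),
    # immunizations
    _mk("bcg", "BCG immunization", "children-u5", composite_member=True),
    _mk("measles", "Measles immunization", "children-12-59m",
        composite_member=True),
    _mk("dpt3", "DPT3 immunization", "children-12-59m", composite_member=True),
    _mk("opv3", "OPV3 immunization", "children-12-59m", composite_member=True),
    # other key MCH interventions
    _mk("anc1", "Antenatal care, one or more visits", "women-15-49",
        attribution="birth-year"),
    _mk("anc4", "Antenatal care, four or more visits", "women-15-49",
        attribution="birth-year", composite_member=True),
    _mk("sba", "Skilled birth attendance", "women-15-49",
        attribution="birth-year", composite_member=True),
    _mk("ifd", "In-facility delivery", "women-15-49",
        attribution="birth-year"),
    _mk("ebf", "Exclusive breastfeeding", "children-u5",
        composite_member=True),
    _mk("contraception", "Modern contraceptive use", "women-15-49"),
    _mk("tt2", "Tetanus toxoid, two or more doses in pregnancy",
        "women-15-49"),
)


def registry_by_id(
    registry: tuple[IndicatorDefinition, ...] = DEFAULT_REGISTRY,
) -> dict[str, IndicatorDefinition]:
    out = {d.id: d for d in registry}
    if len(out) != len(registry):
        raise ValueError("duplicate indicator ids in registry")
    return out


def get_indicator(indicator_id: str) -> IndicatorDefinition:
    return registry_by_id()[indicator_id]


@dataclass(frozen=True)
class CompositeSpec:
    """The equally weighted composite coverage index.

    Exactly 11 member indicators; each enters either as-is or as its
    complement (used for wasting, which is an adverse outcome).
    """

    members: tuple[str, ...] = ()
    transforms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) != 11:
            raise ValueError(
                f"composite requires exactly 11 members, got {len(self.members)}"
            )
        for t in self.transforms.values():
            if t not in TRANSFORMS:
                raise ValueError(f"unknown transform {t!r}")

    @classmethod
    def default(cls) -> "CompositeSpec":
        members = tuple(d.id for d in DEFAULT_REGISTRY if d.composite_member)
        transforms = {
            d.id: d.composite_transform
            for d in DEFAULT_REGISTRY
            if d.composite_member
        }
        return cls(members=members, transforms=transforms)
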