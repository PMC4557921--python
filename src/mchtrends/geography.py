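"""Administrative geography: Nigeria's 36 states plus the Federal Capital
Territory, grouped into the six geopolitical zones used as the upper level of
the random-effects hierarchy."""

from __future__ import annotations

ZONES = (
    "North Central",
    "North East",
    "North West",
    "South East",
    "South South",
    "South West",
)

#: state -> geopolitical zone (37 units: 36 states + FCT Abuja)
STATE_ZONE: dict[str, str] = {
    # North Central
    "Benue": "North Central",
    "FCT Abuja": "North Central",
    "Kogi": "North Central",
    "Kwara": "North Central",
    "Nasarawa": "North Central",
    "Niger": "North Central",
    "Plateau": "North Central",
    # North East
    "Adamawa": "North East",
    "Bauchi": "North East",
    "Borno": "North East",
    "Gombe": "North East",
    "Taraba": "North East",
    "Yobe": "North East",
    # North West
    "Jigawa": "North West",
    "Kaduna": "North West",
    "Kano": "North West",
    "Katsina": "North West",
    "Kebbi": "North West",
    "Sokoto": "North West",
    "Zamfara": "North West",
    # South East
    "Abia": "South East",
    "Anambra": "South East",
    "Ebonyi": "South East",
    "Enugu": "South East",
    "Imo": "South East",
    # South South
    "Akwa Ibom": "South South",
    "Bayelsa": "South South",
    "Cross River": "South South",
    "Delta": "South South",
    "Edo": "South South",
    "Rivers": "South South",
    # South West
    "Ekiti": "South West",
    "Lagos": "South West",
    "Ogun": "South West",
    "Ondo": "South West",
    "Osun": "South West",
    "Oyo": "South West",
}

STATES = tuple(sorted(STATE_ZONE))


def zone_of(state: str) -> str:
    """Geopolitical zone of a state; raises KeyError for unknown states."""
    return STATE_ZONE[state]
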