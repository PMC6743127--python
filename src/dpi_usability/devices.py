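"""The seven dry-powder inhalers under comparison and the trial's group design.

The canonical device order is alphabetical; it is used wherever a
deterministic ordering is required (design matrices, rank tie-breaks,
CSV column order).
"""

from __future__ import annotations

DEVICES: tuple[str, ...] = (
    "Breezhaler",
    "Diskus",
    "Ellipta",
    "Genuair",
    "Nexthaler",
    "Spiromax",
    "Turbohaler",
)

DEVICE_INDEX: dict[str, int] = {d: i for i, d in enumerate(DEVICES)}

#: Breezhaler is the only device tested in all three groups, so anchoring the
#: contrast parameterization on it keeps every stratum's network connected
#: through the reference.
REFERENCE_DEVICE = "Breezhaler"

STRATA: tuple[str, str] = ("experienced", "naive")

#: Which devices each randomized group tested (incomplete-block design;
#: at most four devices per respondent).
GROUP_DEVICES: dict[int, frozenset[str]] = {
    1: frozenset({"Breezhaler", "Spiromax", "Nexthaler", "Ellipta"}),
    2: frozenset({"Breezhaler", "Spiromax", "Diskus", "Turbohaler"}),
    3: frozenset({"Breezhaler", "Genuair"}),
}

_CANONICAL = {d.lower(): d for d in DEVICES}
_STRATUM_ALIASES = {
    "experienced": "experienced",
    "instructed": "experienced",
    "naive": "naive",
    "naïve": "naive",
}


def canonical_device(name: str) -> str:
    """Normalize a device name (trim whitespace, fix case) to its canonical form.

    Raises ``ValueError`` for a name outside the closed set of seven devices.
    """
    key = name.strip().lower()
    if key not in _CANONICAL:
        raise ValueError(f"unknown device name: {name!r}")
    return _CANONICAL[key]


def canonical_stratum(name: str) -> str:
    key = name.strip().lower()
    if key not in _STRATUM_ALIASES:
        raise ValueError(f"unknown stratum: {name!r} (expected experienced|naive)")
    return _STRATUM_ALIASES[key]


def sort_devices(devices) -> list[str]:
    """Return devices in canonical (alphabetical) order."""
    return sorted(devices, key=DEVICE_INDEX.__getitem__)
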