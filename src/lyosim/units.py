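"""Unit conversions between the practical (cal, Torr, cm) and SI unit systems.

Freeze-drying literature mixes practical units (cal/s K cm^2 for vial heat
transfer coefficients, Torr for pressures) with SI (W/m^2 K, Pa).  All internal
computation in this package uses the practical system; these helpers convert at
the boundaries.  The calorie is the thermochemical calorie (4.184 J).
"""

from __future__ import annotations

from .errors import UnitError

CAL_TO_J = 4.184
TORR_TO_PA = 101325.0 / 760.0  # 133.322 Pa

# Multiplicative unit families: unit -> scale relative to the family base unit.
_FAMILIES: dict[str, dict[str, float]] = {
    "pressure": {"Torr": 1.0, "mTorr": 1e-3, "Pa": 1.0 / TORR_TO_PA},
    "heat_transfer_coefficient": {
        "cal/(s K cm2)": 1.0,
        "W/(m2 K)": 1.0 / (CAL_TO_J * 1e4),
    },
    "pressure_slope": {
        # Kp of the vial heat-transfer curve.
        "cal/(s K cm2 Torr)": 1.0,
        "W/(m2 K Pa)": TORR_TO_PA / (CAL_TO_J * 1e4),
    },
    "inverse_pressure": {"1/Torr": 1.0, "1/Pa": TORR_TO_PA},
    "mass_rate": {"kg/h": 1.0, "g/h": 1e-3},
    "flux": {"g/(cm2 h)": 1.0, "kg/(m2 h)": 0.1},
    "length": {"cm": 1.0, "mm": 0.1, "m": 100.0},
    "time": {"h": 1.0, "min": 1.0 / 60.0, "s": 1.0 / 3600.0},
}

_TEMPERATURE = ("C", "K")


def _family_of(unit: str) -> str | None:
    for name, members in _FAMILIES.items():
        if unit in members:
            return name
    return None


def supported_units() -> dict[str, tuple[str, ...]]:
    """Mapping of unit family -> supported unit symbols."""
    table = {name: tuple(members) for name, members in _FAMILIES.items()}
    table["temperature"] = _TEMPERATURE
    return table


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two units of the same physical family.

    Raises :class:`UnitError` for unsupported pairs, listing what is supported.
    """
    if from_unit == to_unit:
        return value
    if from_unit in _TEMPERATURE and to_unit in _TEMPERATURE:
        return value + 273.15 if (from_unit, to_unit) == ("C", "K") else value - 273.15
    fam_from = _family_of(from_unit)
    fam_to = _family_of(to_unit)
    if fam_from is None or fam_from != fam_to:
        raise UnitError(
            f"unsupported unit pair {from_unit!r} -> {to_unit!r}; "
            f"supported families: {supported_units()}"
        )
    members = _FAMILIES[fam_from]
    return value * members[from_unit] / members[to_unit]
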