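"""Unit handling for exposure media.

All internal arithmetic runs in canonical units: mg/L for water, mg/kg for
soil and food (fresh weight), mg/m3 for air, L/day / kg/day / m3/day for the
matching intake rates, mg/day for soil ingestion. Every conversion funnels
through one table so a bad unit fails loudly instead of silently scaling a
dose by a thousand.
"""

from __future__ import annotations


class UnitError(ValueError):
    """Raised for unknown units or dimensionally incompatible pairs."""


#: multiplicative factor to the canonical unit of the same dimension
_TO_CANONICAL: dict[str, tuple[str, float]] = {
    # concentrations
    "mg/L": ("mg/L", 1.0),
    "ug/L": ("mg/L", 1e-3),
    "ng/L": ("mg/L", 1e-6),
    "mg/kg": ("mg/kg", 1.0),
    "ug/kg": ("mg/kg", 1e-3),
    "g/kg": ("mg/kg", 1e3),
    "mg/m3": ("mg/m3", 1.0),
    "ug/m3": ("mg/m3", 1e-3),
    "ng/m3": ("mg/m3", 1e-6),
    # intake rates
    "L/day": ("L/day", 1.0),
    "mL/day": ("L/day", 1e-3),
    "kg/day": ("kg/day", 1.0),
    "g/day": ("kg/day", 1e-3),
    "mg/day": ("mg/day", 1.0),
    "m3/day": ("m3/day", 1.0),
}

#: (concentration unit, intake-rate unit) pairs whose product is mg/day
COMPATIBLE_PAIRS: frozenset[tuple[str, str]] = frozenset(
    {("mg/L", "L/day"), ("mg/kg", "kg/day"), ("mg/m3", "m3/day")}
)


def to_canonical(value: float, unit: str) -> tuple[float, str]:
    """Convert *value* in *unit* to its canonical unit.

    Returns ``(converted_value, canonical_unit)``.
    """
    try:
        canonical, factor = _TO_CANONICAL[unit]
    except KeyError:
        raise UnitError(
            f"unknown unit {unit!r}; known: {sorted(_TO_CANONICAL)}"
        ) from None
    return value * factor, canonical


def canonical_unit(unit: str) -> str:
    return to_canonical(0.0, unit)[1]


def check_intake_compatible(c_unit: str, ir_unit: str) -> None:
    """Require that concentration x intake-rate yields mg/day."""
    pair = (canonical_unit(c_unit), canonical_unit(ir_unit))
    if pair not in COMPATIBLE_PAIRS:
        raise UnitError(
            f"concentration unit {c_unit!r} is not compatible with intake "
            f"rate unit {ir_unit!r}; allowed pairs: {sorted(COMPATIBLE_PAIRS)}"
        )
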