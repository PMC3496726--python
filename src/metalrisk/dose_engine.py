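"""Average-daily-intake (ADI) equations.

The chronic non-carcinogenic dose via ingestion or inhalation is

    ADI = C * IR * EF * ED / (BW * AT)      [mg/kg-day]

and via dermal contact

    ADI_D = C * SA * AF * ABS * 1e-6 * EF * ED / (BW * AT)

with C the medium concentration, IR the intake rate, EF exposure frequency
(day/year), ED exposure duration (year), BW body weight (kg), AT averaging
time (day), SA exposed skin area (cm2), AF the soil-to-skin adherence factor
(mg/cm2-day) and ABS the dimensionless dermal absorption fraction. Under the
chronic-HQ convention EF = 365 and AT = ED * 365, so the EF*ED/AT factor is
exactly 1 and doses are independent of ED.

All functions are plain arithmetic on floats or numpy arrays, so the Monte
Carlo engine can evaluate them vectorized over iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exposure_model import Medium, Metal, Route
from .units import check_intake_compatible, to_canonical

#: mg -> kg for soil mass entering ingestion/adherence terms
MG_TO_KG = 1e-6

#: default exposure frequency, day/year (residents exposed daily)
DEFAULT_EF = 365.0


def _averaging_time(ed, at):
    """Default AT = ED * 365 days (chronic non-carcinogenic convention)."""
    return ed * 365.0 if at is None else at


def _check_positive(bw, at) -> None:
    if np.any(np.asarray(bw) <= 0):
        raise ValueError("body weight must be > 0")
    if np.any(np.asarray(at) <= 0):
        raise ValueError("averaging time must be > 0")


def adi_intake(
    c,
    ir,
    *,
    ef=DEFAULT_EF,
    ed=1.0,
    bw,
    at=None,
    c_unit: Optional[str] = None,
    ir_unit: Optional[str] = None,
):
    """ADI for direct ingestion or inhalation of a medium.

    ``c`` and ``ir`` must be unit-compatible (mg/L x L/day, mg/kg x kg/day,
    or mg/m3 x m3/day); pass ``c_unit``/``ir_unit`` to have the pairing
    audited and prefixed units (ug/..., g/day) converted. Returns mg/kg-day.
    """
    if (c_unit is None) != (ir_unit is None):
        raise ValueError("pass both c_unit and ir_unit, or neither")
    if c_unit is not None:
        check_intake_compatible(c_unit, ir_unit)
        c, _ = to_canonical(c, c_unit)
        ir, _ = to_canonical(ir, ir_unit)
    at = _averaging_time(ed, at)
    _check_positive(bw, at)
    if np.any(np.asarray(c) < 0) or np.any(np.asarray(ir) < 0):
        raise ValueError("concentration and intake rate must be >= 0")
    return c * ir * ef * ed / (bw * at)


def adi_soil_ingestion(c_soil, ir_soil, *, ef=DEFAULT_EF, ed=1.0, bw, at=None):
    """ADI for incidental soil ingestion.

    ``c_soil`` in mg/kg, ``ir_soil`` in mg of soil per day; the mg->kg factor
    1e-6 is applied internally.
    """
    return adi_intake(c_soil, ir_soil * MG_TO_KG, ef=ef, ed=ed, bw=bw, at=at)


def adi_dermal(c, sa, af, abs_frac, *, ef=DEFAULT_EF, ed=1.0, bw, at=None):
    """ADI for dermal contact with soil (or water, with water-specific sa/af).

    ``c`` in mg/kg (soil) or mg/L (water); ``sa`` cm2; ``af`` mg/cm2-day;
    ``abs_frac`` in [0, 1].
    """
    if np.any(np.asarray(abs_frac) < 0) or np.any(np.asarray(abs_frac) > 1):
        raise ValueError("dermal absorption fraction must lie in [0, 1]")
    at = _averaging_time(ed, at)
    _check_positive(bw, at)
    if np.any(np.asarray(c) < 0):
        raise ValueError("concentration must be >= 0")
    return c * sa * af * abs_frac * MG_TO_KG * ef * ed / (bw * at)


@dataclass
class PathwayDose:
    """Dose for one metal via one (medium, route).

    ``adi`` is the body-weight-normalized dose in mg/kg-day (route-to-route
    for inhalation); ``exposure_concentration`` (mg/m3) is the time-averaged
    air level, present only for inhalation, so risk characterization can use
    an RfC where one exists.
    """

    metal: Metal
    medium: Medium
    route: Route
    adi: float
    exposure_concentration: Optional[float] = None

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.adi) < 0):
            raise ValueError("adi must be >= 0")
        has_ec = self.exposure_concentration is not None
        if (self.route is Route.INHALATION) != has_ec:
            raise ValueError(
                "exposure_concentration must be present iff route is inhalation"
            )


def inhalation_exposure(
    c_air,
    ir_air,
    *,
    metal: Metal,
    medium: Medium,
    ef=DEFAULT_EF,
    ed=1.0,
    bw,
    at=None,
) -> PathwayDose:
    """Inhalation dose plus time-averaged exposure concentration.

    ``c_air`` (mg/m3) is the micro-environment-weighted air term (for a
    single micro-environment: concentration x time fraction). The returned
    dose carries both the route-to-route ADI (c*IR_air*EF*ED/(BW*AT)) and
    the averaged concentration c*EF*ED/AT*(AT/(365*ED)) — which reduces to c
    itself under the default EF/AT — so the risk engine can characterize
    against either an RfD or an RfC.
    """
    at = _averaging_time(ed, at)
    adi = adi_intake(c_air, ir_air, ef=ef, ed=ed, bw=bw, at=at)
    # EC = C * EF * ED / AT (days); identity under EF = 365, AT = ED * 365
    ec = c_air * ef * ed / at
    return PathwayDose(
        metal=metal,
        medium=medium,
        route=Route.INHALATION,
        adi=adi,
        exposure_concentration=ec,
    )
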