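"""Domain model for multipathway heavy-metal exposure assessment.

Covers the ten USEPA priority-pollutant (PP) metals measured in drinking
water, soil, indoor/outdoor air and locally produced food; participant-level
exposure-survey records; toxicity references (oral RfD, inhalation RfC); and
the preparation steps that happen before any dose is computed: substitution
of left-censored concentrations at the detection limit and time-weighted
averaging of indoor/outdoor air by activity pattern.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence


class Metal(str, enum.Enum):
    """The ten priority-pollutant metals handled by this package."""

    AG = "Ag"
    CD = "Cd"
    CR = "Cr"
    CU = "Cu"
    NI = "Ni"
    PB = "Pb"
    SE = "Se"
    TL = "Tl"
    ZN = "Zn"
    HG = "Hg"

    @classmethod
    def parse(cls, symbol: str) -> "Metal":
        """Parse a chemical symbol, rejecting anything outside the closed set."""
        try:
            return cls(symbol)
        except ValueError:
            raise ValueError(
                f"unknown metal symbol {symbol!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class MediumKind(str, enum.Enum):
    WATER = "water"
    SOIL = "soil"
    AIR_INDOOR = "air_indoor"
    AIR_OUTDOOR = "air_outdoor"
    FOOD = "food"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: canonical concentration unit per medium kind
CANONICAL_CONC_UNIT: dict[MediumKind, str] = {
    MediumKind.WATER: "mg/L",
    MediumKind.SOIL: "mg/kg",
    MediumKind.AIR_INDOOR: "mg/m3",
    MediumKind.AIR_OUTDOOR: "mg/m3",
    MediumKind.FOOD: "mg/kg",
}


@dataclass(frozen=True, order=True)
class Medium:
    """An exposure medium; food media carry the food item label."""

    kind: MediumKind
    food_item: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind is MediumKind.FOOD:
            if not self.food_item:
                raise ValueError("food medium requires a food_item label")
        elif self.food_item is not None:
            raise ValueError(f"{self.kind.value} medium must not carry a food_item")

    @property
    def key(self) -> str:
        """Stable string key, e.g. ``soil`` or ``food:pakchoi``."""
        if self.kind is MediumKind.FOOD:
            return f"food:{self.food_item}"
        return self.kind.value

    @classmethod
    def parse(cls, key: str) -> "Medium":
        if key.startswith("food:"):
            return cls(MediumKind.FOOD, key.split(":", 1)[1])
        return cls(MediumKind(key))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.key


WATER = Medium(MediumKind.WATER)
SOIL = Medium(MediumKind.SOIL)
AIR_INDOOR = Medium(MediumKind.AIR_INDOOR)
AIR_OUTDOOR = Medium(MediumKind.AIR_OUTDOOR)


def food(item: str) -> Medium:
    return Medium(MediumKind.FOOD, item)


class Route(str, enum.Enum):
    INGESTION = "ingestion"
    INHALATION = "inhalation"
    DERMAL = "dermal"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: default whitelist of (medium kind, route) pairs
DEFAULT_PATHWAYS: frozenset[tuple[MediumKind, Route]] = frozenset(
    {
        (MediumKind.WATER, Route.INGESTION),
        (MediumKind.WATER, Route.DERMAL),
        (MediumKind.SOIL, Route.INGESTION),
        (MediumKind.SOIL, Route.DERMAL),
        (MediumKind.AIR_INDOOR, Route.INHALATION),
        (MediumKind.AIR_OUTDOOR, Route.INHALATION),
        (MediumKind.FOOD, Route.INGESTION),
    }
)


@dataclass
class ConcentrationRecord:
    """One measured metal level in one medium in one village.

    ``value`` is in the medium's canonical unit (mg/L water, mg/kg soil and
    food fresh weight, mg/m3 air). Left-censored records (below the limit of
    detection) carry ``censored=True`` and a positive ``lod``; their ``value``
    is not used until a substitution policy has been applied.
    """

    village: str
    medium: Medium
    metal: Metal
    value: float
    censored: bool = False
    lod: Optional[float] = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"concentration value must be >= 0, got {self.value}")
        if self.censored and not (self.lod and self.lod > 0):
            raise ValueError(
                f"censored record ({self.village}, {self.medium}, "
                f"{self.metal.value}) needs a positive lod, got {self.lod}"
            )


class CensoringPolicy(str, enum.Enum):
    """Substitution rule for left-censored values."""

    HALF_LOD = "half_lod"
    ZERO = "zero"
    LOD = "lod"


def substitute_below_lod(
    records: Iterable[ConcentrationRecord],
    policy: CensoringPolicy | str = CensoringPolicy.HALF_LOD,
) -> list[ConcentrationRecord]:
    """Replace censored values by LOD/2 (default), 0, or the LOD.

    Uncensored records pass through unchanged; order is preserved. The
    operation is idempotent: the censored flag is kept, so re-applying any
    policy reproduces the same substituted value.
    """
    policy = CensoringPolicy(policy)
    out = []
    for rec in records:
        if not rec.censored:
            out.append(rec)
            continue
        if not (rec.lod and rec.lod > 0):
            raise ValueError(
                f"censored record ({rec.village}, {rec.medium}, "
                f"{rec.metal.value}) has unusable lod={rec.lod}"
            )
        if policy is CensoringPolicy.HALF_LOD:
            value = rec.lod / 2.0
        elif policy is CensoringPolicy.ZERO:
            value = 0.0
        else:
            value = rec.lod
        out.append(replace(rec, value=value))
    return out


@dataclass
class ConcentrationSummary:
    """Moments of a (village, medium, metal) group after censoring handling."""

    village: str
    medium: Medium
    metal: Metal
    mean: float
    sd: float
    n: int
    detection_rate: float
    lod: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError("mean and sd must be >= 0")
        if not 0.0 <= self.detection_rate <= 1.0:
            raise ValueError(f"detection_rate {self.detection_rate} outside [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def summarize_concentrations(
    records: Sequence[ConcentrationRecord],
) -> dict[tuple[str, Medium, Metal], ConcentrationSummary]:
    """Arithmetic mean/SD and detection rate per (village, medium, metal).

    Records must already have censored values substituted (the censored flag
    is only read to compute the detection rate). SD is the sample standard
    deviation (ddof=1); a single-record group reports sd 0.
    """
    groups: dict[tuple[str, Medium, Metal], list[ConcentrationRecord]] = {}
    for rec in records:
        groups.setdefault((rec.village, rec.medium, rec.metal), []).append(rec)
    if not groups:
        raise ValueError("no records to summarize")
    out = {}
    for key, recs in groups.items():
        values = [r.value for r in recs]
        n = len(values)
        mean = sum(values) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
        detected = sum(1 for r in recs if not r.censored)
        lods = [r.lod for r in recs if r.lod]
        out[key] = ConcentrationSummary(
            village=key[0],
            medium=key[1],
            metal=key[2],
            mean=mean,
            sd=sd,
            n=n,
            detection_rate=detected / n,
            lod=max(lods) if lods else None,
        )
    return out


class TimeWeightedAir(NamedTuple):
    """Time-weighted air concentration with its indoor/outdoor decomposition.

    ``value = indoor_term + outdoor_term`` where the terms are the
    concentration x time-fraction addends, so downstream attribution can keep
    indoor and outdoor air apart.
    """

    value: float
    indoor_term: float
    outdoor_term: float
    f_indoor: float
    f_outdoor: float


def time_weighted_air(
    c_indoor: float,
    c_outdoor: float,
    hours_indoor: float,
    hours_outdoor: float,
    hours_sleep: float,
) -> TimeWeightedAir:
    """Average indoor/outdoor air levels by time spent in each micro-environment.

    Sleep counts as indoor time. Fractions are normalized over accounted hours
    (indoor + sleep + outdoor), not over 24 h, so unaccounted time is
    apportioned proportionally rather than silently diluting exposure.
    """
    for h in (hours_indoor, hours_outdoor, hours_sleep):
        if h < 0:
            raise ValueError("hours must be >= 0")
    total = hours_indoor + hours_outdoor + hours_sleep
    if total <= 0:
        raise ValueError("at least one activity-hour entry must be positive")
    f_in = (hours_indoor + hours_sleep) / total
    f_out = hours_outdoor / total
    indoor_term = c_indoor * f_in
    outdoor_term = c_outdoor * f_out
    return TimeWeightedAir(
        value=indoor_term + outdoor_term,
        indoor_term=indoor_term,
        outdoor_term=outdoor_term,
        f_indoor=f_in,
        f_outdoor=f_out,
    )


@dataclass
class SurveyRecord:
    """One participant's exposure-survey answers.

    ``food_intake`` maps food item label to intake in g/day (as surveyed);
    conversion to kg/day happens in the dose engine.
    """

    participant: str
    village: str
    body_weight: float
    hours_indoor: float
    hours_outdoor: float
    hours_sleep: float
    water_ingestion: float
    exposure_duration: float
    food_intake: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        numeric = {
            "body_weight": self.body_weight,
            "hours_indoor": self.hours_indoor,
            "hours_outdoor": self.hours_outdoor,
            "hours_sleep": self.hours_sleep,
            "water_ingestion": self.water_ingestion,
            "exposure_duration": self.exposure_duration,
            **{f"intake_{k}": v for k, v in self.food_intake.items()},
        }
        for name, value in numeric.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        hours = self.hours_indoor + self.hours_outdoor + self.hours_sleep
        if hours > 24.0 + 1e-9:
            raise ValueError(f"activity hours sum to {hours:.2f} > 24")


class Distribution(str, enum.Enum):
    FIXED = "fixed"
    LOGNORMAL = "lognormal"
    NORMAL_TRUNCATED_AT_ZERO = "normal_truncated_at_zero"


@dataclass
class ExposureFactorSpec:
    """A named exposure parameter with a fitted distribution or fixed value.

    ``mean``/``sd`` are on the observed scale (what the survey reports), not
    the log scale; distribution fitting translates them.
    """

    name: str
    distribution: Distribution | str
    mean: float
    sd: Optional[float] = None
    units: str = ""

    def __post_init__(self) -> None:
        self.distribution = Distribution(self.distribution)
        if self.distribution is Distribution.FIXED:
            if self.sd not in (None, 0, 0.0):
                raise ValueError(f"fixed spec {self.name!r} must not carry an sd")
            self.sd = None
        else:
            if self.sd is None or self.sd < 0:
                raise ValueError(f"stochastic spec {self.name!r} needs sd >= 0")
            if self.distribution is Distribution.LOGNORMAL and self.mean <= 0:
                raise ValueError(f"lognormal spec {self.name!r} needs mean > 0")

    @property
    def is_fixed(self) -> bool:
        return self.distribution is Distribution.FIXED or self.sd in (None, 0.0)


#: metals that carry an inhalation reference concentration by default
RFC_METALS: frozenset[Metal] = frozenset({Metal.CD, Metal.NI, Metal.SE, Metal.HG})


@dataclass
class ToxRef:
    """Per-metal toxicity reference: oral RfD (mg/kg-day), optional RfC (mg/m3)."""

    metal: Metal
    rfd: float
    rfc: Optional[float] = None
    source_rfd: str = ""
    source_rfc: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rfd <= 0:
            raise ValueError(f"rfd for {self.metal.value} must be > 0")
        if self.rfc is not None and self.rfc <= 0:
            raise ValueError(f"rfc for {self.metal.value} must be > 0 when present")


def validate_tox_table(tox: Mapping[Metal, ToxRef]) -> None:
    """Every PP metal must have an RfD; gaps are configuration errors."""
    missing = [m.value for m in Metal if m not in tox]
    if missing:
        raise ValueError(f"toxicity table missing RfD for metals: {missing}")
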