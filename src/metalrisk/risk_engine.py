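"""Hazard-quotient characterization, aggregation and pathway attribution.

The hazard quotient (HQ) is the ratio of the average daily intake to the
oral reference dose (RfD), or — for inhalation where an inhalation reference
concentration (RfC) exists — the ratio of the time-averaged air level to the
RfC. HQ < 1 is presumed safe. HQs are summed across pathways within a metal
and across metals within a village; the total acts as a conservative
screening index, not a probability of harm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .dose_engine import PathwayDose
from .exposure_model import Medium, MediumKind, Metal, Route, ToxRef

#: key of one pathway term: (metal, medium, route)
PathwayKey = tuple[Metal, Medium, Route]


class HQMode(str, enum.Enum):
    """How inhalation is characterized: prefer RfC when present, or force RfD."""

    AUTO = "auto"
    RFD_ONLY = "rfd_only"


def hazard_quotient(
    dose: PathwayDose, tox: ToxRef, mode: HQMode | str = HQMode.AUTO
) -> float:
    """HQ of a single pathway dose against the metal's reference values.

    Ingestion and dermal doses divide by the oral RfD. Inhalation divides the
    exposure concentration by the RfC when one exists (mode ``auto``),
    otherwise falls back to route-to-route extrapolation against the RfD.
    """
    mode = HQMode(mode)
    if dose.metal is not tox.metal:
        raise ValueError(
            f"dose metal {dose.metal.value} does not match tox ref {tox.metal.value}"
        )
    if dose.route is Route.INHALATION and mode is HQMode.AUTO and tox.rfc is not None:
        if dose.exposure_concentration is None:
            raise ValueError(
                f"RfC-based HQ for {dose.metal.value} requires an exposure "
                "concentration on the inhalation dose"
            )
        return dose.exposure_concentration / tox.rfc
    return dose.adi / tox.rfd


@dataclass
class RiskResult:
    """HQ values at (metal, medium, route) granularity plus aggregates.

    Metals or pathways absent from the input simply contribute zero;
    sub-threshold contributions are retained, never dropped, so the total is
    exactly the sum of its parts.
    """

    village: str
    hq: dict[PathwayKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.hq.items():
            if value < 0:
                raise ValueError(f"negative HQ for {key}")

    @property
    def hq_by_metal(self) -> dict[Metal, float]:
        totals: dict[Metal, float] = {}
        for (metal, _, _), value in self.hq.items():
            totals[metal] = totals.get(metal, 0.0) + value
        return totals

    @property
    def total_hq(self) -> float:
        return sum(self.hq.values())

    def metal_pathways(self, metal: Metal) -> dict[PathwayKey, float]:
        return {k: v for k, v in self.hq.items() if k[0] is metal}


def aggregate_total(
    hqs: Mapping[PathwayKey, float], village: str = ""
) -> RiskResult:
    """Aggregate per-pathway HQs into a RiskResult (exact sums)."""
    if not hqs:
        raise ValueError("cannot aggregate an empty HQ mapping")
    for key, value in hqs.items():
        if value < 0:
            raise ValueError(f"negative HQ for {key}")
    return RiskResult(village=village, hq=dict(hqs))


class Grouping(str, enum.Enum):
    """Granularity of pathway attribution."""

    PATHWAY = "pathway"  # (medium, route) pairs, food collapsed to one slice
    MEDIUM = "medium"  # medium only, air indoor/outdoor collapsed
    FOOD_ITEM = "food_item"  # food items, within the food pathway only
    INDOOR_OUTDOOR = "indoor_outdoor"  # air inhalation only


def _group_label(medium: Medium, route: Route, grouping: Grouping) -> Optional[str]:
    if grouping is Grouping.PATHWAY:
        kind = "food" if medium.kind is MediumKind.FOOD else medium.kind.value
        return f"{kind}_{route.value}"
    if grouping is Grouping.MEDIUM:
        if medium.kind in (MediumKind.AIR_INDOOR, MediumKind.AIR_OUTDOOR):
            return "air"
        return "food" if medium.kind is MediumKind.FOOD else medium.kind.value
    if grouping is Grouping.FOOD_ITEM:
        return medium.food_item if medium.kind is MediumKind.FOOD else None
    if grouping is Grouping.INDOOR_OUTDOOR:
        if medium.kind is MediumKind.AIR_INDOOR:
            return "indoor"
        if medium.kind is MediumKind.AIR_OUTDOOR:
            return "outdoor"
        return None
    raise AssertionError(grouping)


def attribute_pathways(
    result: RiskResult,
    metal: Metal,
    grouping: Grouping | str = Grouping.PATHWAY,
) -> dict[str, float]:
    """Fraction of a metal's HQ carried by each pathway group.

    Fractions are computed on mean HQs (the deterministic values held by the
    RiskResult), sum to 1 over the requested grouping, and are invariant to
    rescaling all HQs by a positive constant. The restricted groupings
    (``food_item``, ``indoor_outdoor``) normalize within their slice (food
    pathway, air inhalation respectively).
    """
    grouping = Grouping(grouping)
    pathway_hqs = result.metal_pathways(metal)
    if not pathway_hqs:
        raise ValueError(f"no pathway data for metal {metal.value}")
    shares: dict[str, float] = {}
    for (m, medium, route), value in pathway_hqs.items():
        label = _group_label(medium, route, grouping)
        if label is None:
            continue
        shares[label] = shares.get(label, 0.0) + value
    total = sum(shares.values())
    if total <= 0:
        if sum(pathway_hqs.values()) <= 0:
            raise ValueError(
                f"metal {metal.value} has zero total HQ: attribution is "
                "undefined (no risk, though data are present)"
            )
        raise ValueError(
            f"metal {metal.value} has no HQ in the {grouping.value} slice"
        )
    return {label: value / total for label, value in shares.items()}


def characterize(
    doses: Iterable[PathwayDose],
    tox: Mapping[Metal, ToxRef],
    village: str = "",
    mode: HQMode | str = HQMode.AUTO,
) -> RiskResult:
    """Convenience: HQ every dose and aggregate in one step."""
    hqs: dict[PathwayKey, float] = {}
    for dose in doses:
        if dose.metal not in tox:
            raise ValueError(f"no toxicity reference for {dose.metal.value}")
        key = (dose.metal, dose.medium, dose.route)
        hqs[key] = hqs.get(key, 0.0) + hazard_quotient(dose, tox[dose.metal], mode)
    return aggregate_total(hqs, village=village)
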