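"""Hair-metal biomonitoring summaries.

Hair levels (mg/kg) serve as an in-vivo indicator of long-term metal
exposure. Values below the limit of detection are left-censored; summaries
substitute LOD/2 before computing moments (geometric means need positive
data), report the detected proportion, and render groups with zero
detections as absent. A descriptive concordance check compares village
rankings by hair level against rankings by modelled hazard quotient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .exposure_model import CensoringPolicy, Metal

#: suggested upper limit of normal hair lead, mg/kg (annotation only)
HAIR_PB_GUIDELINE = 10.0


@dataclass
class HairRecord:
    """One participant's hair level for one metal (mg/kg)."""

    participant: str
    village: str
    metal: Metal
    value: float
    censored: bool = False
    lod: float = 0.0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("hair value must be >= 0")
        if self.lod <= 0:
            raise ValueError("hair records require a positive lod")


@dataclass
class HairSummary:
    """Per (village, metal) summary; means are None when nothing was detected."""

    village: str
    metal: Metal
    n: int
    detected_proportion: float
    mean: Optional[float]
    sd: Optional[float]
    geometric_mean: Optional[float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.detected_proportion <= 1.0:
            raise ValueError("detected_proportion outside [0, 1]")
        if (
            self.mean is not None
            and self.geometric_mean is not None
            and self.geometric_mean > self.mean * (1 + 1e-12)
        ):
            raise ValueError("geometric mean cannot exceed arithmetic mean")


def _substituted(rec: HairRecord, policy: CensoringPolicy) -> float:
    if not rec.censored:
        return rec.value
    if policy is CensoringPolicy.HALF_LOD:
        return rec.lod / 2.0
    if policy is CensoringPolicy.ZERO:
        return 0.0
    return rec.lod


def summarize_hair(
    records: Iterable[HairRecord],
    policy: CensoringPolicy | str = CensoringPolicy.HALF_LOD,
) -> dict[tuple[str, Metal], HairSummary]:
    """Arithmetic and geometric means, SD and detected proportion per group.

    Censored values enter the means after substitution (LOD/2 by default,
    shared with the concentration pipeline); a group with zero detections
    reports all means as absent and proportion 0.
    """
    policy = CensoringPolicy(policy)
    groups: dict[tuple[str, Metal], list[HairRecord]] = {}
    for rec in records:
        groups.setdefault((rec.village, rec.metal), []).append(rec)
    if not groups:
        raise ValueError("no hair records to summarize")
    out = {}
    for key, recs in groups.items():
        n = len(recs)
        detected = sum(1 for r in recs if not r.censored)
        if detected == 0:
            out[key] = HairSummary(
                village=key[0], metal=key[1], n=n,
                detected_proportion=0.0, mean=None, sd=None, geometric_mean=None,
            )
            continue
        values = [_substituted(r, policy) for r in recs]
        mean = sum(values) / n
        sd = (
            math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
            if n > 1 else 0.0
        )
        gm = (
            math.exp(sum(math.log(v) for v in values) / n)
            if all(v > 0 for v in values) else None
        )
        out[key] = HairSummary(
            village=key[0], metal=key[1], n=n,
            detected_proportion=detected / n, mean=mean, sd=sd, geometric_mean=gm,
        )
    return out


@dataclass
class ConcordanceRow:
    """Village rankings (best-exposed last) by hair level and by HQ for one metal."""

    metal: Metal
    ranking_by_hair: tuple[str, ...]
    ranking_by_hq: tuple[str, ...]
    top_village_agrees: bool
    full_ranking_agrees: bool


def compare_to_risk(
    hair_summaries: Mapping[tuple[str, Metal], HairSummary],
    hq_by_village_metal: Mapping[tuple[str, Metal], float],
) -> list[ConcordanceRow]:
    """Rank villages by hair mean and by HQ mean per metal, descending.

    A descriptive concordance flag, not a statistical test: reports whether
    the most-exposed village agrees and whether the full rankings agree.
    Metals with usable hair means in fewer than two villages (e.g. fully
    censored everywhere) are skipped; if nothing is rankable, raises.
    """
    metals = sorted(
        {m for (_, m) in hair_summaries} & {m for (_, m) in hq_by_village_metal},
        key=lambda m: m.value,
    )
    if not metals:
        raise ValueError("no metal is covered by both hair and risk inputs")
    rows = []
    for metal in metals:
        hair = {
            v: s.mean
            for (v, m), s in hair_summaries.items()
            if m is metal and s.mean is not None
        }
        hqs = {v: hq for (v, m), hq in hq_by_village_metal.items() if m is metal}
        villages = sorted(set(hair) & set(hqs))
        if len(villages) < 2:
            continue
        by_hair = tuple(sorted(villages, key=lambda v: (-hair[v], v)))
        by_hq = tuple(sorted(villages, key=lambda v: (-hqs[v], v)))
        rows.append(
            ConcordanceRow(
                metal=metal,
                ranking_by_hair=by_hair,
                ranking_by_hq=by_hq,
                top_village_agrees=by_hair[0] == by_hq[0],
                full_ranking_agrees=by_hair == by_hq,
            )
        )
    if not rows:
        raise ValueError(
            "concordance needs >= 2 villages with both hair and HQ data "
            "for at least one metal"
        )
    return rows
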