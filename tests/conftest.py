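"""Shared fixtures and the independent brute-force HQ oracle.

The oracle re-derives every pathway hazard quotient with plain scalar
arithmetic straight from the intake/dermal equations, deliberately sharing
no code with the package's vectorized evaluation chain.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from metalrisk.defaults import load_exposure_defaults, load_tox_refs
from metalrisk.exposure_model import (
    ConcentrationSummary,
    ExposureFactorSpec,
    Medium,
    MediumKind,
    Metal,
    Route,
)
from metalrisk.uncertainty import VillageModel


@pytest.fixture(scope="session")
def tox():
    return load_tox_refs()


@pytest.fixture(scope="session")
def factors():
    return load_exposure_defaults()


@pytest.fixture(scope="session")
def v1_profile():
    from metalrisk.synthetic_data import village_profile

    return village_profile("V1")


@pytest.fixture(scope="session")
def v1_model(v1_profile):
    from metalrisk.synthetic_data import build_model

    return build_model(v1_profile)


def make_summary(medium: Medium, metal: Metal, mean: float, sd: float = 0.0,
                 village: str = "T", n: int = 5) -> ConcentrationSummary:
    return ConcentrationSummary(
        village=village, medium=medium, metal=metal, mean=mean, sd=sd, n=n,
        detection_rate=1.0,
    )


def fixed_factors(overrides: dict[str, float] | None = None) -> dict[str, ExposureFactorSpec]:
    """All default factors pinned to their means (no randomness)."""
    specs = {}
    for name, spec in load_exposure_defaults().items():
        mean = (overrides or {}).get(name, spec.mean)
        specs[name] = ExposureFactorSpec(
            name=name, distribution="fixed", mean=mean, units=spec.units
        )
    return specs


def oracle_hqs(model: VillageModel) -> dict:
    """Scalar re-derivation of every pathway HQ at parameter means."""
    f = {name: spec.mean for name, spec in model.factors.items()}
    accounted = f["hours_indoor"] + f["hours_outdoor"] + f["hours_sleep"]
    f_in = (f["hours_indoor"] + f["hours_sleep"]) / accounted
    f_out = f["hours_outdoor"] / accounted
    out = {}
    for (medium, metal), summ in model.concentrations.items():
        c = summ.mean
        tox = model.tox[metal]
        abs_frac = f.get(f"ABS_{metal.value}", f.get("ABS_default"))
        kind = medium.kind
        if kind is MediumKind.WATER:
            if (kind, Route.INGESTION) in model.pathways:
                out[(metal, medium, Route.INGESTION)] = (
                    c * f["IR_water"] / f["BW"] / tox.rfd
                )
            if (kind, Route.DERMAL) in model.pathways:
                out[(metal, medium, Route.DERMAL)] = (
                    c * f["SA_water"] * f["AF_water"] * abs_frac * 1e-6
                    / f["BW"] / tox.rfd
                )
        elif kind is MediumKind.SOIL:
            if (kind, Route.INGESTION) in model.pathways:
                out[(metal, medium, Route.INGESTION)] = (
                    c * f["IR_soil"] * 1e-6 / f["BW"] / tox.rfd
                )
            if (kind, Route.DERMAL) in model.pathways:
                out[(metal, medium, Route.DERMAL)] = (
                    c * f["SA_soil"] * f["AF_soil"] * abs_frac * 1e-6
                    / f["BW"] / tox.rfd
                )
        elif kind in (MediumKind.AIR_INDOOR, MediumKind.AIR_OUTDOOR):
            if (kind, Route.INHALATION) not in model.pathways:
                continue
            frac = f_in if kind is MediumKind.AIR_INDOOR else f_out
            if tox.rfc is not None:
                out[(metal, medium, Route.INHALATION)] = c * frac / tox.rfc
            else:
                out[(metal, medium, Route.INHALATION)] = (
                    c * frac * f["IR_air"] / f["BW"] / tox.rfd
                )
        elif kind is MediumKind.FOOD:
            if (kind, Route.INGESTION) in model.pathways:
                out[(metal, medium, Route.INGESTION)] = (
                    c * f[f"IR_{medium.food_item}"] * 1e-3 / f["BW"] / tox.rfd
                )
    return out


def random_small_model(rng: np.random.Generator, village: str = "rand") -> VillageModel:
    """A random model over a random subset of metals and media, fixed factors."""
    from metalrisk.exposure_model import AIR_INDOOR, AIR_OUTDOOR, SOIL, WATER, food

    media_pool = [WATER, SOIL, AIR_INDOOR, AIR_OUTDOOR,
                  food("rice"), food("pakchoi"), food("cabbage")]
    metals = list(Metal)
    chosen_metals = rng.choice(len(metals), size=rng.integers(1, 4), replace=False)
    chosen_media = rng.choice(len(media_pool), size=rng.integers(1, 5), replace=False)
    overrides = {
        "BW": float(rng.uniform(40, 90)),
        "IR_water": float(rng.uniform(0.5, 4)),
        "IR_soil": float(rng.uniform(10, 200)),
        "IR_air": float(rng.uniform(5, 25)),
    }
    conc = {}
    for mi in chosen_metals:
        for di in chosen_media:
            medium, metal = media_pool[di], metals[mi]
            scale = {"water": 1e-2, "soil": 1e3, "air_indoor": 1e-3,
                     "air_outdoor": 1e-3}.get(medium.kind.value, 1.0)
            conc[(medium, metal)] = make_summary(
                medium, metal, float(rng.uniform(0.1, 10) * scale), village=village
            )
    return VillageModel(
        name=village,
        concentrations=conc,
        factors=fixed_factors(overrides),
        tox=load_tox_refs(),
    )
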