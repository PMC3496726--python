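"""Loaders for the bundled toxicity references and exposure-factor defaults."""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import yaml

from .exposure_model import (
    Distribution,
    ExposureFactorSpec,
    Metal,
    ToxRef,
    validate_tox_table,
)


def _read_bundled(name: str) -> dict:
    with resources.files("metalrisk.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def parse_tox_table(raw: Mapping[str, Mapping]) -> dict[Metal, ToxRef]:
    tox = {}
    for symbol, entry in raw.items():
        metal = Metal.parse(symbol)
        tox[metal] = ToxRef(
            metal=metal,
            rfd=float(entry["rfd"]),
            rfc=float(entry["rfc"]) if entry.get("rfc") is not None else None,
            source_rfd=str(entry.get("source_rfd", "")),
            source_rfc=entry.get("source_rfc"),
        )
    validate_tox_table(tox)
    return tox


def load_tox_refs() -> dict[Metal, ToxRef]:
    """The bundled RfD/RfC table, keyed by Metal."""
    return parse_tox_table(_read_bundled("tox_refs.yaml"))


def parse_factor_specs(raw: Mapping[str, Mapping]) -> dict[str, ExposureFactorSpec]:
    specs = {}
    for name, entry in raw.items():
        dist = Distribution(entry["distribution"])
        specs[name] = ExposureFactorSpec(
            name=name,
            distribution=dist,
            mean=float(entry["mean"]),
            sd=float(entry["sd"]) if dist is not Distribution.FIXED else None,
            units=str(entry.get("units", "")),
        )
    return specs


def load_exposure_defaults() -> dict[str, ExposureFactorSpec]:
    """The bundled exposure-parameter defaults, keyed by parameter name."""
    return parse_factor_specs(_read_bundled("exposure_defaults.yaml"))


#: food items with a default dietary intake parameter (IR_<item>)
DEFAULT_FOOD_ITEMS: tuple[str, ...] = (
    "rice",
    "flour",
    "pakchoi",
    "cabbage",
    "spinach",
    "celery",
    "pork",
    "egg",
)
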