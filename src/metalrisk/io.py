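"""File formats, run configuration and pipeline orchestration.

CSV dialects are deliberately dumb: UTF-8, "." decimals, explicit unit
columns (never unit-in-header). Every emitted table re-parses through the
same readers. ``run_pipeline`` wires the whole chain — simulate or read
tables, fit survey factors, summarize concentrations, point-estimate and
Monte Carlo every village, summarize hair — and writes a report bundle plus
a manifest carrying a config hash and the parameter values actually used.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomonitor import HairRecord, compare_to_risk, summarize_hair
from .defaults import load_exposure_defaults, load_tox_refs, parse_factor_specs, parse_tox_table
from .exposure_model import (
    CANONICAL_CONC_UNIT,
    CensoringPolicy,
    ConcentrationRecord,
    ConcentrationSummary,
    Distribution,
    ExposureFactorSpec,
    Medium,
    MediumKind,
    Metal,
    SurveyRecord,
    ToxRef,
    substitute_below_lod,
    summarize_concentrations,
)
from .risk_engine import Grouping, RiskResult, attribute_pathways
from .uncertainty import (
    HQDistribution,
    MonteCarloConfig,
    VillageModel,
    empirical_cdf,
    fit_distribution,
    point_estimate,
    run_monte_carlo,
)
from .units import to_canonical

logger = logging.getLogger("metalrisk")

_CONC_COLUMNS = ["village", "medium", "food_item", "metal", "value", "unit", "censored", "lod"]
_SURVEY_BASE = [
    "participant", "village", "body_weight", "hours_indoor", "hours_outdoor",
    "hours_sleep", "water_ingestion", "exposure_duration",
]
_HAIR_COLUMNS = ["participant", "village", "metal", "value", "censored", "lod"]


class TableError(ValueError):
    """A malformed row, reported with its line context."""


# ---------------------------------------------------------------------------
# concentration tables


def write_concentrations(records: Sequence[ConcentrationRecord], path: Path | str) -> None:
    rows = [
        {
            "village": r.village,
            "medium": r.medium.kind.value,
            "food_item": r.medium.food_item or "",
            "metal": r.metal.value,
            "value": repr(r.value),
            "unit": CANONICAL_CONC_UNIT[r.medium.kind],
            "censored": int(r.censored),
            "lod": repr(r.lod) if r.lod is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_CONC_COLUMNS).to_csv(path, index=False)


def read_concentrations(path: Path | str) -> list[ConcentrationRecord]:
    """Read and validate a concentration CSV, normalizing units."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_CONC_COLUMNS) - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s: no concentration rows", path)
    records = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            kind = MediumKind(row["medium"])
            medium = Medium(kind, row["food_item"] or None)
            metal = Metal.parse(row["metal"])
            value, unit = to_canonical(float(row["value"]), row["unit"])
            if unit != CANONICAL_CONC_UNIT[kind]:
                raise ValueError(
                    f"unit {row['unit']!r} has dimension {unit}, expected "
                    f"{CANONICAL_CONC_UNIT[kind]} for {kind.value}"
                )
            lod = None
            if row["lod"]:
                lod, _ = to_canonical(float(row["lod"]), row["unit"])
            records.append(
                ConcentrationRecord(
                    village=row["village"], medium=medium, metal=metal,
                    value=value, censored=bool(int(row["censored"])), lod=lod,
                )
            )
        except (ValueError, KeyError) as exc:
            raise TableError(f"{path} line {line}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# survey tables


def write_survey(records: Sequence[SurveyRecord], path: Path | str) -> None:
    items = sorted({item for r in records for item in r.food_intake})
    rows = []
    for r in records:
        row = {
            "participant": r.participant,
            "village": r.village,
            "body_weight": repr(r.body_weight),
            "hours_indoor": repr(r.hours_indoor),
            "hours_outdoor": repr(r.hours_outdoor),
            "hours_sleep": repr(r.hours_sleep),
            "water_ingestion": repr(r.water_ingestion),
            "exposure_duration": repr(r.exposure_duration),
        }
        for item in items:
            row[f"intake_{item}"] = repr(r.food_intake.get(item, 0.0))
        rows.append(row)
    columns = _SURVEY_BASE + [f"intake_{i}" for i in items]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_survey(path: Path | str) -> list[SurveyRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_SURVEY_BASE) - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing columns {sorted(missing)}")
    items = [c[len("intake_"):] for c in df.columns if c.startswith("intake_")]
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                SurveyRecord(
                    participant=row["participant"],
                    village=row["village"],
                    body_weight=float(row["body_weight"]),
                    hours_indoor=float(row["hours_indoor"]),
                    hours_outdoor=float(row["hours_outdoor"]),
                    hours_sleep=float(row["hours_sleep"]),
                    water_ingestion=float(row["water_ingestion"]),
                    exposure_duration=float(row["exposure_duration"]),
                    food_intake={i: float(row[f"intake_{i}"]) for i in items},
                )
            )
        except ValueError as exc:
            raise TableError(f"{path} line {idx + 2}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# hair tables


def write_hair(records: Sequence[HairRecord], path: Path | str) -> None:
    rows = [
        {
            "participant": r.participant,
            "village": r.village,
            "metal": r.metal.value,
            "value": repr(r.value),
            "censored": int(r.censored),
            "lod": repr(r.lod),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_HAIR_COLUMNS).to_csv(path, index=False)


def read_hair(path: Path | str) -> list[HairRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_HAIR_COLUMNS) - set(df.columns)
    if missing:
        raise TableError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                HairRecord(
                    participant=row["participant"],
                    village=row["village"],
                    metal=Metal.parse(row["metal"]),
                    value=float(row["value"]),
                    censored=bool(int(row["censored"])),
                    lod=float(row["lod"]),
                )
            )
        except ValueError as exc:
            raise TableError(f"{path} line {idx + 2}: {exc}") from exc
    return records


def read_tox_yaml(path: Path | str) -> dict[Metal, ToxRef]:
    with open(path) as fh:
        return parse_tox_table(yaml.safe_load(fh))


def read_exposure_yaml(path: Path | str) -> dict[str, ExposureFactorSpec]:
    with open(path) as fh:
        return parse_factor_specs(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# survey -> exposure-factor fitting


def fit_factors_from_survey(
    records: Sequence[SurveyRecord],
    kind: Distribution | str = Distribution.LOGNORMAL,
) -> dict[str, ExposureFactorSpec]:
    """Fit exposure-factor distributions to surveyed sample moments.

    Pools all records (use per-village slices if demographics differ) and
    fits the default family to body weight, activity hours, water ingestion,
    exposure duration and every food intake present.
    """
    if not records:
        raise ValueError("no survey records to fit")

    def moments(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values)
        return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    fields = {
        "BW": [r.body_weight for r in records],
        "hours_indoor": [r.hours_indoor for r in records],
        "hours_outdoor": [r.hours_outdoor for r in records],
        "hours_sleep": [r.hours_sleep for r in records],
        "IR_water": [r.water_ingestion for r in records],
        "ED": [r.exposure_duration for r in records],
    }
    units = {
        "BW": "kg", "hours_indoor": "h/day", "hours_outdoor": "h/day",
        "hours_sleep": "h/day", "IR_water": "L/day", "ED": "year",
    }
    for item in sorted({i for r in records for i in r.food_intake}):
        fields[f"IR_{item}"] = [r.food_intake.get(item, 0.0) for r in records]
        units[f"IR_{item}"] = "g/day"
    specs = {}
    for name, values in fields.items():
        mean, sd = moments(values)
        specs[name] = fit_distribution(mean, sd, kind, name=name, units=units[name])
    return specs


def model_from_summaries(
    summaries: Mapping[tuple[str, Medium, Metal], ConcentrationSummary],
    village: str,
    factors: Mapping[str, ExposureFactorSpec],
    tox: Mapping[Metal, ToxRef],
) -> VillageModel:
    """Assemble a VillageModel from one village's concentration summaries."""
    conc = {
        (medium, metal): summ
        for (v, medium, metal), summ in summaries.items()
        if v == village
    }
    if not conc:
        raise ValueError(f"no concentration summaries for village {village!r}")
    return VillageModel(
        name=village, concentrations=conc, factors=dict(factors), tox=dict(tox)
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Inputs for a full pipeline run.

    Either ``simulate_profiles`` names bundled synthetic profiles, or the
    three CSV paths point at user tables. YAML overrides replace the bundled
    toxicity references / exposure defaults wholesale.
    """

    mc: MonteCarloConfig
    out_dir: Path | str = "metalrisk-out"
    simulate_profiles: Optional[Sequence[str]] = ("V1", "V2", "V3")
    concentrations_csv: Optional[Path | str] = None
    survey_csv: Optional[Path | str] = None
    hair_csv: Optional[Path | str] = None
    tox_yaml: Optional[Path | str] = None
    exposure_yaml: Optional[Path | str] = None
    censoring_policy: CensoringPolicy = CensoringPolicy.HALF_LOD
    fit_survey: bool = True

    def digest(self) -> str:
        """Stable hash of the run configuration."""
        payload = {
            "seed": self.mc.seed,
            "n_iterations": self.mc.n_iterations,
            "stochastic": sorted(self.mc.stochastic) if self.mc.stochastic else None,
            "concentration_mode": self.mc.concentration_mode,
            "simulate_profiles": list(self.simulate_profiles or []),
            "paths": [
                str(p) if p else None
                for p in (
                    self.concentrations_csv, self.survey_csv, self.hair_csv,
                    self.tox_yaml, self.exposure_yaml,
                )
            ],
            "censoring_policy": self.censoring_policy.value,
            "fit_survey": self.fit_survey,
            "version": __version__,
        }
        raw = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(raw).hexdigest()


@dataclass
class ReportBundle:
    """In-memory pipeline outputs plus the paths of everything written."""

    models: dict[str, VillageModel]
    point: dict[str, RiskResult]
    mc: dict[str, HQDistribution]
    hair_summaries: dict
    paths: dict[str, Path] = dataclass_field(default_factory=dict)
    manifest: dict = dataclass_field(default_factory=dict)


def _derived_seed(base: int, *key: str) -> int:
    raw = hashlib.sha256(("/".join(key) + f"#{base}").encode()).digest()
    return int.from_bytes(raw[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full assessment and write the report bundle."""
    from . import synthetic_data  # imported here to avoid a module cycle

    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    factors = (
        read_exposure_yaml(config.exposure_yaml)
        if config.exposure_yaml else load_exposure_defaults()
    )
    tox = read_tox_yaml(config.tox_yaml) if config.tox_yaml else load_tox_refs()

    if config.simulate_profiles:
        conc_records, survey_records, hair_records = [], [], []
        for name in config.simulate_profiles:
            profile = synthetic_data.village_profile(name, factors=factors, tox=tox)
            conc_records += synthetic_data.generate_concentrations(
                profile, _derived_seed(config.mc.seed, "conc", name)
            )
            survey_records += synthetic_data.generate_survey(
                profile, _derived_seed(config.mc.seed, "survey", name)
            )
            hair_records += synthetic_data.generate_hair(
                profile, _derived_seed(config.mc.seed, "hair", name)
            )
    else:
        if not (config.concentrations_csv and config.survey_csv):
            raise ValueError(
                "RunConfig needs simulate_profiles or concentration+survey CSVs"
            )
        conc_records = read_concentrations(config.concentrations_csv)
        survey_records = read_survey(config.survey_csv)
        hair_records = read_hair(config.hair_csv) if config.hair_csv else []
    logger.info(
        "inputs: %d concentration, %d survey, %d hair records (%.2fs)",
        len(conc_records), len(survey_records), len(hair_records), time.time() - t0,
    )

    if config.fit_survey and survey_records:
        factors = {**factors, **fit_factors_from_survey(survey_records)}

    substituted = substitute_below_lod(conc_records, config.censoring_policy)
    summaries = summarize_concentrations(substituted)
    villages = sorted({v for (v, _, _) in summaries})

    models, point, mc_out = {}, {}, {}
    for village in villages:
        model = model_from_summaries(summaries, village, factors, tox)
        models[village] = model
        point[village] = point_estimate(model)
        cfg = MonteCarloConfig(
            seed=_derived_seed(config.mc.seed, "mc", village),
            n_iterations=config.mc.n_iterations,
            stochastic=config.mc.stochastic,
            concentration_mode=config.mc.concentration_mode,
        )
        mc_out[village] = run_monte_carlo(model, cfg)
        logger.info(
            "village %s: point total HQ %.3g, MC mean %.3g",
            village, point[village].total_hq, float(np.mean(mc_out[village].total)),
        )

    hair_summaries = (
        summarize_hair(hair_records, config.censoring_policy) if hair_records else {}
    )

    bundle = ReportBundle(
        models=models, point=point, mc=mc_out, hair_summaries=hair_summaries
    )
    _write_reports(bundle, config, out_dir)
    logger.info("pipeline finished in %.2fs -> %s", time.time() - t0, out_dir)
    return bundle


def _write_reports(bundle: ReportBundle, config: RunConfig, out_dir: Path) -> None:
    villages = sorted(bundle.mc)

    # HQ table: metal x village, MC mean and SD plus the point estimate
    rows = []
    for village in villages:
        dist = bundle.mc[village]
        pt = bundle.point[village].hq_by_metal
        for metal in sorted(dist.per_metal, key=lambda m: m.value):
            samples = dist.per_metal[metal]
            rows.append(
                {
                    "village": village, "metal": metal.value,
                    "hq_mean": float(np.mean(samples)),
                    "hq_sd": float(np.std(samples, ddof=1)) if samples.size > 1 else 0.0,
                    "hq_point": pt.get(metal, 0.0),
                }
            )
        rows.append(
            {
                "village": village, "metal": "TOTAL",
                "hq_mean": float(np.mean(dist.total)),
                "hq_sd": float(np.std(dist.total, ddof=1)) if dist.total.size > 1 else 0.0,
                "hq_point": bundle.point[village].total_hq,
            }
        )
    hq_path = out_dir / "hq_table.csv"
    pd.DataFrame(rows).to_csv(hq_path, index=False)

    # pathway attribution on mean HQs
    rows = []
    for village in villages:
        mean_result = bundle.mc[village].mean_result()
        for metal in sorted(mean_result.hq_by_metal, key=lambda m: m.value):
            if mean_result.hq_by_metal[metal] <= 0:
                continue
            for grouping in (Grouping.PATHWAY, Grouping.MEDIUM):
                for label, frac in sorted(
                    attribute_pathways(mean_result, metal, grouping).items()
                ):
                    rows.append(
                        {
                            "village": village, "metal": metal.value,
                            "grouping": grouping.value, "label": label,
                            "fraction": frac,
                        }
                    )
    attr_path = out_dir / "attribution.csv"
    pd.DataFrame(rows).to_csv(attr_path, index=False)

    # cumulative distribution of total HQ
    rows = []
    for village in villages:
        x, p = empirical_cdf(bundle.mc[village].total)
        # thin to at most 500 points for plotting
        step = max(1, len(x) // 500)
        for xi, pi in zip(x[::step], p[::step]):
            rows.append({"village": village, "total_hq": xi, "cumulative_probability": pi})
    cdf_path = out_dir / "cdf.csv"
    pd.DataFrame(rows).to_csv(cdf_path, index=False)

    # hair summaries
    rows = []
    for (village, metal), s in sorted(
        bundle.hair_summaries.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        rows.append(
            {
                "village": village, "metal": metal.value, "n": s.n,
                "detected_proportion": s.detected_proportion,
                "mean": "" if s.mean is None else s.mean,
                "sd": "" if s.sd is None else s.sd,
                "geometric_mean": "" if s.geometric_mean is None else s.geometric_mean,
            }
        )
    hair_path = out_dir / "hair_summary.csv"
    pd.DataFrame(
        rows,
        columns=["village", "metal", "n", "detected_proportion", "mean", "sd", "geometric_mean"],
    ).to_csv(hair_path, index=False)

    # manifest: config hash, versions, and the factor values actually used
    manifest = {
        "config_digest": config.digest(),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "villages": villages,
        "seed": config.mc.seed,
        "n_iterations": config.mc.n_iterations,
        "factors_used": {
            village: {
                name: {
                    "distribution": spec.distribution.value,
                    "mean": spec.mean, "sd": spec.sd, "units": spec.units,
                }
                for name, spec in sorted(bundle.models[village].factors.items())
            }
            for village in villages
        },
        "summaries": {
            village: bundle.mc[village].summary() for village in villages
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    bundle.manifest = manifest
    bundle.paths = {
        "hq_table": hq_path, "attribution": attr_path, "cdf": cdf_path,
        "hair_summary": hair_path, "manifest": manifest_path,
    }
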