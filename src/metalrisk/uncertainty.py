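"""Distribution fitting and Monte Carlo propagation of exposure uncertainty.

A village is described by a :class:`VillageModel`: concentration summaries
per (medium, metal), exposure-factor specifications, and toxicity
references. The same dose -> HQ -> aggregate chain is evaluated either once
at parameter means (:func:`point_estimate`) or vectorized over Monte Carlo
iterations (:func:`run_monte_carlo`), where every stochastic parameter and,
optionally, every concentration is drawn from its fitted distribution.

Sampling is vectorized over a single flattened, name-sorted parameter order,
so seed determinism does not depend on how the model was constructed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from . import dose_engine
from .exposure_model import (
    DEFAULT_PATHWAYS,
    Distribution,
    ExposureFactorSpec,
    Medium,
    MediumKind,
    Metal,
    Route,
    ConcentrationSummary,
    ToxRef,
)
from .risk_engine import HQMode, PathwayKey, RiskResult, aggregate_total
from .units import to_canonical

# ---------------------------------------------------------------------------
# distribution fitting


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with the given mean and sd.

    sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2, so the fitted
    distribution's arithmetic mean equals the input mean exactly.
    """
    if mean <= 0:
        raise ValueError(f"lognormal fit requires mean > 0, got {mean}")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _truncnorm_parent_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a zero-truncated normal with given post-truncation moments.

    Solved iteratively; the achieved moments match the targets to better than
    1e-6 relative error.
    """

    def residual(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a = (0.0 - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.fsolve(residual, [mean, math.log(max(sd, 1e-12))], full_output=True)
    params, _, ier, msg = sol
    if ier != 1:
        raise RuntimeError(f"truncated-normal moment matching failed: {msg}")
    mu, log_sigma = params
    return float(mu), float(math.exp(log_sigma))


def fit_distribution(
    mean: float,
    sd: float,
    kind: Distribution | str = Distribution.LOGNORMAL,
    name: str = "",
    units: str = "",
) -> ExposureFactorSpec:
    """Fit a parametric family to observed (mean, sd) moments.

    ``sd = 0`` degenerates to a fixed spec at the mean. The returned spec
    stores the observed-scale moments; the distribution parameters are
    rederived at sampling time.
    """
    if mean <= 0 and Distribution(kind) is Distribution.LOGNORMAL:
        raise ValueError("lognormal fit requires mean > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return ExposureFactorSpec(name=name, distribution=Distribution.FIXED, mean=mean, units=units)
    return ExposureFactorSpec(
        name=name, distribution=Distribution(kind), mean=mean, sd=sd, units=units
    )


def sample_spec(
    spec: ExposureFactorSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from a factor's fitted distribution."""
    if spec.is_fixed:
        return np.full(n, spec.mean)
    if spec.distribution is Distribution.LOGNORMAL:
        mu, sigma = lognormal_params(spec.mean, spec.sd)
        return rng.lognormal(mu, sigma, n)
    if spec.distribution is Distribution.NORMAL_TRUNCATED_AT_ZERO:
        mu, sigma = _truncnorm_parent_params(spec.mean, spec.sd)
        a = (0.0 - mu) / sigma
        return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)
    raise AssertionError(spec.distribution)


# ---------------------------------------------------------------------------
# village model and evaluation


@dataclass
class VillageModel:
    """Everything needed to evaluate the dose -> HQ chain for one village."""

    name: str
    concentrations: dict[tuple[Medium, Metal], ConcentrationSummary]
    factors: dict[str, ExposureFactorSpec]
    tox: dict[Metal, ToxRef]
    pathways: frozenset[tuple[MediumKind, Route]] = DEFAULT_PATHWAYS
    hq_mode: HQMode = HQMode.AUTO

    def factor(self, name: str) -> ExposureFactorSpec:
        try:
            return self.factors[name]
        except KeyError:
            raise ValueError(
                f"model {self.name!r} is missing exposure factor {name!r}"
            ) from None

    def abs_frac_name(self, metal: Metal) -> str:
        candidate = f"ABS_{metal.value}"
        return candidate if candidate in self.factors else "ABS_default"


@dataclass
class MonteCarloConfig:
    """Monte Carlo settings.

    ``stochastic``: names of exposure factors to sample; ``None`` means every
    factor whose spec is not fixed (the survey-derived set under the bundled
    defaults). ``concentration_mode`` is one of ``lognormal_from_summary``
    (default: concentrations drawn from a lognormal moment-matched to each
    summary), ``fixed_mean`` (held at summary means, for sensitivity runs),
    or ``empirical`` (bootstrap from raw sample values, which must be
    supplied to :func:`run_monte_carlo`).
    """

    seed: int
    n_iterations: int = 10_000
    stochastic: Optional[frozenset[str]] = None
    concentration_mode: str = "lognormal_from_summary"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.concentration_mode not in (
            "lognormal_from_summary",
            "fixed_mean",
            "empirical",
        ):
            raise ValueError(f"unknown concentration mode {self.concentration_mode!r}")
        if self.stochastic is not None:
            self.stochastic = frozenset(self.stochastic)


def _stochastic_set(model: VillageModel, config: MonteCarloConfig) -> frozenset[str]:
    if config.stochastic is not None:
        unknown = config.stochastic - set(model.factors)
        if unknown:
            raise ValueError(f"stochastic parameters not in model: {sorted(unknown)}")
        return config.stochastic
    return frozenset(n for n, s in model.factors.items() if not s.is_fixed)


def _food_intake_kg_per_day(model: VillageModel, item: str, values: Mapping[str, np.ndarray]):
    name = f"IR_{item}"
    spec = model.factor(name)
    raw = values[name]
    if spec.units in ("g/day", "kg/day"):
        factor, _ = to_canonical(1.0, spec.units)
        return raw * factor
    raise ValueError(f"food intake {name} has unsupported units {spec.units!r}")


def _evaluate_chain(
    model: VillageModel,
    factor_values: Mapping[str, np.ndarray],
    conc_values: Mapping[tuple[Medium, Metal], np.ndarray],
) -> dict[PathwayKey, np.ndarray]:
    """Vectorized dose -> HQ evaluation; one array entry per iteration."""
    fv = factor_values

    def g(name: str) -> np.ndarray:
        try:
            return fv[name]
        except KeyError:
            raise ValueError(
                f"model {model.name!r} is missing exposure factor {name!r}"
            ) from None

    bw = g("BW")
    ef = g("EF")
    ed = g("ED")

    _fracs: list[tuple[np.ndarray, np.ndarray]] = []

    def air_fractions() -> tuple[np.ndarray, np.ndarray]:
        # computed lazily: hour factors are only required for air pathways
        if not _fracs:
            h_in, h_out, h_sleep = (
                g("hours_indoor"), g("hours_outdoor"), g("hours_sleep")
            )
            accounted = h_in + h_out + h_sleep
            if np.any(accounted <= 0):
                raise ValueError("activity hours must sum to a positive value")
            _fracs.append(((h_in + h_sleep) / accounted, h_out / accounted))
        return _fracs[0]

    hq: dict[PathwayKey, np.ndarray] = {}
    for (medium, metal), conc in sorted(
        conc_values.items(), key=lambda kv: (kv[0][0].key, kv[0][1].value)
    ):
        tox = model.tox.get(metal)
        if tox is None:
            raise ValueError(f"no toxicity reference for {metal.value}")
        kind = medium.kind

        if kind is MediumKind.WATER:
            if (kind, Route.INGESTION) in model.pathways:
                adi = dose_engine.adi_intake(
                    conc, g("IR_water"), ef=ef, ed=ed, bw=bw
                )
                hq[(metal, medium, Route.INGESTION)] = adi / tox.rfd
            if (kind, Route.DERMAL) in model.pathways:
                adi = dose_engine.adi_dermal(
                    conc, g("SA_water"), g("AF_water"),
                    g(model.abs_frac_name(metal)), ef=ef, ed=ed, bw=bw,
                )
                hq[(metal, medium, Route.DERMAL)] = adi / tox.rfd
        elif kind is MediumKind.SOIL:
            if (kind, Route.INGESTION) in model.pathways:
                adi = dose_engine.adi_soil_ingestion(
                    conc, g("IR_soil"), ef=ef, ed=ed, bw=bw
                )
                hq[(metal, medium, Route.INGESTION)] = adi / tox.rfd
            if (kind, Route.DERMAL) in model.pathways:
                adi = dose_engine.adi_dermal(
                    conc, g("SA_soil"), g("AF_soil"),
                    g(model.abs_frac_name(metal)), ef=ef, ed=ed, bw=bw,
                )
                hq[(metal, medium, Route.DERMAL)] = adi / tox.rfd
        elif kind in (MediumKind.AIR_INDOOR, MediumKind.AIR_OUTDOOR):
            if (kind, Route.INHALATION) not in model.pathways:
                continue
            f_indoor, f_outdoor = air_fractions()
            frac = f_indoor if kind is MediumKind.AIR_INDOOR else f_outdoor
            c_term = conc * frac
            adi = dose_engine.adi_intake(c_term, g("IR_air"), ef=ef, ed=ed, bw=bw)
            ec = c_term  # EF*ED/AT = 1 under the chronic convention
            if model.hq_mode is HQMode.AUTO and tox.rfc is not None:
                hq[(metal, medium, Route.INHALATION)] = ec / tox.rfc
            else:
                hq[(metal, medium, Route.INHALATION)] = adi / tox.rfd
        elif kind is MediumKind.FOOD:
            if (kind, Route.INGESTION) not in model.pathways:
                continue
            ir = _food_intake_kg_per_day(model, medium.food_item, fv)
            adi = dose_engine.adi_intake(conc, ir, ef=ef, ed=ed, bw=bw)
            hq[(metal, medium, Route.INGESTION)] = adi / tox.rfd
        else:  # pragma: no cover
            raise AssertionError(kind)
    if not hq:
        raise ValueError(f"model {model.name!r} produced no pathway HQs")
    return hq


def _factor_values(
    model: VillageModel,
    n: int,
    rng: np.random.Generator,
    stochastic: frozenset[str],
) -> dict[str, np.ndarray]:
    values = {}
    for name in sorted(model.factors):
        spec = model.factors[name]
        if name in stochastic and not spec.is_fixed:
            values[name] = sample_spec(spec, n, rng)
        else:
            values[name] = np.full(n, spec.mean)
    return values


def _concentration_values(
    model: VillageModel,
    n: int,
    rng: np.random.Generator,
    mode: str,
    raw_samples: Optional[Mapping[tuple[Medium, Metal], Sequence[float]]] = None,
) -> dict[tuple[Medium, Metal], np.ndarray]:
    values = {}
    for key in sorted(model.concentrations, key=lambda k: (k[0].key, k[1].value)):
        summ = model.concentrations[key]
        if mode == "empirical":
            if raw_samples is None or key not in raw_samples:
                raise ValueError(
                    f"empirical concentration mode needs raw samples for "
                    f"({key[0].key}, {key[1].value})"
                )
            pool = np.asarray(raw_samples[key], dtype=float)
            values[key] = rng.choice(pool, size=n, replace=True)
        elif mode == "fixed_mean" or summ.sd == 0 or summ.mean == 0:
            values[key] = np.full(n, summ.mean)
        elif mode == "lognormal_from_summary":
            mu, sigma = lognormal_params(summ.mean, summ.sd)
            values[key] = rng.lognormal(mu, sigma, n)
        else:  # pragma: no cover
            raise AssertionError(mode)
    return values


# ---------------------------------------------------------------------------
# results


@dataclass
class HQDistribution:
    """Sampled HQ distributions for one village.

    ``total`` holds one total-HQ value per iteration; ``per_metal`` the
    marginal per-metal totals; ``per_pathway_mean`` the mean HQ of every
    (metal, medium, route) term, which is what pathway attribution uses.
    """

    village: str
    total: np.ndarray
    per_metal: dict[Metal, np.ndarray]
    per_pathway_mean: dict[PathwayKey, float]
    n_iterations: int
    seed: int

    PERCENTILES = (2.5, 5.0, 25.0, 50.0, 75.0, 95.0, 97.5)

    def summary(self, samples: Optional[np.ndarray] = None) -> dict[str, float]:
        """Summary statistics; percentiles use linear order-statistic interpolation."""
        x = self.total if samples is None else np.asarray(samples)
        out = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            "min": float(np.min(x)),
            "max": float(np.max(x)),
        }
        for p, q in zip(self.PERCENTILES, np.percentile(x, self.PERCENTILES)):
            out[f"p{p:g}"] = float(q)
        return out

    def metal_summary(self, metal: Metal) -> dict[str, float]:
        return self.summary(self.per_metal[metal])

    def mean_result(self) -> RiskResult:
        """RiskResult built from mean pathway HQs (the attribution default)."""
        return aggregate_total(self.per_pathway_mean, village=self.village)


def run_monte_carlo(
    model: VillageModel,
    config: MonteCarloConfig,
    raw_concentration_samples: Optional[
        Mapping[tuple[Medium, Metal], Sequence[float]]
    ] = None,
) -> HQDistribution:
    """Propagate parameter and concentration uncertainty to HQ distributions.

    Each iteration draws one value per stochastic parameter and (in the
    default mode) per concentration cell, evaluates the full chain, and
    records per-pathway, per-metal and total HQs. Identical model + config
    (and seed) give identical output.
    """
    n = config.n_iterations
    rng = np.random.default_rng(config.seed)
    stochastic = _stochastic_set(model, config)
    fv = _factor_values(model, n, rng, stochastic)
    cv = _concentration_values(
        model, n, rng, config.concentration_mode, raw_concentration_samples
    )
    hq = _evaluate_chain(model, fv, cv)

    per_metal: dict[Metal, np.ndarray] = {}
    for (metal, _, _), arr in hq.items():
        per_metal[metal] = per_metal.get(metal, 0.0) + arr
    total = sum(per_metal.values())
    return HQDistribution(
        village=model.name,
        total=np.asarray(total),
        per_metal=per_metal,
        per_pathway_mean={k: float(np.mean(v)) for k, v in hq.items()},
        n_iterations=n,
        seed=config.seed,
    )


def point_estimate(model: VillageModel) -> RiskResult:
    """Deterministic evaluation of the chain at every parameter's mean.

    Equals :func:`run_monte_carlo` output exactly when all parameters are
    fixed and concentrations use their means.
    """
    fv = {name: np.array([spec.mean]) for name, spec in model.factors.items()}
    cv = {
        key: np.array([summ.mean]) for key, summ in model.concentrations.items()
    }
    hq = _evaluate_chain(model, fv, cv)
    return aggregate_total(
        {k: float(v[0]) for k, v in hq.items()}, village=model.name
    )


def closed_form_mean(model: VillageModel, config: MonteCarloConfig) -> float:
    """Analytic E[total HQ] under independent lognormal sampling.

    Every pathway HQ has the form k * C * IR / BW (or k * C for RfC-based
    inhalation), a product of independent factors, so its expectation is the
    product of expectations; for lognormal BW, E[1/BW] = (1 + cv^2) / mean.
    Raises if the stochastic set contains activity hours (the indoor/outdoor
    time fractions are ratios, which have no product-form mean) or a
    non-lognormal body weight.
    """
    stochastic = _stochastic_set(model, config)
    for name in ("hours_indoor", "hours_outdoor", "hours_sleep"):
        if name in stochastic and not model.factor(name).is_fixed:
            raise ValueError(
                "closed-form mean undefined with stochastic activity hours"
            )
    fv = {name: np.array([spec.mean]) for name, spec in model.factors.items()}
    bw_spec = model.factor("BW")
    if "BW" in stochastic and not bw_spec.is_fixed:
        if bw_spec.distribution is not Distribution.LOGNORMAL:
            raise ValueError("closed-form mean requires lognormal body weight")
        cv2 = (bw_spec.sd / bw_spec.mean) ** 2
        # substitute the harmonic-effective weight so k/BW_eff = k * E[1/BW]
        fv["BW"] = np.array([bw_spec.mean / (1.0 + cv2)])
    conc = {k: np.array([s.mean]) for k, s in model.concentrations.items()}
    hq = _evaluate_chain(model, fv, conc)
    return float(sum(v[0] for v in hq.values()))


def empirical_cdf(samples: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF: sorted values and cumulative probabilities.

    Returns ``(x, p)`` with ``p[i] = (i + 1) / n``; the step function is 0
    below ``x[0]`` and 1 at and above ``x[-1]``.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    if x.size == 0:
        raise ValueError("empirical CDF of an empty sample is undefined")
    p = np.arange(1, x.size + 1) / x.size
    return x, p


def ecdf_at(samples: Sequence[float], value: float) -> float:
    """Evaluate the empirical CDF at ``value`` (fraction of samples <= value)."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empirical CDF of an empty sample is undefined")
    return float(np.mean(x <= value))
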