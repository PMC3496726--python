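"""Distribution fitting, Monte Carlo propagation and the empirical CDF."""

import math

import numpy as np
import pytest

from metalrisk.exposure_model import Distribution, Metal, food
from metalrisk.uncertainty import (
    MonteCarloConfig,
    VillageModel,
    closed_form_mean,
    ecdf_at,
    empirical_cdf,
    fit_distribution,
    lognormal_params,
    point_estimate,
    run_monte_carlo,
    sample_spec,
)

from conftest import fixed_factors, make_summary


@pytest.fixture()
def pakchoi_model(tox):
    """Single-pathway model: lead in pakchoi only."""
    medium = food("pakchoi")
    return VillageModel(
        name="pakchoi-only",
        concentrations={(medium, Metal.PB): make_summary(medium, Metal.PB, 0.24)},
        factors=fixed_factors(),
        tox=tox,
    )


class TestFitDistribution:
    def test_body_weight_lognormal_parameters(self):
        mu, sigma = lognormal_params(62.58, 10.23)
        assert mu == pytest.approx(4.1233, abs=2e-4)
        assert sigma == pytest.approx(0.1624, abs=2e-4)

    def test_zero_sd_degenerates_to_fixed(self):
        spec = fit_distribution(62.58, 0.0, name="BW")
        assert spec.distribution is Distribution.FIXED

    def test_lognormal_sample_mean_recovers_target(self):
        spec = fit_distribution(62.58, 10.23, name="BW")
        rng = np.random.default_rng(11)
        draws = sample_spec(spec, 400_000, rng)
        se = 10.23 / math.sqrt(draws.size)
        assert abs(draws.mean() - 62.58) < 3 * se

    def test_truncated_normal_moments_match(self):
        # heavy truncation case: mean close to zero relative to sd
        spec = fit_distribution(1.0, 0.8, Distribution.NORMAL_TRUNCATED_AT_ZERO, name="x")
        rng = np.random.default_rng(5)
        draws = sample_spec(spec, 400_000, rng)
        assert draws.min() > 0
        assert draws.mean() == pytest.approx(1.0, abs=3 * 0.8 / math.sqrt(draws.size))
        assert draws.std(ddof=1) == pytest.approx(0.8, rel=0.02)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_distribution(-1.0, 1.0)
        with pytest.raises(ValueError):
            fit_distribution(1.0, -0.5)


class TestPointEstimate:
    def test_single_pathway_worked_value(self, pakchoi_model):
        result = point_estimate(pakchoi_model)
        assert result.total_hq == pytest.approx(4.705, rel=1e-3)

    def test_additivity_of_added_pathway(self, pakchoi_model, tox):
        from metalrisk.exposure_model import SOIL

        base = point_estimate(pakchoi_model).total_hq
        conc = dict(pakchoi_model.concentrations)
        conc[(SOIL, Metal.PB)] = make_summary(SOIL, Metal.PB, 1000.0)
        bigger = VillageModel(
            name="x", concentrations=conc, factors=pakchoi_model.factors,
            tox=pakchoi_model.tox,
        )
        soil_only = VillageModel(
            name="y",
            concentrations={(SOIL, Metal.PB): conc[(SOIL, Metal.PB)]},
            factors=pakchoi_model.factors, tox=pakchoi_model.tox,
        )
        assert point_estimate(bigger).total_hq == pytest.approx(
            base + point_estimate(soil_only).total_hq, rel=1e-12
        )

    def test_missing_factor_error_names_gap(self, pakchoi_model, tox):
        factors = {
            k: v for k, v in pakchoi_model.factors.items() if k != "IR_pakchoi"
        }
        broken = VillageModel(
            name="broken", concentrations=pakchoi_model.concentrations,
            factors=factors, tox=tox,
        )
        with pytest.raises(ValueError, match="IR_pakchoi"):
            point_estimate(broken)


class TestMonteCarlo:
    def test_all_fixed_collapses_to_point_estimate(self, pakchoi_model):
        cfg = MonteCarloConfig(seed=3, n_iterations=50, stochastic=frozenset(),
                               concentration_mode="fixed_mean")
        dist = run_monte_carlo(pakchoi_model, cfg)
        pe = point_estimate(pakchoi_model).total_hq
        assert np.all(dist.total == dist.total[0])
        assert dist.total[0] == pytest.approx(pe, rel=1e-12)
        assert dist.summary()["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_seed_determinism(self, v1_model):
        cfg = MonteCarloConfig(seed=42, n_iterations=2000)
        a = run_monte_carlo(v1_model, cfg)
        b = run_monte_carlo(v1_model, cfg)
        assert np.array_equal(a.total, b.total)
        assert a.per_pathway_mean == b.per_pathway_mean
        c = run_monte_carlo(v1_model, MonteCarloConfig(seed=43, n_iterations=2000))
        assert not np.array_equal(a.total, c.total)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_bw_only_matches_closed_form(self, v1_model, seed):
        """With lognormal body weight as the only stochastic input, the MC
        mean must agree with the analytic E[HQ] = sum k E[X] E[1/BW]."""
        cfg = MonteCarloConfig(
            seed=seed, n_iterations=10_000, stochastic=frozenset({"BW"}),
            concentration_mode="fixed_mean",
        )
        dist = run_monte_carlo(v1_model, cfg)
        analytic = closed_form_mean(v1_model, cfg)
        se = dist.total.std(ddof=1) / math.sqrt(dist.total.size)
        assert abs(dist.total.mean() - analytic) < 4 * se

    def test_jensen_mc_mean_at_least_point_estimate(self, v1_model):
        cfg = MonteCarloConfig(
            seed=9, n_iterations=20_000, stochastic=frozenset({"BW"}),
            concentration_mode="fixed_mean",
        )
        dist = run_monte_carlo(v1_model, cfg)
        assert dist.total.mean() >= point_estimate(v1_model).total_hq

    def test_doubling_concentration_doubles_pathwise(self, v1_model, tox):
        cfg = MonteCarloConfig(seed=17, n_iterations=500)
        base = run_monte_carlo(v1_model, cfg)
        doubled_conc = {}
        for key, s in v1_model.concentrations.items():
            doubled_conc[key] = make_summary(
                key[0], key[1], 2 * s.mean, sd=2 * s.sd, village=s.village, n=s.n
            )
        doubled_model = VillageModel(
            name=v1_model.name, concentrations=doubled_conc,
            factors=v1_model.factors, tox=tox,
        )
        doubled = run_monte_carlo(doubled_model, cfg)
        np.testing.assert_allclose(doubled.total, 2 * base.total, rtol=1e-10)

    def test_closed_form_refuses_stochastic_hours(self, v1_model):
        cfg = MonteCarloConfig(seed=1, stochastic=frozenset({"hours_indoor"}))
        with pytest.raises(ValueError, match="hours"):
            closed_form_mean(v1_model, cfg)

    def test_empirical_mode_needs_samples(self, pakchoi_model):
        cfg = MonteCarloConfig(seed=1, n_iterations=10,
                               concentration_mode="empirical")
        with pytest.raises(ValueError, match="raw samples"):
            run_monte_carlo(pakchoi_model, cfg)
        pool = {(food("pakchoi"), Metal.PB): [0.2, 0.24, 0.3]}
        dist = run_monte_carlo(pakchoi_model, cfg, raw_concentration_samples=pool)
        assert set(np.round(np.unique(dist.total * 62.58 * 1.4e-4 / 0.17176), 6)) <= {
            0.2, 0.24, 0.3
        }

    def test_summary_consistent_with_samples(self, v1_model):
        dist = run_monte_carlo(v1_model, MonteCarloConfig(seed=2, n_iterations=3000))
        s = dist.summary()
        assert s["min"] <= s["p2.5"] <= s["p50"] <= s["p97.5"] <= s["max"]
        assert s["mean"] == pytest.approx(float(dist.total.mean()))
        # marginals recombine to the total, iteration by iteration
        recombined = sum(dist.per_metal.values())
        np.testing.assert_allclose(recombined, dist.total, rtol=1e-12)


class TestEmpiricalCdf:
    def test_small_sample_values(self):
        x, p = empirical_cdf([3, 1, 2])
        assert list(x) == [1, 2, 3]
        assert list(p) == pytest.approx([1 / 3, 2 / 3, 1.0])
        assert ecdf_at([3, 1, 2], 2) == pytest.approx(2 / 3)
        assert ecdf_at([3, 1, 2], 0.999) == 0.0
        assert ecdf_at([3, 1, 2], 3) == 1.0

    def test_median_of_lognormal(self):
        rng = np.random.default_rng(8)
        draws = rng.lognormal(0.0, 1.0, 10_000)
        # binomial error bound at the median
        assert abs(ecdf_at(draws, 1.0) - 0.5) < 3 * math.sqrt(0.25 / 10_000)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            empirical_cdf([])
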