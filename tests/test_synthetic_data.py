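"""Synthetic-data generators and the profile calibration."""

import math

import numpy as np
import pytest

from metalrisk.biomonitor import summarize_hair
from metalrisk.exposure_model import (
    AIR_OUTDOOR,
    SOIL,
    Metal,
    substitute_below_lod,
    summarize_concentrations,
    food,
)
from metalrisk.synthetic_data import (
    TABLE3_HQ_MEAN,
    ConcentrationCell,
    HairCell,
    VillageProfile,
    build_model,
    calibrate_concentrations,
    generate_concentrations,
    generate_hair,
    generate_survey,
    lod_for_detection_rate,
    unit_hq_table,
    village_profile,
)
from metalrisk.uncertainty import point_estimate


def tiny_profile(**kwargs):
    defaults = dict(
        name="T",
        concentrations={
            (SOIL, Metal.PB): ConcentrationCell(mean=2507.0, cv=0.3, n=5000)
        },
        survey={
            "BW": (62.58, 10.23),
            "hours_indoor": (8.47, 3.99),
            "hours_outdoor": (5.84, 3.98),
            "hours_sleep": (9.24, 2.14),
            "IR_water": (1.88, 0.62),
            "ED": (35.35, 18.68),
            "IR_pakchoi": (171.76, 82.74),
        },
        hair={Metal.ZN: HairCell(240.0, 72.0, 0.25)},
        n_participants=10_000,
        n_hair=2_000,
    )
    defaults.update(kwargs)
    return VillageProfile(**defaults)


class TestGenerateSurvey:
    def test_fixed_seed_reproducible(self):
        p = tiny_profile(n_participants=50)
        a = generate_survey(p, seed=5)
        b = generate_survey(p, seed=5)
        assert [(r.body_weight, r.hours_indoor) for r in a] == [
            (r.body_weight, r.hours_indoor) for r in b
        ]

    def test_sample_means_recover_targets(self):
        p = tiny_profile()
        records = generate_survey(p, seed=1)
        bw = np.array([r.body_weight for r in records])
        assert abs(bw.mean() - 62.58) < 3 * 10.23 / math.sqrt(bw.size)
        pak = np.array([r.food_intake["pakchoi"] for r in records])
        assert abs(pak.mean() - 171.76) < 3 * 82.74 / math.sqrt(pak.size)
        # hour means are exact in expectation under the Dirichlet construction
        for field, target in (
            ("hours_indoor", 8.47), ("hours_outdoor", 5.84), ("hours_sleep", 9.24)
        ):
            h = np.array([getattr(r, field) for r in records])
            assert abs(h.mean() - target) < 3 * h.std(ddof=1) / math.sqrt(h.size)

    def test_every_record_respects_24_hour_day(self):
        records = generate_survey(tiny_profile(n_participants=2000), seed=2)
        for r in records:
            assert r.hours_indoor + r.hours_outdoor + r.hours_sleep <= 24 + 1e-9

    def test_zero_sd_profile_is_constant(self):
        survey = {k: (m, 0.0) for k, (m, _) in tiny_profile().survey.items()}
        records = generate_survey(tiny_profile(survey=survey, n_participants=5), seed=3)
        assert len({r.body_weight for r in records}) == 1
        assert len({r.hours_indoor for r in records}) == 1

    def test_infeasible_hours_raise(self):
        survey = dict(tiny_profile().survey)
        survey["hours_indoor"] = (20.0, 1.0)
        with pytest.raises(ValueError, match="> 24"):
            tiny_profile(survey=survey)


class TestGenerateConcentrations:
    def test_soil_lead_mean_recovery(self):
        records = generate_concentrations(tiny_profile(), seed=4)
        values = np.array([r.value for r in substitute_below_lod(records)])
        se = 0.3 * 2507.0 / math.sqrt(values.size)
        assert abs(values.mean() - 2507.0) < 3 * se

    def test_detection_rate_targeting(self):
        cell = ConcentrationCell(
            mean=4.2e-3, cv=0.3, n=1000, target_detection_rate=0.938
        )
        p = tiny_profile(concentrations={(AIR_OUTDOOR, Metal.ZN): cell})
        records = generate_concentrations(p, seed=6)
        rate = np.mean([not r.censored for r in records])
        assert abs(rate - 0.938) < 3 * math.sqrt(0.938 * 0.062 / 1000)

    def test_zero_lod_means_no_censoring(self):
        cell = ConcentrationCell(mean=1.0, cv=1.0, n=500, lod=0.0)
        p = tiny_profile(concentrations={(SOIL, Metal.CD): cell})
        records = generate_concentrations(p, seed=7)
        assert not any(r.censored for r in records)

    def test_censor_flags_consistent_with_lod(self):
        cell = ConcentrationCell(mean=0.03, cv=0.5, n=2000, lod=0.02)
        p = tiny_profile(concentrations={(food("rice"), Metal.HG): cell})
        records = generate_concentrations(p, seed=8)
        assert all((r.value == 0.0) == r.censored or r.value >= r.lod for r in records)
        assert any(r.censored for r in records)

    def test_inconsistent_cell_raises(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ConcentrationCell(mean=1.0, lod=2.0, target_detection_rate=1.0)

    def test_fixed_seed_reproducible(self):
        p = tiny_profile()
        a = generate_concentrations(p, seed=9)
        b = generate_concentrations(p, seed=9)
        assert [r.value for r in a] == [r.value for r in b]

    def test_lod_quantile_placement(self):
        # the LOD sits at the (1 - rate) quantile of the lognormal
        lod = lod_for_detection_rate(4.2e-3, 0.3, 0.938)
        assert 0 < lod < 4.2e-3
        assert lod == pytest.approx(2.56e-3, rel=0.01)


class TestGenerateHair:
    def test_silver_pattern_all_censored(self):
        p = tiny_profile(hair={Metal.AG: HairCell(0.025, 0.0075, 0.05)}, n_hair=500)
        records = generate_hair(p, seed=10)
        rate = np.mean([not r.censored for r in records])
        assert rate < 0.05
        (s,) = summarize_hair(records).values()
        assert s.detected_proportion < 0.05

    def test_zinc_geometric_mean_recovery(self):
        p = tiny_profile()
        records = generate_hair(p, seed=11)
        (s,) = summarize_hair(records).values()
        # GM of the generating lognormal: mean / sqrt(1 + cv^2)
        cv = 72.0 / 240.0
        target_gm = 240.0 / math.sqrt(1 + cv**2)
        log_sd = math.sqrt(math.log(1 + cv**2))
        se = target_gm * log_sd / math.sqrt(len(records))
        assert abs(s.geometric_mean - target_gm) < 3 * se

    def test_fixed_seed_reproducible(self):
        p = tiny_profile(n_hair=30)
        assert [r.value for r in generate_hair(p, 12)] == [
            r.value for r in generate_hair(p, 12)
        ]


class TestCalibration:
    @pytest.mark.parametrize("village", ["V1", "V2", "V3"])
    def test_profile_point_estimate_matches_hq_targets(self, village):
        """The bundled profiles are calibrated so the point-estimate chain
        reproduces the published per-metal mean HQs."""
        result = point_estimate(build_model(village_profile(village)))
        for metal, target in TABLE3_HQ_MEAN[village].items():
            assert result.hq_by_metal[metal] == pytest.approx(target, rel=1e-9)

    def test_anchored_cells_keep_printed_values(self, v1_profile):
        assert v1_profile.concentrations[(SOIL, Metal.PB)].mean == 2507.0
        assert v1_profile.concentrations[(food("pakchoi"), Metal.PB)].mean == 0.24

    def test_overshooting_anchor_rejected(self, factors, tox):
        unit = unit_hq_table(factors, tox)
        with pytest.raises(ValueError, match="anchor"):
            calibrate_concentrations(
                {Metal.PB: 1.0},
                {(SOIL, Metal.PB): 2507.0},  # alone worth ~6.6 HQ
                {Metal.PB: {"water": 1.0}},
                unit,
            )

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError, match="unknown profile"):
            village_profile("V9")

    def test_end_to_end_parameter_recovery(self, v1_profile):
        """generate -> substitute -> summarize -> point estimate lands near
        the profile-implied point estimate (finite-sample media noise only)."""
        records = generate_concentrations(v1_profile, seed=13)
        summaries = summarize_concentrations(substitute_below_lod(records))
        model = build_model(v1_profile)
        realized = {
            (medium, metal): s.mean
            for (v, medium, metal), s in summaries.items()
        }
        implied = point_estimate(model).total_hq
        # rebuild the model with realized means
        conc = {
            key: type(s)(
                village=s.village, medium=s.medium, metal=s.metal,
                mean=realized[(s.medium, s.metal)], sd=s.sd, n=s.n,
                detection_rate=s.detection_rate,
            )
            for key, s in model.concentrations.items()
        }
        realized_total = point_estimate(
            type(model)(
                name=model.name, concentrations=conc,
                factors=model.factors, tox=model.tox,
            )
        ).total_hq
        # cv 0.3 with n >= 5 per cell: the realized total stays within ~15%
        assert realized_total == pytest.approx(implied, rel=0.15)
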