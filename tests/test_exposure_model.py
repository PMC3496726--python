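"""Domain types, censoring substitution, summaries and time-weighted air."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metalrisk.exposure_model import (
    AIR_INDOOR,
    SOIL,
    WATER,
    CensoringPolicy,
    ConcentrationRecord,
    ExposureFactorSpec,
    Medium,
    MediumKind,
    Metal,
    SurveyRecord,
    ToxRef,
    food,
    substitute_below_lod,
    summarize_concentrations,
    time_weighted_air,
    validate_tox_table,
)
from metalrisk.units import UnitError, check_intake_compatible, to_canonical


def rec(value=1.0, censored=False, lod=None, medium=SOIL, metal=Metal.PB):
    return ConcentrationRecord(
        village="V", medium=medium, metal=metal, value=value,
        censored=censored, lod=lod,
    )


class TestDomainTypes:
    def test_metal_closed_enumeration(self):
        assert Metal.parse("Pb") is Metal.PB
        with pytest.raises(ValueError, match="unknown metal"):
            Metal.parse("Fe")

    def test_food_item_present_iff_food(self):
        assert food("pakchoi").key == "food:pakchoi"
        with pytest.raises(ValueError):
            Medium(MediumKind.FOOD)  # missing label
        with pytest.raises(ValueError):
            Medium(MediumKind.SOIL, "rice")  # spurious label

    def test_medium_key_round_trip(self):
        for m in (WATER, SOIL, AIR_INDOOR, food("egg")):
            assert Medium.parse(m.key) == m

    def test_survey_record_rejects_impossible_hours(self):
        with pytest.raises(ValueError, match="> 24"):
            SurveyRecord(
                participant="p", village="V", body_weight=60,
                hours_indoor=12, hours_outdoor=8, hours_sleep=9,
                water_ingestion=2, exposure_duration=30,
            )

    def test_factor_spec_validation(self):
        with pytest.raises(ValueError):
            ExposureFactorSpec(name="BW", distribution="lognormal", mean=-1, sd=1)
        with pytest.raises(ValueError):
            ExposureFactorSpec(name="EF", distribution="fixed", mean=365, sd=3)
        spec = ExposureFactorSpec(name="BW", distribution="lognormal", mean=60, sd=0)
        assert spec.is_fixed

    def test_tox_table_requires_all_metals(self, tox):
        validate_tox_table(tox)
        incomplete = {m: t for m, t in tox.items() if m is not Metal.PB}
        with pytest.raises(ValueError, match="Pb"):
            validate_tox_table(incomplete)
        with pytest.raises(ValueError):
            ToxRef(metal=Metal.PB, rfd=0.0)


class TestCensoringSubstitution:
    @pytest.mark.parametrize(
        "policy, expected",
        [("half_lod", 0.025), ("zero", 0.0), ("lod", 0.05)],
    )
    def test_policies(self, policy, expected):
        (out,) = substitute_below_lod([rec(censored=True, lod=0.05)], policy)
        assert out.value == pytest.approx(expected)
        assert out.censored  # flag preserved for detection-rate accounting

    def test_uncensored_unchanged_and_order_preserved(self):
        records = [rec(value=3.0), rec(censored=True, lod=0.1), rec(value=7.0)]
        out = substitute_below_lod(records)
        assert [r.value for r in out] == [3.0, 0.05, 7.0]

    def test_idempotent(self):
        records = [rec(censored=True, lod=0.05), rec(value=2.0)]
        once = substitute_below_lod(records)
        twice = substitute_below_lod(once)
        assert [r.value for r in twice] == [r.value for r in once]

    def test_unusable_lod_raises(self):
        bad = rec(value=1.0)
        bad.censored = True  # bypass constructor validation
        with pytest.raises(ValueError, match="lod"):
            substitute_below_lod([bad])

    def test_detection_rate_fifteen_of_sixteen(self):
        records = [rec(value=1.0) for _ in range(15)] + [
            rec(censored=True, lod=0.05)
        ]
        summary = summarize_concentrations(substitute_below_lod(records))
        (s,) = summary.values()
        assert s.detection_rate == pytest.approx(15 / 16)
        assert round(100 * s.detection_rate, 1) == 93.8


class TestSummaries:
    def test_constant_group(self):
        s = summarize_concentrations([rec(value=2.0) for _ in range(3)])
        (summ,) = s.values()
        assert (summ.mean, summ.sd, summ.detection_rate) == (2.0, 0.0, 1.0)

    def test_two_point_sample_sd(self):
        (summ,) = summarize_concentrations([rec(value=1.0), rec(value=3.0)]).values()
        assert summ.mean == pytest.approx(2.0)
        assert summ.sd == pytest.approx(math.sqrt(2))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarize_concentrations([])

    def test_groups_keyed_by_village_medium_metal(self):
        records = [
            rec(value=1.0),
            rec(value=2.0, medium=WATER, metal=Metal.CD),
        ]
        assert len(summarize_concentrations(records)) == 2


class TestTimeWeightedAir:
    @given(
        c=st.floats(0, 1e3),
        h=st.tuples(st.floats(0, 24), st.floats(0, 24), st.floats(0, 24)),
    )
    @settings(max_examples=50, deadline=None)
    def test_equal_concentrations_are_invariant(self, c, h):
        if sum(h) <= 0:
            return
        tw = time_weighted_air(c, c, *h)
        assert tw.value == pytest.approx(c, rel=1e-9, abs=1e-12)

    @given(
        c_in=st.floats(0, 1e3),
        c_out=st.floats(0, 1e3),
        h=st.tuples(
            st.floats(0.01, 24), st.floats(0.01, 24), st.floats(0.01, 24)
        ),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_inputs(self, c_in, c_out, h):
        tw = time_weighted_air(c_in, c_out, *h)
        lo, hi = min(c_in, c_out), max(c_in, c_out)
        assert lo - 1e-9 <= tw.value <= hi + 1e-9
        assert tw.value == pytest.approx(tw.indoor_term + tw.outdoor_term)

    def test_lead_air_mix(self):
        # indoor 2.1, outdoor 2.4 ug/m3 with surveyed activity hours
        tw = time_weighted_air(2.1, 2.4, 8.47, 5.84, 9.24)
        assert tw.value == pytest.approx(2.174, abs=5e-4)

    def test_mercury_air_mix(self):
        tw = time_weighted_air(734, 543, 8.47, 5.84, 9.24)
        assert tw.value == pytest.approx(686.6, abs=0.05)
        # sleep is indoor time
        assert tw.f_indoor == pytest.approx((8.47 + 9.24) / 23.55)

    def test_zero_hours_raise(self):
        with pytest.raises(ValueError):
            time_weighted_air(1.0, 1.0, 0, 0, 0)


class TestUnits:
    def test_prefix_conversions(self):
        assert to_canonical(734, "ng/m3") == pytest.approx((7.34e-4, "mg/m3"))
        assert to_canonical(171.76, "g/day") == pytest.approx((0.17176, "kg/day"))

    def test_unknown_unit_raises(self):
        with pytest.raises(UnitError, match="unknown unit"):
            to_canonical(1.0, "ppm")

    def test_incompatible_pair_raises(self):
        with pytest.raises(UnitError, match="not compatible"):
            check_intake_compatible("mg/L", "kg/day")
        check_intake_compatible("ug/m3", "m3/day")  # compatible after prefix
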