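"""Emission equations, GWP conversion and baseline interpolation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landfillch4 import (
    AnnualSeries,
    CH4_PER_C,
    ConfigurationError,
    FODParameters,
    GWPConvention,
    TAMEParameters,
    Unit,
    ValidationError,
    WasteRecord,
    YearRangeError,
    baseline_series,
    co2e_from_mass,
    compute_fod,
    compute_tame,
    interpolate_baseline,
    mass_from_co2e,
)

fractions = st.floats(0.0, 1.0, allow_nan=False)
masses = st.floats(0.0, 1e4, allow_nan=False)


class TestTame:
    def test_single_site_hand_product(self):
        records = [WasteRecord("a", 2022, 100.0)]
        params = {"a": TAMEParameters(fdoc=0.15, fd=0.5, mef=1.0, cr=16 / 12)}
        assert compute_tame(records, params) == pytest.approx(10.0)

    def test_zero_waste_gives_zero(self):
        records = [WasteRecord(s, 2022, 0.0) for s in "ab"]
        params = {s: TAMEParameters(fdoc=0.2, fd=0.5) for s in "ab"}
        assert compute_tame(records, params) == 0.0

    def test_recovery_cancels_gross_term(self):
        records = [WasteRecord("a", 2022, 100.0)]
        params = {"a": TAMEParameters(fdoc=0.15, fd=0.5, mr=10.0)}
        assert compute_tame(records, params) == pytest.approx(0.0)

    def test_excess_recovery_floored_at_zero_with_warning(self, caplog):
        records = [
            WasteRecord("a", 2022, 100.0),
            WasteRecord("b", 2022, 100.0),
        ]
        params = {
            "a": TAMEParameters(fdoc=0.15, fd=0.5, mr=999.0),  # would be negative
            "b": TAMEParameters(fdoc=0.15, fd=0.5),
        }
        with caplog.at_level("WARNING"):
            total = compute_tame(records, params)
        assert total == pytest.approx(10.0)  # site a contributes 0, not -989
        assert "flooring" in caplog.text

    def test_missing_site_parameters_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="no TAME parameters"):
            compute_tame([WasteRecord("x", 2022, 1.0)], {})

    def test_mixed_years_rejected(self):
        records = [WasteRecord("a", 2022, 1.0), WasteRecord("a", 2023, 1.0)]
        with pytest.raises(ValidationError, match="multiple years"):
            compute_tame(records, {"a": TAMEParameters(fdoc=0.1, fd=0.5)})

    @settings(max_examples=50, derandomize=True)
    @given(msw=masses, fdoc=fractions, fd=fractions, scale=st.floats(0.0, 10.0))
    def test_homogeneous_in_waste_mass(self, msw, fdoc, fd, scale):
        params = {"a": TAMEParameters(fdoc=fdoc, fd=fd)}
        base = compute_tame([WasteRecord("a", 2022, msw)], params)
        scaled = compute_tame([WasteRecord("a", 2022, msw * scale)], params)
        assert scaled == pytest.approx(scale * base, abs=1e-9)


class TestFod:
    def test_single_year_hand_product(self):
        params = FODParameters(mcf=1.0, doc=0.15, docf=0.5, f=0.5)
        assert compute_fod({2022: 100.0}, params) == pytest.approx(5.0)

    def test_oxidation_scales_result(self):
        base = FODParameters(mcf=1.0, doc=0.15, docf=0.5, f=0.5)
        oxed = FODParameters(mcf=1.0, doc=0.15, docf=0.5, f=0.5, ox=0.1)
        result = compute_fod({2022: 100.0}, oxed)
        assert result == pytest.approx(0.9 * compute_fod({2022: 100.0}, base))
        assert result == pytest.approx(4.5)

    def test_full_recovery_emits_nothing(self):
        params = FODParameters(mcf=0.8, doc=0.2, docf=0.6, r=1.0)
        assert compute_fod({2020: 50.0, 2021: 70.0}, params) == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mcf": 0.3, "doc": 0.1, "docf": 0.5},  # below management floor
            {"mcf": 1.1, "doc": 0.1, "docf": 0.5},
            {"mcf": 0.5, "doc": 1.5, "docf": 0.5},
            {"mcf": 0.5, "doc": 0.1, "docf": 0.5, "r": -0.1},
        ],
    )
    def test_out_of_bounds_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            FODParameters(**kwargs)

    def test_negative_deposit_rejected(self):
        params = FODParameters(mcf=0.5, doc=0.1, docf=0.5)
        with pytest.raises(ValidationError):
            compute_fod({2022: -1.0}, params)

    @settings(max_examples=60, derandomize=True)
    @given(
        deposits=st.dictionaries(st.integers(2000, 2050), masses, min_size=1, max_size=10),
        mcf=st.floats(0.4, 1.0),
        doc=fractions,
        docf=fractions,
        f=fractions,
        r=fractions,
        ox=fractions,
    )
    def test_matches_per_year_loop_oracle(self, deposits, mcf, doc, docf, f, r, ox):
        """Mass-balance form equals an explicit per-year-term summation."""
        params = FODParameters(mcf=mcf, doc=doc, docf=docf, f=f, r=r, ox=ox)
        oracle = sum(
            m * mcf * doc * docf * f * (16 / 12) * (1 - r) * (1 - ox)
            for m in deposits.values()
        )
        assert compute_fod(deposits, params) == pytest.approx(oracle, rel=1e-12, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(
        mcf=st.floats(0.4, 1.0), doc=st.floats(0.01, 1.0),
        docf=st.floats(0.01, 1.0), f=st.floats(0.01, 1.0),
        r=st.floats(0.0, 0.99), ox=st.floats(0.0, 0.99),
        bump=st.floats(1e-6, 0.3),
    )
    def test_monotone_in_each_parameter(self, mcf, doc, docf, f, r, ox, bump):
        """Emissions fall as R/OX rise and rise with MCF, DOC, DOCf, F."""
        deposits = {2022: 100.0}
        base = compute_fod(deposits, FODParameters(mcf, doc, docf, f, r, ox))

        def emitted(**override):
            kw = dict(mcf=mcf, doc=doc, docf=docf, f=f, r=r, ox=ox)
            kw.update(override)
            return compute_fod(deposits, FODParameters(**kw))

        assert emitted(r=min(1.0, r + bump)) <= base
        assert emitted(ox=min(1.0, ox + bump)) <= base
        assert emitted(mcf=min(1.0, mcf + bump)) >= base
        assert emitted(doc=min(1.0, doc + bump)) >= base
        assert emitted(docf=min(1.0, docf + bump)) >= base
        assert emitted(f=min(1.0, f + bump)) >= base

    @settings(max_examples=40, derandomize=True)
    @given(
        deposits=st.dictionaries(st.integers(2000, 2050), masses, min_size=1, max_size=10),
        scale=st.floats(0.0, 10.0),
    )
    def test_homogeneous_in_waste_mass(self, deposits, scale):
        params = FODParameters(mcf=0.8, doc=0.15, docf=0.5)
        base = compute_fod(deposits, params)
        scaled = compute_fod({y: m * scale for y, m in deposits.items()}, params)
        assert scaled == pytest.approx(scale * base, abs=1e-9)


class TestGwpConversion:
    def test_printed_2022_mass(self):
        mass = mass_from_co2e(4317.58, GWPConvention(factor=25))
        assert mass == pytest.approx(172.7032)
        assert round(mass) == 173

    def test_printed_2050_mass_exceeds_310(self):
        mass = mass_from_co2e(7769.88, GWPConvention(factor=25))
        assert mass == pytest.approx(310.7952)
        assert mass > 310

    def test_unit_factor_is_identity(self):
        gwp = GWPConvention(factor=1)
        assert co2e_from_mass(42.0, gwp) == 42.0

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValidationError):
            GWPConvention(factor=0)

    @settings(max_examples=50, derandomize=True)
    @given(mass=masses, factor=st.floats(1e-3, 1e3))
    def test_conversion_roundtrip_is_identity(self, mass, factor):
        gwp = GWPConvention(factor=factor)
        assert mass_from_co2e(co2e_from_mass(mass, gwp), gwp) == pytest.approx(
            mass, rel=1e-12, abs=1e-12
        )


class TestBaselineInterpolation:
    @pytest.fixture
    def anchors(self, bundle):
        return bundle.table4_baseline

    @pytest.mark.parametrize("mode", ["geometric", "linear"])
    def test_anchor_years_pass_through_exactly(self, anchors, mode):
        for year, value in anchors:
            assert interpolate_baseline(anchors, year, mode) == value

    def test_geometric_midpoint_is_geometric_mean(self):
        anchors = AnnualSeries(Unit.KT_CO2E, {2022: 4317.58, 2030: 5028.02})
        expected = math.sqrt(4317.58 * 5028.02)  # 4659.28
        assert interpolate_baseline(anchors, 2026, "geometric") == pytest.approx(expected)
        assert expected == pytest.approx(4659.28, abs=0.005)

    def test_equal_anchors_give_constant_interior(self):
        anchors = AnnualSeries(Unit.KT_CO2E, {2020: 5.0, 2030: 5.0})
        for year in range(2020, 2031):
            assert interpolate_baseline(anchors, year, "geometric") == pytest.approx(5.0)
            assert interpolate_baseline(anchors, year, "linear") == pytest.approx(5.0)

    def test_no_extrapolation(self, anchors):
        with pytest.raises(YearRangeError):
            interpolate_baseline(anchors, 2021)
        with pytest.raises(YearRangeError):
            interpolate_baseline(anchors, 2051)

    def test_unknown_mode_rejected(self, anchors):
        with pytest.raises(ConfigurationError):
            interpolate_baseline(anchors, 2025, "cubic")

    def test_densified_series_monotone_between_rising_anchors(self, anchors):
        dense = baseline_series(anchors)
        assert dense.years == tuple(range(2022, 2051))
        values = dense.values
        assert all(a < b for a, b in zip(values, values[1:]))
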