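"""Curation rules: preference indices, unit conversions, normalization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from odoratlas.errors import (
    MissingMolecularWeightError,
    MissingReferenceError,
    RangeError,
    UndefinedIndexError,
    UnmappedOdorantError,
)
from odoratlas.records import Concentration, OdorantIdentity
from odoratlas.standardize import (
    canonicalize_odorant,
    compute_preference_index,
    convert_concentration,
    convert_percent_metric,
    normalize_eag,
    round_concentration_decade,
    subtract_background,
)

from conftest import make_records


class TestCanonicalization:
    def test_common_names_map_to_one_identity(self, synonyms):
        # isoamyl alcohol / isopentyl alcohol / isopentanol are all the
        # same alcohol under different common names
        ident = canonicalize_odorant("isopentanol", synonyms)
        assert ident.canonical_name == "3-methyl-1-butanol"
        for variant in ("isoamyl alcohol", "Isopentyl  Alcohol", "ISOPENTANOL"):
            assert canonicalize_odorant(variant, synonyms) is ident

    def test_case_and_whitespace_insensitive(self, synonyms):
        ident = canonicalize_odorant("3-Methyl-1-Butanol ", synonyms)
        assert ident.canonical_name == "3-methyl-1-butanol"

    def test_unknown_name_raises(self, synonyms):
        with pytest.raises(UnmappedOdorantError):
            canonicalize_odorant("odorant-xyz-unknown", synonyms)


class TestPreferenceIndex:
    @pytest.mark.parametrize(
        "n_test,n_control,expected", [(75, 25, 0.5), (40, 40, 0.0), (0, 50, -1.0)]
    )
    def test_two_choice_formula(self, n_test, n_control, expected):
        assert compute_preference_index(n_test, n_control) == expected

    def test_no_choices_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            compute_preference_index(0, 0)

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=200, derandomize=True)
    def test_bounded_and_antisymmetric(self, a, b):
        if a + b == 0:
            return
        pi = compute_preference_index(a, b)
        assert -1.0 <= pi <= 1.0
        assert compute_preference_index(b, a) == pytest.approx(-pi)


class TestPercentMetrics:
    @pytest.mark.parametrize(
        "kind,value,expected",
        [
            ("percent_attraction", 75, 0.5),   # agrees with counts (75, 25)
            ("percent_attraction", 50, 0.0),   # indifference
            ("percent_repellency", 100, -1.0),  # total repellency
            ("protective_efficacy", 100, -1.0),
        ],
    )
    def test_linear_maps(self, kind, value, expected):
        assert convert_percent_metric(kind, value) == pytest.approx(expected)

    @pytest.mark.parametrize("value", [-1, 101])
    def test_out_of_range_rejected(self, value):
        with pytest.raises(RangeError):
            convert_percent_metric("percent_attraction", value)


class TestConcentrationConversion:
    def test_molarity_worked_example(self):
        # 1.11e-5 M lactic acid (MW 90.08) reported as 1e-6 g/mL
        lactic = OdorantIdentity("lactic acid", molecular_weight=90.08)
        out = convert_concentration(Concentration(1.11e-5, "molar"), lactic)
        assert out.unit_kind == "wv_g_per_ml"
        assert out.value == pytest.approx(1e-6, rel=1e-3)
        assert round_concentration_decade(out.value) == 1e-6

    def test_ppm_is_mg_per_l(self):
        out = convert_concentration(Concentration(1.0, "ppm"))
        assert out.unit_kind == "wv_g_per_ml"
        assert out.value == 1e-6  # 1 mg/L

    def test_mass_per_area_with_volume(self):
        # 1e-6 g/cm^2 over 6.6 cm^2 dissolved into 0.025 mL
        conc = Concentration(1e-6, "mass_per_area_with_volume", aux=(6.6, 0.025))
        out = convert_concentration(conc)
        assert out.value == pytest.approx(2.64e-4)
        assert out.unit_kind == "wv_g_per_ml"

    def test_molar_without_mw_raises(self):
        anon = OdorantIdentity("mystery")
        with pytest.raises(MissingMolecularWeightError):
            convert_concentration(Concentration(1.0, "molar"), anon)

    def test_dimensional_consistency(self):
        # 1 M of a MW-1000 compound is exactly 1 g/mL
        heavy = OdorantIdentity("heavy", molecular_weight=1000.0)
        assert convert_concentration(Concentration(1.0, "molar"), heavy).value == 1.0

    def test_fractions_and_dry_pass_through(self):
        for kind in ("vv_fraction", "wv_g_per_ml", "dry_amount_g"):
            conc = Concentration(0.01, kind)
            assert convert_concentration(conc) is conc

    def test_negative_aux_rejected(self):
        with pytest.raises(RangeError):
            Concentration(1e-6, "mass_per_area_with_volume", aux=(-6.6, 0.025))


class TestBackgroundSubtraction:
    @pytest.mark.parametrize(
        "odor,solvent,flag,expected",
        [(50, 10, False, 40), (5, 10, False, -5), (40, 10, True, 40)],
    )
    def test_subtract_and_idempotence(self, odor, solvent, flag, expected):
        assert subtract_background(odor, solvent, flag) == expected


class TestEagNormalization:
    def _eag(self, rows):
        return make_records(
            [
                {"data_type": "EAG", "technique": "eag", "response_unit": "mV", **r}
                for r in rows
            ]
        )

    def test_divides_by_reference_mean(self):
        df = self._eag(
            [
                {"odorant_canonical": "1-octen-3-ol", "response_value": 2.0},
                {"odorant_canonical": "odorant-A", "response_value": 1.0},
            ]
        )
        out = normalize_eag(df, "1-octen-3-ol")
        assert list(out["response_value"]) == [1.0, 0.5]
        assert set(out["eag_reference"]) == {"1-octen-3-ol"}

    def test_idempotent_on_flagged_records(self):
        df = self._eag(
            [
                {"odorant_canonical": "1-octen-3-ol", "response_value": 1.0,
                 "eag_reference": "1-octen-3-ol"},
                {"odorant_canonical": "odorant-A", "response_value": 0.5,
                 "eag_reference": "1-octen-3-ol"},
            ]
        )
        pd.testing.assert_frame_equal(normalize_eag(df, "1-octen-3-ol"), df)

    def test_missing_reference_raises(self):
        df = self._eag([{"odorant_canonical": "odorant-A", "response_value": 1.0}])
        with pytest.raises(MissingReferenceError):
            normalize_eag(df, "1-octen-3-ol")

    def test_zero_reference_raises(self):
        df = self._eag(
            [{"odorant_canonical": "1-octen-3-ol", "response_value": 0.0}]
        )
        with pytest.raises(ZeroDivisionError):
            normalize_eag(df, "1-octen-3-ol")


class TestDecadeRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (3e-3, 1e-3),    # log10 = -2.52 -> -3
            (1e-2, 1e-2),    # fixed point
            (9e-3, 1e-2),    # log10 = -2.046 -> -2
            (10 ** -2.5, 1e-3),  # half-case rounds to the lower exponent
        ],
    )
    def test_nearest_power_of_ten(self, value, expected):
        assert round_concentration_decade(value) == pytest.approx(expected)

    @pytest.mark.parametrize("value", [0.0, -1e-3, math.inf])
    def test_domain_errors(self, value):
        with pytest.raises(RangeError):
            round_concentration_decade(value)

    @given(st.floats(min_value=1e-12, max_value=1e3))
    @settings(max_examples=200, derandomize=True)
    def test_idempotent(self, c):
        once = round_concentration_decade(c)
        assert round_concentration_decade(once) == once
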