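"""Constitutive relations: vial heat transfer, cake resistance, ice vapor
pressure, frozen length, capability line and unit conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lyosim import (
    EquipmentCapability,
    Formulation,
    HeatTransferModel,
    InvalidInputError,
    UnitError,
    VialGeometry,
    convert_units,
    equipment_capability_rate,
    ice_vapor_pressure,
    initial_frozen_length,
    kv_of_pressure,
    rp_of_cake_length,
    sublimation_temperature,
)
from lyosim.errors import ConfigError


class TestVialGeometry:
    def test_areas_from_diameters(self, vial_6r):
        assert vial_6r.av == pytest.approx(math.pi * 1.1**2)
        assert vial_6r.ap == pytest.approx(math.pi * 1.0**2)
        assert vial_6r.av >= vial_6r.ap > 0

    def test_inverted_diameters_rejected(self):
        with pytest.raises(InvalidInputError):
            VialGeometry(outer_diameter=20.0, inner_diameter=22.0)


class TestKvOfPressure:
    @pytest.mark.parametrize(
        "kc, kp, kd, pch, expected",
        [
            # Schott 6R coefficients reproduce the 300 mTorr calibration value
            (2.75e-4, 8.93e-4, 0.46, 0.3, 5.10e-4),
            # 5800W coefficients at 100 mTorr
            (2.64e-4, 33.2e-4, 3.64, 0.1, 5.07e-4),
        ],
    )
    def test_pressure_curve_values(self, kc, kp, kd, pch, expected):
        kv = kv_of_pressure(HeatTransferModel(kc=kc, kp=kp, kd=kd), pch)
        assert kv == pytest.approx(expected, rel=5e-3)

    def test_zero_pressure_limit_is_kc(self):
        model = HeatTransferModel(kc=3.3e-4, kp=9e-4, kd=0.5)
        assert kv_of_pressure(model, 0.0) == pytest.approx(3.3e-4)

    def test_fixed_variant_ignores_pressure(self):
        model = HeatTransferModel(fixed_kv=5.1e-4)
        assert kv_of_pressure(model, 0.05) == kv_of_pressure(model, 1.5) == 5.1e-4

    def test_negative_pressure_rejected(self, htm_6r):
        with pytest.raises(InvalidInputError):
            kv_of_pressure(htm_6r, -0.1)

    def test_both_variants_at_once_rejected(self):
        with pytest.raises(InvalidInputError):
            HeatTransferModel(kc=1e-4, kp=1e-4, kd=1.0, fixed_kv=5e-4)

    @settings(max_examples=50, derandomize=True)
    @given(
        kc=st.floats(1e-5, 1e-3),
        kp=st.floats(1e-5, 1e-2),
        kd=st.floats(0.01, 30.0),
        p1=st.floats(0.0, 2.0),
        p2=st.floats(0.0, 2.0),
    )
    def test_monotone_and_bounded(self, kc, kp, kd, p1, p2):
        model = HeatTransferModel(kc=kc, kp=kp, kd=kd)
        lo, hi = sorted((p1, p2))
        assert kv_of_pressure(model, lo) <= kv_of_pressure(model, hi) + 1e-18
        assert kv_of_pressure(model, hi) <= kc + kp / kd + 1e-18


class TestRpOfCakeLength:
    @pytest.mark.parametrize(
        "form_kwargs, lck, expected",
        [
            (dict(r0=1.4, a1=16.0, a2=0.0, rho_solute=1.52), 0.0, 1.4),
            (dict(r0=1.4, a1=16.0, a2=0.0, rho_solute=1.52), 0.35, 7.0),
            (dict(r0=0.208, a1=15.29, a2=1.6, rho_solute=1.587), 0.5, 4.455),
        ],
    )
    def test_values(self, form_kwargs, lck, expected):
        form = Formulation(csolid=0.05, **form_kwargs)
        assert rp_of_cake_length(form, lck) == pytest.approx(expected, rel=1e-3)

    def test_negative_length_rejected(self, mannitol):
        with pytest.raises(InvalidInputError):
            rp_of_cake_length(mannitol, -0.1)

    @settings(max_examples=50, derandomize=True)
    @given(
        r0=st.floats(0.1, 5.0),
        a1=st.floats(0.0, 50.0),
        a2=st.floats(0.0, 10.0),
    )
    def test_nondecreasing_and_concave(self, r0, a1, a2):
        form = Formulation(csolid=0.05, r0=r0, a1=a1, a2=a2, rho_solute=1.5)
        grid = np.linspace(0.0, 2.0, 41)
        rp = rp_of_cake_length(form, grid)
        assert np.all(np.diff(rp) >= -1e-12)
        assert np.all(rp >= r0 - 1e-12)
        # second differences nonpositive: saturating growth
        assert np.all(np.diff(rp, 2) <= 1e-12)


class TestIceVaporPressure:
    def test_triple_point(self):
        # must agree with the ice triple-point pressure 4.58 Torr within 1%
        assert ice_vapor_pressure(273.15) == pytest.approx(4.58, rel=0.01)

    def test_strictly_increasing(self):
        assert ice_vapor_pressure(250.0) < ice_vapor_pressure(260.0)

    def test_low_temperature_limit(self):
        with pytest.warns(UserWarning):
            assert ice_vapor_pressure(140.0) < 1e-8

    def test_inverse_round_trip(self):
        for t in (230.0, 250.0, 270.0):
            assert sublimation_temperature(ice_vapor_pressure(t)) == pytest.approx(t, rel=1e-12)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(InvalidInputError):
            ice_vapor_pressure(0.0)


class TestInitialFrozenLength:
    def test_hand_computed_value(self):
        form = Formulation(csolid=0.05, r0=1.0, a1=0.0, a2=0.0, rho_solute=1.52)
        ap = math.pi
        expected = 2.0 / (ap * 0.918) * (1.0 - 0.05 * (1.0 - 0.918) / 1.52)
        got = initial_frozen_length(2.0, form, ap)
        assert got == pytest.approx(expected, rel=1e-6)
        assert got == pytest.approx(0.6915, abs=2e-4)

    def test_pure_ice_fill(self):
        form = Formulation(csolid=0.0, r0=1.0, a1=0.0, a2=0.0, rho_solute=1.5,
                           rho_solution=0.918, rho_ice=0.918)
        assert initial_frozen_length(3.0, form, 2.0) == pytest.approx(1.5)

    def test_linear_in_fill_volume(self, mannitol):
        one = initial_frozen_length(1.0, mannitol, math.pi)
        two = initial_frozen_length(2.0, mannitol, math.pi)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_zero_area_rejected(self, mannitol):
        with pytest.raises(InvalidInputError):
            initial_frozen_length(2.0, mannitol, 0.0)


class TestEquipmentCapability:
    def test_line(self):
        cap = EquipmentCapability(a=0.1, b=2.0)
        assert equipment_capability_rate(cap, 0.15) == pytest.approx(0.4)
        assert equipment_capability_rate(EquipmentCapability(), 0.5) == 0.0

    def test_disabled_is_unbounded(self):
        assert math.isinf(equipment_capability_rate(EquipmentCapability.unbounded(), 0.3))

    def test_negative_line_is_config_error(self):
        with pytest.raises(ConfigError):
            equipment_capability_rate(EquipmentCapability(a=-1.0, b=0.1), 0.2)


class TestUnitConversions:
    @pytest.mark.parametrize(
        "value, from_unit, to_unit, expected",
        [
            # dual-unit pairs as tabulated for the Schott 6R coefficients
            (2.75e-4, "cal/(s K cm2)", "W/(m2 K)", 11.51),
            (8.93e-4, "cal/(s K cm2 Torr)", "W/(m2 K Pa)", 0.28),
            (0.46, "1/Torr", "1/Pa", 3.45e-3),
            (300.0, "mTorr", "Torr", 0.3),
            (0.15, "Torr", "Pa", 20.0),
            (25.0, "C", "K", 298.15),
        ],
    )
    def test_known_pairs(self, value, from_unit, to_unit, expected):
        assert convert_units(value, from_unit, to_unit) == pytest.approx(expected, rel=5e-3)

    @settings(max_examples=30, derandomize=True)
    @given(
        value=st.floats(1e-6, 1e6),
        pair=st.sampled_from(
            [
                ("Torr", "Pa"),
                ("mTorr", "Torr"),
                ("cal/(s K cm2)", "W/(m2 K)"),
                ("1/Torr", "1/Pa"),
                ("kg/h", "g/h"),
                ("C", "K"),
                ("g/(cm2 h)", "kg/(m2 h)"),
            ]
        ),
    )
    def test_round_trip_identity(self, value, pair):
        a, b = pair
        back = convert_units(convert_units(value, a, b), b, a)
        assert back == pytest.approx(value, rel=1e-12, abs=1e-12)

    def test_unsupported_pair_lists_families(self):
        with pytest.raises(UnitError, match="supported"):
            convert_units(1.0, "Torr", "C")
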