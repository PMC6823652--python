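"""Quasi-steady primary-drying solver: balance closure, oracles, limits,
conservation and convergence."""

import dataclasses
import math

import numpy as np
import pytest

from lyosim import (
    DryingConfig,
    Formulation,
    HeatTransferModel,
    InvalidInputError,
    Schedule,
    kv_of_pressure,
    quasi_steady_solve,
    rp_of_cake_length,
    simulate_primary_drying,
    simulate_primary_drying_by_divisions,
)
from lyosim.models import S_PER_H, T_ZERO_C


def bisection_oracle(lck, lpr0, tsh, pch, config, tol=1e-10):
    """Independent brute-force bisection on the balance residual in Tsub,
    written against the raw three-way balance (not the series-conductance
    form used by the solver)."""
    c = config.constants
    kv_av = kv_of_pressure(config.htm, pch) * S_PER_H * config.vial.av
    kice_ap = c.k_ice * S_PER_H * config.vial.ap
    rp = rp_of_cake_length(config.form, lck)
    dhs_ap = c.dhs * config.vial.ap
    lpr = lpr0 - lck
    tsh_k = tsh + T_ZERO_C

    def tbot_of(tsub_k):
        # Kv leg = conduction leg, solved for Tbot
        return (kv_av * tsh_k + kice_ap / lpr * tsub_k) / (kv_av + kice_ap / lpr)

    def residual(tsub_k):
        q_heat = kv_av * (tsh_k - tbot_of(tsub_k))
        p_sub = c.vp_a * math.exp(-c.vp_b / tsub_k)
        return q_heat - dhs_ap * (p_sub - pch) / rp

    lo, hi = 150.0, tsh_k
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    tsub_k = 0.5 * (lo + hi)
    p_sub = c.vp_a * math.exp(-c.vp_b / tsub_k)
    return tsub_k - T_ZERO_C, tbot_of(tsub_k) - T_ZERO_C, (p_sub - pch) / rp


def balance_legs(state, lck, lpr0, tsh, pch, config):
    """The three heat-flow expressions, cal/h."""
    c = config.constants
    kv_av = kv_of_pressure(config.htm, pch) * S_PER_H * config.vial.av
    kice_ap = c.k_ice * S_PER_H * config.vial.ap
    rp = rp_of_cake_length(config.form, lck)
    q1 = kv_av * (tsh - state.t_bot)
    lpr = lpr0 - lck
    q2 = kice_ap * (state.t_bot - state.t_sub) / lpr if lpr > 1e-9 else q1
    q3 = c.dhs * config.vial.ap * (state.p_sub - pch) / rp
    return q1, q2, q3


class TestQuasiSteadySolve:
    def test_matches_bisection_oracle(self, mannitol_config):
        """Fresh cake, 6R mannitol conditions: solver and the independent
        bisection oracle agree to 1e-6."""
        lpr0 = mannitol_config.lpr0
        state = quasi_steady_solve(0.0, lpr0, -5.0, 0.3, mannitol_config)
        tsub_o, tbot_o, flux_o = bisection_oracle(0.0, lpr0, -5.0, 0.3, mannitol_config)
        assert state.t_sub == pytest.approx(tsub_o, abs=1e-6)
        assert state.t_bot == pytest.approx(tbot_o, abs=1e-6)
        assert state.flux == pytest.approx(flux_o, rel=1e-6)

    @pytest.mark.parametrize("lck_frac", [0.0, 0.25, 0.5, 0.9])
    def test_three_way_balance(self, mannitol_curve_config, lck_frac):
        cfg = mannitol_curve_config
        lpr0 = cfg.lpr0
        state = quasi_steady_solve(lck_frac * lpr0, lpr0, -5.0, 0.15, cfg)
        q1, q2, q3 = balance_legs(state, lck_frac * lpr0, lpr0, -5.0, 0.15, cfg)
        assert q2 == pytest.approx(q1, rel=1e-9)
        assert q3 == pytest.approx(q1, rel=1e-9)

    def test_insulated_front_limit(self, vial_6r, mannitol_config):
        """Enormous cake resistance: flux vanishes and the product
        equilibrates with the shelf."""
        huge_rp = Formulation(csolid=0.05, r0=1e9, a1=0.0, a2=0.0, rho_solute=1.52)
        cfg = dataclasses.replace(mannitol_config, form=huge_rp)
        state = quasi_steady_solve(0.0, cfg.lpr0, -5.0, 0.3, cfg)
        assert state.flux == pytest.approx(0.0, abs=1e-8)
        assert state.t_bot == pytest.approx(-5.0, abs=1e-3)

    def test_vanishing_frozen_layer(self, mannitol_config):
        lpr0 = mannitol_config.lpr0
        state = quasi_steady_solve(lpr0, lpr0, -5.0, 0.3, mannitol_config)
        assert state.t_bot == pytest.approx(state.t_sub, abs=1e-9)

    def test_cold_shelf_no_sublimation(self, mannitol_config):
        state = quasi_steady_solve(0.0, mannitol_config.lpr0, -60.0, 0.3, mannitol_config)
        assert state.flux == 0.0

    def test_cake_beyond_product_rejected(self, mannitol_config):
        with pytest.raises(InvalidInputError):
            quasi_steady_solve(1.0, 0.5, -5.0, 0.3, mannitol_config)


class TestSimulatePrimaryDrying:
    def test_balance_holds_at_every_step(self, mannitol_curve_config):
        cfg = mannitol_curve_config
        res = simulate_primary_drying(cfg)
        for i in range(0, len(res.time) - 1, 25):
            state = quasi_steady_solve(res.lck[i], res.lpr0, res.tsh[i], res.pch[i], cfg)
            q1, q2, q3 = balance_legs(state, res.lck[i], res.lpr0, res.tsh[i], res.pch[i], cfg)
            assert q2 == pytest.approx(q1, rel=1e-9)
            assert q3 == pytest.approx(q1, rel=1e-9)

    def test_mass_conservation(self, mannitol_config):
        res = simulate_primary_drying(mannitol_config)
        dt_steps = np.diff(res.time)
        sublimated = np.sum(res.flux[:-1] * dt_steps)
        assert sublimated == pytest.approx(
            mannitol_config.form.rho_ice * res.lpr0, rel=1e-9
        )

    def test_cake_monotone_and_complete(self, mannitol_config):
        res = simulate_primary_drying(mannitol_config)
        assert np.all(np.diff(res.lck) >= 0)
        assert res.lck[0] == 0.0
        assert res.lck[-1] == pytest.approx(res.lpr0)
        # reported drying time is the interpolated endpoint, quoted to 1e-3 h
        assert res.drying_time == pytest.approx(res.time[-1], abs=5e-4)

    def test_flux_nonincreasing_under_constant_setpoints(self, mannitol_config):
        res = simulate_primary_drying(mannitol_config)
        assert np.all(np.diff(res.flux) <= 1e-12)

    def test_drying_time_decreases_with_shelf_temperature(self, mannitol_config):
        times, maxima = [], []
        for tsh in (-10.0, -5.0, 0.0):
            cfg = dataclasses.replace(mannitol_config, shelf=Schedule.constant(tsh))
            res = simulate_primary_drying(cfg)
            times.append(res.drying_time)
            maxima.append(res.max_t_bot)
        assert times[0] > times[1] > times[2]
        assert maxima[0] <= maxima[1] <= maxima[2]

    def test_drying_time_decreases_with_kv(self, mannitol_config):
        def time_at(kv):
            cfg = dataclasses.replace(mannitol_config, htm=HeatTransferModel(fixed_kv=kv))
            return simulate_primary_drying(cfg).drying_time

        assert time_at(3e-4) > time_at(5e-4) > time_at(8e-4)

    def test_small_fill_dries_fast(self, mannitol_config):
        cfg = dataclasses.replace(mannitol_config, vfill=0.01, dt=0.001)
        assert simulate_primary_drying(cfg).drying_time < 0.1

    def test_cold_start_errors(self, mannitol_config):
        cfg = dataclasses.replace(mannitol_config, shelf=Schedule.constant(-80.0))
        with pytest.raises(InvalidInputError, match="cannot start"):
            simulate_primary_drying(cfg)


class TestDivisionsScheme:
    def test_single_division_is_rectangle_rule(self, mannitol_config):
        res = simulate_primary_drying_by_divisions(mannitol_config, 1)
        state = quasi_steady_solve(0.0, res.lpr0, -5.0, 0.3, mannitol_config)
        expected = res.lpr0 * mannitol_config.form.rho_ice / state.flux
        assert res.drying_time == pytest.approx(expected, abs=1e-3)

    def test_converges_to_time_stepping(self, mannitol_config):
        cfg = dataclasses.replace(mannitol_config, dt=0.01)
        fine = simulate_primary_drying(cfg).drying_time
        by_div = simulate_primary_drying_by_divisions(cfg, 10_000).drying_time
        assert by_div == pytest.approx(fine, rel=5e-3)

    def test_coarse_divisions_underestimate(self, mannitol_config):
        t10 = simulate_primary_drying_by_divisions(mannitol_config, 10).drying_time
        t100 = simulate_primary_drying_by_divisions(mannitol_config, 100).drying_time
        assert t10 < t100

    def test_invalid_division_count(self, mannitol_config):
        with pytest.raises(InvalidInputError):
            simulate_primary_drying_by_divisions(mannitol_config, 0)
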