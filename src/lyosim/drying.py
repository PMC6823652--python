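"""1D quasi-steady primary-drying simulator.

At each instant the moving sublimation front at temperature ``Tsub`` and the
vial bottom at ``Tbot`` satisfy a three-way heat-flow balance: the heat
delivered from the shelf through the vial bottom equals the heat conducted
through the remaining frozen layer equals the heat consumed by sublimation
driven by the vapor-pressure difference across the dried cake,

    Q = Kv*Av*(Tsh - Tbot)
      = k_ice*Ap*(Tbot - Tsub) / Lpr
      = dHs*Ap*(Psub(Tsub) - Pch) / Rp(Lck),

with ``Lpr = Lpr0 - Lck`` the frozen thickness.  Because the first two legs
are conductances in series, ``Tbot`` can be eliminated, leaving one monotone
scalar equation in ``Tsub`` which is solved by bracketed root finding.  The
front then advances by ``dLck = flux*dt/rho_ice`` and the balance is re-solved
until the cake reaches the initial frozen length.

Heat-transfer coefficients and the ice conductivity are tabulated per second;
internally they are rescaled to per-hour so that fluxes (g/cm^2/h), the cake
resistance (cm^2 h Torr/g) and time steps (h) combine without stray factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InvalidInputError, SolverError
from .models import (
    DEFAULT_CONSTANTS,
    Formulation,
    HeatTransferModel,
    PhysicalConstants,
    S_PER_H,
    T_ZERO_C,
    VialGeometry,
    initial_frozen_length,
    kv_of_pressure,
    rp_of_cake_length,
    sublimation_temperature,
)
from .schedule import Schedule

#: frozen thicknesses below this (cm) are treated as fully dried
_LPR_EPS = 1e-9
#: relative tolerance demanded of the three-way balance
_BALANCE_RTOL = 1e-9


def _pvap(t_k: float, c: PhysicalConstants) -> float:
    # Bare correlation, no range warning: the root finder brackets from the
    # shelf temperature, which may legitimately sit far above the ice range.
    return c.vp_a * math.exp(-c.vp_b / t_k)


@dataclass(frozen=True)
class DryingConfig:
    """Everything needed to simulate primary drying of one vial batch."""

    vial: VialGeometry
    form: Formulation
    htm: HeatTransferModel
    vfill: float  # mL per vial
    shelf: Schedule  # Tsh(t), degC
    pressure: Schedule  # Pch(t), Torr
    constants: PhysicalConstants = DEFAULT_CONSTANTS
    n_vials: int = 1
    dt: float = 0.05  # h

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidInputError("time step must be positive")
        if self.n_vials < 1:
            raise InvalidInputError("n_vials must be at least 1")
        if self.vfill <= 0:
            raise InvalidInputError("fill volume must be positive")

    @property
    def lpr0(self) -> float:
        """Initial frozen-product length, cm."""
        return initial_frozen_length(self.vfill, self.form, self.vial.ap)


@dataclass(frozen=True)
class QuasiSteadyState:
    """Solution of the instantaneous heat/mass balance."""

    t_sub: float  # sublimation-front temperature, degC
    t_bot: float  # vial-bottom product temperature, degC
    p_sub: float  # vapor pressure at the front, Torr
    flux: float  # sublimation mass flux, g/cm^2/h
    q_dot: float  # heat flow, cal/h


@dataclass
class DryingTimeSeries:
    """Per-step record of a primary-drying run."""

    time: np.ndarray  # h
    lck: np.ndarray  # cm
    t_sub: np.ndarray  # degC
    t_bot: np.ndarray  # degC
    flux: np.ndarray  # g/cm^2/h
    tsh: np.ndarray  # degC
    pch: np.ndarray  # Torr
    lpr0: float  # cm
    drying_time: float  # h

    @property
    def max_t_bot(self) -> float:
        return float(np.max(self.t_bot))

    @property
    def mean_t_bot(self) -> float:
        return float(np.mean(self.t_bot))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time,
                "Lck_cm": self.lck,
                "Tsub_C": self.t_sub,
                "Tbot_C": self.t_bot,
                "flux_kg_h_m2": self.flux * 10.0,
                "Pch_Torr": self.pch,
                "Tsh_C": self.tsh,
            }
        )


def _per_hour_coefficients(config: DryingConfig, pch: float) -> tuple[float, float]:
    """(Kv*Av, k_ice*Ap) rescaled to cal/h K."""
    kv = kv_of_pressure(config.htm, pch)
    return kv * S_PER_H * config.vial.av, config.constants.k_ice * S_PER_H * config.vial.ap


def quasi_steady_solve(
    lck: float, lpr0: float, tsh: float, pch: float, config: DryingConfig
) -> QuasiSteadyState:
    """Solve the three-way heat-flow balance at cake length ``lck``.

    Returns the no-sublimation fixed point (zero flux, product equilibrated
    with the shelf) when the shelf is too cold to push the front vapor
    pressure above the chamber pressure.
    """
    if not 0.0 <= lck <= lpr0 + _LPR_EPS:
        raise InvalidInputError(f"cake length {lck} outside [0, {lpr0}]")
    c = config.constants
    kv_av, kice_ap = _per_hour_coefficients(config, pch)
    lpr = max(lpr0 - lck, 0.0)
    rp = rp_of_cake_length(config.form, lck)
    dhs_ap = c.dhs * config.vial.ap
    tsh_k = tsh + T_ZERO_C

    # Series conductance from shelf to front; the conduction leg drops out
    # when the frozen layer has vanished.
    if lpr < _LPR_EPS:
        u = kv_av
    else:
        u = 1.0 / (1.0 / kv_av + lpr / kice_ap)

    if pch > 0.0 and _pvap(tsh_k, c) <= pch:
        # Even a front equilibrated with the shelf cannot sublime.
        return QuasiSteadyState(
            t_sub=tsh, t_bot=tsh, p_sub=_pvap(tsh_k, c), flux=0.0, q_dot=0.0
        )

    def residual(t_sub_k: float) -> float:
        return u * (tsh_k - t_sub_k) - dhs_ap * (_pvap(t_sub_k, c) - pch) / rp

    lo = tsh_k - 80.0
    while residual(lo) < 0.0:
        lo -= 40.0
        if lo < 120.0:
            raise SolverError(
                f"no bracket for the front temperature below the shelf at "
                f"Tsh={tsh} C, Pch={pch} Torr, Lck={lck} cm"
            )
    t_sub_k = brentq(residual, lo, tsh_k, xtol=1e-12, rtol=8.9e-16)
    p_sub = _pvap(t_sub_k, c)
    q_dot = u * (tsh_k - t_sub_k)
    t_bot_k = tsh_k - q_dot / kv_av
    flux = (p_sub - pch) / rp
    if flux < 0.0:
        flux, q_dot = 0.0, 0.0
        t_sub_k = t_bot_k = tsh_k
    return QuasiSteadyState(
        t_sub=t_sub_k - T_ZERO_C,
        t_bot=t_bot_k - T_ZERO_C,
        p_sub=p_sub,
        flux=flux,
        q_dot=q_dot,
    )


def solve_pinned_bottom(
    lck: float, lpr0: float, t_bot: float, pch: float, config: DryingConfig
) -> tuple[QuasiSteadyState, float]:
    """Solve the balance with the vial-bottom temperature pinned (the critical
    product-temperature isotherm): the conduction and sublimation legs fix
    ``Tsub`` and the flux, and the shelf temperature required to deliver that
    heat is backed out of the Kv leg.

    Returns ``(state, tsh_required)``.  Flux <= 0 (chamber pressure above the
    front vapor pressure at the pinned bottom temperature) raises
    :class:`InvalidInputError`.
    """
    if not 0.0 <= lck <= lpr0 + _LPR_EPS:
        raise InvalidInputError(f"cake length {lck} outside [0, {lpr0}]")
    c = config.constants
    kv_av, kice_ap = _per_hour_coefficients(config, pch)
    lpr = max(lpr0 - lck, 0.0)
    rp = rp_of_cake_length(config.form, lck)
    dhs_ap = c.dhs * config.vial.ap
    t_bot_k = t_bot + T_ZERO_C

    if lpr < _LPR_EPS:
        t_sub_k = t_bot_k
    else:

        def residual(t_sub_k: float) -> float:
            return (t_bot_k - t_sub_k) * kice_ap / lpr - dhs_ap * (
                _pvap(t_sub_k, c) - pch
            ) / rp

        if residual(t_bot_k) >= 0.0:
            raise InvalidInputError(
                f"no sublimation at Tbot={t_bot} C, Pch={pch} Torr: chamber "
                "pressure exceeds the front vapor pressure"
            )
        lo = t_bot_k - 80.0
        while residual(lo) < 0.0:
            lo -= 40.0
            if lo < 120.0:
                raise SolverError("no bracket for the pinned-bottom front temperature")
        t_sub_k = brentq(residual, lo, t_bot_k, xtol=1e-12, rtol=8.9e-16)

    p_sub = _pvap(t_sub_k, c)
    flux = (p_sub - pch) / rp
    if flux <= 0.0:
        raise InvalidInputError(
            f"no sublimation at Tbot={t_bot} C, Pch={pch} Torr: chamber "
            "pressure exceeds the front vapor pressure"
        )
    q_dot = flux * dhs_ap
    tsh_required_k = t_bot_k + q_dot / kv_av
    state = QuasiSteadyState(
        t_sub=t_sub_k - T_ZERO_C,
        t_bot=t_bot,
        p_sub=p_sub,
        flux=flux,
        q_dot=q_dot,
    )
    return state, tsh_required_k - T_ZERO_C


def state_from_flux(
    flux: float, lck: float, lpr0: float, pch: float, config: DryingConfig
) -> tuple[QuasiSteadyState, float]:
    """Invert the balance for a prescribed flux (used when the equipment
    capability caps the batch sublimation rate).  Returns
    ``(state, tsh_required)``."""
    if flux <= 0:
        raise InvalidInputError("prescribed flux must be positive")
    c = config.constants
    kv_av, kice_ap = _per_hour_coefficients(config, pch)
    lpr = max(lpr0 - lck, 0.0)
    rp = rp_of_cake_length(config.form, lck)
    dhs_ap = c.dhs * config.vial.ap

    p_sub = pch + flux * rp
    t_sub_k = sublimation_temperature(p_sub, c)
    q_dot = flux * dhs_ap
    t_bot_k = t_sub_k if lpr < _LPR_EPS else t_sub_k + q_dot * lpr / kice_ap
    tsh_required_k = t_bot_k + q_dot / kv_av
    state = QuasiSteadyState(
        t_sub=t_sub_k - T_ZERO_C,
        t_bot=t_bot_k - T_ZERO_C,
        p_sub=p_sub,
        flux=flux,
        q_dot=q_dot,
    )
    return state, tsh_required_k - T_ZERO_C


def simulate_primary_drying(config: DryingConfig) -> DryingTimeSeries:
    """Time-step the quasi-steady balance until the cake reaches the initial
    frozen length.  The final partial step is linearly interpolated in cake
    length so the reported drying time does not quantize to the step size."""
    lpr0 = config.lpr0
    dt = config.dt
    rho_ice = config.form.rho_ice

    times, lcks, tsubs, tbots, fluxes, tshs, pchs = [], [], [], [], [], [], []
    t = 0.0
    lck = 0.0
    drying_time = None
    while True:
        tsh = config.shelf.value(t)
        pch = config.pressure.value(t)
        state = quasi_steady_solve(lck, lpr0, tsh, pch, config)
        if t == 0.0 and state.flux <= 0.0:
            raise InvalidInputError(
                "no sublimation at the initial setpoints; drying cannot start"
            )
        times.append(t)
        lcks.append(lck)
        tsubs.append(state.t_sub)
        tbots.append(state.t_bot)
        fluxes.append(state.flux)
        tshs.append(tsh)
        pchs.append(pch)

        dlck = state.flux * dt / rho_ice
        if lck + dlck >= lpr0:
            frac = (lpr0 - lck) / dlck if dlck > 0 else 0.0
            drying_time = t + frac * dt
            times.append(drying_time)
            lcks.append(lpr0)
            tsubs.append(state.t_sub)
            tbots.append(state.t_bot)
            fluxes.append(state.flux)
            tshs.append(tsh)
            pchs.append(pch)
            break
        lck += dlck
        t += dt
        if t > 1e5:
            raise SolverError("primary drying did not complete within 1e5 h")

    return DryingTimeSeries(
        time=np.asarray(times),
        lck=np.asarray(lcks),
        t_sub=np.asarray(tsubs),
        t_bot=np.asarray(tbots),
        flux=np.asarray(fluxes),
        tsh=np.asarray(tshs),
        pch=np.asarray(pchs),
        lpr0=lpr0,
        drying_time=round(drying_time, 3),
    )


def simulate_primary_drying_by_divisions(
    config: DryingConfig, n_divisions: int
) -> DryingTimeSeries:
    """Legacy product-length stepping: divide the frozen length into
    ``n_divisions`` equal segments and hold the flux at its segment-start
    value across each segment.  Coarse divisions overestimate the flux late in
    drying (where the cake resistance is largest) and so underestimate the
    drying time; the scheme converges to the time-stepped result as the
    division count grows."""
    if n_divisions < 1:
        raise InvalidInputError("n_divisions must be at least 1")
    lpr0 = config.lpr0
    rho_ice = config.form.rho_ice
    dl = lpr0 / n_divisions

    times, lcks, tsubs, tbots, fluxes, tshs, pchs = [], [], [], [], [], [], []
    t = 0.0
    for i in range(n_divisions):
        lck = i * dl
        tsh = config.shelf.value(t)
        pch = config.pressure.value(t)
        state = quasi_steady_solve(lck, lpr0, tsh, pch, config)
        if state.flux <= 0.0:
            raise InvalidInputError(
                f"no sublimation at segment {i} (t={t:.3f} h); cannot advance"
            )
        times.append(t)
        lcks.append(lck)
        tsubs.append(state.t_sub)
        tbots.append(state.t_bot)
        fluxes.append(state.flux)
        tshs.append(tsh)
        pchs.append(pch)
        t += dl * rho_ice / state.flux

    times.append(t)
    lcks.append(lpr0)
    tsubs.append(tsubs[-1])
    tbots.append(tbots[-1])
    fluxes.append(fluxes[-1])
    tshs.append(tshs[-1])
    pchs.append(pchs[-1])

    return DryingTimeSeries(
        time=np.asarray(times),
        lck=np.asarray(lcks),
        t_sub=np.asarray(tsubs),
        t_bot=np.asarray(tbots),
        flux=np.asarray(fluxes),
        tsh=np.asarray(tshs),
        pch=np.asarray(pchs),
        lpr0=lpr0,
        drying_time=round(t, 3),
    )
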