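"""Inverse modes: determine heat-transfer and cake-resistance parameters from
experiments instead of dedicated instrumentation.

* ``fit_kv_to_drying_time`` finds the single vial heat-transfer coefficient Kv
  whose forward simulation reproduces a measured primary-drying time; drying
  time is strictly decreasing in Kv, so the search is a bracketed bisection.
* ``fit_kv_pressure_curve`` regresses the three-coefficient pressure curve
  Kv = Kc + Kp*Pch/(1 + KD*Pch) through (Pch, Kv) calibration points.
* ``rp_profile_from_temperature`` walks a measured vial-bottom temperature
  trace through the heat/mass balance to recover the cake resistance as a
  function of cake length, and ``fit_rp_curve`` fits
  Rp = R0 + A1*Lck/(1 + A2*Lck) through that profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, least_squares

from .drying import DryingConfig, simulate_primary_drying
from .errors import InvalidInputError, SolverError
from .models import (
    HeatTransferModel,
    S_PER_H,
    T_ZERO_C,
    ice_vapor_pressure,
    kv_of_pressure,
)


@dataclass(frozen=True)
class KvCalibrationPoint:
    """One (chamber pressure, fitted Kv) pair, with the drying times that
    produced it."""

    pch: float  # Torr
    kv: float  # cal/s K cm^2
    experimental_drying_time: float | None = None  # h
    simulated_drying_time: float | None = None  # h

    def __post_init__(self) -> None:
        if self.kv <= 0:
            raise InvalidInputError("kv must be positive")
        for t in (self.experimental_drying_time, self.simulated_drying_time):
            if t is not None and t <= 0:
                raise InvalidInputError("drying times must be positive")


@dataclass
class RpProfile:
    """Pointwise cake resistance vs cake length, with optional fitted
    coefficients."""

    lck: np.ndarray  # cm
    rp: np.ndarray  # cm^2 h Torr / g
    r0: float | None = None
    a1: float | None = None
    a2: float | None = None


def _with_fixed_kv(config: DryingConfig, kv: float) -> DryingConfig:
    return replace(config, htm=HeatTransferModel(fixed_kv=kv))


def fit_kv_to_drying_time(
    config: DryingConfig,
    t_exp: float,
    bracket: tuple[float, float] = (1e-5, 1e-2),
    tol: float = 1e-3,
) -> KvCalibrationPoint:
    """Find the fixed Kv whose simulated drying time matches ``t_exp`` (h).

    Exploits the strict monotonicity of drying time in Kv; raises if the
    target time is outside what the bracket can reach.
    """
    if t_exp <= 0:
        raise InvalidInputError("experimental drying time must be positive")
    lo, hi = bracket

    def time_at(kv: float) -> float:
        return simulate_primary_drying(_with_fixed_kv(config, kv)).drying_time

    t_slow, t_fast = time_at(lo), time_at(hi)
    if not (t_fast <= t_exp <= t_slow):
        raise InvalidInputError(
            f"target drying time {t_exp} h outside achievable range "
            f"[{t_fast:.3f}, {t_slow:.3f}] h on Kv bracket {bracket}"
        )

    # Bisect on kv until the time mismatch is within tol (hours).
    f_lo = t_slow - t_exp
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        t_mid = time_at(mid)
        if abs(t_mid - t_exp) < tol:
            return KvCalibrationPoint(
                pch=config.pressure.value(0.0),
                kv=mid,
                experimental_drying_time=t_exp,
                simulated_drying_time=t_mid,
            )
        if (t_mid - t_exp) * f_lo > 0:
            lo = mid
        else:
            hi = mid
    raise SolverError("Kv bisection did not reach the drying-time tolerance")


def fit_kv_pressure_curve(
    points: list[KvCalibrationPoint] | tuple[KvCalibrationPoint, ...],
) -> tuple[float, float, float]:
    """Least-squares fit of (Kc, Kp, KD) through >= 3 (Pch, Kv) points.

    With exactly three distinct pressures the 3-parameter fit interpolates the
    data (residual ~ 0).  Coefficients are constrained nonnegative; a KD
    pinned at zero degenerates gracefully to the linear-in-pressure model.
    """
    if len(points) < 3:
        raise InvalidInputError("at least 3 calibration points are required")
    pch = np.array([p.pch for p in points], float)
    kv = np.array([p.kv for p in points], float)
    if np.unique(pch).size < 3:
        raise InvalidInputError("calibration pressures must include >= 3 distinct values")

    order = np.argsort(pch)
    pch, kv = pch[order], kv[order]

    def model(theta: np.ndarray) -> np.ndarray:
        kc, kp, kd = theta
        return kc + kp * pch / (1.0 + kd * pch)

    # Initial guess: Kc from the low-pressure end, Kp from the secant of the
    # two extreme points, KD of order one.
    kp0 = max((kv[-1] - kv[0]) / (pch[-1] - pch[0]), 1e-12)
    x0 = np.array([max(kv[0] - kp0 * pch[0], 1e-12), kp0, 1.0])
    fit = least_squares(
        lambda th: model(th) - kv,
        x0,
        bounds=(np.zeros(3), np.full(3, np.inf)),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if not fit.success:
        raise SolverError(f"(Kc, Kp, KD) regression did not converge: {fit.message}")
    kc, kp, kd = (float(v) for v in fit.x)
    if kd < 1e-12 and len(points) == 3:
        warnings.warn(
            "KD fit collapsed to zero; Kv is effectively linear in pressure "
            "over the calibrated range",
            stacklevel=2,
        )
    return kc, kp, kd


def rp_profile_from_temperature(
    measured_t: np.ndarray,
    measured_t_bot: np.ndarray,
    config: DryingConfig,
) -> RpProfile:
    """Recover the cake resistance vs cake length from a measured vial-bottom
    temperature trace during primary drying.

    Per sample: the heat flow follows from the Kv leg, the flux from the
    sublimation enthalpy, the front temperature from conduction through the
    remaining frozen layer, and the resistance from the vapor-pressure drop
    across the cake.  The cake length advances with the running flux integral.
    Samples with nonpositive flux or front pressure at/below chamber pressure
    are dropped with a warning.
    """
    t = np.asarray(measured_t, float)
    tbot = np.asarray(measured_t_bot, float)
    if t.size != tbot.size or t.size < 2:
        raise InvalidInputError("need matching time/temperature arrays with >= 2 samples")

    c = config.constants
    av, ap = config.vial.av, config.vial.ap
    lpr0 = config.lpr0
    kice_ap = c.k_ice * S_PER_H * ap
    dhs_ap = c.dhs * ap

    lcks, rps = [], []
    n_dropped = 0
    lck = 0.0
    for i in range(t.size):
        tsh = config.shelf.value(t[i])
        pch = config.pressure.value(t[i])
        kv_av = kv_of_pressure(config.htm, pch) * S_PER_H * av
        q_dot = kv_av * (tsh - tbot[i])  # cal/h
        flux = q_dot / dhs_ap  # g/cm^2/h
        lpr = max(lpr0 - lck, 0.0)
        if flux <= 0.0:
            n_dropped += 1
        else:
            t_sub_k = (tbot[i] + T_ZERO_C) - q_dot * lpr / kice_ap
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_sub = ice_vapor_pressure(t_sub_k, c)
            if p_sub <= pch:
                n_dropped += 1
            else:
                lcks.append(lck)
                rps.append((p_sub - pch) / flux)
        if i + 1 < t.size:
            lck = min(lck + max(flux, 0.0) * (t[i + 1] - t[i]) / config.form.rho_ice, lpr0)

    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} sample(s) with no resolvable sublimation",
            stacklevel=2,
        )
    if not lcks:
        raise InvalidInputError("no usable samples: every point had nonpositive flux")
    return RpProfile(lck=np.asarray(lcks), rp=np.asarray(rps))


def fit_rp_curve(profile: RpProfile) -> tuple[float, float, float]:
    """Nonnegative least-squares fit of (R0, A1, A2) through an Rp profile."""
    lck, rp = np.asarray(profile.lck, float), np.asarray(profile.rp, float)
    if lck.size < 3:
        raise InvalidInputError("at least 3 profile points are required")

    def model(theta: np.ndarray) -> np.ndarray:
        r0, a1, a2 = theta
        return r0 + a1 * lck / (1.0 + a2 * lck)

    span = np.ptp(lck)
    a1_0 = (rp[-1] - rp[0]) / span if span > 0 else 0.0
    x0 = np.array([max(rp[0], 1e-9), max(a1_0, 1e-9), 0.1])
    fit = least_squares(
        lambda th: model(th) - rp,
        x0,
        bounds=(np.zeros(3), np.full(3, np.inf)),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if not fit.success:
        raise SolverError(f"(R0, A1, A2) fit did not converge: {fit.message}")
    r0, a1, a2 = (float(v) for v in fit.x)
    profile.r0, profile.a1, profile.a2 = r0, a1, a2
    return r0, a1, a2
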