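"""0D lumped-capacitance freezing simulator.

The product in the vial is treated as a single thermal mass exchanging heat
only with the shelf: ``rho*Cp*V dTpr/dt = -h*Av*(Tpr - Tsh)``.  Cooling with
liquid properties proceeds until the (user-supplied) nucleation temperature is
reached; the temperature then jumps to the equilibrium freezing temperature
and holds there while the latent-heat budget ``rho*V*(Hf - Cp*(Tf - Tn))`` is
removed; finally the solid cools with ice properties.  The lumped treatment
is accurate for Biot numbers below about 0.1 and is used here with the
understanding that water fills during cooling sit above that (Bi ~ 0.6), which
the :func:`biot_number` diagnostic flags.

Heat-transfer coefficients are given in cal/s K cm^2 as tabulated; times are
hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InvalidInputError, SolverError
from .models import S_PER_H
from .schedule import Schedule

STAGE_COOLING = "cooling"
STAGE_CRYSTALLIZATION = "crystallization"
STAGE_SOLID = "solid-cooling"


@dataclass(frozen=True)
class FreezingInputs:
    """Product, vial and thermal parameters of a freezing run."""

    rho: float  # liquid product density, g/cm^3
    cp_liquid: float  # cal/g K
    cp_ice: float  # cal/g K
    v: float  # fill volume, cm^3
    av: float  # vial area, cm^2
    h: float  # shelf-to-product heat-transfer coefficient, cal/s K cm^2
    t_n: float  # nucleation temperature, degC
    t_f: float  # equilibrium freezing temperature, degC
    hf: float  # latent heat of fusion, cal/g
    t0: float | None = None  # initial product temperature, degC (default: shelf at t=0)

    def __post_init__(self) -> None:
        if self.t_n > self.t_f:
            raise InvalidInputError("nucleation temperature cannot exceed freezing temperature")
        if self.h <= 0 or self.v <= 0 or self.av <= 0 or self.rho <= 0:
            raise InvalidInputError("h, v, av, rho must be positive")
        if self.hf <= self.cp_liquid * (self.t_f - self.t_n):
            raise InvalidInputError(
                "latent budget Hf - Cp*(Tf - Tn) is nonpositive; no crystallization "
                "hold is possible with these inputs"
            )


@dataclass
class FreezingResult:
    """Product-temperature trajectory through the three freezing stages."""

    time: np.ndarray  # h
    t_pr: np.ndarray  # degC
    stage: np.ndarray  # str tags
    t_nucleation_onset: float | None  # h
    crystallization_duration: float | None  # h
    t_end: float  # h
    complete: bool  # False when the schedule ended before nucleation/solidification

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.time, "Tpr_C": self.t_pr, "stage": self.stage})


def crystallization_time(inp: FreezingInputs, tsh: float) -> float:
    """Closed-form crystallization hold (h) at constant shelf temperature:
    the latent budget divided by the constant heat-removal rate
    ``h*Av*(Tf - Tsh)``."""
    if tsh >= inp.t_f:
        raise InvalidInputError("no driving force: shelf temperature is at or above Tf")
    budget = inp.rho * inp.v * (inp.hf - inp.cp_liquid * (inp.t_f - inp.t_n))
    rate = inp.h * S_PER_H * inp.av * (inp.t_f - tsh)  # cal/h
    return budget / rate


def simulate_freezing(
    inp: FreezingInputs,
    shelf: Schedule,
    dt: float = 1e-3,
    duration: float | None = None,
) -> FreezingResult:
    """Integrate the lumped-capacitance balance through cooling, the
    crystallization hold and solid cooling.

    ``duration`` defaults to the schedule duration.  If the nucleation
    temperature is never reached within it, a truncated result is returned
    with a warning and ``complete=False``.
    """
    if dt <= 0:
        raise InvalidInputError("time step must be positive")
    if duration is None:
        duration = shelf.duration
    if duration <= 0:
        raise InvalidInputError("a positive duration (or a finite schedule) is required")

    h_av = inp.h * S_PER_H * inp.av  # cal/h K
    mass = inp.rho * inp.v  # g
    t0 = shelf.value(0.0) if inp.t0 is None else inp.t0

    times = [0.0]
    temps = [t0]
    stages = [STAGE_COOLING]
    t = 0.0
    t_pr = t0
    stage = STAGE_COOLING
    onset = None
    crys_end = None
    budget = mass * (inp.hf - inp.cp_liquid * (inp.t_f - inp.t_n))
    removed = 0.0

    while t < duration - 0.5 * dt:
        tsh = shelf.value(t)
        if stage == STAGE_COOLING:
            t_pr += -h_av * (t_pr - tsh) * dt / (mass * inp.cp_liquid)
            if t_pr <= inp.t_n:
                onset = t + dt
                t_pr = inp.t_f
                stage = STAGE_CRYSTALLIZATION
        elif stage == STAGE_CRYSTALLIZATION:
            removed += h_av * (inp.t_f - tsh) * dt
            t_pr = inp.t_f
            if removed >= budget:
                crys_end = t + dt
                stage = STAGE_SOLID
        else:
            t_pr += -h_av * (t_pr - tsh) * dt / (mass * inp.cp_ice)
        t += dt
        times.append(t)
        temps.append(t_pr)
        stages.append(stage)

    complete = crys_end is not None
    if onset is None:
        warnings.warn(
            "nucleation temperature never reached within the schedule; "
            "returning the truncated cooling trajectory",
            stacklevel=2,
        )
    return FreezingResult(
        time=np.asarray(times),
        t_pr=np.asarray(temps),
        stage=np.asarray(stages, dtype=object),
        t_nucleation_onset=onset,
        crystallization_duration=None if crys_end is None else crys_end - onset,
        t_end=t,
        complete=complete,
    )


def _cooling_trajectory(
    h: float, inp: FreezingInputs, shelf: Schedule, t_eval: np.ndarray, dt: float = 1e-3
) -> np.ndarray:
    """Pre-nucleation (stage 1) trajectory at candidate ``h``, evaluated at
    ``t_eval`` by dense explicit integration and linear interpolation."""
    h_av = h * S_PER_H * inp.av
    tau = inp.rho * inp.v * inp.cp_liquid
    t_end = float(t_eval[-1])
    n = max(int(np.ceil(t_end / dt)), 2)
    grid = np.linspace(0.0, t_end, n + 1)
    step = grid[1] - grid[0]
    temps = np.empty_like(grid)
    temps[0] = shelf.value(0.0) if inp.t0 is None else inp.t0
    for i in range(n):
        tsh = shelf.value(grid[i])
        temps[i + 1] = temps[i] - h_av * (temps[i] - tsh) * step / tau
    return np.interp(t_eval, grid, temps)


def fit_film_coefficient(
    measured_t: np.ndarray,
    measured_t_pr: np.ndarray,
    shelf: Schedule,
    inp: FreezingInputs,
) -> float:
    """Estimate the shelf-to-product film coefficient h (cal/s K cm^2) by
    nonlinear least squares on the pre-nucleation cooling segment.

    ``inp.h`` is ignored (it only seeds the search).  The measured series must
    show actual cooling; a flat trace is rejected.
    """
    t = np.asarray(measured_t, float)
    y = np.asarray(measured_t_pr, float)
    if t.size < 3:
        raise InvalidInputError("at least 3 measured points are required")
    if np.ptp(y) < 1e-9:
        raise InvalidInputError("measured trace shows no cooling; cannot identify h")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("measured times must be strictly increasing")

    def residuals(log_h: np.ndarray) -> np.ndarray:
        return _cooling_trajectory(float(np.exp(log_h[0])), inp, shelf, t) - y

    x0 = np.log([inp.h if inp.h > 0 else 1e-4])
    fit = least_squares(residuals, x0, method="lm")
    if not fit.success:
        raise SolverError(f"film-coefficient fit did not converge: {fit.message}")
    return float(np.exp(fit.x[0]))


def biot_number(h: float, lc: float, k: float) -> float:
    """Biot number h*Lc/k (dimensionless); warns when above 0.1, where the
    lumped-capacitance error stops being negligible."""
    if h <= 0 or lc <= 0 or k <= 0:
        raise InvalidInputError("h, lc, k must be positive")
    bi = h * lc / k
    if bi > 0.1:
        warnings.warn(
            f"Biot number {bi:.3g} exceeds 0.1; the lumped-capacitance "
            "approximation degrades",
            stacklevel=2,
        )
    return bi
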