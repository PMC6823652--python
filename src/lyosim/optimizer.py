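"""Per-time-step constrained maximization of the sublimation flux.

At every control interval the optimizer picks the chamber pressure and/or
shelf temperature that maximize the instantaneous sublimation flux subject to

* the product constraint  Tbot <= Tpr,max,
* the equipment constraint  n_vials * per-vial rate <= a + b*Pch,
* practical box bounds on Pch and Tsh.

For a candidate pressure the best admissible shelf temperature is the smaller
of the ceiling ``tsh_max`` and the temperature that pins the vial bottom at
``Tpr,max`` (recovered in closed form through the heat/mass balance); if the
resulting batch rate exceeds the equipment capability, the flux is cut back to
the capability and the shelf temperature that sustains exactly that flux is
backed out.  The flux is then maximized over pressure by a coarse scan plus
golden-section refinement, ties resolving to the lower (cheaper vacuum)
pressure.  Repeating each control interval while the front advances yields
variable setpoint profiles and the minimized drying time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drying import (
    DryingConfig,
    DryingTimeSeries,
    QuasiSteadyState,
    quasi_steady_solve,
    solve_pinned_bottom,
    state_from_flux,
)
from .errors import InfeasibleError, InvalidInputError
from .models import EquipmentCapability, equipment_capability_rate

MODE_BOTH = "both"
MODE_PCH_ONLY = "pch-only"
MODE_TSH_ONLY = "tsh-only"

TAG_TSH_MAX = "Tsh-max"
TAG_TPR_MAX = "Tpr-max"
TAG_PCH_MIN = "Pch-min"
TAG_PCH_MAX = "Pch-max"
TAG_EQUIPMENT = "equipment"

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class OptimizerConstraints:
    """Constraint box and mode for the cycle optimizer."""

    t_pr_max: float  # degC
    tsh_max: float = 120.0  # degC
    tsh_min: float = -60.0  # degC
    pch_min: float = 0.05  # Torr
    pch_max: float = 1.0  # Torr
    cap: EquipmentCapability = field(default_factory=EquipmentCapability.unbounded)
    mode: str = MODE_BOTH
    control_interval: float = 0.05  # h

    def __post_init__(self) -> None:
        if self.tsh_min >= self.tsh_max:
            raise InvalidInputError("tsh_min must be below tsh_max")
        if not 0 < self.pch_min < self.pch_max:
            raise InvalidInputError("require 0 < pch_min < pch_max")
        if not math.isfinite(self.t_pr_max):
            raise InvalidInputError("t_pr_max must be finite")
        if self.mode not in (MODE_BOTH, MODE_PCH_ONLY, MODE_TSH_ONLY):
            raise InvalidInputError(f"unknown optimizer mode {self.mode!r}")
        if self.control_interval <= 0:
            raise InvalidInputError("control interval must be positive")


@dataclass
class OptimizedCycleResult:
    """Drying series plus the optimized setpoint profiles and, per step, the
    constraint that bound the optimum."""

    series: DryingTimeSeries
    pch_opt: np.ndarray
    tsh_opt: np.ndarray
    binding: np.ndarray  # str tags

    @property
    def drying_time(self) -> float:
        return self.series.drying_time

    def to_frame(self) -> pd.DataFrame:
        frame = self.series.to_frame()
        frame["pch_opt_Torr"] = self.pch_opt
        frame["tsh_opt_C"] = self.tsh_opt
        frame["binding_constraint"] = self.binding
        return frame


def _flux_cap(cons: OptimizerConstraints, pch: float, config: DryingConfig) -> float:
    """Per-vial flux ceiling (g/cm^2/h) implied by the equipment line."""
    rate = equipment_capability_rate(cons.cap, pch)
    if math.isinf(rate):
        return math.inf
    return rate * 1e3 / (config.n_vials * config.vial.ap)


def _candidate_at_pch(
    pch: float,
    lck: float,
    lpr0: float,
    config: DryingConfig,
    cons: OptimizerConstraints,
    tsh_fixed: float | None = None,
) -> tuple[float, float, QuasiSteadyState, str] | None:
    """Best admissible (flux, tsh, state, tag) at chamber pressure ``pch``,
    or None if no admissible operating point exists there."""
    if tsh_fixed is not None:
        # Shelf temperature is not a degree of freedom: take the quasi-steady
        # state and check admissibility.
        state = quasi_steady_solve(lck, lpr0, tsh_fixed, pch, config)
        if state.flux <= 0.0 or state.t_bot > cons.t_pr_max + 1e-9:
            return None
        tsh, tag = tsh_fixed, TAG_TPR_MAX
        if state.flux > _flux_cap(cons, pch, config):
            return None
    else:
        try:
            pinned, tsh_req = solve_pinned_bottom(lck, lpr0, cons.t_pr_max, pch, config)
        except InvalidInputError:
            return None
        if tsh_req <= cons.tsh_max:
            if tsh_req < cons.tsh_min:
                return None  # even the coldest shelf would overheat the product
            state, tsh, tag = pinned, tsh_req, TAG_TPR_MAX
        else:
            state = quasi_steady_solve(lck, lpr0, cons.tsh_max, pch, config)
            if state.flux <= 0.0:
                return None
            tsh, tag = cons.tsh_max, TAG_TSH_MAX
    cap_flux = _flux_cap(cons, pch, config)
    if state.flux > cap_flux:
        if tsh_fixed is not None:
            return None
        capped, tsh_capped = state_from_flux(cap_flux, lck, lpr0, pch, config)
        if tsh_capped > cons.tsh_max + 1e-9:
            # the shelf ceiling cuts the flux below the capability by itself
            state = quasi_steady_solve(lck, lpr0, cons.tsh_max, pch, config)
            if state.flux <= 0.0 or state.flux > cap_flux:
                return None
            tsh, tag = cons.tsh_max, TAG_TSH_MAX
        else:
            state, tsh = capped, tsh_capped
            if tsh < cons.tsh_min or state.t_bot > cons.t_pr_max + 1e-9:
                return None
            tag = TAG_EQUIPMENT
    return state.flux, tsh, state, tag


def optimize_step(
    lck: float,
    lpr0: float,
    config: DryingConfig,
    cons: OptimizerConstraints,
    tsh_fixed: float | None = None,
    pch_fixed: float | None = None,
    n_scan: int = 40,
) -> tuple[float, float, QuasiSteadyState, str]:
    """Flux-maximizing (pch, tsh, state, binding tag) at cake length ``lck``.

    ``tsh_fixed``/``pch_fixed`` implement the single-variable modes.  The
    pressure search is a log-spaced scan over the constraint box followed by
    golden-section refinement around the best bracket.
    """
    if lck >= lpr0:
        raise InvalidInputError("cake length must be below the initial frozen length")

    if pch_fixed is not None:
        cand = _candidate_at_pch(pch_fixed, lck, lpr0, config, cons, tsh_fixed)
        if cand is None:
            raise InfeasibleError(
                f"no admissible shelf temperature at fixed Pch={pch_fixed} Torr "
                f"under Tbot<={cons.t_pr_max} C, Tsh<={cons.tsh_max} C, capability"
            )
        flux, tsh, state, tag = cand
        return pch_fixed, tsh, state, tag

    def flux_at(pch: float) -> float:
        cand = _candidate_at_pch(pch, lck, lpr0, config, cons, tsh_fixed)
        return -math.inf if cand is None else cand[0]

    grid = np.geomspace(cons.pch_min, cons.pch_max, n_scan)
    fluxes = np.array([flux_at(p) for p in grid])
    if not np.any(np.isfinite(fluxes)):
        raise InfeasibleError(
            "no admissible (Pch, Tsh) in the constraint box: "
            f"Pch in [{cons.pch_min}, {cons.pch_max}] Torr, "
            f"Tsh in [{cons.tsh_min}, {cons.tsh_max}] C, Tbot <= {cons.t_pr_max} C"
        )
    i = int(np.argmax(fluxes))  # argmax takes the first (lowest-pressure) max

    # Golden-section refinement inside the bracketing neighbors, restricted to
    # the admissible region.
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_scan - 1)]
    a, b = lo, hi
    fa_cache: dict[float, float] = {}

    def f(p: float) -> float:
        if p not in fa_cache:
            fa_cache[p] = flux_at(p)
        return fa_cache[p]

    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    for _ in range(60):
        if f(x1) >= f(x2):
            b, x2 = x2, x1
            x1 = b - _GOLDEN * (b - a)
        else:
            a, x1 = x1, x2
            x2 = a + _GOLDEN * (b - a)
        if b - a < 1e-5:
            break
    # The optimum may sit at a feasibility boundary (admissible flux jumps to
    # -inf); prefer the admissible end of the refined bracket.
    best = None
    for p in (0.5 * (a + b), a, b, grid[i]):
        cand = _candidate_at_pch(p, lck, lpr0, config, cons, tsh_fixed)
        if cand is not None and (best is None or cand[0] > best[1][0] + 1e-15):
            best = (p, cand)
    pch_best, cand = best
    flux, tsh, state, tag = cand
    if abs(pch_best - cons.pch_min) < 1e-6:
        tag = TAG_PCH_MIN
    elif abs(pch_best - cons.pch_max) < 1e-6:
        tag = TAG_PCH_MAX
    return pch_best, tsh, state, tag


def optimize_cycle(
    config: DryingConfig, cons: OptimizerConstraints
) -> OptimizedCycleResult:
    """Run the per-step optimizer over the whole of primary drying.

    In ``pch-only`` mode the shelf follows the configured shelf schedule; in
    ``tsh-only`` mode the pressure follows the configured pressure schedule.
    """
    lpr0 = config.lpr0
    rho_ice = config.form.rho_ice
    dt = cons.control_interval

    times, lcks, tsubs, tbots, fluxes, tshs, pchs, tags = ([] for _ in range(8))
    t, lck = 0.0, 0.0
    drying_time = None
    while True:
        tsh_fixed = config.shelf.value(t) if cons.mode == MODE_PCH_ONLY else None
        pch_fixed = config.pressure.value(t) if cons.mode == MODE_TSH_ONLY else None
        pch, tsh, state, tag = optimize_step(
            lck, lpr0, config, cons, tsh_fixed=tsh_fixed, pch_fixed=pch_fixed
        )
        times.append(t)
        lcks.append(lck)
        tsubs.append(state.t_sub)
        tbots.append(state.t_bot)
        fluxes.append(state.flux)
        tshs.append(tsh)
        pchs.append(pch)
        tags.append(tag)

        dlck = state.flux * dt / rho_ice
        if dlck <= 0:
            raise InfeasibleError("optimizer reached a zero-flux state; cannot finish")
        if lck + dlck >= lpr0:
            frac = (lpr0 - lck) / dlck
            drying_time = t + frac * dt
            times.append(drying_time)
            lcks.append(lpr0)
            tsubs.append(state.t_sub)
            tbots.append(state.t_bot)
            fluxes.append(state.flux)
            tshs.append(tsh)
            pchs.append(pch)
            tags.append(tag)
            break
        lck += dlck
        t += dt

    series = DryingTimeSeries(
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
    return OptimizedCycleResult(
        series=series,
        pch_opt=np.asarray(pchs),
        tsh_opt=np.asarray(tshs),
        binding=np.asarray(tags, dtype=object),
    )
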