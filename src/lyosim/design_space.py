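"""Primary-drying design-space generation.

The design space plots sublimation flux against chamber pressure with shelf
temperature isotherms, bounded above by the critical product-temperature
trajectory (vial bottom pinned at Tpr,max) and by the equipment-capability
line.  It can be evaluated at any stage of drying (cake-length fraction), the
conservative convention being end-of-drying where the cake resistance is
largest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .drying import DryingConfig, quasi_steady_solve, solve_pinned_bottom
from .errors import InfeasibleError, InvalidInputError
from .models import EquipmentCapability, equipment_capability_rate

END_OF_DRYING = "end-of-drying"

#: g/cm^2/h -> kg/m^2/h
_FLUX_TO_SI = 10.0


@dataclass
class DesignSpaceGrid:
    """Flux/temperature map over a (Pch, Tsh) grid at a fixed drying stage."""

    pch_grid: np.ndarray  # Torr
    tsh_grid: np.ndarray  # degC
    flux: np.ndarray  # kg/h/m^2, shape (n_pch, n_tsh)
    max_t_bot: np.ndarray  # degC, shape (n_pch, n_tsh)
    limit_tsh: np.ndarray  # degC: shelf temperature on the Tpr,max isotherm, per pch
    limit_flux: np.ndarray  # kg/h/m^2 on the Tpr,max isotherm, per pch
    capability_flux: np.ndarray  # kg/h/m^2 equivalent per-vial flux of the equipment line
    stage: float | str  # cake-length fraction in [0, 1] or "end-of-drying"
    config: DryingConfig
    t_pr_max: float | None

    def to_frame(self) -> pd.DataFrame:
        pch, tsh = np.meshgrid(self.pch_grid, self.tsh_grid, indexing="ij")
        return pd.DataFrame(
            {
                "Pch_Torr": pch.ravel(),
                "Tsh_C": tsh.ravel(),
                "flux_kg_h_m2": self.flux.ravel(),
                "max_Tbot_C": self.max_t_bot.ravel(),
            }
        )

    def limit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Pch_Torr": self.pch_grid,
                "Tsh_limit_C": self.limit_tsh,
                "flux_limit_kg_h_m2": self.limit_flux,
                "capability_flux_kg_h_m2": self.capability_flux,
            }
        )


def _stage_lck(stage: float | str, lpr0: float) -> float:
    if stage == END_OF_DRYING:
        return lpr0
    stage = float(stage)
    if not 0.0 <= stage <= 1.0:
        raise InvalidInputError("stage fraction must lie in [0, 1]")
    return stage * lpr0


def generate_design_space(
    config: DryingConfig,
    pch_grid=None,
    tsh_grid=None,
    stage: float | str = END_OF_DRYING,
    t_pr_max: float | None = None,
    cap: EquipmentCapability | None = None,
) -> DesignSpaceGrid:
    """Evaluate the quasi-steady balance over a (Pch, Tsh) grid at the given
    drying stage; infeasible (no-sublimation) cells record zero flux.

    Defaults: 25 log-spaced pressures over 50-1000 mTorr and 17 shelf
    temperatures over -40..120 degC.
    """
    if pch_grid is None:
        pch_grid = np.geomspace(0.05, 1.0, 25)
    if tsh_grid is None:
        tsh_grid = np.linspace(-40.0, 120.0, 17)
    pch_grid = np.asarray(pch_grid, float)
    tsh_grid = np.asarray(tsh_grid, float)
    if pch_grid.size == 0 or tsh_grid.size == 0:
        raise InvalidInputError("grids must be nonempty")
    if np.any(np.diff(pch_grid) <= 0) or np.any(np.diff(tsh_grid) <= 0):
        raise InvalidInputError("grids must be strictly increasing")

    lpr0 = config.lpr0
    lck = _stage_lck(stage, lpr0)
    if t_pr_max is None:
        t_pr_max = config.form.t_pr_max
    cap = cap if cap is not None else EquipmentCapability.unbounded()

    flux = np.zeros((pch_grid.size, tsh_grid.size))
    tbot = np.zeros_like(flux)
    for i, pch in enumerate(pch_grid):
        for j, tsh in enumerate(tsh_grid):
            state = quasi_steady_solve(lck, lpr0, tsh, pch, config)
            flux[i, j] = state.flux * _FLUX_TO_SI
            tbot[i, j] = state.t_bot

    limit_tsh = np.full(pch_grid.size, np.nan)
    limit_flux = np.full(pch_grid.size, np.nan)
    if t_pr_max is not None:
        for i, pch in enumerate(pch_grid):
            try:
                state, tsh_req = solve_pinned_bottom(lck, lpr0, t_pr_max, pch, config)
            except InvalidInputError:
                continue  # chamber pressure too high for this product limit
            limit_tsh[i] = tsh_req
            limit_flux[i] = state.flux * _FLUX_TO_SI

    cap_flux = np.array(
        [
            equipment_capability_rate(cap, p) * 1e3 / (config.n_vials * config.vial.ap)
            for p in pch_grid
        ]
    ) * _FLUX_TO_SI  # kg/h -> g/h over cm^2, then to kg/h/m^2

    return DesignSpaceGrid(
        pch_grid=pch_grid,
        tsh_grid=tsh_grid,
        flux=flux,
        max_t_bot=tbot,
        limit_tsh=limit_tsh,
        limit_flux=limit_flux,
        capability_flux=cap_flux,
        stage=stage,
        config=config,
        t_pr_max=t_pr_max,
    )


def product_limit_trajectory(
    config: DryingConfig, t_pr_max: float, pch: float
) -> pd.DataFrame:
    """March the drying forward with the vial bottom pinned at ``t_pr_max``
    and the chamber pressure fixed, reporting the shelf temperature required
    to hold that limit as the cake grows.

    Returns a frame with columns time_h, Lck_cm, Tsh_required_C,
    flux_kg_h_m2, Tsub_C.
    """
    lpr0 = config.lpr0
    rho_ice = config.form.rho_ice
    dt = config.dt
    t, lck = 0.0, 0.0
    rows = []
    while True:
        state, tsh_req = solve_pinned_bottom(lck, lpr0, t_pr_max, pch, config)
        rows.append((t, lck, tsh_req, state.flux * _FLUX_TO_SI, state.t_sub))
        dlck = state.flux * dt / rho_ice
        if lck + dlck >= lpr0:
            break
        lck += dlck
        t += dt
    return pd.DataFrame(
        rows, columns=["time_h", "Lck_cm", "Tsh_required_C", "flux_kg_h_m2", "Tsub_C"]
    )


def optimal_setpoint(
    grid: DesignSpaceGrid,
    cap: EquipmentCapability | None = None,
    t_pr_max: float | None = None,
    tsh_max: float = 120.0,
) -> tuple[float, float, float]:
    """Optimal constant setpoint (pch*, tsh*, flux* in kg/h/m^2) on the design
    space.

    With an enabled capability line, the optimum is where the product-limit
    flux meets the capability flux; otherwise it is the pressure maximizing
    the product-limit flux subject to the required shelf temperature staying
    at or below ``tsh_max``.  Ties resolve to the lower pressure.
    """
    cfg = grid.config
    t_pr_max = t_pr_max if t_pr_max is not None else grid.t_pr_max
    if t_pr_max is None:
        raise InvalidInputError("a product temperature limit is required")
    lck = _stage_lck(grid.stage, cfg.lpr0)
    lpr0 = cfg.lpr0

    def limit_point(pch: float) -> tuple[float, float]:
        state, tsh_req = solve_pinned_bottom(lck, lpr0, t_pr_max, pch, cfg)
        return state.flux * _FLUX_TO_SI, tsh_req

    pgrid = grid.pch_grid
    if cap is not None and not cap.disabled:

        def gap(pch: float) -> float:
            flux, _ = limit_point(pch)
            cap_flux = (
                equipment_capability_rate(cap, pch) * 1e3 / (cfg.n_vials * cfg.vial.ap)
            ) * _FLUX_TO_SI
            return flux - cap_flux

        gaps = []
        for p in pgrid:
            try:
                gaps.append(gap(p))
            except InvalidInputError:
                gaps.append(np.nan)
        gaps = np.asarray(gaps)
        sign_change = np.nonzero(np.diff(np.sign(gaps[~np.isnan(gaps)])) != 0)[0]
        valid = pgrid[~np.isnan(gaps)]
        if sign_change.size == 0:
            if np.all(np.isnan(gaps)) or np.nanmax(gaps) > 0:
                raise InfeasibleError(
                    "equipment capability lies below the product-limit curve "
                    "everywhere on this grid; binding constraint: equipment"
                )
            # capability wholly above the curve: never binding, fall through
            # to the product-limit optimum below
        else:
            i = sign_change[0]
            pch_star = brentq(gap, valid[i], valid[i + 1], xtol=1e-6)
            flux_star, tsh_star = limit_point(pch_star)
            return pch_star, tsh_star, flux_star

    # Capability disabled: smallest pressure keeping Tsh_required <= tsh_max
    # maximizes the product-limit flux (flux falls with pressure along the
    # pinned-bottom curve).
    feasible = []
    for p in pgrid:
        try:
            flux, tsh_req = limit_point(p)
        except InvalidInputError:
            continue
        if tsh_req <= tsh_max:
            feasible.append((p, flux, tsh_req))
    if not feasible:
        raise InfeasibleError(
            "no grid pressure keeps the required shelf temperature below "
            f"{tsh_max} C at the product limit; binding constraint: Tsh-max"
        )
    best_p, best_flux, best_tsh = max(feasible, key=lambda row: (row[1], -row[0]))
    # Refine toward the Tsh-max boundary if it lies just below the best point.
    lo = pgrid[0]
    if best_p > lo:

        def excess(pch: float) -> float:
            try:
                _, tsh_req = limit_point(pch)
            except InvalidInputError:
                return -math.inf
            return tsh_req - tsh_max

        if excess(lo) > 0 >= excess(best_p):
            pch_star = brentq(excess, lo, best_p, xtol=1e-6)
            flux_star, tsh_star = limit_point(pch_star)
            if flux_star > best_flux:
                return pch_star, tsh_star, flux_star
    return best_p, best_tsh, best_flux
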