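"""Configuration loading, CSV readers/writers and synthetic profile
generation.

Config files are YAML with explicit unit suffixes on every physical quantity
(``fill_volume_mL``, ``initial_C``, ``pch_min_Torr`` ...).  Unknown keys and
wrong unit suffixes fail loudly: the mixed-unit culture of this domain makes
silent misreads the dominant failure mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import library
from .drying import DryingConfig, simulate_primary_drying
from .errors import ConfigError, InvalidInputError, UnitError
from .freezing import FreezingInputs, simulate_freezing
from .models import (
    DEFAULT_CONSTANTS,
    EquipmentCapability,
    Formulation,
    HeatTransferModel,
    PhysicalConstants,
    VialGeometry,
)
from .optimizer import OptimizerConstraints
from .schedule import Schedule, Segment

MODES = (
    "freeze",
    "dry",
    "dry-by-divisions",
    "fit-kv",
    "fit-kv-curve",
    "fit-rp",
    "design-space",
    "optimize",
)


@dataclass
class RunConfig:
    """Fully resolved run description."""

    mode: str
    drying: DryingConfig | None = None
    constraints: OptimizerConstraints | None = None
    freezing: FreezingInputs | None = None
    freezing_shelf: Schedule | None = None
    n_divisions: int | None = None
    seed: int = 0


def _require_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}"
        )


def _schedule_from_mapping(mapping, unit: str, context: str) -> Schedule:
    """Build a Schedule from ``{initial_<unit>: x, segments: [...]}`` or a
    bare number (constant setpoint)."""
    if isinstance(mapping, (int, float)):
        return Schedule.constant(float(mapping))
    if not isinstance(mapping, dict):
        raise ConfigError(f"{context} must be a number or a mapping")
    initial_key = f"initial_{unit}"
    ramp_key = f"ramp_{unit}_per_min"
    target_key = f"target_{unit}"
    for key in mapping:
        if key.startswith("initial_") and key != initial_key:
            raise UnitError(
                f"{context}: expected {initial_key!r}, got {key!r} "
                f"(setpoints must carry the {unit!r} unit suffix)"
            )
    _require_keys(mapping, {initial_key, "segments"}, context)
    if initial_key not in mapping:
        raise ConfigError(f"{context}: missing {initial_key!r}")
    segments = []
    for i, seg in enumerate(mapping.get("segments") or []):
        _require_keys(seg, {target_key, ramp_key, "hold_h"}, f"{context}.segments[{i}]")
        if target_key not in seg:
            raise ConfigError(f"{context}.segments[{i}]: missing {target_key!r}")
        segments.append(
            Segment(
                target=float(seg[target_key]),
                ramp_rate=float(seg.get(ramp_key, 0.0)),
                hold=float(seg.get("hold_h", 0.0)),
            )
        )
    return Schedule(float(mapping[initial_key]), segments)


def _vial_from(entry, context: str) -> VialGeometry:
    if isinstance(entry, str):
        return library.get_vial(entry)
    _require_keys(entry, {"outer_diameter_mm", "inner_diameter_mm"}, context)
    return VialGeometry(entry["outer_diameter_mm"], entry["inner_diameter_mm"])


def _product_from(entry, context: str) -> Formulation:
    if isinstance(entry, str):
        return library.get_product(entry)
    allowed = {
        "csolid_g_per_mL",
        "r0_cm2_h_Torr_per_g",
        "a1_cm_h_Torr_per_g",
        "a2_per_cm",
        "rho_solute_g_per_cm3",
        "rho_solution_g_per_cm3",
        "rho_ice_g_per_cm3",
        "t_pr_max_C",
        "name",
    }
    _require_keys(entry, allowed, context)
    return Formulation(
        csolid=entry["csolid_g_per_mL"],
        r0=entry["r0_cm2_h_Torr_per_g"],
        a1=entry["a1_cm_h_Torr_per_g"],
        a2=entry["a2_per_cm"],
        rho_solute=entry["rho_solute_g_per_cm3"],
        rho_solution=entry.get("rho_solution_g_per_cm3", 1.0),
        rho_ice=entry.get("rho_ice_g_per_cm3", 0.918),
        t_pr_max=entry.get("t_pr_max_C"),
        name=entry.get("name", ""),
    )


def _heat_transfer_from(entry, context: str) -> HeatTransferModel:
    if isinstance(entry, str):
        return library.get_heat_transfer(entry)
    allowed = {
        "kc_cal_s_K_cm2",
        "kp_cal_s_K_cm2_Torr",
        "kd_per_Torr",
        "fixed_kv_cal_s_K_cm2",
    }
    _require_keys(entry, allowed, context)
    if "fixed_kv_cal_s_K_cm2" in entry:
        return HeatTransferModel(fixed_kv=entry["fixed_kv_cal_s_K_cm2"])
    return HeatTransferModel(
        kc=entry["kc_cal_s_K_cm2"],
        kp=entry["kp_cal_s_K_cm2_Torr"],
        kd=entry["kd_per_Torr"],
    )


def _constants_from(entry) -> PhysicalConstants:
    if not entry:
        return DEFAULT_CONSTANTS
    allowed = {
        "dhs_cal_per_g": "dhs",
        "k_ice_cal_s_cm_K": "k_ice",
        "hf_cal_per_g": "hf",
        "cp_liquid_cal_per_g_K": "cp_liquid",
        "cp_ice_cal_per_g_K": "cp_ice",
        "vp_a_Torr": "vp_a",
        "vp_b_K": "vp_b",
    }
    _require_keys(entry, set(allowed), "constants")
    return PhysicalConstants(
        **{allowed[k]: float(v) for k, v in entry.items()}
    )


def _constraints_from(entry) -> OptimizerConstraints:
    allowed = {
        "t_pr_max_C",
        "tsh_max_C",
        "tsh_min_C",
        "pch_min_Torr",
        "pch_max_Torr",
        "control_interval_h",
        "mode",
        "capability",
    }
    _require_keys(entry, allowed, "constraints")
    cap_entry = entry.get("capability")
    if cap_entry:
        _require_keys(cap_entry, {"a_kg_per_h", "b_kg_per_h_Torr"}, "constraints.capability")
        cap = EquipmentCapability(
            a=float(cap_entry["a_kg_per_h"]), b=float(cap_entry["b_kg_per_h_Torr"])
        )
    else:
        cap = EquipmentCapability.unbounded()
    return OptimizerConstraints(
        t_pr_max=float(entry["t_pr_max_C"]),
        tsh_max=float(entry.get("tsh_max_C", 120.0)),
        tsh_min=float(entry.get("tsh_min_C", -60.0)),
        pch_min=float(entry.get("pch_min_Torr", 0.05)),
        pch_max=float(entry.get("pch_max_Torr", 1.0)),
        cap=cap,
        mode=entry.get("mode", "both"),
        control_interval=float(entry.get("control_interval_h", 0.05)),
    )


def _freezing_from(entry, constants: PhysicalConstants, v: float, av: float) -> FreezingInputs:
    allowed = {
        "h_cal_s_K_cm2",
        "t_n_C",
        "t_f_C",
        "t0_C",
        "rho_g_per_cm3",
        "cp_liquid_cal_per_g_K",
        "cp_ice_cal_per_g_K",
        "hf_cal_per_g",
    }
    _require_keys(entry, allowed, "freezing")
    return FreezingInputs(
        rho=float(entry.get("rho_g_per_cm3", 1.0)),
        cp_liquid=float(entry.get("cp_liquid_cal_per_g_K", constants.cp_liquid)),
        cp_ice=float(entry.get("cp_ice_cal_per_g_K", constants.cp_ice)),
        v=v,
        av=av,
        h=float(entry["h_cal_s_K_cm2"]),
        t_n=float(entry["t_n_C"]),
        t_f=float(entry["t_f_C"]),
        hf=float(entry.get("hf_cal_per_g", constants.hf)),
        t0=entry.get("t0_C"),
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse and fully resolve a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    allowed = {
        "mode",
        "vial",
        "product",
        "heat_transfer",
        "fill_volume_mL",
        "n_vials",
        "dt_h",
        "n_divisions",
        "shelf_temperature",
        "chamber_pressure",
        "constants",
        "constraints",
        "freezing",
        "seed",
    }
    _require_keys(raw, allowed, str(path))
    mode = raw.get("mode", "dry")
    if mode not in MODES:
        raise ConfigError(f"unknown mode {mode!r}; choose one of {MODES}")

    constants = _constants_from(raw.get("constants"))
    vial = _vial_from(raw["vial"], "vial") if "vial" in raw else None
    form = _product_from(raw["product"], "product") if "product" in raw else None
    shelf = (
        _schedule_from_mapping(raw["shelf_temperature"], "C", "shelf_temperature")
        if "shelf_temperature" in raw
        else None
    )
    pressure = (
        _schedule_from_mapping(raw["chamber_pressure"], "Torr", "chamber_pressure")
        if "chamber_pressure" in raw
        else None
    )

    cfg = RunConfig(mode=mode, seed=int(raw.get("seed", 0)))
    cfg.n_divisions = raw.get("n_divisions")

    if mode == "freeze":
        if vial is None or "freezing" not in raw or shelf is None:
            raise ConfigError("freeze mode needs vial, freezing and shelf_temperature")
        v = float(raw.get("fill_volume_mL", 0.0))
        if v <= 0:
            raise ConfigError("freeze mode needs a positive fill_volume_mL")
        cfg.freezing = _freezing_from(raw["freezing"], constants, v, vial.av)
        cfg.freezing_shelf = shelf
        return cfg

    for name, val in (("vial", vial), ("product", form), ("shelf_temperature", shelf),
                      ("chamber_pressure", pressure)):
        if val is None:
            raise ConfigError(f"mode {mode!r} requires {name!r}")
    htm = (
        _heat_transfer_from(raw["heat_transfer"], "heat_transfer")
        if "heat_transfer" in raw
        else HeatTransferModel(fixed_kv=1e-4)  # placeholder for fit-kv mode
    )
    cfg.drying = DryingConfig(
        vial=vial,
        form=form,
        htm=htm,
        vfill=float(raw["fill_volume_mL"]),
        shelf=shelf,
        pressure=pressure,
        constants=constants,
        n_vials=int(raw.get("n_vials", 1)),
        dt=float(raw.get("dt_h", 0.05)),
    )
    if "constraints" in raw:
        cfg.constraints = _constraints_from(raw["constraints"])
    elif mode == "optimize":
        raise ConfigError("optimize mode requires a constraints block")
    return cfg


def read_profile_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a measured 2-column profile (time h, value) with a header row."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.shape[1] < 2 or frame.shape[0] == 0:
        raise InvalidInputError(f"{path}: expected a nonempty 2-column CSV with header")
    return frame.iloc[:, 0].to_numpy(float), frame.iloc[:, 1].to_numpy(float)


def write_timeseries_csv(series, path: str | Path) -> None:
    """Write any result object exposing ``to_frame()`` (or a DataFrame) as
    CSV.  Values round-trip losslessly (shortest-repr float formatting)."""
    frame = series.to_frame() if hasattr(series, "to_frame") else series
    if len(frame) == 0:
        raise InvalidInputError("refusing to write an empty time series")
    frame.to_csv(path, index=False)


def generate_synthetic_profile(
    truth,
    noise_sd: float = 0.0,
    seed: int = 0,
    shelf: Schedule | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Forward-simulate a temperature profile and add seeded Gaussian noise.

    ``truth`` is a :class:`DryingConfig` (vial-bottom temperature during
    primary drying) or :class:`FreezingInputs` (product temperature during
    freezing; requires ``shelf``).  Deterministic for a fixed seed.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    if isinstance(truth, DryingConfig):
        res = simulate_primary_drying(truth)
        frame = pd.DataFrame({"time_h": res.time, "Tbot_C": res.t_bot})
        col = "Tbot_C"
    elif isinstance(truth, FreezingInputs):
        if shelf is None:
            raise InvalidInputError("freezing profiles need a shelf schedule")
        res = simulate_freezing(truth, shelf, duration=shelf.duration or 10.0)
        # thin the dense integration grid to a thermocouple-like sampling
        keep = slice(None, None, max(len(res.time) // 2000, 1))
        frame = pd.DataFrame({"time_h": res.time[keep], "Tpr_C": res.t_pr[keep]})
        col = "Tpr_C"
    else:
        raise InvalidInputError("truth must be a DryingConfig or FreezingInputs")
    if noise_sd > 0:
        frame[col] = frame[col] + rng.normal(0.0, noise_sd, size=len(frame))
    if path is not None:
        frame.to_csv(path, index=False)
    return frame
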