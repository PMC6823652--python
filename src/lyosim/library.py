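"""Access to the shipped parameter library (products, heat-transfer entries,
vial geometries)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .errors import ConfigError
from .models import Formulation, HeatTransferModel, VialGeometry


@lru_cache(maxsize=1)
def _load() -> dict:
    with resources.files("lyosim.data").joinpath("parameters.yaml").open() as fh:
        return yaml.safe_load(fh)


def _lookup(section: str, name: str) -> dict:
    table = _load()[section]
    if name not in table:
        raise ConfigError(
            f"unknown {section} entry {name!r}; available: {sorted(table)}"
        )
    return table[name]


def product_names() -> list[str]:
    return sorted(_load()["products"])


def vial_names() -> list[str]:
    return sorted(_load()["vials"])


def heat_transfer_names() -> list[str]:
    return sorted(_load()["heat_transfer"])


def get_product(name: str) -> Formulation:
    entry = _lookup("products", name)
    return Formulation(
        csolid=entry["csolid_g_per_mL"],
        r0=entry["r0_cm2_h_Torr_per_g"],
        a1=entry["a1_cm_h_Torr_per_g"],
        a2=entry["a2_per_cm"],
        rho_solute=entry["rho_solute_g_per_cm3"],
        t_pr_max=entry.get("t_pr_max_C"),
        name=name,
    )


def get_heat_transfer(name: str) -> HeatTransferModel:
    entry = _lookup("heat_transfer", name)
    if "fixed_kv_cal_s_K_cm2" in entry:
        return HeatTransferModel(fixed_kv=entry["fixed_kv_cal_s_K_cm2"])
    return HeatTransferModel(
        kc=entry["kc_cal_s_K_cm2"],
        kp=entry["kp_cal_s_K_cm2_Torr"],
        kd=entry["kd_per_Torr"],
    )


def get_vial(name: str) -> VialGeometry:
    entry = _lookup("vials", name)
    return VialGeometry(
        outer_diameter=entry["outer_diameter_mm"],
        inner_diameter=entry["inner_diameter_mm"],
    )
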