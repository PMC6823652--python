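"""Constitutive relations shared by every simulator in the package.

All quantities live in the practical unit system used throughout the vial
freeze-drying literature: lengths in cm, areas in cm^2, pressures in Torr,
temperatures in degrees C at the API surface (K internally where a vapor
pressure is evaluated), heat in cal, mass in g, and time in hours except for
heat-transfer coefficients which are tabulated per second (cal/s K cm^2).

The relations are:

* the pressure-dependent vial heat-transfer coefficient
  ``Kv(Pch) = Kc + Kp*Pch / (1 + KD*Pch)``,
* the dried-cake (product) resistance
  ``Rp(Lck) = R0 + A1*Lck / (1 + A2*Lck)``,
* the vapor pressure of ice ``Psub(T) = vp_a * exp(-vp_b / T)``,
* the initial frozen-product length obtained from the fill volume and the
  volume contraction of water freezing around the dissolved solid, and
* the equipment-capability line ``m_dot_cap = a + b*Pch``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InvalidInputError

T_ZERO_C = 273.15
S_PER_H = 3600.0


@dataclass(frozen=True)
class VialGeometry:
    """Vial dimensions; the derived areas follow the convention that
    shelf-to-vial heat transfer acts over the outer cross-section ``av``
    while sublimation acts over the product cross-section ``ap`` (inner
    diameter)."""

    outer_diameter: float  # mm
    inner_diameter: float  # mm

    def __post_init__(self) -> None:
        if not (0.0 < self.inner_diameter <= self.outer_diameter):
            raise InvalidInputError(
                "require 0 < inner_diameter <= outer_diameter, got "
                f"{self.inner_diameter} / {self.outer_diameter} mm"
            )

    @property
    def av(self) -> float:
        """Vial (shelf-contact) cross-sectional area, cm^2."""
        return math.pi * (self.outer_diameter / 20.0) ** 2

    @property
    def ap(self) -> float:
        """Product cross-sectional area, cm^2."""
        return math.pi * (self.inner_diameter / 20.0) ** 2


@dataclass(frozen=True)
class HeatTransferModel:
    """Vial heat-transfer coefficient: either the three-coefficient pressure
    curve (kc, kp, kd) or a fixed, pressure-independent value."""

    kc: float | None = None  # cal/s K cm^2
    kp: float | None = None  # cal/s K cm^2 Torr
    kd: float | None = None  # 1/Torr
    fixed_kv: float | None = None  # cal/s K cm^2

    def __post_init__(self) -> None:
        has_curve = all(v is not None for v in (self.kc, self.kp, self.kd))
        any_curve = any(v is not None for v in (self.kc, self.kp, self.kd))
        if self.fixed_kv is not None:
            if any_curve:
                raise InvalidInputError("give either (kc, kp, kd) or fixed_kv, not both")
            if self.fixed_kv <= 0:
                raise InvalidInputError("fixed_kv must be positive")
        else:
            if not has_curve:
                raise InvalidInputError("incomplete (kc, kp, kd) coefficient set")
            if self.kc < 0 or self.kp < 0 or self.kd < 0:
                raise InvalidInputError("kc, kp, kd must be nonnegative")

    @property
    def is_fixed(self) -> bool:
        return self.fixed_kv is not None


@dataclass(frozen=True)
class Formulation:
    """Product formulation: solids content, densities and the fitted
    cake-resistance coefficients of ``Rp = R0 + A1*Lck/(1 + A2*Lck)``."""

    csolid: float  # solute mass concentration, g/mL
    r0: float  # cm^2 h Torr / g
    a1: float  # cm h Torr / g
    a2: float  # 1/cm
    rho_solute: float  # g/cm^3
    rho_solution: float = 1.0  # g/cm^3
    rho_ice: float = 0.918  # g/cm^3
    t_pr_max: float | None = None  # critical/target product temperature, degC
    name: str = ""

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.a1 < 0 or self.a2 < 0:
            raise InvalidInputError("require r0 > 0, a1 >= 0, a2 >= 0")
        if not (0.0 <= self.csolid < self.rho_solution):
            raise InvalidInputError("require 0 <= csolid < rho_solution")
        if self.rho_ice >= self.rho_solution:
            warnings.warn(
                "rho_ice >= rho_solution is unusual for aqueous formulations",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermophysical constants of water/ice (handbook values, overridable).

    ``vp_a`` (Torr) and ``vp_b`` (K) parameterize the ice vapor-pressure
    correlation ``P = vp_a * exp(-vp_b / T)``.
    """

    dhs: float = 650.0  # heat of sublimation of ice, cal/g (classic vial-drying value)
    k_ice: float = 0.0059  # frozen-layer conductivity, cal/s cm K
    hf: float = 79.7  # latent heat of fusion, cal/g
    cp_liquid: float = 1.0  # cal/g K
    cp_ice: float = 0.503  # cal/g K
    vp_a: float = 2.698e10  # Torr
    vp_b: float = 6144.96  # K

    def __post_init__(self) -> None:
        for name in ("dhs", "k_ice", "hf", "cp_liquid", "cp_ice", "vp_a", "vp_b"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"constant {name} must be strictly positive")


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class EquipmentCapability:
    """Maximum total sublimation rate the dryer sustains, as a line in
    chamber pressure: ``rate = a + b*Pch`` (kg/h).  ``disabled`` means the
    dryer is never equipment-limited."""

    a: float = 0.0  # kg/h
    b: float = 0.0  # kg/h Torr
    disabled: bool = False

    @classmethod
    def unbounded(cls) -> "EquipmentCapability":
        return cls(disabled=True)

    def rate(self, pch: float) -> float:
        return equipment_capability_rate(self, pch)


def kv_of_pressure(model: HeatTransferModel, pch):
    """Vial heat-transfer coefficient at chamber pressure ``pch`` (Torr),
    in cal/s K cm^2.  Accepts scalars or numpy arrays."""
    pch = np.asarray(pch, dtype=float)
    if np.any(pch < 0):
        raise InvalidInputError("chamber pressure must be nonnegative")
    if model.is_fixed:
        out = np.full_like(pch, model.fixed_kv)
    else:
        out = model.kc + model.kp * pch / (1.0 + model.kd * pch)
    return out.item() if out.ndim == 0 else out


def rp_of_cake_length(form: Formulation, lck):
    """Area-normalized dried-cake resistance at cake length ``lck`` (cm),
    in cm^2 h Torr / g."""
    lck = np.asarray(lck, dtype=float)
    if np.any(lck < 0):
        raise InvalidInputError("cake length must be nonnegative")
    out = form.r0 + form.a1 * lck / (1.0 + form.a2 * lck)
    return out.item() if out.ndim == 0 else out


def ice_vapor_pressure(t, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Equilibrium vapor pressure of ice (Torr) at temperature ``t`` (K)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise InvalidInputError("absolute temperature must be positive")
    if np.any((t <= 150.0) | (t >= 280.0)):
        warnings.warn(
            "ice vapor-pressure correlation evaluated outside 150-280 K",
            stacklevel=2,
        )
    out = constants.vp_a * np.exp(-constants.vp_b / t)
    return out.item() if out.ndim == 0 else out


def sublimation_temperature(p, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Inverse of :func:`ice_vapor_pressure`: front temperature (K) at which
    ice exerts vapor pressure ``p`` (Torr)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise InvalidInputError("vapor pressure must be positive")
    out = constants.vp_b / np.log(constants.vp_a / p)
    return out.item() if out.ndim == 0 else out


def initial_frozen_length(vfill: float, form: Formulation, ap: float) -> float:
    """Initial frozen-product length (cm) for fill volume ``vfill`` (mL) over
    product area ``ap`` (cm^2), accounting for the density change on freezing
    and the volume occupied by the dissolved solid."""
    if vfill <= 0:
        raise InvalidInputError("fill volume must be positive")
    if ap <= 0:
        raise InvalidInputError("product area must be positive")
    return (
        vfill
        / (ap * form.rho_ice)
        * (
            form.rho_solution
            - form.csolid * (form.rho_solution - form.rho_ice) / form.rho_solute
        )
    )


def equipment_capability_rate(cap: EquipmentCapability, pch: float) -> float:
    """Total sublimation rate (kg/h) the equipment sustains at ``pch`` (Torr);
    +infinity when the capability line is disabled."""
    if pch < 0:
        raise InvalidInputError("chamber pressure must be nonnegative")
    if cap.disabled:
        return math.inf
    rate = cap.a + cap.b * pch
    if rate < 0:
        raise ConfigError(
            f"equipment capability line a={cap.a}, b={cap.b} is negative at "
            f"{pch} Torr"
        )
    return rate
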