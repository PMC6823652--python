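import pytest

from lyosim import (
    DryingConfig,
    Formulation,
    HeatTransferModel,
    Schedule,
    VialGeometry,
)


@pytest.fixture
def vial_6r() -> VialGeometry:
    return VialGeometry(outer_diameter=22.0, inner_diameter=20.0)


@pytest.fixture
def vial_5800w() -> VialGeometry:
    return VialGeometry(outer_diameter=24.5, inner_diameter=22.0)


@pytest.fixture
def mannitol() -> Formulation:
    return Formulation(
        csolid=0.05, r0=1.4, a1=16.0, a2=0.0, rho_solute=1.52, t_pr_max=-5.0,
        name="5% mannitol",
    )


@pytest.fixture
def sucrose() -> Formulation:
    return Formulation(
        csolid=0.05, r0=0.208, a1=15.29, a2=1.6, rho_solute=1.587, t_pr_max=-35.0,
        name="5% sucrose",
    )


@pytest.fixture
def htm_6r() -> HeatTransferModel:
    # Schott 6R / Millrock REVO pressure curve
    return HeatTransferModel(kc=2.75e-4, kp=8.93e-4, kd=0.46)


@pytest.fixture
def htm_5800w() -> HeatTransferModel:
    return HeatTransferModel(kc=2.64e-4, kp=33.2e-4, kd=3.64)


@pytest.fixture
def mannitol_config(vial_6r, mannitol, htm_6r) -> DryingConfig:
    """2 mL of 5% mannitol in a 6R vial at -5 C / 300 mTorr, fixed Kv."""
    return DryingConfig(
        vial=vial_6r,
        form=mannitol,
        htm=HeatTransferModel(fixed_kv=5.1e-4),
        vfill=2.0,
        shelf=Schedule.constant(-5.0),
        pressure=Schedule.constant(0.3),
    )


@pytest.fixture
def mannitol_curve_config(vial_6r, mannitol, htm_6r) -> DryingConfig:
    """Same fill with the pressure-dependent Kv curve at 150 mTorr."""
    return DryingConfig(
        vial=vial_6r,
        form=mannitol,
        htm=htm_6r,
        vfill=2.0,
        shelf=Schedule.constant(-5.0),
        pressure=Schedule.constant(0.15),
    )
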