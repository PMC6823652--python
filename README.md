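# lyosim

Simulation and optimization of pharmaceutical lyophilization (freeze-drying)
cycles: a freezing calculator, a primary-drying calculator with calibration
modes, a design-space generator, and a variable-setpoint cycle optimizer.

## Who this is for

Formulation and process scientists designing freeze-drying cycles for
drug products in vials. Primary drying — sublimation of ice under vacuum —
is usually the longest and most expensive stage of a cycle, and the common
practice of holding the chamber pressure `Pch` and shelf temperature `Tsh`
at conservative constant setpoints wastes most of the equipment's capacity.
`lyosim` models the relevant heat and mass transfer well enough to answer,
in seconds: how long will primary drying take, how hot does the product get,
what are the equipment-transfer and cake-resistance parameters of my
vial/dryer/formulation, and what `Pch(t)`/`Tsh(t)` profiles minimize drying
time without exceeding the critical product temperature.

## The models

**Freezing** is treated as a 0D lumped-capacitance body exchanging heat only
with the shelf,

    rho * Cp * V * dTpr/dt = -h * Av * (Tpr - Tsh),

cooled until the (measured) nucleation temperature `Tn`, held at the freezing
temperature `Tf` while the latent budget `rho*V*(Hf - Cp*(Tf - Tn))` is
removed, then cooled as a solid with ice properties.

**Primary drying** is the 1D quasi-steady balance across a vial: heat from
the shelf through the vial bottom equals conduction through the frozen layer
equals the sublimation heat drawn through the dried cake,

    Q = Kv*Av*(Tsh - Tbot)
      = k_ice*Ap*(Tbot - Tsub) / Lpr
      = dHs*Ap*(Psub(Tsub) - Pch) / Rp(Lck),

with the vial heat-transfer coefficient `Kv = Kc + Kp*Pch/(1 + KD*Pch)`,
the cake resistance `Rp = R0 + A1*Lck/(1 + A2*Lck)`, and `Psub` the vapor
pressure of ice at the front temperature. Solving this per time step and
advancing the front by `flux*dt/rho_ice` yields the drying time, product
temperatures and sublimation flux. Inverse modes fit `Kv` to a measured
drying time, the `(Kc, Kp, KD)` curve to several such fits, and
`(R0, A1, A2)` to a measured product-temperature trace.

**Design space and optimization.** Scanning the balance over `(Pch, Tsh)`
grids produces the classical design space bounded by the equipment
capability line `m_cap = a + b*Pch` and the critical product-temperature
curve (vial bottom pinned at `Tpr,max`). The optimizer re-solves, every
control interval, for the `(Pch, Tsh)` that maximize sublimation flux
subject to `Tbot <= Tpr,max`, the batch rate staying under the capability
line, and practical box bounds — yielding variable setpoint profiles and the
minimized drying time.

All quantities use the field's practical units: cm, Torr, cal, g, hours
(`cal/s K cm^2` for heat-transfer coefficients, as tabulated in the
literature); converters to SI are provided.

## Worked example

Primary drying of 2 mL of 5% mannitol in a Schott 6R vial at 150 mTorr and
-5 °C shelf temperature, using the library entries for the vial, product and
dryer (`examples/02_primary_drying.py`):

```python
from lyosim import (DryingConfig, Schedule, get_heat_transfer, get_product,
                    get_vial, simulate_primary_drying)

config = DryingConfig(
    vial=get_vial("Schott 6R"),
    form=get_product("5% mannitol"),
    htm=get_heat_transfer("Schott 6R / Millrock REVO"),
    vfill=2.0,
    shelf=Schedule.constant(-5.0),
    pressure=Schedule.constant(0.15),
)
result = simulate_primary_drying(config)
```

prints

```
initial frozen length:  0.692 cm
drying time:            12.36 h
max product temperature: -21.18 C
mean product temperature:-24.13 C
initial / final flux:   0.67 / 0.43 kg/h m^2
```

The 12.36 h drying time is the model's central output; the flux falls
through the run as the dried-cake resistance grows, and the product stays
far below a -5 °C critical temperature — this conservative cycle is exactly
what the optimizer improves on. Running
`examples/05_optimized_cycle.py` on the same load shows the typical
constant-setpoint cycle at 5.26 h against 2.00 h with both setpoints
re-optimized every 3 minutes, a 62% reduction.

The other examples cover freezing (`01`), parameter calibration (`03`) and
design-space generation (`04`). A thin CLI exposes the same operations
(`lyosim dry|freeze|dry-by-divisions|fit-kv|fit-kv-curve|fit-rp|design-space|optimize --help`)
over YAML configs with explicit unit suffixes.

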