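"""Primary drying of 2 mL of 5% mannitol in a Schott 6R vial at 150 mTorr.

The 1D quasi-steady model balances shelf-to-vial heat transfer, conduction
through the frozen layer, and sublimation through the dried cake, advancing
the sublimation front every 3 minutes until the product is dry.
"""

from lyosim import (
    DryingConfig,
    Schedule,
    get_heat_transfer,
    get_product,
    get_vial,
    simulate_primary_drying,
)

config = DryingConfig(
    vial=get_vial("Schott 6R"),
    form=get_product("5% mannitol"),
    htm=get_heat_transfer("Schott 6R / Millrock REVO"),
    vfill=2.0,                          # mL
    shelf=Schedule.constant(-5.0),      # degC
    pressure=Schedule.constant(0.15),   # Torr (150 mTorr)
)

result = simulate_primary_drying(config)
print(f"initial frozen length:  {result.lpr0:.3f} cm")
print(f"drying time:            {result.drying_time:.2f} h")
print(f"max product temperature:{result.max_t_bot:7.2f} C")
print(f"mean product temperature:{result.mean_t_bot:6.2f} C")
print(f"initial / final flux:   {result.flux[0]*10:.2f} / {result.flux[-1]*10:.2f} kg/h m^2")
# The flux falls through the run because the dried-cake resistance grows with
# cake length; the product stays well below a -5 C critical temperature.
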