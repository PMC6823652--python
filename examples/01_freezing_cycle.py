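"""Freezing of 2 mL of water in a 6R vial on a ramped shelf.

The shelf cools from room temperature to -30 C at 1 C/min and holds.  The 0D
lumped-capacitance model tracks the product through supercooled liquid
cooling, the isothermal crystallization hold at the freezing temperature, and
solid cooling toward the shelf.
"""

from lyosim import FreezingInputs, Schedule, Segment, biot_number, simulate_freezing

inputs = FreezingInputs(
    rho=1.0,          # g/cm^3
    cp_liquid=1.0,    # cal/g K
    cp_ice=0.503,     # cal/g K
    v=2.0,            # mL fill
    av=3.8013,        # cm^2, 6R vial outer cross-section
    h=4.0e-4,         # cal/s K cm^2 shelf-to-product film coefficient
    t_n=-8.0,         # degC nucleation temperature (measured input)
    t_f=0.0,          # degC equilibrium freezing temperature
    hf=79.7,          # cal/g latent heat of fusion
    t0=20.0,          # degC initial product temperature
)
shelf = Schedule(20.0, [Segment(target=-30.0, ramp_rate=1.0, hold=4.0)])

result = simulate_freezing(inputs, shelf)
print(f"nucleation onset:        {result.t_nucleation_onset:.2f} h")
print(f"crystallization hold:    {result.crystallization_duration:.2f} h")
print(f"final product temp:      {result.t_pr[-1]:.1f} C (shelf at -30 C)")

# The lumped model assumes small internal temperature gradients; the Biot
# number for a water fill flags that this is only marginally satisfied during
# liquid cooling.  The characteristic length is the larger of fill height and
# vial diameter (2.2 cm here); water conductivity 1.43e-3 cal/s cm K.
bi = biot_number(inputs.h, 2.2, 1.43e-3)
print(f"Biot number (cooling):   {bi:.2f}  (>0.1: expect extra model error)")
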