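"""Calibrating heat-transfer and cake-resistance parameters from experiments.

Three calibrations, each replacing a dedicated instrument:
1. a single Kv from a measured drying time,
2. the (Kc, Kp, KD) pressure curve from Kv values at three pressures,
3. the cake-resistance curve (R0, A1, A2) from a vial-bottom temperature
   trace (here a synthetic trace generated from the known mannitol truth).
"""

from lyosim import (
    DryingConfig,
    HeatTransferModel,
    KvCalibrationPoint,
    Schedule,
    fit_kv_pressure_curve,
    fit_kv_to_drying_time,
    fit_rp_curve,
    generate_synthetic_profile,
    get_heat_transfer,
    get_product,
    get_vial,
    rp_profile_from_temperature,
)

base = DryingConfig(
    vial=get_vial("Schott 6R"),
    form=get_product("5% mannitol"),
    htm=HeatTransferModel(fixed_kv=1e-4),  # placeholder, to be fitted
    vfill=2.0,
    shelf=Schedule.constant(-5.0),
    pressure=Schedule.constant(0.3),
)

# 1. Kv from the measured 300 mTorr drying time (11.62 h)
point = fit_kv_to_drying_time(base, t_exp=11.62)
print(f"Kv at 300 mTorr: {point.kv*1e4:.2f} x 10^-4 cal/s K cm^2 "
      f"(simulated {point.simulated_drying_time:.2f} h)")

# 2. (Kc, Kp, KD) through calibrated Kv values at three pressures
points = [
    KvCalibrationPoint(pch=0.1, kv=3.6e-4),
    KvCalibrationPoint(pch=0.3, kv=5.1e-4),
    KvCalibrationPoint(pch=1.5, kv=10.67e-4),
]
kc, kp, kd = fit_kv_pressure_curve(points)
print(f"Kv(Pch) curve:   Kc={kc*1e4:.2f}e-4, Kp={kp*1e4:.2f}e-4 cal units, "
      f"KD={kd:.2f} /Torr")

# 3. Rp(Lck) from a noisy synthetic product-temperature trace
import dataclasses

truth = dataclasses.replace(base, htm=get_heat_transfer("Schott 6R / Millrock REVO"),
                            pressure=Schedule.constant(0.15), dt=0.02)
trace = generate_synthetic_profile(truth, noise_sd=0.1, seed=7)
profile = rp_profile_from_temperature(
    trace["time_h"].to_numpy()[:-1], trace["Tbot_C"].to_numpy()[:-1], truth
)
r0, a1, a2 = fit_rp_curve(profile)
print(f"Rp(Lck) fit:     R0={r0:.2f} cm^2 h Torr/g, A1={a1:.1f} cm h Torr/g, "
      f"A2={a2:.2f} /cm   (truth: 1.40, 16.0, 0.00)")
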