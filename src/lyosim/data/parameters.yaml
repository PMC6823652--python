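# Parameter library: published cake-resistance, vial heat-transfer and vial
# geometry entries used throughout the freeze-drying modeling literature.
# Units are recorded per field; resistances in the practical cm/h/Torr/g
# system, heat-transfer coefficients in cal/s K cm^2 (and per Torr), vial
# diameters in mm.

products:
  "5% mannitol":
    csolid_g_per_mL: 0.05
    r0_cm2_h_Torr_per_g: 1.4
    a1_cm_h_Torr_per_g: 16.0
    a2_per_cm: 0.0
    rho_solute_g_per_cm3: 1.52
    t_pr_max_C: -5.0          # typical target for mannitol cycles
  "5% sucrose":
    csolid_g_per_mL: 0.05
    r0_cm2_h_Torr_per_g: 0.208
    a1_cm_h_Torr_per_g: 15.29
    a2_per_cm: 1.6
    rho_solute_g_per_cm3: 1.587
    t_pr_max_C: -35.0         # 3 C below the 5% sucrose glass transition
  "5% povidone":
    csolid_g_per_mL: 0.05
    r0_cm2_h_Torr_per_g: 1.13
    a1_cm_h_Torr_per_g: 5.0
    a2_per_cm: 0.0
    rho_solute_g_per_cm3: 1.2

heat_transfer:
  "Schott 6R / Millrock REVO":
    kc_cal_s_K_cm2: 2.75e-4
    kp_cal_s_K_cm2_Torr: 8.93e-4
    kd_per_Torr: 0.46
  "5800W":
    kc_cal_s_K_cm2: 2.64e-4
    kp_cal_s_K_cm2_Torr: 33.2e-4
    kd_per_Torr: 3.64
  "5816W":
    kc_cal_s_K_cm2: 2.03e-4
    kp_cal_s_K_cm2_Torr: 33.2e-4
    kd_per_Torr: 3.97
  "5303":
    kc_cal_s_K_cm2: 1.52e-4
    kp_cal_s_K_cm2_Torr: 33.2e-4
    kd_per_Torr: 6.97
  "warped stainless steel tray":
    kc_cal_s_K_cm2: 0.6e-4
    kp_cal_s_K_cm2_Torr: 65.9e-4
    kd_per_Torr: 27.0
  "Wheaton 2mL / LyoStar II, Tsh=-25C, thermocouple":
    fixed_kv_cal_s_K_cm2: 3.8e-4
  "Wheaton 2mL / LyoStar II, Tsh=-25C, Pirani":
    fixed_kv_cal_s_K_cm2: 2.7e-4
  "Wheaton 2mL / LyoStar II, Tsh=25C, thermocouple":
    fixed_kv_cal_s_K_cm2: 2.0e-4
  "Wheaton 2mL / LyoStar II, Tsh=25C, Pirani":
    fixed_kv_cal_s_K_cm2: 1.9e-4

vials:
  "Schott 6R":
    outer_diameter_mm: 22.0
    inner_diameter_mm: 20.0
  "5800W":
    outer_diameter_mm: 24.5
    inner_diameter_mm: 22.0
  "5816W":
    outer_diameter_mm: 29.5
    inner_diameter_mm: 27.0
  "5303":
    outer_diameter_mm: 46.8
    inner_diameter_mm: 42.7
  "Wheaton 2mL":
    outer_diameter_mm: 15.0
    inner_diameter_mm: 13.0
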