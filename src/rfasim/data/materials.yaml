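# Physical characteristics of tissues and materials at 37 degC (sigma at 500 kHz).
# sigma_ref: S/m, k: W/(m K), rho: kg/m^3, c: J/(kg K), water_mass_fraction: -
materials:
  myocardium:
    sigma_ref: 0.281
    k: 0.56
    rho: 1081.0
    c: 3686.0
    water_mass_fraction: 0.737
    k_transverse: 0.487
    k_longitudinal: 0.633
  striated_muscle:
    sigma_ref: 0.446
    k: 0.49
    rho: 1090.0
    c: 3421.0
    water_mass_fraction: 0.795
  electrode_pt_ir:
    sigma_ref: 4.6e+6
    k: 71.0
    rho: 21500.0
    c: 132.0
  catheter_polyurethane:
    sigma_ref: 1.0e-5
    k: 23.0
    rho: 1440.0
    c: 1050.0
blood:
  sigma: 0.748
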