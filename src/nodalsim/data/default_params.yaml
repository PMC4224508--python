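# Default nodalsim parameter set.
#
# The (D, c1, c2, b, d) columns are the published per-tissue table, verbatim.
# alpha (excitation threshold), q (SAN recovery-nullcline offset), the global
# diffusion unit and the recovery boost were calibrated once on the 50x5x5
# strand protocol (scripts/calibrate.py) and are frozen here.

dx_um: 60.0
diffusion_unit: 0.02343      # mm^2/ms per table unit of D (calibrated)
anisotropy_ratio: 10.0       # D_l / D_t; CV anisotropy ~ sqrt(10) ~ 3.2
recovery_boost: 3.0          # rho: sub-threshold recovery acceleration
recovery_switch_u: 0.3
recovery_switch_width: 0.05
activation_threshold: 0.5
san_hold_fraction: 0.5       # diastolic phase used for paced SAN protocols

voltage_scale:
  Vr: -80.0
  Vos: 20.0
  Vth: -67.0

block_zone:
  Rb: 0.5

periphery:
  band_width: 4              # elements = 0.24 mm at 60 um

tissues:
  san:
    {D: 2.0, c1: 1.0, c2: 0.22, b: 0.003, d: 3.5,
     alpha: 0.18, q: 0.51, pacemaker: true}
  atrial:
    {D: 7.0, c1: 12.7, c2: 1.84, b: 0.01, d: 2.475, alpha: 0.235}
  ine:
    {D: 2.0, c1: 1.45, c2: 1.0, b: 0.013, d: 2.5, alpha: 0.148}
  pb:
    {D: 2.0, c1: 3.05, c2: 1.0, b: 0.0048, d: 2.0, alpha: 0.105}

# Cellular-automaton engine: per-tissue excitation threshold (theta, counter
# units), counter gain per excited neighbour per step, neighbourhood reach
# (lattice radius), excited period E and refractory period R (time steps).
# Tuned so the 1D-fibre conduction velocities and S1-S2 refractory periods
# match the published cellular-automaton table at dt = 1 ms, dx = 60 um.
ca:
  dt_ms: 1.0
  tissues:
    atrial: {theta: 1.0, gain: 1.0, reach: 7, excited: 12, refractory: 68}
    ine:    {theta: 1.0, gain: 1.0, reach: 2, excited: 12, refractory: 81}
    tz:     {theta: 10.0, gain: 1.0, reach: 8, excited: 12, refractory: 121}
    pb:     {theta: 13.0, gain: 1.0, reach: 7, excited: 15, refractory: 138}
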