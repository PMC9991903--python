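# Diaphragm-paralysis model: both phrenic nerves severed; breathing is
# carried by hypercapnia-driven accessory/ribcage efforts with large
# breath-to-breath timing variability.  Actuation is flow-triggered with
# the threshold titrated near the noise floor, as in the alignment
# analysis (occasional pre-emptive/false triggers are expected).
schema_version: 1
name: severed-phrenic
duration: 1200.0
sim:
  fs: 1000.0
  R_aw: 0.606187
  C_L: 210.265
  lung_p_rec: 1.49254
  lung_v_rec: 33.5019
  C_cw: 342.374
  V_D: 45.0
  body_mass: 35.0
  f_di: 0.7
  severed_phrenic: true
  A0: 7.1
  G_drive: 0.05
  paco2_set: 40.0
  rr_base: 12.6
  G_rr: 0.05
  Ti_frac: 0.30
  amp_ti_coupling: 2.2
  tau_rel: 1.0
  tau_drive: 20.0
  k_act: 0.0501522
  tau_act: 0.06
  gamma_ab: 0.9
  k_disp: 0.253555
  k_disp_act: 0.0793102
  gas:
    paco2_0: 65.0
    hco3_0: 29.0
    vco2: 120.0
    v_store: 25.0
  noise:
    flow_sd: 0.004
    p_pl_sd: 0.02
    p_ab_sd: 0.02
    p_act_sd: 0.05
    d_dia_sd: 0.01
    amp_jitter_sd: 0.02
    ti_jitter_sd: 0.45
  seed: 202
controller:
  mode: synchronized
  threshold: 0.025
  hysteresis: 0.03
  waveform:
    peak: 20.0
    t_rise: 0.324563
    t_hold: 0.293454
    t_release: 0.35
    shape: trapezoid
ventilator: null
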