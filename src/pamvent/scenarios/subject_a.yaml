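# Best-responder subject: anaesthesia-depressed spontaneous breathing,
# synchronized PAM assist at the nominal 20 psi.
schema_version: 1
name: subject-A
duration: 75.0
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
  severed_phrenic: false
  A0: 0.872409
  G_drive: 0.05
  paco2_set: 40.0
  rr_base: 19.3
  G_rr: 0.05
  Ti_frac: 0.174516
  tau_rel: 2.19837
  tau_drive: 20.0
  k_act: 0.0501522
  tau_act: 0.06
  gamma_ab: 0.9
  k_disp: 0.253555
  k_disp_act: 0.0793102
  gas:
    paco2_0: 52.0
    hco3_0: 27.0
    vco2: 120.0
    v_store: 25.0
  noise:
    flow_sd: 0.004
    p_pl_sd: 0.02
    p_ab_sd: 0.02
    p_act_sd: 0.05
    d_dia_sd: 0.01
    amp_jitter_sd: 0.04
  seed: 101
controller:
  mode: synchronized
  threshold: 0.04
  hysteresis: 0.03
  waveform:
    peak: 20.0
    t_rise: 0.324563
    t_hold: 0.293454
    t_release: 0.35
    shape: trapezoid
ventilator: null
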