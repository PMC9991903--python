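# Positive-pressure mechanical ventilation between challenges: passive
# respiratory muscles, volume-targeted pressure-controlled breaths.  Used
# to fit the passive chest-wall compliance line of the Campbell diagram.
schema_version: 1
name: mech-vent
duration: 60.0
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
  A0: 0.0
  G_drive: 0.0
  paco2_set: 40.0
  rr_base: 15.0
  G_rr: 0.0
  Ti_frac: 0.174516
  tau_rel: 2.19837
  tau_drive: 20.0
  k_act: 0.0501522
  tau_act: 0.06
  gamma_ab: 0.9
  k_disp: 0.253555
  k_disp_act: 0.0793102
  gas:
    paco2_0: 42.0
    hco3_0: 24.0
    vco2: 120.0
    v_store: 25.0
  noise:
    flow_sd: 0.004
    p_pl_sd: 0.02
    p_ab_sd: 0.02
    p_act_sd: 0.05
    d_dia_sd: 0.01
    amp_jitter_sd: 0.0
  seed: 303
controller:
  mode: "off"
ventilator:
  rate: 15.0
  pip: 3.5
  ti_frac: 0.33
  t_ramp: 0.15
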