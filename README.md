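# pamvent

Respiratory-mechanics surrogate, pneumatic-artificial-muscle (PAM)
diaphragm assist, and breath/work-of-breathing waveform analysis.

Severe diaphragm dysfunction — phrenic nerve injury, neuromuscular
disease, deep anaesthetic depression — can leave a subject unable to
ventilate adequately.  An implantable diaphragm-assist system places
contractile McKibben actuators above the diaphragm and pressurizes them
in synchrony with the native inspiratory effort, augmenting tidal volume
by negative-pressure means rather than pushing air in from above.
`pamvent` packages the computational side of evaluating such a system:

* **`mechanics_sim`** — a lumped respiratory-mechanics model of an
  anaesthetized ~35 kg pig: single-compartment equation of motion
  `R_aw Q = P_vent + P_mus + P_assist − P_el(V)`, recruitment-knee lung
  recoil `P_lung(V) = P_rec tanh(V/V_rec) + V/C_L`, linear chest wall,
  CO2 balance `dPaCO2/dt = (0.863 VCO2 − PaCO2·V̇A)/V_store` with
  Henderson–Hasselbalch pH and a slow chemoreflex drive.  Spontaneous,
  mechanically ventilated, actuator-assisted, and severed-phrenic modes.
* **`actuator`** — commanded pressurization cycles (trapezoid /
  raised-cosine, nominal 20 psi), a first-order regulator lag, and the
  braided-actuator static force law
  `F = (π D0² P / 4)(3(1−ε)²/tan²θ0 − 1/sin²θ0)`, calibrated to 40 N at
  20 psi isometric.
* **`controller`** — flow-triggered synchronization (threshold
  0.01–0.07 l/s, hysteresis 2–5%, refractory) and fixed-rate independent
  actuation.
* **`breath_analysis`** — breath segmentation at volume-waveform local
  minima (V0), landmarks (Vpk, Fpk, P0), tidal volume / peak inspiratory
  flow / minute ventilation, breath–actuation alignment metrics
  (Vpk−P0, P0−V0) with OLS timing regressions, pressure normalization
  and per-breath ΔPpl / ΔPab / ΔPdi (Pdi = Pab − Ppl).
* **`wob`** — Campbell diagram: passive chest-wall compliance line fit
  from mechanical-ventilation PV loops, and work of breathing as the
  area between a breath's inspiratory limb and that line
  (1 cmH2O·l = 0.0980665 J).
* **`io_cli`** — waveform CSV + JSON-sidecar format, packaged scenario
  configs, and a `pamvent` command line (`simulate`, `analyze`, `wob`,
  `characterize-pam`, `run-all`).

See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

Simulate the packaged best-responder subject with the assist off and
with synchronized actuation, and compare ventilation metrics:

```python
import pamvent

sc = pamvent.load_scenario("subject-A")

rec_off, _, _ = sc.with_controller(mode="off").run(75.0)
rec_on,  _, _ = sc.run(75.0)   # synchronized assist at 20 psi

for name, rec in [("unassisted", rec_off), ("assisted", rec_on)]:
    table, summary = pamvent.analyze_record(rec)
    print(f"{name}: {summary['n_breaths']} breaths, "
          f"TV {summary['mean_TV_ml']:.0f} ml, "
          f"PIF {summary['mean_PIF_lps']:.2f} l/s, "
          f"MV {summary['minute_ventilation_lpm']:.2f} l/min")
```

prints

```
unassisted: 23 breaths, TV 55 ml, PIF 0.18 l/s, MV 1.12 l/min
assisted: 23 breaths, TV 157 ml, PIF 0.59 l/s, MV 3.17 l/min
```

— the synchronized assist roughly triples tidal volume and peak
inspiratory flow, and lifts minute ventilation from hypoventilation to
the low-normal range.  The same pipeline is available from the shell:

```sh
pamvent simulate --scenario subject-A --duration 75 --out run.csv
pamvent analyze --in run.csv --out breaths.csv
```

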