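# Methods

`pamvent` is an in-silico test bench for a diaphragm-assist system built
from McKibben pneumatic artificial muscles (PAMs): a respiratory-mechanics
surrogate of an anaesthetized ~35 kg pig, the flow-triggered controller
that synchronizes actuation with the native inspiratory effort, and the
waveform-analysis pipeline (breath segmentation, ventilation metrics,
actuation-timing alignment, pressure biomechanics and Campbell-diagram
work of breathing) used to evaluate it.

## Respiratory-mechanics surrogate

The subject is a lumped single compartment.  Airway flow Q (l/s,
inspiratory positive) is driven through the airway resistance `R_aw`
against the total elastic recoil of lung plus chest wall:

    R_aw * Q = P_vent + P_mus,di + P_mus,rc + P_assist - P_el(V)
    dV/dt    = 1000 * Q

with volume V in ml above the record-start relaxation volume.  There is no
inertance: at breathing frequencies the inertial pressure is negligible
next to resistive and elastic terms.

**Elastic recoil.**  The chest wall is linear, `V / C_cw`, so the passive
chest-wall relaxation line of the Campbell diagram is a straight line by
construction.  The lung follows a recruitment curve

    P_lung(V) = P_rec * tanh(V / V_rec) + V / C_L

— a stiff low-volume knee of amplitude `P_rec` (cmH2O) that saturates over
the first ~`V_rec` ml as atelectatic units recruit, plus a linear term with
the recruited compliance `C_L`.  Anaesthetized, supine, shallowly breathing
subjects sit on exactly such a knee: small unassisted breaths pay a high
elastic price per millilitre, while the larger assisted breaths spend most
of their volume on the recruited, compliant part of the curve.  A single
logistic (sigmoid) P-V curve was tried first and rejected: within the
logistic family the ratio of chord stiffness between the small-breath band
and the large-breath band is bounded near 1.5, which cannot reproduce the
observed combination of tidal-volume augmentation and work-of-breathing
ratios.  The `tanh + linear` form decouples the knee sharpness from the
high-volume compliance.  `lung_p_rec = 0` recovers a plain linear lung.

**Muscle pressure.**  Each breath contributes an occupational waveform:
raised-cosine rise from 0 to amplitude A over the inspiratory time
`Ti = Ti_frac * T`, then exponential relaxation with time constant
`tau_rel`.  Consecutive breaths overlap (the relaxation tail of the
previous breath is summed), so at fast rates expiration is incomplete and
a residual muscle tone persists at the breath bounds — visible in the
pressure channels and material to the Campbell analysis.  The relaxation
under deep anaesthesia is deliberately slow (`tau_rel` of order 1-3 s in
the packaged scenarios).

The amplitude splits into a diaphragmatic share `f_di` (default 0.7 — the
diaphragm dominates inspiration) and a ribcage share `1 - f_di`.  Severing
the phrenic nerves zeroes the diaphragmatic term; the remaining ribcage
effort additionally works against a flaccid diaphragm that ascends
paradoxically, modelled as an efficiency factor `rc_eff_severed` (default
0.8) on the ribcage pressure.

**Pressure channels.**  With P_mus = P_mus,di + P_mus,rc and the actuator
coupling P_assist (below):

    p_pl  = V / C_cw - (P_mus + P_assist)          (oesophageal surrogate)
    p_ab  = gamma_ab * (P_mus,di + P_assist)       (gastric surrogate)
    d_dia = k_disp * P_mus,di + k_disp_act * p_act (caudal displacement)

Under positive-pressure ventilation the muscles are passive and p_pl rises
with inspiration; under spontaneous or assisted breathing p_pl swings
negative and p_ab positive — the sign contrast the pressure analysis is
built around.  The displacement channel carries two separate gains: the
PAM pushes the diaphragm caudally by direct contact, a geometric effect of
braid contraction, so its displacement per psi (`k_disp_act`) is not tied
to its pleural-pressure coupling per psi (`k_act`).  A single shared gain
was tried and discarded — it rigidly locks the displacement augmentation
ratio to the pressure augmentation ratio, which the in-vivo endpoints
contradict (displacement rises ~5x while tidal volume rises ~3x).

**Gas exchange and drive.**  Arterial CO2 follows a one-compartment
balance, in mmHg and minutes:

    dPaCO2/dt = (0.863 * VCO2 - PaCO2 * VA) / V_store

with metabolic production `VCO2` (ml/min), alveolar ventilation
`VA = RR * max(TV - V_D, 0) / 1000` (l/min, updated each completed breath)
and an effective storage volume `V_store` (l).  The update is the exact
exponential relaxation toward the steady state PaCO2* = 0.863 VCO2 / VA;
under apnoea PaCO2 rises linearly.  pH is reported through
Henderson-Hasselbalch, `pH = 6.1 + log10(HCO3 / (0.03 PaCO2))`, with
bicarbonate held constant (no metabolic compensation on the minutes
timescale simulated).  Muscle amplitude and respiratory rate relax with a
~20 s time constant toward `A0 + G_drive * max(PaCO2 - set, 0)` and
`rr_base + G_rr * max(PaCO2 - set, 0)` — the slow drift of drive under
hypoventilation.

**Noise.**  Additive Gaussian sensor noise per channel plus a
multiplicative per-breath amplitude jitter, all drawn from a single seeded
generator; identical seeds give bit-identical records.  The measured
(noisy) flow feeds the trigger path, so a threshold set below the noise
floor produces false triggers, as the real system does.

**Integration.**  Fixed-step midpoint (RK2) at the 1 kHz output rate; the
actuator pressure lag uses its exact exponential update.  Accuracy is
guarded by a test comparing against a 10x finer step (relative error
< 1e-3 in tidal volume and peak |p_pl|).  The emitted volume channel is
the cumulative trapezoidal integral of the emitted flow channel, so
flow-volume conservation holds exactly on every record.

## Actuator model

The PAM command is one cycle of pressurization per trigger: a trapezoid
(or raised-cosine) with rise, hold and release segments and nominal 20 psi
peak.  The regulator and air line are a first-order lag (`tau_act`,
~60 ms).  Actuator pressure couples additively into the diaphragmatic
muscle-pressure path as `k_act * p_act` (cmH2O per psi).

Static contractile force uses the idealized braided-actuator (virtual
work) law

    F = (pi D0^2 P / 4) * (3 (1 - eps)^2 / tan^2(theta0) - 1 / sin^2(theta0))

with P in Pa, clamped at zero past braid lock, `(1 - eps) = 1 /
(sqrt(3) cos(theta0))`.  Friction, end effects and bladder elasticity are
ignored.  The default geometry fixes the braid angle at 30 degrees and
solves the resting diameter once so that the isometric force at 20 psi is
40 N (the bench headline); a test checks the law against a numerical
virtual-work computation on the braid cylinder to < 2%.

## Controller

Synchronized mode replays the hardware trigger path: a causal, single-pass
state machine fires when the measured flow crosses the set threshold while
armed, then disarms; re-arming requires the flow to fall below
`threshold * (1 - hysteresis)` **and** a refractory interval (default: one
command-waveform cycle, since the regulator plays one full cycle per
pulse) to elapse.  The threshold is exposed in the titration range
0.01-0.07 l/s with hysteresis 2-5%, as fractions of the threshold.
Independent mode fires at a fixed rate, blind to the flow signal.

## Analysis pipeline

* **Breath segmentation** — breath bounds are the local minima of the
  volume waveform (V0), found with prominence (default 5 ml) and
  separation (default 0.5 s) guards against sensor noise at 1 kHz;
  `scipy.signal.find_peaks` on the negated volume.  Within each breath the
  volume maximum is the start of expiration (Vpk) and the flow maximum over
  [V0, Vpk] is the peak inspiratory flow instant (Fpk) — expiratory-phase
  flow spikes are excluded by construction.
* **Features** — TV = V(Vpk) - V(V0); PIF = max flow in the inspiratory
  window; minute ventilation sums TV over breaths whose V0 lies in the
  window (default 30 s, centred in the record) scaled to a per-minute rate,
  optionally normalized by body mass.
* **Actuation onsets** — P0 is the first sample of each rising excursion
  of the actuator-pressure channel above 1 psi; the excursion closes only
  below half the threshold so noise chatter on the release tail cannot
  create phantom onsets.
* **Alignment** — each breath is matched to the unique P0 inside
  [t_V0 - Ttot/2, t_Vpk + Ttot/2); breaths with zero or multiple onsets are
  flagged and excluded from regressions.  The matching window is this
  package's rule (recorded in the summary metadata); ordinary least squares
  (`scipy.stats.linregress`) relates TV or PIF to the timing metrics
  Vpk-P0 and P0-V0.
* **Pressure analysis** — channels are zero-referenced so the mean of the
  samples at the breath bounds is zero; per breath, dPpl is the signed
  largest-magnitude excursion, dPab the peak rise, and dPdi the peak rise
  of the sample-wise Pdi = Pab - Ppl channel.
* **Campbell WOB** — the passive chest-wall line is fit by least squares
  of volume on normalized pleural pressure pooled over the inspiratory
  limbs of mechanical-ventilation breaths (expiratory limbs are excluded
  to avoid hysteresis bias).  Work of breathing is the area between a
  breath's inspiratory limb and that line over the limb's volume range,
  summing absolute sub-areas where the limb crosses the line, at
  1 cmH2O.l = 0.0980665 J.  The headline figure is the per-breath mean of
  J/l; the pooled alternative (total work / total volume) is also exposed
  because the two differ under breath-size variability.

## Packaged scenarios and calibration

Four scenario files ship with the package: `subject-A` (best responder,
synchronized assist), `weak-responder`, `severed-phrenic` and `mech-vent`
(passive positive-pressure ventilation, used for the chest-wall line).

The severed-phrenic scenario models the most severe insufficiency:
diaphragm paralysis with breathing carried by hypercapnia-driven
accessory/ribcage efforts.  Its drive uses the classic inspiratory-ramp
pattern — a constant-slope neural ramp with a variable off-switch — so
per-breath inspiratory time varies widely (`ti_jitter_sd`) and effort
amplitude co-varies with duration (`amp_ti_coupling`).  Actuation is
flow-triggered with the threshold titrated near the noise floor, which is
how timing variation arises in practice: trigger delay is dominated by
sensor noise (occasionally firing pre-emptively, giving negative P0-V0
values), so the P0-V0 metric carries no information about breath outcome,
while Vpk-P0 tracks the duration of the effort that the actuation rides
on and is strongly, linearly related to tidal volume.  An independent
fixed-rate variant was explored and rejected for this scenario: with a
rate incommensurate to the residual rhythm, both timing metrics become
functions of the same actuation-vs-effort phase and cannot reproduce the
observed asymmetry (one metric predictive, the other not).

No direct measurements of the subjects' mechanical constants (resistance,
compliances, muscle-pressure amplitudes) are available, so the subject-A
parameters were calibrated once, by bounded least squares on the full
simulate-to-analysis pipeline, against the reference in-vivo endpoints
(tidal volume 55 to 161 ml, peak inspiratory flow 0.18 to 0.59 l/s, minute
ventilation 3.1 l/min, diaphragm displacement 0.37 to 1.92 cm, work of
breathing 0.10 to 0.17 J/l), and then frozen.  The scenario files are the
study conditions; they are not retuned per run.

What the generator emulates: anaesthesia-depressed CO2-responsive
breathing with slow drive drift, breath-amplitude jitter, sensor noise,
actuator-synchronized or independent assist, phrenic transection, and
positive-pressure ventilation.  What it does not: cardiogenic
oscillations on the oesophageal balloon, airway secretions/flow-limitation
artefacts, image-derived diaphragm kinematics (displacement is a scalar
channel), O2 transport, and anaesthetic pharmacokinetics.  Tests passing
on these scenarios show the pipeline recovers the structure this model
generates at realistic noise; they do not certify performance on in-vivo
recordings.

## Numerical choices and degenerate inputs

* 1 kHz fixed step; RK2 midpoint; exact exponential updates for the
  actuator lag and CO2 balance.
* Segmentation of a constant volume trace returns zero breaths (not an
  error); series shorter than twice the separation guard are rejected.
* Pressure normalization with no segments warns and returns the series
  unchanged; an empty minute-ventilation window warns and reports 0.
* Zero-variance predictors and sub-3-point regressions raise.
* Half-open, 0-based sample indexing internally; reported times are
  seconds from record start.
* Scenario runs of 60-1200 s at 1 kHz keep every packaged experiment
  within seconds of wall time; the severed-phrenic regression uses a
  1200 s run (>= 250 breaths) and the synchronization-variance comparison
  420 s per arm (>= 120 breaths), sizes chosen to make the statistical
  contrasts decisive at desk scale.

## Known limitations

* The single-compartment model has one flow path: no distinct upper-airway
  vs pleural pressure drops, so airway occlusion manoeuvres are out of
  scope.
* The actuator-to-diaphragm coupling is additive in pressure; no contact
  mechanics, so assist during positive-pressure ventilation is rejected
  rather than modelled.
* Gas exchange tracks CO2 only; hypoxaemia is invisible.
* The chemoreflex is a static gain with first-order smoothing — adequate
  for minutes-long drifts, not for sleep-apnoea-style instability.
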