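"""In-silico respiratory-mechanics surrogate of the anaesthetized pig.

A lumped single-compartment model drives airway flow through a resistance
against the elastic recoil of lung plus chest wall.  Pressure sources are
the respiratory muscles (split into a diaphragmatic and a ribcage
component), an optional positive-pressure ventilator, and the implanted
pneumatic-artificial-muscle (PAM) assist, whose pressure couples linearly
into the diaphragmatic path.

Lung elastic recoil is a recruitment curve: a stiff low-volume knee
(atelectasis under anaesthesia) that saturates as units recruit, plus a
linear compliant term, P_lung(V) = P_rec * tanh(V / V_rec) + V / C_L.
The chest wall is linear, so the passive chest-wall line of a Campbell
diagram remains a straight line.  Respiratory drive (muscle
amplitude and rate) responds slowly to the CO2 state through a simple
chemoreflex with first-order smoothing.

Units: flow l/s (inspiratory positive), volume ml above the record-start
reference, respiratory pressures cmH2O, actuation pressure psi, time s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .actuator import PressureWaveformSpec, command_waveform
from .controller import ControllerConfig, FlowTriggerStateMachine, TriggerEvent

# ---------------------------------------------------------------------------
# Gas exchange state (CO2 balance + Henderson-Hasselbalch pH)
# ---------------------------------------------------------------------------

#: mmHg * l/min of CO2 clearance per ml/min of CO2 production (BTPS factor)
CO2_PRODUCTION_FACTOR = 0.863


def ph_from_gas(paco2: float, hco3: float) -> float:
    """Arterial pH from the Henderson-Hasselbalch relation.

    pH = 6.1 + log10(HCO3- / (0.03 * PaCO2)); decreases monotonically in
    PaCO2 at fixed bicarbonate (respiratory acidosis direction).
    """
    if paco2 <= 0 or hco3 <= 0:
        raise ValueError("PaCO2 and HCO3- must be positive")
    return 6.1 + math.log10(hco3 / (0.03 * paco2))


@dataclass(frozen=True)
class GasState:
    """Arterial CO2 tension (mmHg) and bicarbonate (mmol/l)."""

    paco2: float
    hco3: float = 24.0

    def __post_init__(self) -> None:
        if self.paco2 <= 0 or self.hco3 <= 0:
            raise ValueError("PaCO2 and HCO3- must be positive")

    @property
    def ph(self) -> float:
        return ph_from_gas(self.paco2, self.hco3)


@dataclass(frozen=True)
class GasConfig:
    """Initial gas state plus CO2 production and effective storage volume."""

    paco2_0: float = 45.0  # mmHg
    hco3_0: float = 24.0  # mmol/l
    vco2: float = 120.0  # ml CO2 / min (metabolic production)
    v_store: float = 25.0  # l, effective body CO2 storage volume


def update_gas_state(
    state: GasState, alveolar_ventilation: float, dt: float, config: "SimConfig"
) -> GasState:
    """Advance the CO2 balance by ``dt`` seconds at fixed alveolar ventilation.

    dPaCO2/dt = (k_prod - PaCO2 * VA) / V_store   (per minute),

    with k_prod = 0.863 * VCO2.  For VA > 0 the update is the exact
    exponential relaxation toward the steady state PaCO2* = k_prod / VA;
    under apnoea (VA = 0) PaCO2 rises linearly, so hypercarbia accumulates.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if alveolar_ventilation < 0:
        raise ValueError("alveolar ventilation must be >= 0")
    g = config.gas
    k_prod = CO2_PRODUCTION_FACTOR * g.vco2  # mmHg * l/min
    dt_min = dt / 60.0
    if alveolar_ventilation == 0.0:
        paco2 = state.paco2 + k_prod / g.v_store * dt_min
    else:
        ss = k_prod / alveolar_ventilation
        decay = math.exp(-alveolar_ventilation * dt_min / g.v_store)
        paco2 = ss + (state.paco2 - ss) * decay
    return GasState(paco2=paco2, hco3=state.hco3)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    """Per-channel additive Gaussian sensor noise SDs and breath jitter."""

    flow_sd: float = 0.004  # l/s
    p_pl_sd: float = 0.02  # cmH2O
    p_ab_sd: float = 0.02  # cmH2O
    p_act_sd: float = 0.05  # psi
    d_dia_sd: float = 0.01  # cm
    amp_jitter_sd: float = 0.04  # multiplicative, per breath
    ti_jitter_sd: float = 0.0  # multiplicative, per-breath inspiratory time

    def __post_init__(self) -> None:
        for name in ("flow_sd", "p_pl_sd", "p_ab_sd", "p_act_sd", "d_dia_sd",
                     "amp_jitter_sd", "ti_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def off(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class VentilatorSettings:
    """Positive-pressure (pressure-controlled) ventilator settings."""

    rate: float = 15.0  # breaths/min
    pip: float = 8.0  # cmH2O, peak inspiratory pressure above PEEP
    ti_frac: float = 0.33  # inspiratory fraction of the cycle
    t_ramp: float = 0.15  # s, pressure rise/fall ramp

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.pip < 0 or not (0 < self.ti_frac < 1):
            raise ValueError("invalid ventilator settings")


@dataclass(frozen=True)
class SimConfig:
    """Mechanical and chemoreflex parameters of the surrogate subject.

    Lung recoil combines a recruitment knee (amplitude ``lung_p_rec``
    cmH2O, saturating over ``lung_v_rec`` ml) with a linear compliance
    ``C_L``; setting ``lung_p_rec = 0`` gives a plain linear lung.
    """

    fs: float = 1000.0  # Hz
    R_aw: float = 2.0  # cmH2O * s / l
    C_L: float = 215.0  # ml/cmH2O, linear (recruited) lung compliance
    lung_p_rec: float = 2.3  # cmH2O, recruitment-knee amplitude
    lung_v_rec: float = 40.0  # ml, recruitment-knee volume scale
    C_cw: float = 250.0  # ml/cmH2O, chest wall (linear)
    V_D: float = 45.0  # ml anatomical dead space
    body_mass: float = 35.0  # kg
    f_di: float = 0.7  # diaphragm fraction of total muscle pressure
    severed_phrenic: bool = False
    # efficiency of ribcage efforts against a flaccid diaphragm: part of the
    # pleural swing is absorbed by paradoxical cephalad diaphragm motion
    rc_eff_severed: float = 0.8
    A0: float = 1.5  # cmH2O baseline muscle-pressure amplitude
    G_drive: float = 0.04  # cmH2O per mmHg PaCO2 above set point
    paco2_set: float = 40.0  # mmHg
    rr_base: float = 16.0  # breaths/min
    G_rr: float = 0.1  # breaths/min per mmHg above set point
    Ti_frac: float = 0.3  # inspiratory fraction of the breath
    # constant-slope ramp drive: amplitude scales as (Ti_k / Ti_nominal)^c,
    # c = 1 reproduces the classic variable-off-switch inspiratory ramp
    amp_ti_coupling: float = 0.0
    tau_rel: float = 0.35  # s, muscle relaxation time constant
    tau_drive: float = 20.0  # s, chemoreflex drive smoothing
    k_act: float = 0.25  # cmH2O of equivalent muscle pressure per psi
    tau_act: float = 0.06  # s, regulator + line pressure lag
    gamma_ab: float = 0.9  # abdominal transmission coefficient
    k_disp: float = 0.3  # cm of caudal displacement per cmH2O of diaphragm drive
    k_disp_act: float = 0.09  # cm per psi: direct caudal push of the PAM
    gas: GasConfig = field(default_factory=GasConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        positives = {
            "fs": self.fs, "R_aw": self.R_aw, "C_L": self.C_L,
            "C_cw": self.C_cw, "body_mass": self.body_mass,
            "tau_rel": self.tau_rel, "tau_drive": self.tau_drive,
            "tau_act": self.tau_act, "rr_base": self.rr_base,
        }
        for name, val in positives.items():
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be finite and positive")
        for name in ("V_D", "A0", "G_drive", "G_rr", "k_act", "gamma_ab",
                     "k_disp", "k_disp_act", "paco2_set", "lung_p_rec"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not (0 <= self.f_di <= 1):
            raise ValueError("f_di must lie in [0, 1]")
        if not (0 < self.rc_eff_severed <= 1):
            raise ValueError("rc_eff_severed must lie in (0, 1]")
        if not (0 < self.Ti_frac < 1):
            raise ValueError("Ti_frac must lie in (0, 1)")
        if self.lung_v_rec <= 0:
            raise ValueError("lung_v_rec must be positive")

    # -- elastic recoil -----------------------------------------------------

    def lung_recoil(self, v_ml: float) -> float:
        """Lung elastic recoil pressure (cmH2O) at volume ``v_ml`` above FRC.

        Stiff recruitment knee saturating over ``lung_v_rec``, then the
        linear compliance ``C_L``; monotone increasing for all volumes.
        """
        return self.lung_p_rec * math.tanh(v_ml / self.lung_v_rec) + v_ml / self.C_L

    def elastic_recoil(self, v_ml: float) -> float:
        """Total (lung + chest wall) elastic recoil pressure, cmH2O."""
        return self.lung_recoil(v_ml) + v_ml / self.C_cw


# ---------------------------------------------------------------------------
# Muscle pressure profile
# ---------------------------------------------------------------------------

def muscle_pressure(phase: float, amplitude: float, Ti: float, tau_rel: float) -> float:
    """Occupational muscle-pressure waveform at ``phase`` seconds into a breath.

    Raised-cosine rise from 0 to ``amplitude`` over the inspiratory time
    ``Ti``, then exponential relaxation with time constant ``tau_rel``.
    """
    if Ti <= 0 or tau_rel <= 0:
        raise ValueError("Ti and tau_rel must be positive")
    if phase < 0:
        raise ValueError("phase must be >= 0")
    if phase <= Ti:
        return amplitude * math.sin(0.5 * math.pi * phase / Ti) ** 2
    return amplitude * math.exp(-(phase - Ti) / tau_rel)


# ---------------------------------------------------------------------------
# Waveform record
# ---------------------------------------------------------------------------

@dataclass
class WaveformRecord:
    """Uniformly sampled multichannel physiological recording."""

    fs: float
    t: np.ndarray  # s from record start
    flow: np.ndarray  # l/s, inspiratory positive
    volume: np.ndarray  # ml above record-start reference
    p_pl: np.ndarray  # cmH2O (pleural surrogate)
    p_ab: np.ndarray  # cmH2O (abdominal surrogate)
    p_act: np.ndarray  # psi
    d_dia: Optional[np.ndarray] = None  # cm caudal diaphragm displacement
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.t.size
        channels = [self.flow, self.volume, self.p_pl, self.p_ab, self.p_act]
        if self.d_dia is not None:
            channels.append(self.d_dia)
        if any(c.size != n for c in channels):
            raise ValueError("all channels must have the same length")
        # volume-flow conservation (l -> ml)
        dt = 1.0 / self.fs
        vol = np.concatenate(
            ([0.0], np.cumsum((self.flow[1:] + self.flow[:-1]) * 0.5 * dt))
        ) * 1000.0
        if np.max(np.abs(vol + self.volume[0] - self.volume)) > 0.1:
            raise ValueError("volume channel is not the integral of flow")

    @property
    def duration(self) -> float:
        return self.t.size / self.fs


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(
    config: SimConfig,
    controller: Optional[ControllerConfig] = None,
    ventilator: Optional[VentilatorSettings] = None,
    duration: float = 60.0,
) -> Tuple[WaveformRecord, List[TriggerEvent], List[Tuple[float, GasState]]]:
    """Run the surrogate subject for ``duration`` seconds.

    Returns the sampled waveform record, the list of actuation trigger
    events emitted by the controller, and the CO2/pH state sampled once per
    second.  Exactly one respiratory drive is active per run: spontaneous
    (optionally actuator-assisted) or positive-pressure mechanical
    ventilation.
    """
    controller = controller or ControllerConfig(mode="off")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration < 60.0 / config.rr_base and ventilator is None:
        raise ValueError("duration must cover at least one breath period")
    if ventilator is not None and controller.mode != "off":
        raise ValueError(
            "actuator assist during positive-pressure ventilation is not modelled; "
            "use controller mode 'off' with a ventilator"
        )

    fs = config.fs
    dt = 1.0 / fs
    n = int(round(duration * fs))
    rng = np.random.default_rng(config.seed)
    noise = config.noise
    noise_flow = rng.normal(0.0, noise.flow_sd, n) if noise.flow_sd else np.zeros(n)
    noise_ppl = rng.normal(0.0, noise.p_pl_sd, n) if noise.p_pl_sd else np.zeros(n)
    noise_pab = rng.normal(0.0, noise.p_ab_sd, n) if noise.p_ab_sd else np.zeros(n)
    noise_pact = rng.normal(0.0, noise.p_act_sd, n) if noise.p_act_sd else np.zeros(n)
    noise_dia = rng.normal(0.0, noise.d_dia_sd, n) if noise.d_dia_sd else np.zeros(n)

    spontaneous = ventilator is None
    if config.severed_phrenic:
        mus_fraction = (1.0 - config.f_di) * config.rc_eff_severed
        di_share = 0.0
    else:
        mus_fraction = 1.0
        di_share = config.f_di
    # ribcage share of the generated muscle pressure, relative to mus_fraction
    wf: PressureWaveformSpec = controller.waveform
    sm = None
    schedule: List[float] = []
    if controller.mode == "synchronized":
        sm = FlowTriggerStateMachine(
            controller.threshold, controller.hysteresis, controller.effective_refractory
        )
    elif controller.mode == "independent":
        period = 60.0 / controller.rate
        schedule = [k * period for k in range(int(duration / period) + 1)]

    # state
    v = 0.0  # ml above record start
    p_act = 0.0  # psi
    gas = GasState(config.gas.paco2_0, config.gas.hco3_0)
    amp = config.A0 + config.G_drive * max(gas.paco2 - config.paco2_set, 0.0)
    rr = config.rr_base + config.G_rr * max(gas.paco2 - config.paco2_set, 0.0)
    va = CO2_PRODUCTION_FACTOR * config.gas.vco2 / gas.paco2  # consistent start
    t_last_trig = -math.inf
    sched_idx = 0
    triggers: List[TriggerEvent] = []
    gas_series: List[Tuple[float, GasState]] = []

    # breath bookkeeping: list of (onset, amplitude, Ti) for active + previous
    breaths: List[Tuple[float, float, float]] = []
    next_onset = 0.0
    cycle_vmin = 0.0
    cycle_vmax = 0.0
    cycle_tmin = 0.0
    cycle_tmax = 0.0
    period_cur = 60.0 / rr
    # per-completed-breath ground truth (exposed in record.meta)
    truth: dict = {"t_onset": [], "tv_ml": [], "t_vmin": [], "t_vmax": []}

    if ventilator is not None:
        vent_period = 60.0 / ventilator.rate
        vent_ti = ventilator.ti_frac * vent_period

    flow_arr = np.empty(n)
    ppl_arr = np.empty(n)
    pab_arr = np.empty(n)
    pact_arr = np.empty(n)
    dia_arr = np.empty(n)

    tau_rel = config.tau_rel
    r_aw = config.R_aw
    k_act = config.k_act
    recoil = config.elastic_recoil
    exp_act = math.exp(-dt / config.tau_act)

    def p_mus_at(tq: float) -> float:
        total = 0.0
        for onset, a, ti in breaths:
            ph = tq - onset
            if ph < 0:
                continue
            if ph <= ti:
                total += a * math.sin(0.5 * math.pi * ph / ti) ** 2
            else:
                total += a * math.exp(-(ph - ti) / tau_rel)
        return total

    def p_vent_at(tq: float) -> float:
        ph = tq % vent_period
        ramp = ventilator.t_ramp
        if ph < ramp:
            return ventilator.pip * ph / ramp
        if ph < vent_ti:
            return ventilator.pip
        if ph < vent_ti + ramp:
            return ventilator.pip * (1.0 - (ph - vent_ti) / ramp)
        return 0.0

    gas_stride = int(round(fs))  # 1 Hz gas sampling

    for i in range(n):
        t = i * dt

        # breath onset scheduling (spontaneous drive only)
        if spontaneous and t >= next_onset:
            if breaths:
                tv_cycle = cycle_vmax - cycle_vmin
                rr_inst = 60.0 / period_cur
                va = rr_inst * max(tv_cycle - config.V_D, 0.0) / 1000.0
                truth["t_onset"].append(breaths[-1][0])
                truth["tv_ml"].append(tv_cycle)
                truth["t_vmin"].append(cycle_tmin)
                truth["t_vmax"].append(cycle_tmax)
            jitter = 1.0
            if noise.amp_jitter_sd:
                jitter = max(0.0, 1.0 + noise.amp_jitter_sd * rng.standard_normal())
            period_cur = 60.0 / rr
            ti_nom = config.Ti_frac * period_cur
            ti = ti_nom
            if noise.ti_jitter_sd:
                ti *= max(0.3, 1.0 + noise.ti_jitter_sd * rng.standard_normal())
            if config.amp_ti_coupling:
                jitter *= (ti / ti_nom) ** config.amp_ti_coupling
            breaths.append((next_onset, amp * jitter, ti))
            if len(breaths) > 2:
                breaths.pop(0)
            next_onset = next_onset + period_cur
            cycle_vmin = v
            cycle_vmax = v
            cycle_tmin = t
            cycle_tmax = t

        # independent-mode scheduled triggers
        if controller.mode == "independent" and sched_idx < len(schedule) \
                and t >= schedule[sched_idx] - 0.5 * dt:
            triggers.append(TriggerEvent(t, "schedule"))
            t_last_trig = t
            sched_idx += 1

        # pressure sources at t
        p_mus = p_mus_at(t) if spontaneous else 0.0
        p_di = di_share * p_mus
        p_rc = (mus_fraction - di_share) * p_mus if spontaneous else 0.0
        p_assist = k_act * p_act
        p_vent = p_vent_at(t) if ventilator is not None else 0.0
        p_drive = p_vent + p_di + p_rc + p_assist

        flow = (p_drive - recoil(v)) / r_aw  # l/s
        flow_arr[i] = flow
        ppl_arr[i] = v / config.C_cw - (p_di + p_rc + p_assist)
        pab_arr[i] = config.gamma_ab * (p_di + p_assist)
        pact_arr[i] = p_act
        # the PAM pushes the diaphragm caudally directly: its displacement
        # gain is geometric, distinct from its pleural pressure coupling
        dia_arr[i] = config.k_disp * p_di + config.k_disp_act * p_act

        # flow trigger operates on the measured (noisy) flow, causally
        if sm is not None:
            armed_before = sm.armed
            if sm.step(flow + noise_flow[i], t):
                triggers.append(TriggerEvent(t, "flow-crossing", armed_before))
                t_last_trig = t

        # actuator pressure lag toward the commanded waveform
        t_next = t + dt
        since = t_next - t_last_trig
        p_cmd = command_waveform(wf, since) if since < wf.cycle_length else 0.0
        p_act_next = p_cmd + (p_act - p_cmd) * exp_act

        # volume update (midpoint RK2 on dV/dt = 1000*(P_drive - P_el)/R)
        tm = t + 0.5 * dt
        p_mus_m = p_mus_at(tm) if spontaneous else 0.0
        p_assist_m = k_act * 0.5 * (p_act + p_act_next)
        p_vent_m = p_vent_at(tm) if ventilator is not None else 0.0
        p_drive_m = p_vent_m + mus_fraction * p_mus_m + p_assist_m \
            if spontaneous else p_vent_m + p_assist_m
        v_mid = v + 0.5 * dt * 1000.0 * flow
        v = v + dt * 1000.0 * (p_drive_m - recoil(v_mid)) / r_aw
        p_act = p_act_next

        if v < cycle_vmin:
            cycle_vmin = v
            cycle_tmin = t + dt
        if v > cycle_vmax:
            cycle_vmax = v
            cycle_tmax = t + dt

        # gas exchange and chemoreflex drive
        gas = update_gas_state(gas, va, dt, config)
        excess = max(gas.paco2 - config.paco2_set, 0.0)
        amp += dt / config.tau_drive * (config.A0 + config.G_drive * excess - amp)
        rr += dt / config.tau_drive * (config.rr_base + config.G_rr * excess - rr)
        if i % gas_stride == 0:
            gas_series.append((t, gas))

    flow_meas = flow_arr + noise_flow
    dt_arr = dt
    volume = np.concatenate(
        ([0.0], np.cumsum((flow_meas[1:] + flow_meas[:-1]) * 0.5 * dt_arr))
    ) * 1000.0

    record = WaveformRecord(
        fs=fs,
        t=np.arange(n) / fs,
        flow=flow_meas,
        volume=volume,
        p_pl=ppl_arr + noise_ppl,
        p_ab=pab_arr + noise_pab,
        p_act=np.maximum(pact_arr + noise_pact, 0.0) if noise.p_act_sd else pact_arr,
        d_dia=dia_arr + noise_dia,
        meta={
            "seed": config.seed,
            "body_mass_kg": config.body_mass,
            "controller_mode": controller.mode,
            "ventilator": ventilator is not None,
            "severed_phrenic": config.severed_phrenic,
            "truth": truth,
        },
    )
    record.validate()
    return record, triggers, gas_series


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different RNG seed."""
    return replace(config, seed=int(seed))
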