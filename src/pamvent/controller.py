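"""Actuation scheduling: flow-triggered synchronization and fixed-rate timing.

The synchronized mode replays the hardware trigger path: when the airway
flow crosses a user-set threshold while the detector is armed, a trigger
pulse fires and one pressurization cycle is played.  The detector disarms
on firing and re-arms only once the flow has fallen below
``threshold * (1 - hysteresis)`` and the refractory interval has elapsed.
The detector is causal and single-pass (no lookahead), mirroring the
real-time hardware.

The independent mode fires on a fixed schedule regardless of the flow
signal (manual timing initiated by user input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .actuator import PressureWaveformSpec

#: manual titration range of the flow trigger threshold (l/s)
THRESHOLD_RANGE_LPS = (0.01, 0.07)
#: manual titration range of the trigger hysteresis (fraction of threshold)
HYSTERESIS_RANGE = (0.02, 0.05)


@dataclass(frozen=True)
class ControllerConfig:
    """Trigger configuration for one run.

    mode: "off", "independent" (fixed rate) or "synchronized" (flow trigger).
    threshold: flow threshold in l/s (synchronized mode).
    hysteresis: re-arm fraction of threshold (dimensionless).
    refractory: minimum spacing between triggers, s.  ``None`` defaults to
        the commanded waveform cycle length (the regulator plays one full
        cycle per pulse).
    rate: actuations per minute (independent mode).
    """

    mode: str = "off"
    threshold: float = 0.04
    hysteresis: float = 0.03
    refractory: Optional[float] = None
    rate: float = 14.0
    waveform: PressureWaveformSpec = field(default_factory=PressureWaveformSpec)

    def __post_init__(self) -> None:
        if self.mode not in ("off", "independent", "synchronized"):
            raise ValueError(f"unknown controller mode {self.mode!r}")
        if self.mode == "synchronized" and self.threshold <= 0:
            raise ValueError("threshold must be > 0 in synchronized mode")
        if not (0 <= self.hysteresis < 1):
            raise ValueError("hysteresis must lie in [0, 1)")
        if self.refractory is not None and self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        if self.mode == "independent" and self.rate <= 0:
            raise ValueError("rate must be > 0 in independent mode")

    @property
    def effective_refractory(self) -> float:
        if self.refractory is not None:
            return self.refractory
        return self.waveform.cycle_length


@dataclass(frozen=True)
class TriggerEvent:
    """One emitted actuation command."""

    t_trigger: float  # s from record start
    cause: str  # "flow-crossing" or "schedule"
    armed_state_before: bool = True


class FlowTriggerStateMachine:
    """Causal per-sample trigger detector (threshold + hysteresis + refractory).

    The same state machine drives both offline detection on a recorded flow
    series and the online trigger path inside the simulator loop.
    """

    def __init__(self, threshold: float, hysteresis: float, refractory: float):
        if threshold <= 0:
            raise ValueError("threshold must be > 0")
        self.threshold = threshold
        self.rearm_level = threshold * (1.0 - hysteresis)
        self.refractory = refractory
        self.armed = True
        self.last_fire: float = -np.inf

    def step(self, flow: float, t: float) -> bool:
        """Advance one sample; return True when a trigger fires at ``t``."""
        if self.armed:
            if flow >= self.threshold:
                self.armed = False
                self.last_fire = t
                return True
        else:
            if flow < self.rearm_level and (t - self.last_fire) >= self.refractory:
                self.armed = True
        return False


def detect_triggers(
    flow: Sequence[float],
    fs: float,
    config: ControllerConfig,
    t0: float = 0.0,
) -> List[TriggerEvent]:
    """Run the synchronized trigger detector over a uniformly sampled flow.

    A trigger fires at the first sample where flow >= threshold while
    armed; re-arming requires the flow to fall below
    threshold * (1 - hysteresis) AND the refractory interval to elapse.
    """
    if config.mode != "synchronized":
        raise ValueError("detect_triggers requires synchronized mode")
    flow = np.asarray(flow, dtype=float)
    if flow.size == 0:
        raise ValueError("empty flow series")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    sm = FlowTriggerStateMachine(
        config.threshold, config.hysteresis, config.effective_refractory
    )
    events: List[TriggerEvent] = []
    dt = 1.0 / fs
    # candidate samples are the armed-and-above ones; the sequential pass
    # below resolves arming/refractory, which depend on past firings
    for i in range(flow.size):
        t = t0 + i * dt
        armed_before = sm.armed
        if sm.step(flow[i], t):
            events.append(TriggerEvent(t, "flow-crossing", armed_before))
    return events


def independent_schedule(
    rate: float, duration: float, t0: float = 0.0
) -> List[TriggerEvent]:
    """Fixed-rate trigger schedule: events at t0 + k * 60/rate within duration."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if duration < t0:
        raise ValueError("duration must be >= t0")
    period = 60.0 / rate
    events = [TriggerEvent(t0, "schedule")]
    k = 1
    while t0 + k * period < duration - 1e-9:
        events.append(TriggerEvent(t0 + k * period, "schedule"))
        k += 1
    return events
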