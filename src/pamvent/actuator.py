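"""McKibben pneumatic-artificial-muscle (PAM) model.

Covers the commanded pressurization waveform played by the electropneumatic
regulator on each trigger, a first-order lag standing in for the regulator
and air line, the classic braided-actuator static force law, and the linear
coupling of actuator pressure to an equivalent respiratory muscle pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

PSI_TO_PA = 6894.757
"""Conversion constant, pounds-per-square-inch to pascal."""

NOMINAL_PEAK_PSI = 20.0
"""Nominal peak actuation pressure used throughout the in-vivo protocol."""


# ---------------------------------------------------------------------------
# Commanded pressurization waveform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PressureWaveformSpec:
    """One cycle of pressurization and depressurization.

    Parameters
    ----------
    peak : float
        Plateau pressure in psi (nominal 20).
    t_rise, t_hold, t_release : float
        Durations in seconds of the rising ramp, plateau hold and release.
    shape : {"trapezoid", "raised-cosine"}
        Ramp shape; the plateau and total cycle length are identical.
    """

    peak: float = NOMINAL_PEAK_PSI
    t_rise: float = 0.3
    t_hold: float = 0.4
    t_release: float = 0.3
    shape: str = "trapezoid"

    def __post_init__(self) -> None:
        if self.peak < 0:
            raise ValueError("peak pressure must be >= 0")
        if min(self.t_rise, self.t_hold, self.t_release) < 0:
            raise ValueError("waveform durations must be >= 0")
        if self.shape not in ("trapezoid", "raised-cosine"):
            raise ValueError(f"unknown waveform shape {self.shape!r}")

    @property
    def cycle_length(self) -> float:
        return self.t_rise + self.t_hold + self.t_release


def command_waveform(spec: PressureWaveformSpec, t_since_trigger):
    """Commanded regulator pressure (psi) at time ``t`` after a trigger.

    Zero at t = 0 and after the cycle ends, ``spec.peak`` on the plateau,
    continuous throughout.  Accepts scalars or arrays.
    """
    t = np.asarray(t_since_trigger, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since trigger must be >= 0")
    r, h, rel = spec.t_rise, spec.t_hold, spec.t_release
    up = np.zeros_like(t)
    # rising limb
    if r > 0:
        frac = np.clip(t / r, 0.0, 1.0)
    else:
        frac = (t >= 0).astype(float)
    if spec.shape == "raised-cosine":
        frac = 0.5 * (1.0 - np.cos(np.pi * frac))
    up = frac
    # release limb
    if rel > 0:
        dfrac = np.clip((t - r - h) / rel, 0.0, 1.0)
    else:
        dfrac = (t >= r + h).astype(float)
    if spec.shape == "raised-cosine":
        dfrac = 0.5 * (1.0 - np.cos(np.pi * dfrac))
    out = spec.peak * (up - dfrac)
    out = np.where(t >= spec.cycle_length, 0.0, out)
    if np.ndim(t_since_trigger) == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Static force law (braided actuator)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActuatorGeometry:
    """Idealized braid geometry: resting diameter, braid angle, length."""

    D0: float  # m
    theta0: float  # rad
    L0: float = 0.15  # m

    def __post_init__(self) -> None:
        if not (0 < self.theta0 < math.pi / 2):
            raise ValueError("braid angle must lie in (0, pi/2)")
        if self.D0 <= 0 or self.L0 <= 0:
            raise ValueError("geometry dimensions must be positive")

    @property
    def lock_contraction(self) -> float:
        """Contraction ratio at which braid geometry gives zero force.

        Root of the force law: 3 (1 - eps)^2 cos^2(theta0) = 1.
        """
        return 1.0 - 1.0 / (math.sqrt(3.0) * math.cos(self.theta0))


def mckibben_force(pressure_psi, contraction_ratio, geom: ActuatorGeometry):
    """Static contractile force (N) of an idealized braided actuator.

    F = (pi * D0^2 * P / 4) * (3 (1 - eps)^2 / tan^2(theta0) - 1 / sin^2(theta0))

    with P in Pa.  Force is clamped at zero past braid lock.  Friction and
    end effects are ignored.
    """
    p = np.asarray(pressure_psi, dtype=float)
    eps = np.asarray(contraction_ratio, dtype=float)
    if np.any(p < 0):
        raise ValueError("pressure must be >= 0")
    if np.any((eps < 0) | (eps >= 1)):
        raise ValueError("contraction ratio must lie in [0, 1)")
    p_pa = p * PSI_TO_PA
    t2 = math.tan(geom.theta0) ** 2
    s2 = math.sin(geom.theta0) ** 2
    f = (math.pi * geom.D0**2 * p_pa / 4.0) * (3.0 * (1.0 - eps) ** 2 / t2 - 1.0 / s2)
    f = np.maximum(f, 0.0)
    if np.ndim(pressure_psi) == 0 and np.ndim(contraction_ratio) == 0:
        return float(f)
    return f


def calibrated_geometry(
    force_target_n: float = 40.0,
    pressure_psi: float = NOMINAL_PEAK_PSI,
    theta0: float = math.pi / 6,
    L0: float = 0.15,
) -> ActuatorGeometry:
    """Geometry whose isometric force at the nominal pressure equals the target.

    The bench characterization of the implanted actuators gives a single
    headline endpoint (40 N at 20 psi, zero contraction); the braid diameter
    is solved from the force law at eps = 0 with the braid angle fixed at 30
    degrees (a typical resting McKibben angle), then frozen.
    """
    t2 = math.tan(theta0) ** 2
    s2 = math.sin(theta0) ** 2
    coeff = 3.0 / t2 - 1.0 / s2
    d0 = math.sqrt(4.0 * force_target_n / (math.pi * pressure_psi * PSI_TO_PA * coeff))
    return ActuatorGeometry(D0=d0, theta0=theta0, L0=L0)


DEFAULT_GEOMETRY = calibrated_geometry()


# ---------------------------------------------------------------------------
# Pressure dynamics and respiratory coupling
# ---------------------------------------------------------------------------

def actuator_pressure_dynamics(p_cmd: float, p_now: float, tau: float, dt: float) -> float:
    """One first-order-lag step of the regulator + line pressure (psi).

    Exact exponential update toward the commanded pressure; the step
    response reaches 63.2% of a step at t = tau.
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    return p_cmd + (p_now - p_cmd) * math.exp(-dt / tau)


def assist_pressure(p_act_psi, k_act: float):
    """Equivalent respiratory muscle pressure (cmH2O) of the pressurized PAM.

    Linear coupling: the pressurized actuator pushes the diaphragm caudally
    and its contribution is treated as an additive muscle-pressure term.
    """
    p = np.asarray(p_act_psi, dtype=float)
    if np.any(p < 0) or k_act < 0:
        raise ValueError("actuator pressure and coupling gain must be >= 0")
    out = k_act * p
    if np.ndim(p_act_psi) == 0:
        return float(out)
    return out


def characterize(
    geom: ActuatorGeometry = DEFAULT_GEOMETRY,
    pressures_psi=(0, 5, 10, 15, 20, 25),
    contractions=(0.0, 0.05, 0.1, 0.15, 0.2, 0.25),
):
    """Force-pressure and force-contraction tables for a geometry.

    Returns a list of dict rows (pressure_psi, contraction_ratio, force_n)
    suitable for CSV export.
    """
    rows = []
    for p in pressures_psi:
        for e in contractions:
            if e >= 1:
                continue
            rows.append(
                {
                    "pressure_psi": float(p),
                    "contraction_ratio": float(e),
                    "force_n": mckibben_force(float(p), float(e), geom),
                }
            )
    return rows
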