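"""Campbell-diagram work of breathing.

The passive chest-wall compliance line is fit from pleural
pressure-volume data recorded under positive-pressure mechanical
ventilation (the respiratory muscles are passive, so the pleural trace
follows the chest-wall relaxation line).  Work of breathing for a
spontaneous or assisted breath is the area enclosed between the
inspiratory limb of its pleural PV loop and that compliance line over the
limb's volume range, converted at 1 cmH2O.l = 0.0980665 J.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import stats

from .breath_analysis import BreathSegment

CMH2O_L_TO_J = 0.0980665
NORMAL_WOB_RANGE_J_PER_L = (0.35, 0.7)


@dataclass(frozen=True)
class PVLoop:
    """Pleural pressure-volume loop for one breath.

    Ordered (p_pl cmH2O, volume ml) vertices, split into inspiratory and
    expiratory limbs at the Vpk landmark.
    """

    p_insp: np.ndarray  # cmH2O, V0 -> Vpk
    v_insp: np.ndarray  # ml
    p_exp: np.ndarray  # cmH2O, Vpk -> end
    v_exp: np.ndarray  # ml

    def __post_init__(self) -> None:
        if self.p_insp.size < 2 or self.p_exp.size < 1:
            raise ValueError("loop limbs must be non-empty")
        if self.p_insp.size != self.v_insp.size or self.p_exp.size != self.v_exp.size:
            raise ValueError("limb pressure/volume lengths differ")

    @property
    def tidal_volume(self) -> float:
        return float(self.v_insp[-1] - self.v_insp[0])


@dataclass(frozen=True)
class ComplianceFit:
    """Passive chest-wall compliance line: V = C_cw_fit * P + intercept."""

    C_cw_fit: float  # ml/cmH2O
    intercept: float  # ml
    r2: float
    n_breaths: int

    def pressure_at(self, volume_ml) -> np.ndarray:
        """Compliance-line pressure evaluated at the given volumes."""
        return (np.asarray(volume_ml, dtype=float) - self.intercept) / self.C_cw_fit


@dataclass(frozen=True)
class WOBResult:
    """Work of breathing for one breath."""

    work: float  # J
    work_per_litre: float  # J/l
    TV: float  # ml


def loops_from_record(
    p_pl: Sequence[float],
    volume: Sequence[float],
    segments: Sequence[BreathSegment],
    fs: float,
) -> List[PVLoop]:
    """Build per-breath PV loops from (normalized) pleural pressure and volume."""
    p = np.asarray(p_pl, dtype=float)
    v = np.asarray(volume, dtype=float)
    loops = []
    for seg in segments:
        ipk = int(round(seg.t_Vpk * fs))
        if ipk <= seg.i_start or seg.i_end > p.size:
            continue
        loops.append(
            PVLoop(
                p_insp=p[seg.i_start : ipk + 1].copy(),
                v_insp=v[seg.i_start : ipk + 1].copy(),
                p_exp=p[ipk : seg.i_end].copy(),
                v_exp=v[ipk : seg.i_end].copy(),
            )
        )
    return loops


def fit_chest_wall_compliance(mv_breaths: Sequence[PVLoop]) -> ComplianceFit:
    """Least-squares chest-wall line from mechanical-ventilation PV loops.

    Volume is regressed on pleural pressure pooled over the inspiratory
    limbs only (passive inflation); expiratory limbs are excluded to avoid
    hysteresis bias.
    """
    if not mv_breaths:
        raise ValueError("need at least one mechanical-ventilation breath")
    p = np.concatenate([lp.p_insp for lp in mv_breaths])
    v = np.concatenate([lp.v_insp for lp in mv_breaths])
    if np.ptp(p) == 0:
        raise ValueError("zero pressure variance in MV data")
    res = stats.linregress(p, v)
    return ComplianceFit(
        C_cw_fit=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_breaths=len(mv_breaths),
    )


def campbell_wob(loop: PVLoop, fit: ComplianceFit) -> WOBResult:
    """Work of breathing of one breath from its Campbell diagram.

    The compliance line is evaluated at the inspiratory limb's volume
    samples; the enclosed area is integrated over volume, with sub-regions
    where the limb crosses the line contributing absolute areas summed
    (the shaded-region reading of the diagram).
    """
    tv = loop.tidal_volume
    if tv <= 0:
        raise ValueError("tidal volume must be positive for WOB")
    v_l = loop.v_insp / 1000.0  # litres
    dev = fit.pressure_at(loop.v_insp) - loop.p_insp  # cmH2O below the line
    # piecewise trapezoid areas between samples, split at sign changes
    total = 0.0
    run = 0.0
    prev_sign = 0.0
    for k in range(1, v_l.size):
        dv = v_l[k] - v_l[k - 1]
        a, b = dev[k - 1], dev[k]
        if a * b < 0:  # crossing inside the interval: split at the root
            frac = a / (a - b)
            run += 0.5 * a * frac * dv
            total += abs(run)
            run = 0.5 * b * (1 - frac) * dv
        else:
            run += 0.5 * (a + b) * dv
    total += abs(run)
    work_j = total * CMH2O_L_TO_J
    return WOBResult(work=work_j, work_per_litre=work_j / (tv / 1000.0), TV=tv)


def mean_wob_per_litre(loops: Sequence[PVLoop], fit: ComplianceFit) -> float:
    """Headline summary: per-breath mean of work per litre (J/l).

    The pooled alternative sum(work)/sum(TV) is available via
    :func:`pooled_wob_per_litre`.
    """
    results = [campbell_wob(lp, fit) for lp in loops if lp.tidal_volume > 0]
    if not results:
        raise ValueError("no usable loops")
    return float(np.mean([r.work_per_litre for r in results]))


def pooled_wob_per_litre(loops: Sequence[PVLoop], fit: ComplianceFit) -> float:
    """Pooled total work divided by total ventilated volume (J/l)."""
    results = [campbell_wob(lp, fit) for lp in loops if lp.tidal_volume > 0]
    if not results:
        raise ValueError("no usable loops")
    return float(sum(r.work for r in results) / (sum(r.TV for r in results) / 1000.0))
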