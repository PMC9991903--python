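"""Waveform-analysis pipeline: breath segmentation, ventilation metrics,
actuation-timing alignment, pressure normalization and per-breath pressure
deltas, and timing-outcome regressions.

Breath bounds are the local minima of the volume waveform (the V0
landmarks); the start of expiration is the volume maximum within the
breath (Vpk); the actuation onset is the start of each pressurization
excursion (P0).  All indices are half-open and 0-based internally; all
reported times are seconds from record start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal, stats

DEFAULT_MIN_SEPARATION_S = 0.5
DEFAULT_MIN_PROMINENCE_ML = 5.0
DEFAULT_ONSET_THRESHOLD_PSI = 1.0


@dataclass(frozen=True)
class BreathSegment:
    """One breath: [i_start, i_end) samples plus landmark times."""

    i_start: int
    i_end: int
    t_V0: float  # s, start of inspiration (left-bound volume minimum)
    t_Vpk: float  # s, start of expiration (volume maximum within breath)
    t_Fpk: float  # s, time of peak inspiratory flow

    def __post_init__(self) -> None:
        if not (self.t_V0 <= self.t_Fpk <= self.t_Vpk):
            raise ValueError("landmarks must satisfy t_V0 <= t_Fpk <= t_Vpk")


@dataclass(frozen=True)
class BreathFeatures:
    """Per-breath ventilation metrics."""

    TV: float  # ml, V(t_Vpk) - V(t_V0)
    PIF: float  # l/s, max flow over the inspiratory window
    Ti: float  # s
    Ttot: float  # s
    rr_inst: float  # breaths/min
    t_V0: float  # s (carried for windowing)

    def __post_init__(self) -> None:
        if self.TV < 0 or self.PIF < 0 or not (0 < self.Ti <= self.Ttot):
            raise ValueError("invalid breath features")


@dataclass(frozen=True)
class ActuationEvent:
    """Onset of one actuation pressure waveform."""

    t_P0: float  # s
    p_peak: float  # psi


@dataclass(frozen=True)
class AlignmentMetrics:
    """Per-breath actuation-timing metrics (defined only when matched)."""

    matched: bool
    dt_Vpk_P0: Optional[float] = None  # s, t_Vpk - t_P0
    dt_P0_V0: Optional[float] = None  # s, t_P0 - t_V0


@dataclass(frozen=True)
class PressureDeltas:
    """Signed maximum pressure changes per breath, cmH2O.

    dPpl carries the sign of its largest-magnitude excursion from the
    normalized breath-bound baseline; dPab and dPdi are peak increases.
    dPdi is computed on the sample-wise Pdi = Pab - Ppl channel.
    """

    dPpl: float
    dPab: float
    dPdi: float


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary-least-squares fit summary."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError("r2 must lie in [0, 1]")
        if self.n < 3:
            raise ValueError("regression needs n >= 3")


# ---------------------------------------------------------------------------
# Segmentation and features
# ---------------------------------------------------------------------------

def segment_breaths(
    volume: Sequence[float],
    fs: float,
    flow: Optional[Sequence[float]] = None,
    min_separation: float = DEFAULT_MIN_SEPARATION_S,
    min_prominence: float = DEFAULT_MIN_PROMINENCE_ML,
) -> List[BreathSegment]:
    """Segment breaths at the local minima of the volume waveform.

    Bounds are volume local minima separated by at least ``min_separation``
    seconds with prominence at least ``min_prominence`` ml.  Segments tile
    the record between consecutive qualifying minima; within each segment
    the Vpk landmark is the volume argmax and Fpk the flow argmax over the
    inspiratory window [V0, Vpk].
    """
    v = np.asarray(volume, dtype=float)
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if v.size <= 2 * int(min_separation * fs):
        raise ValueError("series too short to segment")
    q = np.asarray(flow, dtype=float) if flow is not None else None
    minima, _ = signal.find_peaks(
        -v,
        distance=max(int(round(min_separation * fs)), 1),
        prominence=min_prominence,
    )
    segments: List[BreathSegment] = []
    for a, b in zip(minima[:-1], minima[1:]):
        i_pk = a + int(np.argmax(v[a:b]))
        if q is not None and i_pk > a:
            i_f = a + int(np.argmax(q[a : i_pk + 1]))
        else:
            i_f = a
        segments.append(
            BreathSegment(
                i_start=int(a),
                i_end=int(b),
                t_V0=a / fs,
                t_Vpk=i_pk / fs,
                t_Fpk=i_f / fs,
            )
        )
    return segments


def breath_features(
    seg: BreathSegment, flow: Sequence[float], volume: Sequence[float], fs: float
) -> BreathFeatures:
    """Ventilation metrics for one segmented breath.

    TV is the volume rise from V0 to Vpk; PIF the maximum flow within the
    inspiratory window [t_V0, t_Vpk] (expiratory-phase spikes excluded).
    """
    v = np.asarray(volume, dtype=float)
    q = np.asarray(flow, dtype=float)
    if seg.i_end > v.size or seg.i_start < 0:
        raise IndexError("segment indices out of range")
    i0 = seg.i_start
    ipk = int(round(seg.t_Vpk * fs))
    tv = float(v[ipk] - v[i0])
    pif = float(np.max(q[i0 : ipk + 1])) if ipk >= i0 else 0.0
    ttot = (seg.i_end - seg.i_start) / fs
    ti = max(seg.t_Vpk - seg.t_V0, 1.0 / fs)
    return BreathFeatures(
        TV=max(tv, 0.0),
        PIF=max(pif, 0.0),
        Ti=ti,
        Ttot=ttot,
        rr_inst=60.0 / ttot,
        t_V0=seg.t_V0,
    )


def minute_ventilation(
    features: Sequence[BreathFeatures],
    window: float,
    body_mass: Optional[float] = None,
    t_start: float = 0.0,
) -> Tuple[float, Optional[float]]:
    """Minute ventilation over a window, in l/min (and ml/min/kg if mass given).

    Breaths whose t_V0 falls in [t_start, t_start + window) contribute;
    the summed tidal volume is scaled to a per-minute rate.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    in_win = [f for f in features if t_start <= f.t_V0 < t_start + window]
    if not in_win:
        warnings.warn("no breaths in window; minute ventilation is 0", stacklevel=2)
        return 0.0, (0.0 if body_mass else None)
    mv_lpm = sum(f.TV for f in in_win) / 1000.0 * (60.0 / window)
    if body_mass:
        return mv_lpm, mv_lpm * 1000.0 / body_mass
    return mv_lpm, None


# ---------------------------------------------------------------------------
# Actuation onsets and alignment
# ---------------------------------------------------------------------------

def detect_actuation_onsets(
    p_act: Sequence[float],
    fs: float,
    onset_threshold: float = DEFAULT_ONSET_THRESHOLD_PSI,
    close_fraction: float = 0.5,
) -> List[ActuationEvent]:
    """P0 landmarks: first sample of each rising excursion above threshold.

    A new onset is recognized only after the channel has returned below the
    threshold; the excursion closes once the channel falls below
    ``close_fraction * onset_threshold``, so sensor noise chattering around
    the threshold on the release tail cannot create phantom onsets.  Empty
    output is allowed.
    """
    p = np.asarray(p_act, dtype=float)
    close_level = close_fraction * onset_threshold
    events: List[ActuationEvent] = []
    above = False
    start = 0
    for i in range(p.size):
        if not above and p[i] >= onset_threshold:
            above = True
            start = i
        elif above and p[i] < close_level:
            events.append(
                ActuationEvent(t_P0=start / fs, p_peak=float(np.max(p[start:i])))
            )
            above = False
    if above:
        events.append(ActuationEvent(t_P0=start / fs, p_peak=float(np.max(p[start:]))))
    return events


def align_actuations(
    breaths: Sequence[BreathSegment],
    events: Sequence[ActuationEvent],
    fs: float = 1000.0,
) -> List[AlignmentMetrics]:
    """Match each breath to the unique actuation onset in its window.

    The matching window is [t_V0 - Ttot/2, t_Vpk + Ttot/2); breaths with
    zero or multiple onsets inside it are flagged unmatched and excluded
    from downstream regressions.
    """
    onsets = np.array([e.t_P0 for e in events], dtype=float)
    out: List[AlignmentMetrics] = []
    for seg in breaths:
        ttot = (seg.i_end - seg.i_start) / fs
        lo = seg.t_V0 - 0.5 * ttot
        hi = seg.t_Vpk + 0.5 * ttot
        inside = onsets[(onsets >= lo) & (onsets < hi)]
        if inside.size != 1:
            out.append(AlignmentMetrics(matched=False))
        else:
            p0 = float(inside[0])
            out.append(
                AlignmentMetrics(
                    matched=True,
                    dt_Vpk_P0=seg.t_Vpk - p0,
                    dt_P0_V0=p0 - seg.t_V0,
                )
            )
    return out


def normalize_pressure(
    series: Sequence[float],
    segments: Sequence[BreathSegment],
) -> np.ndarray:
    """Zero-reference a pressure channel at the breath bounds.

    Subtracts the mean of the samples at the segment boundary instants over
    the analysis window, so the boundary samples average to zero.  With no
    segments the series is returned unchanged (with a warning).
    """
    p = np.asarray(series, dtype=float)
    if not segments:
        warnings.warn("no segments; pressure returned unnormalized", stacklevel=2)
        return p.copy()
    idx = sorted({s.i_start for s in segments} | {s.i_end for s in segments if s.i_end < p.size})
    return p - float(np.mean(p[list(idx)]))


def pressure_deltas(
    seg: BreathSegment,
    p_pl: Sequence[float],
    p_ab: Sequence[float],
) -> PressureDeltas:
    """Maximum change in pressure per breath on normalized channels.

    dPpl is the signed largest-magnitude excursion from the breath-start
    baseline; dPab is the peak rise; dPdi is the peak rise of the
    sample-wise transdiaphragmatic channel Pdi = Pab - Ppl.
    """
    ppl = np.asarray(p_pl, dtype=float)
    pab = np.asarray(p_ab, dtype=float)
    if seg.i_end > ppl.size:
        raise IndexError("segment outside series")
    sl = slice(seg.i_start, seg.i_end)
    base_pl = 0.5 * (ppl[seg.i_start] + ppl[min(seg.i_end, ppl.size - 1)])
    base_ab = 0.5 * (pab[seg.i_start] + pab[min(seg.i_end, pab.size - 1)])
    exc_pl = ppl[sl] - base_pl
    exc_ab = pab[sl] - base_ab
    pdi = pab - ppl
    exc_di = pdi[sl] - (base_ab - base_pl)
    dppl = float(exc_pl[np.argmax(np.abs(exc_pl))]) if exc_pl.size else 0.0
    return PressureDeltas(
        dPpl=dppl,
        dPab=float(np.max(exc_ab)) if exc_ab.size else 0.0,
        dPdi=float(np.max(exc_di)) if exc_di.size else 0.0,
    )


def fit_timing_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of an outcome (TV or PIF) on a timing metric.

    Reports slope, intercept, r-squared and the two-sided slope p-value.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("regression needs n >= 3 matched pairs")
    if np.ptp(xa) == 0:
        raise ValueError("degenerate predictor (zero variance)")
    res = stats.linregress(xa, ya)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(xa.size),
    )
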