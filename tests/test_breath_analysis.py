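"""Segmentation, features, alignment, normalization and regressions."""

import numpy as np
import pytest

from pamvent.breath_analysis import (
    ActuationEvent,
    BreathSegment,
    align_actuations,
    breath_features,
    detect_actuation_onsets,
    fit_timing_regression,
    minute_ventilation,
    normalize_pressure,
    pressure_deltas,
    segment_breaths,
)

FS = 200.0


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def brute_force_minima(v, fs, min_separation, min_prominence):
    """Exhaustive scan applying the local-minima/prominence definition."""
    y = -np.asarray(v)
    n = y.size
    cand = [i for i in range(1, n - 1) if y[i - 1] < y[i] >= y[i + 1]]
    out = []
    for i in cand:
        # prominence of peak i in y: descend to the lowest point between i
        # and the nearest higher peak (or edge) on each side
        left = y[: i + 1]
        higher = np.flatnonzero(left[:-1] > y[i])
        lbase = left[higher[-1] :].min() if higher.size else left.min()
        right = y[i:]
        higher = np.flatnonzero(right[1:] > y[i])
        rbase = right[: higher[0] + 2].min() if higher.size else right.min()
        if y[i] - max(lbase, rbase) >= min_prominence:
            out.append(i)
    # enforce separation (no two qualifying minima closer than the bound)
    keep = []
    for i in sorted(out, key=lambda j: -y[j]):
        if all(abs(i - k) >= min_separation * fs for k in keep):
            keep.append(i)
    return sorted(keep)


class TestSegmentBreaths:
    def test_sinusoid_bounds_at_analytic_minima(self):
        t = np.arange(0, 20, 1 / FS)
        v = 100.0 * (1 - np.cos(2 * np.pi * 0.25 * t))  # minima every 4 s
        segs = segment_breaths(v, FS)
        bounds = [s.t_V0 for s in segs] + [segs[-1].i_end / FS]
        assert bounds == pytest.approx([4.0, 8.0, 12.0, 16.0], abs=2 / FS)
        for s in segs:
            assert s.t_Vpk == pytest.approx(s.t_V0 + 2.0, abs=2 / FS)

    def test_constant_volume_yields_no_breaths(self):
        assert segment_breaths(np.full(5000, 120.0), FS) == []

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            segment_breaths(np.zeros(50), FS)

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(11)
        t = np.arange(0, 40, 1 / FS)
        v = (
            120 * (1 - np.cos(2 * np.pi * 0.27 * t))
            + 2.0 * np.sin(2 * np.pi * 1.7 * t)
            + rng.normal(0, 0.4, t.size)
        )
        segs = segment_breaths(v, FS, min_separation=0.5, min_prominence=5.0)
        oracle = brute_force_minima(v, FS, 0.5, 5.0)
        assert [s.i_start for s in segs] == oracle[:-1]
        assert [s.i_end for s in segs] == oracle[1:]

    def test_segments_tile_without_overlap(self):
        t = np.arange(0, 30, 1 / FS)
        v = 150 * (1 - np.cos(2 * np.pi * 0.3 * t))
        segs = segment_breaths(v, FS)
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.i_end == b.i_start


# ---------------------------------------------------------------------------
# features and minute ventilation
# ---------------------------------------------------------------------------

class TestBreathFeatures:
    def _triangle(self):
        # volume rises 150 ml over 1 s then falls back over 3 s (Ttot = 4 s)
        t = np.arange(0, 4, 1 / FS)
        v = np.where(t <= 1.0, 150 * t, 150 * (1 - (t - 1) / 3))
        flow = np.gradient(v, 1 / FS) / 1000.0
        seg = BreathSegment(0, t.size, 0.0, 1.0, 0.5)
        return seg, flow, v

    def test_triangle_arithmetic(self):
        seg, flow, v = self._triangle()
        f = breath_features(seg, flow, v, FS)
        assert f.TV == pytest.approx(150.0, rel=1e-6)
        assert f.rr_inst == pytest.approx(15.0)
        assert f.Ti == pytest.approx(1.0)

    def test_flat_channels_zero_features(self):
        seg = BreathSegment(0, 800, 0.0, 1.0, 0.5)
        f = breath_features(seg, np.zeros(800), np.full(800, 80.0), FS)
        assert f.TV == 0.0 and f.PIF == 0.0

    def test_volume_scaling_doubles_tv_only(self):
        seg, flow, v = self._triangle()
        f1 = breath_features(seg, flow, v, FS)
        f2 = breath_features(seg, flow, 2 * v, FS)
        assert f2.TV == pytest.approx(2 * f1.TV)
        assert (f2.Ti, f2.Ttot) == (f1.Ti, f1.Ttot)

    def test_out_of_range_segment_rejected(self):
        seg = BreathSegment(0, 10_000, 0.0, 1.0, 0.5)
        with pytest.raises(IndexError):
            breath_features(seg, np.zeros(100), np.zeros(100), FS)


class TestMinuteVentilation:
    def _feats(self, n, tv, spacing):
        from pamvent.breath_analysis import BreathFeatures
        return [
            BreathFeatures(TV=tv, PIF=0.2, Ti=1.0, Ttot=spacing,
                           rr_inst=60 / spacing, t_V0=i * spacing)
            for i in range(n)
        ]

    def test_eight_breaths_arithmetic(self):
        mv, _ = minute_ventilation(self._feats(8, 100.0, 3.7), window=30.0)
        assert mv == pytest.approx(1.6)

    def test_weight_normalization(self):
        mv, mvkg = minute_ventilation(self._feats(8, 100.0, 3.7), 30.0, 40.0)
        assert mvkg == pytest.approx(40.0)

    def test_empty_window_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            mv, _ = minute_ventilation([], window=30.0)
        assert mv == 0.0


# ---------------------------------------------------------------------------
# actuation onsets and alignment
# ---------------------------------------------------------------------------

def onset_oracle(p, fs, threshold):
    """Independent replay of the rising-excursion rule (hysteretic close)."""
    events = []
    above = False
    for i, x in enumerate(p):
        if not above and x >= threshold:
            events.append(i / fs)
            above = True
        elif above and x < 0.5 * threshold:
            above = False
    return events


class TestActuationOnsets:
    def test_zero_channel_empty(self):
        assert detect_actuation_onsets(np.zeros(2000), FS) == []

    def test_three_trapezoids_onsets_at_ramp_starts(self):
        t = np.arange(0, 12, 1 / FS)
        p = np.zeros_like(t)
        for t0 in (1.0, 5.0, 9.0):
            ph = t - t0
            p += np.clip(ph / 0.3, 0, 1) * 20 - np.clip((ph - 0.7) / 0.3, 0, 1) * 20
        p = np.clip(p, 0, 20)
        events = detect_actuation_onsets(p, FS, onset_threshold=1.0)
        assert len(events) == 3
        for ev, t0 in zip(events, (1.0, 5.0, 9.0)):
            # threshold of 1 psi on a 20 psi / 0.3 s ramp: within ~0.02 s
            assert ev.t_P0 == pytest.approx(t0 + 0.015, abs=0.02)
            assert ev.p_peak == pytest.approx(20.0, abs=0.1)

    def test_matches_replay_oracle_on_noisy_channel(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 60, 1 / FS)
        p = 10 * (1 + np.sin(2 * np.pi * 0.2 * t)) + rng.normal(0, 0.3, t.size)
        p = np.clip(p, 0, None)
        events = detect_actuation_onsets(p, FS, onset_threshold=5.0)
        assert [e.t_P0 for e in events] == pytest.approx(onset_oracle(p, FS, 5.0))


class TestAlignActuations:
    def _breaths(self, n=10, period=4.0):
        fs = FS
        return [
            BreathSegment(int(i * period * fs), int((i + 1) * period * fs),
                          i * period, i * period + 1.5, i * period + 0.7)
            for i in range(n)
        ]

    def test_one_to_one_alternation(self):
        breaths = self._breaths()
        events = [ActuationEvent(s.t_V0 + 0.3, 20.0) for s in breaths]
        metrics = align_actuations(breaths, events, FS)
        assert all(m.matched for m in metrics)
        for m, s in zip(metrics, breaths):
            assert m.dt_P0_V0 == pytest.approx(0.3)
            assert m.dt_Vpk_P0 == pytest.approx(1.2)

    def test_no_actuations_all_unmatched(self):
        metrics = align_actuations(self._breaths(), [], FS)
        assert not any(m.matched for m in metrics)

    def test_double_actuation_flags_unmatched(self):
        breaths = self._breaths(3)
        events = [ActuationEvent(0.3, 20.0), ActuationEvent(0.9, 20.0),
                  ActuationEvent(4.3, 20.0), ActuationEvent(8.3, 20.0)]
        metrics = align_actuations(breaths, events, FS)
        assert metrics[0].matched is False
        assert metrics[1].matched and metrics[2].matched


# ---------------------------------------------------------------------------
# pressure normalization and deltas
# ---------------------------------------------------------------------------

class TestNormalizePressure:
    def _segs(self):
        return [BreathSegment(i * 400, (i + 1) * 400, i * 2.0, i * 2.0 + 0.8,
                              i * 2.0 + 0.3) for i in range(4)]

    def test_constant_series_becomes_zero(self):
        out = normalize_pressure(np.full(1600, 3.7), self._segs())
        assert np.allclose(out, 0.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 1600)
        segs = self._segs()
        np.testing.assert_allclose(
            normalize_pressure(x, segs), normalize_pressure(x + 7.0, segs),
            atol=1e-12)

    def test_boundary_mean_zero_on_sawtooth(self):
        x = np.tile(np.linspace(2.0, 6.0, 400), 4)
        segs = self._segs()
        out = normalize_pressure(x, segs)
        idx = sorted({s.i_start for s in segs})
        assert np.mean(out[idx]) == pytest.approx(0.0, abs=1e-9)

    def test_no_segments_warns_identity(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning):
            out = normalize_pressure(x, [])
        np.testing.assert_array_equal(out, x)


class TestPressureDeltas:
    def test_constructed_excursions(self):
        n = 800
        t = np.linspace(0, 4, n, endpoint=False)
        bump = np.sin(np.pi * t / 4.0) ** 2
        ppl = -8.0 * bump
        pab = 5.0 * bump
        seg = BreathSegment(0, n, 0.0, 2.0, 1.0)
        d = pressure_deltas(seg, ppl, pab)
        assert d.dPpl == pytest.approx(-8.0, rel=1e-3)
        assert d.dPab == pytest.approx(5.0, rel=1e-3)
        assert d.dPdi == pytest.approx(13.0, rel=1e-3)

    def test_flat_channels_zero(self):
        seg = BreathSegment(0, 100, 0.0, 0.25, 0.1)
        d = pressure_deltas(seg, np.zeros(200), np.zeros(200))
        assert d.dPpl == d.dPab == d.dPdi == 0.0

    def test_pdi_from_subtracted_channel_not_delta_difference(self):
        # Ppl dips early, Pab peaks late: dPdi < dPab - dPpl
        n = 400
        ppl = np.zeros(n)
        pab = np.zeros(n)
        ppl[50:100] = -6.0
        pab[300:350] = 4.0
        seg = BreathSegment(0, n, 0.0, 1.75, 0.5)
        d = pressure_deltas(seg, ppl, pab)
        assert d.dPdi == pytest.approx(6.0)
        assert d.dPdi < d.dPab - d.dPpl


class TestTimingRegression:
    def test_exact_line(self):
        x = np.linspace(-1, 1, 20)
        r = fit_timing_regression(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r2 == pytest.approx(1.0)

    def test_independent_noise_r2_near_zero(self):
        rng = np.random.default_rng(17)
        x = rng.normal(0, 1, 200)
        y = rng.normal(0, 1, 200)
        r = fit_timing_regression(x, y)
        assert r.r2 < 0.1
        assert r.p_value > 0.001

    def test_matches_normal_equations_fixture(self):
        x = np.array([0.1, 0.4, 0.5, 0.9, 1.3])
        y = np.array([42.0, 60.0, 55.0, 91.0, 110.0])
        # closed-form normal equations solved independently
        a = np.vstack([x, np.ones_like(x)]).T
        slope_ne, intercept_ne = np.linalg.solve(a.T @ a, a.T @ y)
        r = fit_timing_regression(x, y)
        assert r.slope == pytest.approx(slope_ne, rel=1e-12)
        assert r.intercept == pytest.approx(intercept_ne, rel=1e-12)
        assert r.n == 5

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_timing_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
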