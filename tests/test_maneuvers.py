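"""Regrip/sniff detection, peak metrics, alignment and timing."""

import numpy as np
import pytest

import handkin as hk
from handkin.maneuvers import BASELINE_PRE, BASELINE_POST

FPS = 294.1


def _triangular_pulse(t, centre, apex, base, flank_s):
    """Piecewise-linear pulse reaching `apex` at `centre` with linear flanks."""
    y = np.zeros_like(t)
    rising = (t >= centre - flank_s) & (t <= centre)
    falling = (t > centre) & (t <= centre + flank_s)
    y[rising] = (apex - base) * (t[rising] - (centre - flank_s)) / flank_s
    y[falling] = (apex - base) * ((centre + flank_s) - t[falling]) / flank_s
    return y


def _grid(duration, fps=FPS):
    return np.arange(int(round(duration * fps))) / fps


# ---------------------------------------------------------------------------
# Regrip detection
# ---------------------------------------------------------------------------

def test_regrip_triangular_pulse_detected_at_apex():
    t = _grid(1.0)
    centre = t[147]  # apex exactly on a sample
    D = 5.0 + _triangular_pulse(t, centre, 6.0, 5.0, 0.010)
    events = hk.detect_regrips(D, FPS)
    assert len(events) == 1
    assert events[0].peak_frame == 147
    assert events[0].prominence >= 0.75


def test_regrip_below_prominence_rejected():
    t = _grid(1.0)
    D = 5.0 + _triangular_pulse(t, t[147], 5.5, 5.0, 0.010)  # prominence 0.5
    assert hk.detect_regrips(D, FPS) == []


def test_regrip_slow_bump_rejected_by_slope():
    t = _grid(4.0)
    D = 5.0 + 1.0 * np.exp(-((t - 2.0) ** 2) / (2 * 0.5**2))  # max slope ~1.2 mm/s
    assert hk.detect_regrips(D, FPS) == []


def test_regrip_either_flank_switch():
    # fast rise, slow fall: rejected with both_flanks, accepted with either
    t = _grid(4.0)
    D = np.full_like(t, 5.0)
    i = 588  # t = 2.0 s
    D[i - 3 : i + 1] += np.linspace(0, 1.2, 4)[:]  # ~118 mm/s rise
    D[i + 1 :] += 1.2 * np.exp(-(t[i + 1 :] - t[i]) / 0.8)  # slow decay
    assert hk.detect_regrips(D, FPS) == []
    got = hk.detect_regrips(D, FPS, hk.RegripParams(both_flanks=False))
    assert len(got) == 1


def test_regrip_ethogram_filter():
    t = _grid(1.0)
    D = 5.0 + _triangular_pulse(t, t[60], 6.5, 5.0, 0.010) + _triangular_pulse(
        t, t[200], 6.5, 5.0, 0.010
    )
    n = len(t)
    eth = hk.ethogram_from_rows([(0, "oromanual"), (130, "holding")], n)
    events = hk.detect_regrips(D, FPS, ethogram=eth)
    assert [e.peak_frame for e in events] == [60]


def test_regrip_offset_invariance_and_threshold_contract():
    rng = np.random.default_rng(4)
    t = _grid(10.0)
    D = 5.0 + rng.normal(0, 0.02, len(t))
    for centre in (1.0, 3.0, 7.5):
        D += 1.5 * np.exp(-((t - centre) ** 2) / (2 * 0.0072**2))
    ev0 = hk.detect_regrips(D, FPS)
    ev1 = hk.detect_regrips(D + 42.0, FPS)
    assert [e.peak_frame for e in ev0] == [e.peak_frame for e in ev1]
    params = hk.RegripParams()
    for e in ev0:
        assert e.prominence >= params.min_prominence
        for lo, hi in ((e.left_base, e.peak_frame), (e.peak_frame, e.right_base)):
            assert np.max(np.abs(np.diff(D[lo : hi + 1]))) * FPS > params.min_slope


def test_regrip_requires_mm_units():
    with pytest.raises(hk.UnitError):
        hk.detect_regrips(np.ones(100), FPS, units="px")


# ---------------------------------------------------------------------------
# Sniff detection
# ---------------------------------------------------------------------------

def _dip_trace(depths, centres, sigma=0.030, baseline=5.0, duration=4.0):
    t = _grid(duration)
    y = np.full_like(t, baseline)
    for d, c in zip(depths, centres):
        y -= d * np.exp(-((t - c) ** 2) / (2 * sigma**2))
    return t, y


def test_sniff_dip_detected_at_minimum():
    t, y = _dip_trace([3.0], [2.0])
    events = hk.detect_sniffs(y, FPS)
    assert len(events) == 1
    assert abs(events[0].peak_time - 2.0) < 2 / FPS
    assert events[0].peak_value == pytest.approx(2.0, abs=0.01)


def test_sniff_above_height_criterion_rejected():
    _, y = _dip_trace([2.0], [2.0])  # dips only to 3.0 mm
    assert hk.detect_sniffs(y, FPS) == []


def test_sniff_separation_keeps_more_prominent():
    t, y = _dip_trace([3.0, 2.8], [2.0, 2.1])  # 100 ms apart
    events = hk.detect_sniffs(y, FPS)
    assert len(events) == 1
    assert abs(events[0].peak_time - 2.0) < 2 / FPS


def test_sniff_head_fixed_parameter_set():
    params = hk.sniff_params("head_fixed")
    assert params.min_prominence == 2.5 and params.max_width_s == 0.600
    # prominence 1.5 dip passes freely-moving but not head-fixed thresholds
    _, y = _dip_trace([3.2], [2.0], baseline=4.0)
    _, y2 = _dip_trace([1.6], [2.0], baseline=4.0)
    assert len(hk.detect_sniffs(y2, FPS, mode="freely_moving")) == 1
    assert hk.detect_sniffs(y2, FPS, mode="head_fixed") == []
    # very wide dip rejected by the width cap in head-fixed mode
    _, wide = _dip_trace([3.2], [2.0], sigma=0.4, baseline=4.0)
    assert len(hk.detect_sniffs(wide, FPS, mode="freely_moving")) == 1
    assert hk.detect_sniffs(wide, FPS, mode="head_fixed") == []
    assert len(hk.detect_sniffs(y, FPS, mode="head_fixed")) == 1


# ---------------------------------------------------------------------------
# Peak metrics
# ---------------------------------------------------------------------------

def test_peak_metrics_ramp_plus_triangle_fixture():
    """Linear ramp 4.9 -> 5.1 mm with a triangular pulse to 6.0 mm: pooled
    baseline 5.0 mm, amplitude 1.0 mm, FWHM 10 ms."""
    t = _grid(1.0)
    ramp = 4.9 + 0.2 * t
    centre = t[147]
    D = ramp + _triangular_pulse(t, centre, 6.0, 5.0, 0.010)
    events = hk.detect_regrips(D, FPS)
    assert len(events) == 1
    ev = hk.peak_metrics(D, events[0], FPS)
    assert ev.baseline_value == pytest.approx(5.0, abs=0.005)
    assert ev.amplitude == pytest.approx(1.0, abs=0.01)
    assert ev.fwhm * 1e3 == pytest.approx(10.0, abs=1.5)
    # pre/post window means straddle the pooled baseline
    pre = np.arange(147 + int(np.ceil(BASELINE_PRE[0] * FPS)), 147 + int(BASELINE_PRE[1] * FPS) + 1)
    assert D[pre].mean() == pytest.approx(4.96, abs=0.01)


def test_peak_metrics_gaussian_fwhm_closed_form():
    sigma = 0.010
    t = _grid(2.0)
    D = 5.0 + 1.5 * np.exp(-((t - 1.0) ** 2) / (2 * sigma**2))
    events = hk.detect_regrips(D, FPS)
    ev = hk.peak_metrics(D, events[0], FPS)
    assert ev.fwhm == pytest.approx(2.3548 * sigma, abs=1 / FPS)


def test_peak_metrics_sniff_amplitude_sign():
    t, y = _dip_trace([3.0], [2.0])
    ev = hk.peak_metrics(y, hk.detect_sniffs(y, FPS)[0], FPS)
    assert ev.amplitude == pytest.approx(3.0, abs=0.02)
    assert ev.baseline_value == pytest.approx(5.0, abs=0.02)


def test_peak_metrics_out_of_range_flags_invalid():
    t = _grid(1.0)
    D = 5.0 + _triangular_pulse(t, t[5], 6.0, 5.0, 0.010)
    ev = hk.ManeuverEvent("regrip", 5, 5 / FPS, float(D[5]), 1.0, 2, 8)
    out = hk.peak_metrics(D, ev, FPS)
    assert not out.baseline_valid
    assert out.amplitude is None and out.fwhm is None


def test_amplitude_invariant_to_offset_fwhm_to_scale():
    t = _grid(2.0)
    pulse = np.exp(-((t - 1.0) ** 2) / (2 * 0.010**2))
    for scale in (1.5, 3.0):
        D = 5.0 + scale * pulse
        ev = hk.peak_metrics(D, hk.detect_regrips(D, FPS)[0], FPS)
        ev_off = hk.peak_metrics(D + 7.0, hk.detect_regrips(D + 7.0, FPS)[0], FPS)
        assert ev.amplitude == pytest.approx(ev_off.amplitude, abs=1e-12)
        assert ev.fwhm == pytest.approx(2.3548 * 0.010, abs=1 / FPS)


# ---------------------------------------------------------------------------
# Alignment and timing
# ---------------------------------------------------------------------------

def test_align_and_average_identical_pulses():
    t = _grid(4.0)
    D = 5.0 + _triangular_pulse(t, t[300], 6.0, 5.0, 0.010) + _triangular_pulse(
        t, t[800], 6.0, 5.0, 0.010
    )
    events = hk.detect_regrips(D, FPS)
    lags, snippets, mean = hk.align_and_average(D, events, FPS, 0.05)
    assert snippets.shape[0] == 2
    np.testing.assert_allclose(snippets[0], snippets[1], atol=1e-12)
    np.testing.assert_allclose(mean, snippets[0], atol=1e-12)
    assert lags[np.nanargmax(mean)] == pytest.approx(0.0, abs=1 / FPS)


def test_align_event_at_trace_edge():
    D = np.full(100, 5.0)
    D[0] = 6.0
    ev = hk.ManeuverEvent("regrip", 0, 0.0, 6.0, 1.0, 0, 3)
    lags, snippets, mean = hk.align_and_average(D, [ev], FPS, 0.02)
    w = (len(lags) - 1) // 2
    assert np.isnan(snippets[0, :w]).all()
    assert np.isfinite(mean[w:]).all()


def test_rates_and_latencies():
    fps = 100.0
    eth = hk.ethogram_from_rows(
        [(0, "oromanual"), (100, "holding"), (200, "oromanual"), (300, "holding")], 400
    )

    def ev(frame):
        return hk.ManeuverEvent("sniff", frame, frame / fps, 2.0, 3.0, frame - 5, frame + 5)

    timing = hk.maneuver_rates_and_timing([ev(150), ev(190), ev(350)], eth, fps, total_time=2.0)
    assert timing.rate_hz == pytest.approx(1.5)
    # sniff 100 ms before the next oromanual onset
    assert timing.latency_next_s[1] == pytest.approx(0.100)
    assert timing.latency_prev_s[1] == pytest.approx(0.900)
    # final (non-interior) holding segment: no next oromanual
    assert timing.latency_next_s[2] is None
    with pytest.raises(hk.ParameterError):
        hk.maneuver_rates_and_timing([], eth, fps, total_time=0.0)


def test_event_in_oromanual_gets_no_latency():
    fps = 100.0
    eth = hk.ethogram_from_rows([(0, "holding"), (100, "oromanual"), (200, "holding")], 300)
    ev = hk.ManeuverEvent("regrip", 150, 1.5, 6.0, 1.0, 140, 160)
    timing = hk.maneuver_rates_and_timing([ev], eth, fps, total_time=3.0)
    assert timing.latency_next_s == [None] and timing.latency_prev_s == [None]


# ---------------------------------------------------------------------------
# Detector performance on synthetic ground truth
# ---------------------------------------------------------------------------

def _precision_recall(detected_times, true_times, window):
    if len(true_times) == 0 or len(detected_times) == 0:
        return 0.0, 0.0
    det = np.asarray(detected_times)
    tru = np.asarray(true_times)
    recall = np.mean([np.min(np.abs(det - t)) <= window for t in tru])
    precision = np.mean([np.min(np.abs(tru - d)) <= window for d in det])
    return precision, recall


def test_regrip_detector_precision_recall(default_session, session_features):
    front, _ = session_features
    events = hk.detect_regrips(front.D, FPS)
    p, r = _precision_recall(
        [e.peak_time for e in events], default_session.truth.regrip_times_s, 0.010
    )
    assert p >= 0.9 and r >= 0.9


def test_sniff_detector_precision_recall(default_session, session_features):
    _, ventral = session_features
    events = hk.detect_sniffs(ventral.L_ventral, FPS)
    p, r = _precision_recall(
        [e.peak_time for e in events], default_session.truth.sniff_times_s, 0.020
    )
    assert p >= 0.9 and r >= 0.9
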