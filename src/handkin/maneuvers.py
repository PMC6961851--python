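"""Detection and measurement of regrip and sniff maneuvers.

Regrips — rapid (~20 ms) readjustments of the bimanual grip while the food is
bite-held — appear as sharp upward spikes in the inter-D3 distance D.  They
are detected as local maxima with topographic prominence >= 0.75 mm whose
flanks are steeper than 88 mm/s.  Sniffs — brief movements bringing the item
under the nares — appear as dips in the ventral snout-to-hands distance
L_ventral and are detected on its additive inverse with a dip value
<= 2.5 mm, a mode-dependent prominence floor, a 250 ms minimum separation
and, in head-fixed recordings, a 600 ms maximum width at half prominence.

Amplitude is measured against the mean of two baseline windows, 300-100 ms
before and 100-300 ms after the peak; FWHM is the width at halfway between
that baseline and the peak value, with linear interpolation at the crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_widths

from .errors import ParameterError, UnitError
from .tracking_io import PHASE_HOLDING, PHASE_OROMANUAL, Ethogram

#: Baseline windows relative to the peak, seconds (pre must precede post).
BASELINE_PRE = (-0.300, -0.100)
BASELINE_POST = (0.100, 0.300)


@dataclass(frozen=True)
class RegripParams:
    """Regrip detector thresholds (mm, mm/s)."""

    min_prominence: float = 0.75
    min_slope: float = 88.0
    #: require both flanks (True) or either flank (False) to exceed min_slope
    both_flanks: bool = True
    #: optional moving-average pre-smoothing, in frames (0 = off)
    smooth_frames: int = 0


@dataclass(frozen=True)
class SniffParams:
    """Sniff detector thresholds (mm, s)."""

    max_dip_value: float = 2.5
    min_prominence: float = 1.0
    min_separation_s: float = 0.250
    max_width_s: float | None = None  # head-fixed only
    smooth_frames: int = 0


def sniff_params(mode: str = "freely_moving") -> SniffParams:
    """Sniff parameter set for a recording mode.

    ``freely_moving`` uses the base thresholds; ``head_fixed`` raises the
    prominence floor to 2.5 mm and caps the half-prominence width at 600 ms
    (the looser set produced false positives on head-fixed data).
    """
    if mode == "freely_moving":
        return SniffParams()
    if mode == "head_fixed":
        return SniffParams(min_prominence=2.5, max_width_s=0.600)
    raise ParameterError(f"unknown sniff mode {mode!r}")


@dataclass
class ManeuverEvent:
    """One detected regrip or sniff with its measured peak parameters."""

    kind: str                      # "regrip" | "sniff"
    peak_frame: int
    peak_time: float               # s
    peak_value: float              # series value at the peak, mm
    prominence: float              # mm (of the detection-orientation signal)
    left_base: int
    right_base: int
    amplitude: float | None = None   # mm, vs pooled baseline windows
    fwhm: float | None = None        # s
    baseline_value: float | None = None
    baseline_valid: bool = True
    fwhm_from_base: bool = False


def events_to_frame(events: list[ManeuverEvent]) -> pd.DataFrame:
    """Tidy CSV-ready export of an event list."""
    rows = []
    for e in events:
        rows.append(
            {
                "kind": e.kind,
                "peak_frame": e.peak_frame,
                "peak_time_s": e.peak_time,
                "peak_value_mm": e.peak_value,
                "prominence_mm": e.prominence,
                "amplitude_mm": e.amplitude,
                "fwhm_ms": None if e.fwhm is None else e.fwhm * 1e3,
                "baseline_mm": e.baseline_value,
                "baseline_valid": e.baseline_valid,
                "fwhm_from_base": e.fwhm_from_base,
            }
        )
    return pd.DataFrame(rows)


def _check_units(units: str) -> None:
    if units != "mm":
        raise UnitError(f"trace must be calibrated to mm, got units {units!r}")


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    out = np.full_like(x, np.nan)
    for start, stop in _finite_runs(x):
        if stop - start >= window:
            out[start:stop] = np.convolve(x[start:stop], kernel, mode="same")
        else:
            out[start:stop] = x[start:stop]
    return out


def _finite_runs(x: np.ndarray):
    """Yield (start, stop) index ranges of maximal finite runs."""
    finite = np.isfinite(x)
    if not finite.any():
        return
    edges = np.flatnonzero(np.diff(finite.astype(int)))
    starts = [0] if finite[0] else []
    starts += [int(e) + 1 for e in edges if not finite[e]]
    stops = [int(e) + 1 for e in edges if finite[e]]
    if finite[-1]:
        stops.append(len(x))
    yield from zip(starts, stops)


def _flank_slope(x: np.ndarray, lo: int, hi: int, fps: float) -> float:
    """Maximum absolute single-frame slope (value/s) within x[lo:hi+1]."""
    if hi <= lo:
        return 0.0
    return float(np.max(np.abs(np.diff(x[lo : hi + 1]))) * fps)


def detect_regrips(
    D: np.ndarray,
    fps: float,
    params: RegripParams | None = None,
    ethogram: Ethogram | None = None,
    units: str = "mm",
) -> list[ManeuverEvent]:
    """Detect regrips as prominent, steep spikes in the inter-D3 distance.

    A local maximum qualifies when its topographic prominence is at least
    ``min_prominence`` and the maximum absolute single-frame slope within the
    rising and falling flanks (peak to prominence base) exceeds ``min_slope``
    on both flanks (or either, with ``both_flanks=False``).  NaN gaps split
    the trace; prominence is evaluated within each finite run.  With an
    ethogram, only peaks inside oromanual phases are kept.
    """
    _check_units(units)
    params = params or RegripParams()
    x = _smooth(np.asarray(D, dtype=float), params.smooth_frames)
    events: list[ManeuverEvent] = []
    for start, stop in _finite_runs(x):
        seg = x[start:stop]
        peaks, props = find_peaks(seg, prominence=params.min_prominence)
        for p, prom, lb, rb in zip(
            peaks, props["prominences"], props["left_bases"], props["right_bases"]
        ):
            rise = _flank_slope(seg, lb, p, fps)
            fall = _flank_slope(seg, p, rb, fps)
            ok = (rise > params.min_slope) and (fall > params.min_slope)
            if not params.both_flanks:
                ok = (rise > params.min_slope) or (fall > params.min_slope)
            if not ok:
                continue
            frame = start + int(p)
            events.append(
                ManeuverEvent(
                    kind="regrip",
                    peak_frame=frame,
                    peak_time=frame / fps,
                    peak_value=float(x[frame]),
                    prominence=float(prom),
                    left_base=start + int(lb),
                    right_base=start + int(rb),
                )
            )
    if ethogram is not None:
        events = [e for e in events if ethogram.phase_at(e.peak_frame) == PHASE_OROMANUAL]
    events.sort(key=lambda e: e.peak_frame)
    return events


def detect_sniffs(
    L_ventral: np.ndarray,
    fps: float,
    mode: str = "freely_moving",
    params: SniffParams | None = None,
    units: str = "mm",
) -> list[ManeuverEvent]:
    """Detect sniffs as prominent dips in the ventral snout-to-hands distance.

    Detection runs on -L_ventral: maxima with value >= -``max_dip_value``
    (dips reaching 2.5 mm or less), prominence >= the mode's floor and, in
    head-fixed mode, half-prominence width <= 600 ms.  Peaks closer together
    than the minimum separation resolve to the more prominent one (earlier
    peak on ties).
    """
    _check_units(units)
    params = params or sniff_params(mode)
    y = -_smooth(np.asarray(L_ventral, dtype=float), params.smooth_frames)
    candidates: list[ManeuverEvent] = []
    for start, stop in _finite_runs(y):
        seg = y[start:stop]
        peaks, props = find_peaks(
            seg, height=-params.max_dip_value, prominence=params.min_prominence
        )
        widths = peak_widths(seg, peaks, rel_height=0.5)[0] / fps if len(peaks) else []
        for p, prom, lb, rb, w in zip(
            peaks,
            props["prominences"],
            props["left_bases"],
            props["right_bases"],
            widths,
        ):
            if params.max_width_s is not None and w > params.max_width_s:
                continue
            frame = start + int(p)
            candidates.append(
                ManeuverEvent(
                    kind="sniff",
                    peak_frame=frame,
                    peak_time=frame / fps,
                    peak_value=float(-y[frame]),
                    prominence=float(prom),
                    left_base=start + int(lb),
                    right_base=start + int(rb),
                )
            )
    # enforce minimum separation: keep the more prominent peak, earlier on ties
    kept: list[ManeuverEvent] = []
    for ev in sorted(candidates, key=lambda e: (-e.prominence, e.peak_frame)):
        if all(
            abs(ev.peak_time - other.peak_time) >= params.min_separation_s for other in kept
        ):
            kept.append(ev)
    kept.sort(key=lambda e: e.peak_frame)
    return kept


# ---------------------------------------------------------------------------
# Peak metrics: amplitude and FWHM against pre/post baseline windows
# ---------------------------------------------------------------------------

def _window_indices(peak: int, fps: float, window: tuple[float, float], n: int):
    lo = peak + int(np.ceil(window[0] * fps - 1e-9))
    hi = peak + int(np.floor(window[1] * fps + 1e-9))
    if lo < 0 or hi >= n:
        return None
    return np.arange(lo, hi + 1)


def _half_crossing(
    x: np.ndarray, peak: int, half: float, sign: float, direction: int, bound: int
) -> float | None:
    """Interpolated frame position of the half-level crossing adjacent to the peak."""
    i = peak
    while 0 <= i + direction and i + direction < len(x) and direction * (i + direction) <= direction * bound:
        j = i + direction
        if np.isnan(x[j]):
            return None
        if sign * (x[j] - half) <= 0:
            frac = (x[i] - half) / (x[i] - x[j])
            return i + direction * frac
        i = j
    return None


def peak_metrics(
    series: np.ndarray,
    event: ManeuverEvent,
    fps: float,
    search_bounds: tuple[int, int] | None = None,
) -> ManeuverEvent:
    """Amplitude and FWHM of one event against the pooled baseline windows.

    Baseline = mean of the samples in the pre (-300..-100 ms) and post
    (+100..+300 ms) windows pooled; amplitude = |series(peak) - baseline|;
    FWHM = time between the linear-interpolated crossings of
    (baseline + peak) / 2 adjacent to the peak.  If either window falls
    outside the trace the event is flagged invalid and the metrics stay
    missing.  If a half crossing is not found before ``search_bounds`` (e.g.
    the neighbouring event), the prominence base stands in and the event is
    flagged ``fwhm_from_base``.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    peak = event.peak_frame
    pre = _window_indices(peak, fps, BASELINE_PRE, n)
    post = _window_indices(peak, fps, BASELINE_POST, n)
    if pre is None or post is None:
        return replace(event, baseline_valid=False)
    pooled = x[np.concatenate([pre, post])]
    if np.isnan(pooled).all():
        return replace(event, baseline_valid=False)
    baseline = float(np.nanmean(pooled))
    peak_val = x[peak]
    amplitude = abs(peak_val - baseline)
    half = 0.5 * (peak_val + baseline)
    sign = np.sign(peak_val - baseline) or 1.0
    lo_bound, hi_bound = (0, n - 1) if search_bounds is None else search_bounds
    left = _half_crossing(x, peak, half, sign, -1, lo_bound)
    right = _half_crossing(x, peak, half, sign, +1, hi_bound)
    from_base = False
    if left is None:
        left, from_base = float(event.left_base), True
    if right is None:
        right, from_base = float(event.right_base), True
    fwhm = (right - left) / fps
    return replace(
        event,
        amplitude=float(amplitude),
        fwhm=float(fwhm),
        baseline_value=baseline,
        fwhm_from_base=from_base,
    )


def measure_events(
    series: np.ndarray, events: list[ManeuverEvent], fps: float
) -> list[ManeuverEvent]:
    """Apply :func:`peak_metrics` to every event, bounding half-level searches
    at the neighbouring events' peaks."""
    out = []
    for i, ev in enumerate(events):
        lo = events[i - 1].peak_frame if i > 0 else 0
        hi = events[i + 1].peak_frame if i + 1 < len(events) else len(series) - 1
        out.append(peak_metrics(series, ev, fps, search_bounds=(lo, hi)))
    return out


# ---------------------------------------------------------------------------
# Peak-aligned averaging and rates/timing
# ---------------------------------------------------------------------------

def align_and_average(
    series: np.ndarray, events: list[ManeuverEvent], fps: float, half_window: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Peak-aligned snippet matrix and its mean trace.

    Returns ``(lags_s, snippets, mean)`` where ``snippets`` has one row per
    event on the common lag axis [-half_window, +half_window]; out-of-range
    lags are NaN and the mean ignores missing samples.
    """
    x = np.asarray(series, dtype=float)
    w = int(round(half_window * fps))
    lags = np.arange(-w, w + 1)
    snippets = np.full((len(events), len(lags)), np.nan)
    for i, ev in enumerate(events):
        idx = ev.peak_frame + lags
        ok = (idx >= 0) & (idx < len(x))
        snippets[i, ok] = x[idx[ok]]
    with np.errstate(invalid="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(snippets, axis=0) if len(events) else np.full(len(lags), np.nan)
    return lags / fps, snippets, mean


@dataclass
class ManeuverTiming:
    """Event rate and per-event latencies to the surrounding oromanual phases."""

    rate_hz: float
    latency_next_s: list[float | None]   # to the next oromanual onset
    latency_prev_s: list[float | None]   # since the previous oromanual offset


def maneuver_rates_and_timing(
    events: list[ManeuverEvent], eth: Ethogram, fps: float, total_time: float
) -> ManeuverTiming:
    """Overall event rate plus holding-phase latencies around each event.

    For an event inside a holding phase, ``latency_next`` is the time to the
    next oromanual onset and ``latency_prev`` the time since the previous
    oromanual offset (the holding segment's own start).  Events in oromanual
    phases, outside the ethogrammed span, or in a boundary holding segment
    lacking the relevant neighbour get missing latencies.
    """
    if total_time <= 0:
        raise ParameterError(f"total_time must be positive, got {total_time}")
    rate = len(events) / total_time
    nexts: list[float | None] = []
    prevs: list[float | None] = []
    for ev in events:
        seg = eth.segment_at(ev.peak_frame)
        if seg is None or seg.phase != PHASE_HOLDING:
            nexts.append(None)
            prevs.append(None)
            continue
        idx = eth.segments.index(seg)
        nexts.append(
            seg.end / fps - ev.peak_time if idx + 1 < len(eth.segments) else None
        )
        prevs.append(ev.peak_time - seg.start / fps if idx > 0 else None)
    return ManeuverTiming(rate_hz=rate, latency_next_s=nexts, latency_prev_s=prevs)
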