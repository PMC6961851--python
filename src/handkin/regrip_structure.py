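"""Microstructure of regripping: periodicity, asymmetry, variability, angle.

Regrips often arrive in bursts.  Burst periodicity is estimated in the time
domain: groups of regrips with inter-event intervals <= 300 ms are cut out of
the D trace with 300 ms margins, each segment's mean-subtracted
autocorrelation (normalised by its zero-lag value) is averaged across groups,
the mean correlogram is min-max normalised to [0, 1], and the periodicity is
the reciprocal of the lag of its largest positive-lag peak beyond the central
peak.

Bimanual asymmetry of a single regrip is the difference of the two hands' 2D
path integrals over the 40 ms window centred on the peak, divided by their
sum: 0 for equal travel, +/-1 for a unimanual regrip (positive = right hand).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .maneuvers import ManeuverEvent

MAX_GROUP_INTERVAL_S = 0.300
CORRELOGRAM_MARGIN_S = 0.300
CORRELOGRAM_MAX_LAG_S = 0.300


@dataclass
class Correlogram:
    """Mean regrip-burst autocorrelogram, min-max normalised to [0, 1]."""

    lags_s: np.ndarray
    values: np.ndarray
    periodicity_hz: float | None
    n_groups: int


def _event_groups(times: np.ndarray, max_interval: float) -> list[np.ndarray]:
    """Maximal runs of >= 2 events with consecutive gaps <= max_interval."""
    if len(times) < 2:
        return []
    breaks = np.flatnonzero(np.diff(times) > max_interval)
    groups = np.split(times, breaks + 1)
    return [g for g in groups if len(g) >= 2]


def regrip_autocorrelogram(
    D: np.ndarray, events: list[ManeuverEvent], fps: float
) -> Correlogram:
    """Burst periodicity of regrips from the mean segment autocorrelogram.

    Groups whose padded segment would leave the trace, or whose segment
    contains missing samples, are skipped.  With no qualifying group the
    periodicity is undefined (None) and ``n_groups`` is 0.
    """
    x = np.asarray(D, dtype=float)
    max_lag = int(round(CORRELOGRAM_MAX_LAG_S * fps))
    margin = int(round(CORRELOGRAM_MARGIN_S * fps))
    lags = np.arange(-max_lag, max_lag + 1)
    times = np.array(sorted(e.peak_time for e in events))
    acs = []
    for group in _event_groups(times, MAX_GROUP_INTERVAL_S):
        first = int(round(group[0] * fps)) - margin
        last = int(round(group[-1] * fps)) + margin
        if first < 0 or last >= len(x):
            continue
        seg = x[first : last + 1]
        if np.isnan(seg).any():
            continue
        seg = seg - seg.mean()
        full = np.correlate(seg, seg, mode="full")
        centre = len(seg) - 1
        if full[centre] <= 0:
            continue
        ac = full[centre - max_lag : centre + max_lag + 1] / full[centre]
        acs.append(ac)
    if not acs:
        return Correlogram(lags / fps, np.full(len(lags), np.nan), None, 0)
    mean = np.mean(acs, axis=0)
    rng = mean.max() - mean.min()
    values = (mean - mean.min()) / rng if rng > 0 else np.zeros_like(mean)
    periodicity = _periodicity_from_correlogram(values, lags, fps)
    return Correlogram(lags / fps, values, periodicity, len(acs))


def _periodicity_from_correlogram(
    values: np.ndarray, lags: np.ndarray, fps: float
) -> float | None:
    """Reciprocal of the largest positive-lag local maximum beyond the central peak.

    The central (zero-lag) peak extends to the first positive-lag local
    minimum; the search for the largest peak starts beyond it.
    """
    pos = values[lags >= 0]
    # first local minimum after lag 0
    i0 = None
    for i in range(1, len(pos) - 1):
        if pos[i] < pos[i - 1] and pos[i] <= pos[i + 1]:
            i0 = i
            break
    if i0 is None:
        return None
    best_lag, best_val = None, -np.inf
    for i in range(i0 + 1, len(pos) - 1):
        if pos[i] >= pos[i - 1] and pos[i] > pos[i + 1] and pos[i] > best_val:
            best_val, best_lag = pos[i], i
    if best_lag is None:
        return None
    return float(fps / best_lag)


# ---------------------------------------------------------------------------
# Bimanual asymmetry
# ---------------------------------------------------------------------------

@dataclass
class AsymmetryResult:
    """Signed path-integral asymmetry of one regrip (positive = right hand)."""

    index: float | None
    left_path_mm: float
    right_path_mm: float
    valid: bool = True


def asymmetry_index(
    left_hand: np.ndarray,
    right_hand: np.ndarray,
    peak_time: float,
    fps: float,
    window: float = 0.040,
) -> AsymmetryResult:
    """Asymmetry of the two hands' travel in the peri-peak window.

    Path length per hand is the sum of Euclidean step lengths over the
    ``window`` (default 40 ms, about twice the average regrip FWHM) centred
    on the regrip peak; the index is (right - left) / (right + left), missing
    when neither hand moves.  Windows leaving the trace, or containing masked
    samples, flag the result invalid.
    """
    left = np.asarray(left_hand, dtype=float)
    right = np.asarray(right_hand, dtype=float)
    n = len(left)
    lo = int(np.ceil((peak_time - window / 2) * fps - 1e-9))
    hi = int(np.floor((peak_time + window / 2) * fps + 1e-9))
    if lo < 0 or hi >= n:
        return AsymmetryResult(None, np.nan, np.nan, valid=False)
    lseg, rseg = left[lo : hi + 1], right[lo : hi + 1]
    if np.isnan(lseg).any() or np.isnan(rseg).any():
        return AsymmetryResult(None, np.nan, np.nan, valid=False)
    lpath = float(np.sum(np.hypot(*np.diff(lseg, axis=0).T)))
    rpath = float(np.sum(np.hypot(*np.diff(rseg, axis=0).T)))
    total = lpath + rpath
    index = (rpath - lpath) / total if total > 0 else None
    return AsymmetryResult(index, lpath, rpath)


# ---------------------------------------------------------------------------
# Rolling coefficient of variation
# ---------------------------------------------------------------------------

@dataclass
class RollingCV:
    """Rolling CV trace with its regrip-adjacent / elsewhere median contrast."""

    cv: np.ndarray
    median_near_regrips: float
    median_elsewhere: float


def rolling_cv_contrast(
    series: np.ndarray,
    events: list[ManeuverEvent],
    fps: float,
    window: float = 0.040,
    near: float = 0.020,
) -> RollingCV:
    """Rolling CV (std/mean over a 40 ms centred window) split by regrip adjacency.

    Window centres within ``near`` (20 ms) of any regrip peak form the
    regrip-adjacent partition; medians of both partitions are reported.
    Windows with non-positive mean yield a missing CV.
    """
    x = pd.Series(np.asarray(series, dtype=float))
    w = max(2, int(round(window * fps)))
    roll = x.rolling(w, center=True, min_periods=w)
    mean = roll.mean()
    std = roll.std(ddof=1)
    cv = (std / mean).to_numpy()
    cv[mean.to_numpy() <= 0] = np.nan
    t = np.arange(len(x)) / fps
    if events:
        peak_times = np.array([e.peak_time for e in events])
        dist = np.min(np.abs(t[:, None] - peak_times[None, :]), axis=1)
        near_mask = dist <= near
    else:
        near_mask = np.zeros(len(x), dtype=bool)
    med_near = float(np.nanmedian(cv[near_mask])) if near_mask.any() else np.nan
    med_far = float(np.nanmedian(cv[~near_mask])) if (~near_mask).any() else np.nan
    return RollingCV(cv, med_near, med_far)


# ---------------------------------------------------------------------------
# Grip-angle changes around regrips
# ---------------------------------------------------------------------------

@dataclass
class ThetaChange:
    """Median absolute angle deviation from baseline, per regrip."""

    baseline_dev_deg: float | None
    post_dev_deg: float | None
    valid: bool = True


BASELINE_EPOCH = (-0.060, -0.020)
POST_EPOCH = (0.020, 0.060)


def theta_change(
    theta: np.ndarray, events: list[ManeuverEvent], fps: float
) -> list[ThetaChange]:
    """Grip-angle change across each regrip.

    The baseline is the median inter-D3 angle over 60-20 ms before the peak;
    reported per event are the median absolute deviations from that baseline
    within the baseline epoch itself and within the 20-60 ms post epoch.
    Adding a constant angle leaves both values unchanged.
    """
    x = np.asarray(theta, dtype=float)
    n = len(x)
    out = []
    for ev in events:
        lo_b = ev.peak_frame + int(np.ceil(BASELINE_EPOCH[0] * fps - 1e-9))
        hi_b = ev.peak_frame + int(np.floor(BASELINE_EPOCH[1] * fps + 1e-9))
        lo_p = ev.peak_frame + int(np.ceil(POST_EPOCH[0] * fps - 1e-9))
        hi_p = ev.peak_frame + int(np.floor(POST_EPOCH[1] * fps + 1e-9))
        if lo_b < 0 or hi_p >= n:
            out.append(ThetaChange(None, None, valid=False))
            continue
        base_epoch = x[lo_b : hi_b + 1]
        post_epoch = x[lo_p : hi_p + 1]
        if np.isnan(base_epoch).all() or np.isnan(post_epoch).all():
            out.append(ThetaChange(None, None, valid=False))
            continue
        baseline = np.nanmedian(base_epoch)
        out.append(
            ThetaChange(
                float(np.nanmedian(np.abs(base_epoch - baseline))),
                float(np.nanmedian(np.abs(post_epoch - baseline))),
            )
        )
    return out
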