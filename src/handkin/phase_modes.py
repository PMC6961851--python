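"""Oromanual/holding phase statistics, postural-mode clustering and rise times.

Food handling alternates between an *oromanual* phase (active manipulation at
the mouth) and a *holding* phase (static grip below the mouth).  Three
complementary quantifications live here:

* ethogram-based phase statistics (switch rate, duty cycle, durations);
* unsupervised recovery of the two postural modes by k-means over (L, D),
  with the cluster count chosen by the L-method knee of the SSE curve;
* kernel-smoothed (L, D) density maps with 10 %-of-maximum contours; and
* the rise-time of the holding-to-oromanual transition of L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from sklearn.cluster import KMeans

from .errors import InsufficientDataError, ParameterError, UndefinedResultError
from .kinematics import FeatureSeries
from .tracking_io import PHASE_HOLDING, PHASE_OROMANUAL, Ethogram


@dataclass
class PhaseStats:
    """Mode-switching statistics derived from one ethogram."""

    switch_rate_hz: float
    duty_cycle: float
    phase_durations_s: dict[str, list[float]]
    total_time_s: float
    n_switches: int


def phase_statistics(eth: Ethogram, fps: float) -> PhaseStats:
    """Switch rate, oromanual duty cycle and per-phase interior durations.

    The switch rate counts segment boundaries interior to the ethogrammed
    span divided by the total ethogrammed duration.  The duty cycle (time in
    the oromanual phase over time in either phase) uses *all* segments, while
    duration distributions use interior segments only — the first and last
    segments' true durations are unknown.
    """
    if not eth.segments:
        raise InsufficientDataError("empty ethogram")
    total_frames = eth.segments[-1].end - eth.segments[0].start
    total_s = total_frames / fps
    n_switches = len(eth.segments) - 1
    oro_s = sum(s.duration_s(fps) for s in eth.segments if s.phase == PHASE_OROMANUAL)
    durations = {PHASE_OROMANUAL: [], PHASE_HOLDING: []}
    for seg in eth.segments:
        if seg.interior:
            durations[seg.phase].append(seg.duration_s(fps))
    return PhaseStats(
        switch_rate_hz=n_switches / total_s,
        duty_cycle=oro_s / total_s,
        phase_durations_s=durations,
        total_time_s=total_s,
        n_switches=n_switches,
    )


# ---------------------------------------------------------------------------
# L-method knee selection and k-means mode clustering
# ---------------------------------------------------------------------------

def _line_rmse(xs: np.ndarray, ys: np.ndarray) -> float:
    if len(xs) == 1:
        return 0.0
    coef = np.polyfit(xs, ys, 1)
    resid = ys - np.polyval(coef, xs)
    return float(np.sqrt(np.mean(resid**2)))


def select_k_lmethod(sse_curve) -> int:
    """Select the knee of an SSE-vs-k curve with the two-line L-method.

    For each candidate knee ``c`` in ``2..k_max-1`` a least-squares line is
    fit to points ``1..c`` and another to ``c..k_max`` (the knee point is
    shared); the candidate minimising the point-count-weighted sum of the two
    residual RMSEs wins, ties breaking to the smaller ``c``.
    """
    sse = np.asarray(sse_curve, dtype=float)
    k_max = len(sse)
    if k_max < 4:
        raise ParameterError(f"L-method needs k_max >= 4, got {k_max}")
    ks = np.arange(1, k_max + 1, dtype=float)
    best_c, best_err = None, np.inf
    for c in range(2, k_max):
        left_x, left_y = ks[:c], sse[:c]
        right_x, right_y = ks[c - 1 :], sse[c - 1 :]
        n_l, n_r = len(left_x), len(right_x)
        err = (n_l * _line_rmse(left_x, left_y) + n_r * _line_rmse(right_x, right_y)) / (
            n_l + n_r
        )
        if err < best_err - 1e-12:
            best_err, best_c = err, c
    return int(best_c)


@dataclass
class ClusterResult:
    """Outcome of k-means postural-mode clustering over (L, D)."""

    k_selected: int
    assignments: np.ndarray        # per-frame cluster index, -1 where missing
    centroids: np.ndarray          # (k, 2) in mm, columns (L, D)
    phase_labels: dict[int, str]   # cluster index -> phase name (k == 2 only)
    sse_curve: np.ndarray          # SSE for k = 1..k_max
    degenerate: bool = False
    rng_seed: int | None = None


def cluster_phases(
    features: FeatureSeries,
    k_max: int = 10,
    replicates: int = 10,
    rng_seed: int = 0,
) -> ClusterResult:
    """k-means over the non-missing (L, D) samples with L-method k selection.

    Clustering runs on raw millimetre coordinates (no standardisation), with
    ``replicates`` random initialisations per k keeping the lowest-SSE
    solution.  When two clusters are selected, the one with the smaller L
    centroid (hands at the mouth) is labelled oromanual, the other holding.
    All-identical samples short-circuit to a degenerate single cluster.
    """
    if features.L is None or features.D is None:
        raise InsufficientDataError("feature series lacks L and D (front view required)")
    good = ~(np.isnan(features.L) | np.isnan(features.D))
    pts = np.column_stack([features.L[good], features.D[good]])
    if pts.shape[0] < k_max:
        raise InsufficientDataError(
            f"need >= {k_max} non-missing (L, D) samples, have {pts.shape[0]}"
        )

    assignments = np.full(features.n_frames, -1, dtype=int)
    if np.ptp(pts, axis=0).max() == 0.0:
        assignments[good] = 0
        return ClusterResult(
            k_selected=1,
            assignments=assignments,
            centroids=pts[:1].copy(),
            phase_labels={},
            sse_curve=np.zeros(k_max),
            degenerate=True,
            rng_seed=rng_seed,
        )

    fits = []
    sse = np.empty(k_max)
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=replicates, random_state=rng_seed)
        km.fit(pts)
        fits.append(km)
        sse[k - 1] = km.inertia_
    k_sel = select_k_lmethod(sse)
    km = fits[k_sel - 1]
    assignments[good] = km.labels_
    labels: dict[int, str] = {}
    if k_sel == 2:
        oro = int(np.argmin(km.cluster_centers_[:, 0]))
        labels = {oro: PHASE_OROMANUAL, 1 - oro: PHASE_HOLDING}
    return ClusterResult(
        k_selected=k_sel,
        assignments=assignments,
        centroids=km.cluster_centers_.copy(),
        phase_labels=labels,
        sse_curve=sse,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# Kernel-smoothed (L, D) density maps and 10% contours
# ---------------------------------------------------------------------------

@dataclass
class DensityMap:
    """Gridded kernel-smoothed density over [0, 20]^2 mm, max-normalised to 1."""

    x_grid: np.ndarray             # L axis centres (mm)
    y_grid: np.ndarray             # D axis centres (mm)
    density: np.ndarray            # (grid_n, grid_n), indexed [iy, ix]
    contours: list[np.ndarray]     # polylines, columns (L, D) in mm
    level: float = 0.1


SUPPORT_MM = (0.0, 20.0)


def _kde_map(points: np.ndarray, grid_n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from scipy.ndimage import gaussian_filter

    lo, hi = SUPPORT_MM
    edges = np.linspace(lo, hi, grid_n + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    hist, _, _ = np.histogram2d(points[:, 0], points[:, 1], bins=[edges, edges])
    # normal-reference (Scott) bandwidth per dimension, in grid cells
    n = points.shape[0]
    cell = (hi - lo) / grid_n
    sigmas = []
    for dim in range(2):
        s = np.std(points[:, dim], ddof=1)
        h = (s if s > 0 else cell) * n ** (-1.0 / 6.0)
        sigmas.append(max(h / cell, 1e-6))
    density = gaussian_filter(hist, sigma=sigmas, mode="constant")
    return centres, centres, density.T  # transpose to [iy(D), ix(L)]


def _contours_mm(density: np.ndarray, x_grid: np.ndarray, y_grid: np.ndarray, level: float):
    polylines = []
    for contour in measure.find_contours(density, level):
        iy, ix = contour[:, 0], contour[:, 1]
        xs = np.interp(ix, np.arange(len(x_grid)), x_grid)
        ys = np.interp(iy, np.arange(len(y_grid)), y_grid)
        polylines.append(np.column_stack([xs, ys]))
    return polylines


def density_contours(
    points_by_group: dict,
    grid_n: int = 128,
    level: float = 0.1,
) -> tuple[dict[str, DensityMap], DensityMap]:
    """Per-group smoothed (L, D) density maps plus their cross-group average.

    Each group's points are binned on a shared ``grid_n`` x ``grid_n`` grid
    over [0, 20]^2 mm and smoothed with a Gaussian kernel of per-dimension
    normal-reference bandwidth, truncated at the support boundary; each map
    is normalised to a maximum of 1, the average map is the mean of the
    normalised maps, and contour polylines are traced at ``level`` times each
    map's maximum.  Points outside the support are clipped in, with a warning.
    """
    if not points_by_group:
        raise InsufficientDataError("no groups provided")
    maps: dict[str, DensityMap] = {}
    stack = []
    x_grid = y_grid = None
    for name, pts in points_by_group.items():
        pts = np.asarray(pts, dtype=float)
        pts = pts[~np.isnan(pts).any(axis=1)]
        if pts.shape[0] < 2:
            raise InsufficientDataError(f"group {name!r} has < 2 usable points")
        lo, hi = SUPPORT_MM
        if (pts < lo).any() or (pts > hi).any():
            warnings.warn(
                f"group {name!r}: points outside [{lo}, {hi}] mm clipped to support",
                stacklevel=2,
            )
            pts = np.clip(pts, lo, hi)
        x_grid, y_grid, dens = _kde_map(pts, grid_n)
        dens = dens / dens.max()
        maps[name] = DensityMap(
            x_grid, y_grid, dens, _contours_mm(dens, x_grid, y_grid, level * dens.max()), level
        )
        stack.append(dens)
    mean_map = np.mean(stack, axis=0)
    average = DensityMap(
        x_grid,
        y_grid,
        mean_map,
        _contours_mm(mean_map, x_grid, y_grid, level * mean_map.max()),
        level,
    )
    return maps, average


# ---------------------------------------------------------------------------
# Phase-transition rise time
# ---------------------------------------------------------------------------

def _last_crossing_before(t: np.ndarray, y: np.ndarray, level: float, t_end: float) -> float | None:
    """Time of the last linear-interpolated crossing of ``level`` at t <= t_end."""
    usable = t <= t_end + 1e-12
    tt, yy = t[usable], y[usable]
    best = None
    for i in range(len(tt) - 1):
        y0, y1 = yy[i] - level, yy[i + 1] - level
        if np.isnan(y0) or np.isnan(y1):
            continue
        if y0 == 0.0:
            best = tt[i]
        if y0 * y1 < 0:
            frac = y0 / (y0 - y1)
            best = tt[i] + frac * (tt[i + 1] - tt[i])
    if len(tt) and yy[-1] == level:
        best = tt[-1]
    return best


def transition_rise_time(
    L: np.ndarray,
    fps: float,
    transition_time: float,
    t: np.ndarray | None = None,
) -> float:
    """Rise time of a holding-to-oromanual transition of L.

    A baseline is the mean of L over [t-750 ms, t-250 ms] before the
    transition.  A line is fit through the last pre-transition crossings of
    10 % and 90 % of the difference between baseline and L at the transition;
    the rise time is how long before the transition that line attains the
    baseline.  A pure linear ramp is recovered exactly.

    Raises :class:`UndefinedResultError` when the excursion is zero or the
    crossings collapse (e.g. an instantaneous step).
    """
    L = np.asarray(L, dtype=float)
    if t is None:
        t = np.arange(len(L)) / fps
    if t[0] > transition_time - 0.75 - 1e-9 or t[-1] < transition_time - 1e-9:
        raise ParameterError(
            "trace must cover [transition - 0.75 s, transition] "
            f"(covers [{t[0]:.3f}, {t[-1]:.3f}], transition {transition_time:.3f})"
        )
    in_base = (t >= transition_time - 0.75) & (t <= transition_time - 0.25)
    baseline = np.nanmean(L[in_base])
    l_at = float(np.interp(transition_time, t, L))
    delta = l_at - baseline
    if delta == 0 or np.isnan(delta):
        raise UndefinedResultError("no excursion between baseline and transition value")
    lev10 = baseline + 0.1 * delta
    lev90 = baseline + 0.9 * delta
    t10 = _last_crossing_before(t, L, lev10, transition_time)
    t90 = _last_crossing_before(t, L, lev90, transition_time)
    if t10 is None or t90 is None:
        raise UndefinedResultError("10%/90% crossings not found before the transition")
    if abs(t90 - t10) < 1e-12:
        raise UndefinedResultError("crossings collapse (step-like transition)")
    slope = (lev90 - lev10) / (t90 - t10)
    t_base = t10 - (lev10 - baseline) / slope
    return float(transition_time - t_base)
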