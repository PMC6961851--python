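"""Synthetic food-handling sessions with full ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, in the exact input dialects the readers consume:

* alternating holding/oromanual phases with lognormal durations;
* state-dependent (L, D) levels joined by logistic ramps centred on each
  phase boundary, plus slow smooth jitter;
* bursty Gaussian regrip pulses added to D during oromanual phases, each
  pulse's motion split between the two hands by a drawn asymmetry ``a``
  (right share (1+a)/2, left share (1-a)/2), so the path-integral asymmetry
  index recovers ``a`` exactly in the noiseless limit;
* Gaussian sniff dips in the ventral snout-to-hands distance near the end of
  holding phases;
* an eye sweeping a circular arc for head-angle input; and
* isotropic Gaussian tracking noise and random dropouts (masked samples,
  written with likelihood < 0.1 so a 0.5 likelihood floor recovers the mask).

The same seed reproduces every array bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .errors import ParameterError
from .tracking_io import (
    Calibration,
    DEFAULT_FPS,
    Ethogram,
    PHASE_HOLDING,
    PHASE_OROMANUAL,
    TrackedTrajectory,
    ethogram_from_rows,
    write_ethogram,
    write_tracking_table,
)


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of one synthetic session (distances mm, times s)."""

    fps: float = DEFAULT_FPS
    duration_s: float = 60.0
    # phase alternation: lognormal durations, medians from the two modes
    holding_median_s: float = 0.30
    oromanual_median_s: float = 0.25
    duration_log_sigma: float = 0.4
    # state-dependent levels (mm)
    L_holding: float = 5.1
    L_oromanual: float = 2.7
    D_holding: float = 4.8
    D_oromanual: float = 5.5
    L_ventral_holding: float = 5.0
    L_ventral_oromanual: float = 4.0
    D_ventral: float = 3.0
    # transition ramp (10-90 % span of the logistic)
    ramp_time_s: float = 0.050
    # regrips: bursts within oromanual phases
    regrip_burst_rate_hz: float = 0.8       # bursts per second of oromanual time
    burst_pulses_min: int = 1
    burst_pulses_max: int = 4
    intra_burst_interval_s: float = 0.065
    intra_burst_jitter_s: float = 0.005
    regrip_amplitude_mm: float = 1.5
    regrip_sigma_s: float = 0.0072
    # sniffs: at most one near the end of a holding phase
    sniff_prob: float = 0.15
    sniff_lead_s: float = 0.120
    sniff_depth_mm: float = 3.0
    sniff_sigma_s: float = 0.034
    # slow posture jitter and measurement model
    slow_jitter_mm: float = 0.1
    slow_jitter_tau_s: float = 0.15
    theta_jitter_deg: float = 2.0
    noise_mm: float = 0.02
    dropout_rate: float = 0.001
    mm_per_px: float = 0.05

    def __post_init__(self) -> None:
        positives = (
            "fps duration_s holding_median_s oromanual_median_s ramp_time_s "
            "intra_burst_interval_s regrip_amplitude_mm regrip_sigma_s "
            "sniff_depth_mm sniff_sigma_s mm_per_px"
        ).split()
        for name in positives:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("L_holding", "L_oromanual", "D_holding", "D_oromanual"):
            if not (0.0 <= getattr(self, name) <= 20.0):
                raise ParameterError(f"{name} must lie within [0, 20] mm")
        if self.duration_s < 0.5:
            raise ParameterError("duration too short to fit one phase (min 0.5 s)")

    @property
    def analytic_switch_rate_hz(self) -> float:
        """Expected mode changes per second from the lognormal duration means."""
        factor = np.exp(self.duration_log_sigma**2 / 2)
        mean_cycle = (self.holding_median_s + self.oromanual_median_s) * factor
        return 2.0 / mean_cycle

    @property
    def analytic_duty_cycle(self) -> float:
        """Expected oromanual time fraction (the lognormal shape cancels)."""
        return self.oromanual_median_s / (self.oromanual_median_s + self.holding_median_s)


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows about one session."""

    ethogram: Ethogram
    regrip_times_s: np.ndarray
    regrip_asymmetry: np.ndarray
    sniff_times_s: np.ndarray
    latent: dict[str, np.ndarray]      # t, L, D, theta, L_ventral
    calibration: Calibration
    params: GeneratorParams
    seed: int


@dataclass
class SyntheticSession:
    """Generated trajectories (uncalibrated, pixel units) plus ground truth."""

    front: TrackedTrajectory
    ventral: TrackedTrajectory
    truth: SyntheticGroundTruth


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------

def _sample_phases(params: GeneratorParams, rng: np.random.Generator):
    """Alternating (start_frame, phase) rows covering the session."""
    n_frames = int(round(params.duration_s * params.fps))
    medians = {PHASE_HOLDING: params.holding_median_s, PHASE_OROMANUAL: params.oromanual_median_s}
    rows = []
    phase = PHASE_HOLDING
    t = 0.0
    frame = 0
    while frame < n_frames:
        rows.append((frame, phase))
        dur = rng.lognormal(np.log(medians[phase]), params.duration_log_sigma)
        t += dur
        next_frame = int(round(t * params.fps))
        frame = max(next_frame, frame + 2)  # every segment spans >= 2 frames
        phase = PHASE_OROMANUAL if phase == PHASE_HOLDING else PHASE_HOLDING
    if len(rows) < 1:
        raise ParameterError("duration too short to fit one phase")
    return rows, n_frames


def _level_trace(
    t: np.ndarray,
    boundaries_s: np.ndarray,
    levels: np.ndarray,
    ramp_time_s: float,
) -> np.ndarray:
    """Piecewise-constant levels joined by logistic ramps centred on boundaries."""
    scale = ramp_time_s / np.log(81.0)  # 10-90 % span = ramp_time
    out = np.full(len(t), levels[0], dtype=float)
    for tb, lo, hi in zip(boundaries_s, levels[:-1], levels[1:]):
        out += (hi - lo) * expit((t - tb) / scale)
    return out


def _slow_jitter(
    n: int, amp_mm: float, tau_s: float, fps: float, rng: np.random.Generator
) -> np.ndarray:
    if amp_mm <= 0:
        return np.zeros(n)
    raw = gaussian_filter1d(rng.standard_normal(n), sigma=tau_s * fps, mode="reflect")
    sd = raw.std()
    return raw / sd * amp_mm if sd > 0 else np.zeros(n)


def _place_regrips(ethogram: Ethogram, params: GeneratorParams, rng: np.random.Generator):
    """Pulse centre times and asymmetries within oromanual phases."""
    margin = 0.030
    times: list[float] = []
    for seg in ethogram.segments:
        if seg.phase != PHASE_OROMANUAL:
            continue
        t0, t1 = seg.start / params.fps, seg.end / params.fps
        avail = t1 - t0 - 2 * margin
        if avail <= 0:
            continue
        n_bursts = rng.poisson(params.regrip_burst_rate_hz * avail)
        for _ in range(n_bursts):
            onset = rng.uniform(t0 + margin, t1 - margin)
            n_pulses = rng.integers(params.burst_pulses_min, params.burst_pulses_max + 1)
            tp = onset
            for k in range(n_pulses):
                if k > 0:
                    tp += params.intra_burst_interval_s + rng.normal(
                        0.0, params.intra_burst_jitter_s
                    )
                if tp > t1 - margin:
                    break
                times.append(tp)
    times.sort()
    kept: list[float] = []
    for tp in times:
        if not kept or tp - kept[-1] >= 0.050:
            kept.append(tp)
    asym = rng.uniform(-1.0, 1.0, size=len(kept))
    return np.array(kept), asym


def _place_sniffs(ethogram: Ethogram, params: GeneratorParams, rng: np.random.Generator):
    times: list[float] = []
    for seg in ethogram.segments:
        if seg.phase != PHASE_HOLDING:
            continue
        t0, t1 = seg.start / params.fps, seg.end / params.fps
        if t1 - t0 < params.sniff_lead_s + 0.10:
            continue
        if rng.random() < params.sniff_prob:
            times.append(max(t1 - params.sniff_lead_s, t0 + 0.08))
    return np.array(times)


def _gaussian_bumps(
    t: np.ndarray, centres: np.ndarray, amps: np.ndarray, sigma: float
) -> np.ndarray:
    """Sum of Gaussian bumps, each evaluated on a local +-6 sigma window."""
    out = np.zeros(len(t))
    if len(t) < 2:
        return out
    dt = t[1] - t[0]
    half = int(np.ceil(6 * sigma / dt))
    for tc, amp in zip(centres, amps):
        i = int(round(tc / dt))
        lo, hi = max(0, i - half), min(len(t), i + half + 1)
        out[lo:hi] += amp * np.exp(-((t[lo:hi] - tc) ** 2) / (2 * sigma**2))
    return out


def _measurement(
    xy_mm: dict[str, np.ndarray],
    params: GeneratorParams,
    rng: np.random.Generator,
    view: str,
) -> TrackedTrajectory:
    """Embed exact mm coordinates into a noisy, pixel-unit trajectory."""
    parts = tuple(xy_mm)
    n = len(next(iter(xy_mm.values())))
    x = np.empty((n, len(parts)))
    y = np.empty_like(x)
    for j, bp in enumerate(parts):
        x[:, j] = xy_mm[bp][:, 0]
        y[:, j] = xy_mm[bp][:, 1]
    if params.noise_mm > 0:
        x += rng.normal(0.0, params.noise_mm, x.shape)
        y += rng.normal(0.0, params.noise_mm, y.shape)
    dropped = rng.random(x.shape) < params.dropout_rate
    likelihood = rng.uniform(0.9, 1.0, x.shape)
    likelihood[dropped] = rng.uniform(0.0, 0.1, int(dropped.sum()))
    return TrackedTrajectory(
        view=view,
        bodyparts=parts,
        x=x / params.mm_per_px,
        y=y / params.mm_per_px,
        likelihood=likelihood,
        valid=~dropped,
    )


def generate_session(params: GeneratorParams | None = None, seed: int = 0) -> SyntheticSession:
    """Generate a front-view and a ventral-view session with ground truth.

    The front view embeds the latent (L, D, theta) series exactly: the snout
    is fixed, the D3 midpoint sits L below it, and the D3s sit on the
    inter-D3 axis at angle theta, so recomputing the features from the
    noiseless coordinates reproduces the latents to numerical precision.
    The ventral view is an independent projection with its own latent
    L_ventral carrying the sniff dips.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)

    rows, n_frames = _sample_phases(params, rng)
    ethogram = ethogram_from_rows(rows, n_frames)
    t = np.arange(n_frames) / params.fps
    boundaries = np.array([seg.start for seg in ethogram.segments[1:]]) / params.fps

    levels_of = {
        "L": {PHASE_HOLDING: params.L_holding, PHASE_OROMANUAL: params.L_oromanual},
        "D": {PHASE_HOLDING: params.D_holding, PHASE_OROMANUAL: params.D_oromanual},
        "Lv": {
            PHASE_HOLDING: params.L_ventral_holding,
            PHASE_OROMANUAL: params.L_ventral_oromanual,
        },
    }
    phase_seq = [seg.phase for seg in ethogram.segments]
    L_base = _level_trace(
        t, boundaries, np.array([levels_of["L"][p] for p in phase_seq]), params.ramp_time_s
    )
    D_base = _level_trace(
        t, boundaries, np.array([levels_of["D"][p] for p in phase_seq]), params.ramp_time_s
    )
    Lv_base = _level_trace(
        t, boundaries, np.array([levels_of["Lv"][p] for p in phase_seq]), params.ramp_time_s
    )
    L_base += _slow_jitter(n_frames, params.slow_jitter_mm, params.slow_jitter_tau_s, params.fps, rng)
    D_base += _slow_jitter(n_frames, params.slow_jitter_mm, params.slow_jitter_tau_s, params.fps, rng)
    Lv_base += _slow_jitter(n_frames, params.slow_jitter_mm, params.slow_jitter_tau_s, params.fps, rng)
    theta_lat = _slow_jitter(
        n_frames, params.theta_jitter_deg, params.slow_jitter_tau_s, params.fps, rng
    )

    regrip_times, regrip_asym = _place_regrips(ethogram, params, rng)
    sniff_times = _place_sniffs(ethogram, params, rng)

    # split each pulse between the hands: right share (1+a)/2, left (1-a)/2
    r_right = D_base / 2 + _gaussian_bumps(
        t, regrip_times, params.regrip_amplitude_mm * (1 + regrip_asym) / 2, params.regrip_sigma_s
    )
    r_left = D_base / 2 + _gaussian_bumps(
        t, regrip_times, params.regrip_amplitude_mm * (1 - regrip_asym) / 2, params.regrip_sigma_s
    )
    Lv = Lv_base + _gaussian_bumps(
        t, sniff_times, -params.sniff_depth_mm * np.ones(len(sniff_times)), params.sniff_sigma_s
    )

    # front-view embedding (image coords, y down; mm)
    nose = np.array([10.0, 4.0])
    th = np.radians(theta_lat)
    u = np.column_stack([np.cos(th), -np.sin(th)])  # left->right axis, y-up angle
    d_avg0 = nose + np.column_stack([np.zeros(n_frames), L_base])
    rd3 = d_avg0 + r_right[:, None] * u
    ld3 = d_avg0 - r_left[:, None] * u
    # analytic latents of the noiseless embedding
    D_lat = r_right + r_left
    mid = d_avg0 + 0.5 * (r_right - r_left)[:, None] * u
    L_lat = np.hypot(mid[:, 0] - nose[0], mid[:, 1] - nose[1])

    front = _measurement({"nose": np.tile(nose, (n_frames, 1)), "LD3": ld3, "RD3": rd3},
                         params, rng, view="front")

    nose_v = np.array([10.0, 4.0])
    mid_v = nose_v + np.column_stack([np.zeros(n_frames), Lv])
    off_v = np.array([params.D_ventral / 2, 0.0])
    ventral = _measurement(
        {
            "nose": np.tile(nose_v, (n_frames, 1)),
            "LD3": mid_v - off_v,
            "RD3": mid_v + off_v,
        },
        params,
        rng,
        view="ventral",
    )

    truth = SyntheticGroundTruth(
        ethogram=ethogram,
        regrip_times_s=regrip_times,
        regrip_asymmetry=regrip_asym,
        sniff_times_s=sniff_times,
        latent={"t": t, "L": L_lat, "D": D_lat, "theta": theta_lat, "L_ventral": Lv},
        calibration=Calibration(mm_per_px=params.mm_per_px, fps=params.fps),
        params=params,
        seed=seed,
    )
    return SyntheticSession(front=front, ventral=ventral, truth=truth)


# ---------------------------------------------------------------------------
# Eye arcs for head-angle estimation
# ---------------------------------------------------------------------------

def generate_eye_arc(
    center: tuple[float, float],
    radius: float,
    angles_deg: np.ndarray,
    noise_px: float = 0.0,
    seed: int = 0,
    fps: float = DEFAULT_FPS,
) -> tuple[TrackedTrajectory, np.ndarray]:
    """Eye positions on a circular arc at programmed head angles.

    Positions are in image coordinates (y down): an angle Θ places the eye at
    ``(cx + r cos Θ, cy - r sin Θ)``, matching the y-up angle convention of
    the head-angle estimator.  Returns the pixel-unit trajectory and the true
    angles.
    """
    if radius <= 0:
        raise ParameterError(f"radius must be positive, got {radius}")
    rng = np.random.default_rng(seed)
    angles = np.asarray(angles_deg, dtype=float)
    th = np.radians(angles)
    x = center[0] + radius * np.cos(th)
    y = center[1] - radius * np.sin(th)
    if noise_px > 0:
        x = x + rng.normal(0.0, noise_px, len(x))
        y = y + rng.normal(0.0, noise_px, len(y))
    traj = TrackedTrajectory(
        view="side",
        bodyparts=("eye",),
        x=x[:, None],
        y=y[:, None],
        likelihood=np.ones((len(x), 1)),
        valid=np.ones((len(x), 1), dtype=bool),
        fps=fps,
    )
    return traj, angles


# ---------------------------------------------------------------------------
# Fixture files
# ---------------------------------------------------------------------------

TRUTH_SCHEMA_KEYS = {
    "seed": int,
    "fps": float,
    "mm_per_px": float,
    "regrip_times_s": list,
    "regrip_asymmetry": list,
    "sniff_times_s": list,
    "ethogram_rows": list,
    "video_length_frames": int,
}


def validate_truth(doc: dict) -> None:
    """Check a ground-truth JSON document against the expected schema."""
    for key, typ in TRUTH_SCHEMA_KEYS.items():
        if key not in doc:
            raise ParameterError(f"truth document missing key {key!r}")
        if not isinstance(doc[key], typ):
            raise ParameterError(
                f"truth key {key!r} has type {type(doc[key]).__name__}, expected {typ.__name__}"
            )


def write_fixtures(session: SyntheticSession, directory) -> dict[str, str]:
    """Write a session to disk in the pipeline's input dialects.

    Emits ``front.csv`` and ``ventral.csv`` (tracking dialect),
    ``ethogram.csv``, ``truth.json`` and ``params.json``; returns the paths.
    All files re-read to the written values exactly.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {name: os.path.join(directory, name) for name in
             ("front.csv", "ventral.csv", "ethogram.csv", "truth.json", "params.json")}
    try:
        write_tracking_table(session.front, paths["front.csv"])
        write_tracking_table(session.ventral, paths["ventral.csv"])
        write_ethogram(session.truth.ethogram, paths["ethogram.csv"])
        truth_doc = {
            "seed": session.truth.seed,
            "fps": float(session.truth.calibration.fps),
            "mm_per_px": float(session.truth.calibration.mm_per_px),
            "regrip_times_s": [float(v) for v in session.truth.regrip_times_s],
            "regrip_asymmetry": [float(v) for v in session.truth.regrip_asymmetry],
            "sniff_times_s": [float(v) for v in session.truth.sniff_times_s],
            "ethogram_rows": [
                [seg.start, seg.phase, seg.grip_left, seg.grip_right]
                for seg in session.truth.ethogram.segments
            ],
            "video_length_frames": session.truth.ethogram.video_length_frames,
        }
        validate_truth(truth_doc)
        with open(paths["truth.json"], "w", encoding="utf-8") as fh:
            json.dump(truth_doc, fh, indent=1, sort_keys=True)
        with open(paths["params.json"], "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(session.truth.params), fh, indent=1, sort_keys=True)
    except OSError as exc:
        raise OSError(f"failed writing fixtures under {directory!r}: {exc}") from exc
    return paths
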