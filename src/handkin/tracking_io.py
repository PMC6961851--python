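"""Reading, validation and calibration of pose-tracking tables and ethograms.

Tracking tables follow the DeepLabCut export dialect: a CSV with three header
rows (scorer / bodyparts / coords, with coords = x, y, likelihood per body
part) or the equivalent HDF5 container.  Ethograms are per-video CSV files
with a ``frame,phase,grip_left,grip_right`` header, phase codes ``O``
(oromanual) and ``H`` (holding), and the video length declared on a leading
``# video_length_frames=N`` comment line.

Positions are in pixels until :func:`calibrate` is applied, after which they
are in millimetres; the unit state is explicit on the trajectory and cannot
be mixed.  Frame indices are 0-based; segment intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EthogramValidationError,
    FormatError,
    ParameterError,
    ParseError,
    StateError,
)

PHASE_OROMANUAL = "oromanual"
PHASE_HOLDING = "holding"
PHASES = (PHASE_OROMANUAL, PHASE_HOLDING)
PHASE_CODES = {"O": PHASE_OROMANUAL, "H": PHASE_HOLDING}
PHASE_TO_CODE = {v: k for k, v in PHASE_CODES.items()}

GRIP_LABELS = ("thumb_hold", "pincer", "indeterminate", "absent")

#: Default acquisition rate of the high-speed cameras, frames per second.
DEFAULT_FPS = 294.1


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale and frame rate of one recording session."""

    mm_per_px: float
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        for name in ("mm_per_px", "fps"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be strictly positive and finite, got {v!r}")


@dataclass
class TrackedTrajectory:
    """Per-frame 2D positions and confidences for named body parts in one view.

    ``x``/``y``/``likelihood`` are ``(n_frames, n_parts)`` float arrays in
    image convention (y grows downward).  ``valid`` is a boolean mask of the
    same shape; ``False`` marks samples excluded from analysis (the original
    values are retained underneath).
    """

    view: str
    bodyparts: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    valid: np.ndarray
    units: str = "px"  # "px" (uncalibrated) or "mm"
    fps: float | None = None
    mm_per_px: float | None = None

    def __post_init__(self) -> None:
        shape = (self.n_frames, self.n_parts)
        for name in ("x", "y", "likelihood", "valid"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise FormatError(f"{name} has shape {arr.shape}, expected {shape}")
        lk = self.likelihood[self.valid]
        lk = lk[np.isfinite(lk)]
        if lk.size and (lk.min() < -1e-9 or lk.max() > 1 + 1e-9):
            raise FormatError("likelihood values outside [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_parts(self) -> int:
        return len(self.bodyparts)

    @property
    def is_calibrated(self) -> bool:
        return self.units == "mm"

    def part_index(self, name: str) -> int:
        try:
            return self.bodyparts.index(name)
        except ValueError:
            raise KeyError(f"body part {name!r} not tracked (have {list(self.bodyparts)})")

    def position(self, name: str, masked: bool = True) -> np.ndarray:
        """``(n_frames, 2)`` positions of one part; masked samples are NaN."""
        j = self.part_index(name)
        xy = np.column_stack([self.x[:, j], self.y[:, j]]).astype(float)
        if masked:
            xy[~self.valid[:, j]] = np.nan
        return xy

    def times(self) -> np.ndarray:
        if self.fps is None:
            raise StateError("fps unknown; calibrate the trajectory first")
        return np.arange(self.n_frames) / self.fps

    def copy(self) -> "TrackedTrajectory":
        return replace(
            self,
            x=self.x.copy(),
            y=self.y.copy(),
            likelihood=self.likelihood.copy(),
            valid=self.valid.copy(),
        )


@dataclass(frozen=True)
class PhaseSegment:
    """One half-open ethogram segment ``[start, end)`` in frame coordinates."""

    start: int
    end: int
    phase: str
    grip_left: str = "absent"
    grip_right: str = "absent"
    interior: bool = False

    def duration_s(self, fps: float) -> float:
        return (self.end - self.start) / fps


@dataclass
class Ethogram:
    """Ordered, alternating oromanual/holding segments tiling the video span.

    The first and last segments carry ``interior=False``: their true durations
    are unknown (the video starts or ends mid-phase), so duration and
    switching statistics exclude them.
    """

    segments: list[PhaseSegment]
    video_length_frames: int

    def __post_init__(self) -> None:
        _validate_segments(self.segments, self.video_length_frames)

    @property
    def span_frames(self) -> tuple[int, int]:
        return self.segments[0].start, self.segments[-1].end

    def phase_at(self, frame: int) -> str | None:
        for seg in self.segments:
            if seg.start <= frame < seg.end:
                return seg.phase
        return None

    def segment_at(self, frame: int) -> PhaseSegment | None:
        for seg in self.segments:
            if seg.start <= frame < seg.end:
                return seg
        return None


def _validate_segments(segments: Sequence[PhaseSegment], video_length: int) -> None:
    if not segments:
        raise EthogramValidationError("ethogram has no segments")
    prev = None
    for i, seg in enumerate(segments):
        if seg.phase not in PHASES:
            raise EthogramValidationError(f"segment {i}: unknown phase {seg.phase!r}")
        if not (0 <= seg.start < seg.end <= video_length):
            raise EthogramValidationError(
                f"segment {i}: [{seg.start}, {seg.end}) outside [0, {video_length})"
            )
        if prev is not None:
            if seg.start != prev.end:
                raise EthogramValidationError(
                    f"segment {i}: starts at {seg.start}, previous ends at {prev.end}"
                )
            if seg.phase == prev.phase:
                raise EthogramValidationError(
                    f"segment {i}: phase {seg.phase!r} does not alternate"
                )
        prev = seg
    expected_interior = [False] + [True] * (len(segments) - 2) + [False]
    if len(segments) == 1:
        expected_interior = [False]
    for i, (seg, flag) in enumerate(zip(segments, expected_interior)):
        if seg.interior != flag:
            raise EthogramValidationError(f"segment {i}: interior flag must be {flag}")


# ---------------------------------------------------------------------------
# Tracking tables
# ---------------------------------------------------------------------------

def read_tracking_table(source, view: str = "front") -> TrackedTrajectory:
    """Read a pose-tracking table (DeepLabCut CSV or HDF5) into a trajectory.

    The container type is detected from the file extension (``.h5``/``.hdf5``
    for HDF5, anything else is parsed as CSV).  Body parts are located by
    name, so column order does not matter.  The result is uncalibrated
    (pixel units); samples with non-finite coordinates are masked.
    """
    if isinstance(source, (str, os.PathLike)) and str(source).lower().endswith((".h5", ".hdf5")):
        df = pd.read_hdf(source)
    else:
        if isinstance(source, (str, os.PathLike)):
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        else:
            text = source.read()
        _check_csv_header(text)
        df = pd.read_csv(io.StringIO(text), header=[0, 1, 2], index_col=0, dtype=str)
    return _trajectory_from_frame(df, view)


def _check_csv_header(text: str) -> None:
    """Reject duplicate (bodypart, coord) columns before pandas mangles them."""
    lines = text.splitlines()
    if len(lines) < 3:
        raise FormatError("tracking CSV needs scorer / bodyparts / coords header rows")
    bodyparts = [c.strip() for c in lines[1].split(",")[1:]]
    coords = [c.strip() for c in lines[2].split(",")[1:]]
    seen = set()
    for key in zip(bodyparts, coords):
        if key in seen:
            raise FormatError(f"duplicate body-part column {key[0]!r}/{key[1]!r}")
        seen.add(key)


def _trajectory_from_frame(df: pd.DataFrame, view: str) -> TrackedTrajectory:
    if df.shape[0] < 1:
        raise FormatError("tracking table has no frames")
    cols = df.columns
    if cols.nlevels != 3:
        raise FormatError(
            "expected three header rows (scorer / bodyparts / coords), "
            f"got {cols.nlevels} level(s)"
        )
    if cols.duplicated().any():
        dupes = sorted({bp for _, bp, _ in cols[cols.duplicated()]})
        raise FormatError(f"duplicate body-part columns: {dupes}")

    bodyparts: list[str] = []
    for _, bp, _ in cols:
        if bp not in bodyparts:
            bodyparts.append(bp)

    by_part: dict[str, dict[str, pd.Series]] = {bp: {} for bp in bodyparts}
    for col in cols:
        _, bp, coord = col
        by_part[bp][coord] = df[col]
    for bp in bodyparts:
        for coord in ("x", "y", "likelihood"):
            if coord not in by_part[bp]:
                raise FormatError(f"body part {bp!r} is missing its {coord!r} column")

    n = df.shape[0]
    x = np.empty((n, len(bodyparts)))
    y = np.empty_like(x)
    lk = np.empty_like(x)
    for j, bp in enumerate(bodyparts):
        x[:, j] = _numeric_column(by_part[bp]["x"], bp, "x")
        y[:, j] = _numeric_column(by_part[bp]["y"], bp, "y")
        lk[:, j] = _numeric_column(by_part[bp]["likelihood"], bp, "likelihood")

    valid = np.isfinite(x) & np.isfinite(y) & np.isfinite(lk)
    return TrackedTrajectory(
        view=view, bodyparts=tuple(bodyparts), x=x, y=y, likelihood=lk, valid=valid
    )


def _numeric_column(col: pd.Series, part: str, coord: str) -> np.ndarray:
    converted = pd.to_numeric(col, errors="coerce")
    bad = converted.isna() & col.notna() & (col.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {col.iloc[row]!r} in {part}/{coord} at row {row}"
        )
    return converted.to_numpy(dtype=float)


def _trajectory_to_frame(traj: TrackedTrajectory, scorer: str) -> pd.DataFrame:
    cols = pd.MultiIndex.from_tuples(
        [(scorer, bp, coord) for bp in traj.bodyparts for coord in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    data = np.empty((traj.n_frames, 3 * traj.n_parts))
    for j in range(traj.n_parts):
        data[:, 3 * j] = traj.x[:, j]
        data[:, 3 * j + 1] = traj.y[:, j]
        data[:, 3 * j + 2] = traj.likelihood[:, j]
    return pd.DataFrame(data, columns=cols)


def write_tracking_table(traj: TrackedTrajectory, path, scorer: str = "handkin") -> None:
    """Write a trajectory in the tracking dialect matching the path's extension."""
    df = _trajectory_to_frame(traj, scorer)
    if str(path).lower().endswith((".h5", ".hdf5")):
        df.to_hdf(path, key="tracking", mode="w")
    else:
        df.to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# Ethograms
# ---------------------------------------------------------------------------

def read_ethogram(source, fps: float | None = None, video_length_frames: int | None = None) -> Ethogram:
    """Parse an ethogram CSV into alternating half-open phase segments.

    Rows are ``(start_frame, phase[, grip_left, grip_right])`` sorted by
    start frame; each segment runs to the next row's start (the last to the
    declared video length).  The video length comes from an explicit argument
    or a leading ``# video_length_frames=N`` comment.  Missing grip columns
    become ``"absent"``.  ``fps`` is accepted for interface symmetry but not
    stored (durations are derived later with an explicit rate).
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    elif isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        text = str(source)

    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    length = video_length_frames
    while lines and lines[0].startswith("#"):
        comment = lines.pop(0).lstrip("#").strip()
        if comment.startswith("video_length_frames"):
            try:
                parsed = int(comment.split("=", 1)[1])
            except (IndexError, ValueError):
                raise ParseError(f"cannot parse video length from {comment!r}")
            if length is None:
                length = parsed
    if length is None:
        raise EthogramValidationError(
            "video length undeclared: pass video_length_frames= or add a "
            "'# video_length_frames=N' comment line"
        )
    if lines and lines[0].lower().startswith("frame"):
        lines.pop(0)  # header
    if not lines:
        raise EthogramValidationError("ethogram file has no segment rows")

    rows: list[tuple[int, str, str, str]] = []
    for i, ln in enumerate(lines):
        fields = [f.strip() for f in ln.split(",")]
        if len(fields) < 2:
            raise ParseError(f"row {i}: expected at least frame,phase, got {ln!r}")
        try:
            start = int(fields[0])
        except ValueError:
            raise ParseError(f"row {i}: non-integer start frame {fields[0]!r}")
        phase = PHASE_CODES.get(fields[1].upper(), fields[1].lower())
        grips = []
        for k in (2, 3):
            g = fields[k].lower() if len(fields) > k and fields[k] else "absent"
            if g not in GRIP_LABELS:
                raise ParseError(f"row {i}: unknown grip label {g!r}")
            grips.append(g)
        rows.append((start, phase, grips[0], grips[1]))

    return ethogram_from_rows(rows, length)


def ethogram_from_rows(rows: Sequence[tuple], video_length_frames: int) -> Ethogram:
    """Build an :class:`Ethogram` from ``(start, phase[, grips])`` rows."""
    starts = [r[0] for r in rows]
    if any(b <= a for a, b in zip(starts, starts[1:])):
        raise EthogramValidationError(f"start frames not strictly increasing: {starts}")
    if any(s >= video_length_frames for s in starts):
        bad = next(s for s in starts if s >= video_length_frames)
        raise EthogramValidationError(
            f"start frame {bad} beyond video length {video_length_frames}"
        )
    n = len(rows)
    segments = []
    for i, row in enumerate(rows):
        start, phase = row[0], row[1]
        grip_l = row[2] if len(row) > 2 else "absent"
        grip_r = row[3] if len(row) > 3 else "absent"
        end = rows[i + 1][0] if i + 1 < n else video_length_frames
        interior = 0 < i < n - 1
        segments.append(
            PhaseSegment(start, end, phase, grip_l, grip_r, interior=interior)
        )
    return Ethogram(segments, video_length_frames)


def write_ethogram(eth: Ethogram, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# video_length_frames={eth.video_length_frames}\n")
        fh.write("frame,phase,grip_left,grip_right\n")
        for seg in eth.segments:
            fh.write(
                f"{seg.start},{PHASE_TO_CODE[seg.phase]},{seg.grip_left},{seg.grip_right}\n"
            )


def read_exclusion_intervals(source) -> list[tuple[int, int]]:
    """Read half-open frame intervals from a ``start_frame,end_frame`` CSV."""
    df = pd.read_csv(source)
    cols = [c.strip().lower() for c in df.columns]
    if "start_frame" not in cols or "end_frame" not in cols:
        raise FormatError("exclusion file must have columns start_frame,end_frame")
    df.columns = cols
    return [(int(a), int(b)) for a, b in zip(df["start_frame"], df["end_frame"])]


# ---------------------------------------------------------------------------
# Quality masking and calibration
# ---------------------------------------------------------------------------

def mask_low_quality(
    traj: TrackedTrajectory,
    likelihood_floor: float = 0.0,
    exclusion_intervals: Iterable[tuple[int, int]] = (),
) -> TrackedTrajectory:
    """Mask samples below a confidence floor and inside exclusion intervals.

    The default floor of 0.0 masks nothing: tracking quality in the source
    studies was curated by manual refinement rather than thresholding, so a
    likelihood cut is strictly opt-in.  Original values stay in place under
    the mask, and masking is idempotent and order-independent between the two
    mechanisms.
    """
    if not (0.0 <= likelihood_floor <= 1.0):
        raise ParameterError(f"likelihood_floor must be in [0, 1], got {likelihood_floor}")
    out = traj.copy()
    if likelihood_floor > 0.0:
        out.valid &= ~(out.likelihood < likelihood_floor)
    for start, end in exclusion_intervals:
        if not (0 <= start <= end <= traj.n_frames):
            raise ParameterError(
                f"exclusion interval [{start}, {end}) outside [0, {traj.n_frames})"
            )
        out.valid[start:end, :] = False
    return out


def calibrate(traj: TrackedTrajectory, cal: Calibration) -> TrackedTrajectory:
    """Convert positions from pixels to millimetres and attach the frame rate."""
    if traj.is_calibrated:
        raise StateError("trajectory is already calibrated (positions in mm)")
    out = traj.copy()
    out.x *= cal.mm_per_px
    out.y *= cal.mm_per_px
    out.units = "mm"
    out.fps = cal.fps
    out.mm_per_px = cal.mm_per_px
    return out
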