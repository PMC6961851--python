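"""Head pitch angle from tracked eye positions via algebraic circle fitting.

When a head-restrained animal is allowed to pitch its head, the tracked eye
sweeps a circular arc around the rotation axis.  The arc's circle is
recovered with Pratt's algebraic fit — minimise the algebraic distance
``a(x^2+y^2) + bx + cy + d`` under the Pratt normalisation constraint
``b^2 + c^2 - 4ad = 1`` — which is exact on noiseless circle samples and
nearly unbiased for small arcs.  The head angle Θ of each frame is then the
four-quadrant arctangent of the eye's displacement from the circle centre,
with the image vertical flipped to up-positive, so 0° points horizontally
toward the animal's front and positive angles are counter-clockwise.  A
``flip`` flag mirrors the horizontal displacement for recordings where the
camera faced the other side (the convention is: eye on the left of the
centre).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import FitError
from .kinematics import wrap_angle_deg


@dataclass
class CircleFit:
    """Circle centre, radius and RMS radial residual (image units)."""

    cx: float
    cy: float
    radius: float
    rms_residual: float

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)


def fit_circle_pratt(points: np.ndarray) -> CircleFit:
    """Pratt's algebraic circle fit to >= 3 non-collinear 2D points.

    Solves the generalised eigenproblem of the design scatter matrix under
    the Pratt constraint and keeps the eigenvector of the smallest
    non-negative eigenvalue.  The data are centred first for conditioning;
    the fit is invariant to point ordering and translates rigidly with the
    points.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[~np.isnan(pts).any(axis=1)]
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise FitError(f"need >= 3 finite 2D points, got shape {pts.shape}")
    centroid = pts.mean(axis=0)
    x, y = (pts - centroid).T
    scale = np.sqrt(np.mean(x**2 + y**2))
    if scale == 0:
        raise FitError("all points coincide")
    x, y = x / scale, y / scale
    z = x**2 + y**2
    design = np.column_stack([z, x, y, np.ones_like(z)])
    M = design.T @ design / len(z)
    B = np.array(
        [
            [0.0, 0.0, 0.0, -2.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [-2.0, 0.0, 0.0, 0.0],
        ]
    )
    eigvals, eigvecs = scipy.linalg.eig(M, B)
    eigvals = np.real_if_close(eigvals, tol=1e6)
    real = np.isfinite(eigvals.real) & (np.abs(eigvals.imag) < 1e-8 * (1 + np.abs(eigvals.real)))
    candidates = [
        (lam.real, eigvecs[:, i].real)
        for i, lam in enumerate(eigvals)
        if real[i] and lam.real > -1e-10
    ]
    if not candidates:
        raise FitError("no admissible eigenvalue: points may be collinear")
    _, v = min(candidates, key=lambda t: t[0])
    a, b, c, d = v
    if abs(a) < 1e-12 * max(abs(b), abs(c), 1e-30):
        raise FitError("degenerate (collinear) configuration: fitted curve is a line")
    cx = -b / (2 * a)
    cy = -c / (2 * a)
    r2 = (b**2 + c**2 - 4 * a * d) / (4 * a**2)
    if r2 <= 0 or not np.isfinite(r2):
        raise FitError("fit produced a non-positive radius")
    cx, cy, r = cx * scale + centroid[0], cy * scale + centroid[1], np.sqrt(r2) * scale
    radial = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r
    return CircleFit(float(cx), float(cy), float(r), float(np.sqrt(np.mean(radial**2))))


@dataclass
class HeadAngleSeries:
    """Per-frame head pitch angle, degrees in (-180, 180]; NaN = undefined."""

    theta_deg: np.ndarray
    fit: CircleFit
    flip: bool

    def to_frame(self, fps: float | None = None):
        import pandas as pd

        out = {"frame": np.arange(len(self.theta_deg))}
        if fps is not None:
            out["t"] = out["frame"] / fps
        out["theta_deg"] = self.theta_deg
        return pd.DataFrame(out)


def head_angle_series(
    eye: np.ndarray, fit: CircleFit, flip: bool = False
) -> HeadAngleSeries:
    """Head angle per frame from eye displacement off the fitted circle centre.

    Θ = atan2(-dy, dx) in degrees, with (dx, dy) the eye-minus-centre
    displacement in image (y-down) coordinates — the sign flip on dy makes
    the angle y-up.  ``flip`` negates dx first, for mirrored recordings.
    Frames with the eye exactly at the centre are undefined (NaN).
    """
    xy = np.asarray(eye, dtype=float)
    dx = xy[:, 0] - fit.cx
    dy = xy[:, 1] - fit.cy
    if flip:
        dx = -dx
    with np.errstate(invalid="ignore"):
        theta = np.degrees(np.arctan2(-dy, dx))
    theta = wrap_angle_deg(theta)
    theta = np.where((dx == 0) & (dy == 0), np.nan, theta)
    theta = np.where(np.isnan(dx) | np.isnan(dy), np.nan, theta)
    return HeadAngleSeries(theta, fit, flip)
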