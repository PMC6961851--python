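"""Derived kinematic features from tracked body parts.

The two coordinates that span the food-handling posture space are

* ``D`` — inter-D3 distance (mm), the bimanual grip aperture, and
* ``L`` — distance (mm) from the snout tip to the midpoint of the two D3
  knuckles, the hand-to-mouth distance.

``theta`` is the orientation of the left-to-right D3 vector in degrees,
measured against the image horizontal with the vertical axis flipped to
up-positive, in (-180, 180].  Only *changes* in theta are analysed downstream,
which makes the reference-axis choice immaterial.  Side and ventral camera
views yield the view-specific snout-to-hands distances ``L_side`` and
``L_ventral`` computed the same way.

Any feature whose constituent samples are masked is missing (NaN) and stays
missing through all downstream computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import ConfigurationError, InsufficientDataError, UnitError
from .tracking_io import TrackedTrajectory

DEFAULT_PARTS = {"nose": "nose", "left_d3": "LD3", "right_d3": "RD3"}


@dataclass
class FeatureSeries:
    """Per-frame kinematic features on a shared timebase (NaN = missing)."""

    t: np.ndarray
    fps: float
    view: str
    L: np.ndarray | None = None
    D: np.ndarray | None = None
    theta: np.ndarray | None = None
    D_avg: np.ndarray | None = None  # (n, 2) midpoint of the two D3s
    L_ventral: np.ndarray | None = None
    L_side: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: frame, t and whichever features this view defines."""
        out = {"frame": np.arange(self.n_frames), "t": self.t}
        for name in ("L", "D", "theta", "L_ventral", "L_side"):
            arr = getattr(self, name)
            if arr is not None:
                out[name] = arr
        return pd.DataFrame(out)


def wrap_angle_deg(theta: np.ndarray) -> np.ndarray:
    """Wrap angles in degrees into (-180, 180]."""
    wrapped = (np.asarray(theta, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(wrapped <= -180.0, wrapped + 360.0, wrapped)


def compute_features(
    traj: TrackedTrajectory,
    nose: str = "nose",
    left_d3: str = "LD3",
    right_d3: str = "RD3",
) -> FeatureSeries:
    """Compute L, D, theta (front view) or L_side / L_ventral from a trajectory.

    The trajectory must be calibrated (mm).  For side/ventral views a single
    visible D3 stands in for the pair (its position is its own midpoint).
    Frames with any masked constituent sample yield missing features.
    """
    if not traj.is_calibrated:
        raise UnitError("trajectory must be calibrated to mm before feature extraction")
    if nose not in traj.bodyparts:
        raise ConfigurationError(f"required body part {nose!r} absent from trajectory")
    nose_xy = traj.position(nose)

    have = [p for p in (left_d3, right_d3) if p in traj.bodyparts]
    if traj.view == "front" and len(have) < 2:
        missing = [p for p in (left_d3, right_d3) if p not in traj.bodyparts]
        raise ConfigurationError(f"required body part(s) {missing} absent from front view")
    if not have:
        raise ConfigurationError(f"no D3 part among {(left_d3, right_d3)} in trajectory")

    if len(have) == 2:
        lxy = traj.position(left_d3)
        rxy = traj.position(right_d3)
        mid = 0.5 * (lxy + rxy)
        diff = rxy - lxy
        D = np.hypot(diff[:, 0], diff[:, 1])
        with np.errstate(invalid="ignore"):
            theta = np.degrees(np.arctan2(-diff[:, 1], diff[:, 0]))
        theta = wrap_angle_deg(theta)
        theta = np.where(D == 0, np.nan, theta)
        theta = np.where(np.isnan(D), np.nan, theta)
    else:
        mid = traj.position(have[0])
        D = None
        theta = None

    dl = nose_xy - mid
    L = np.hypot(dl[:, 0], dl[:, 1])

    fs = FeatureSeries(t=traj.times(), fps=float(traj.fps), view=traj.view)
    if traj.view == "ventral":
        fs.L_ventral = L
    elif traj.view == "side":
        fs.L_side = L
    else:
        fs.L = L
    if D is not None:
        fs.D = D
        fs.theta = theta
        fs.D_avg = mid
    return fs


@dataclass
class PairwisePCA:
    """Principal components of per-frame pairwise body-part distances."""

    pairs: list[tuple[str, str]]
    components: np.ndarray          # (n_components, n_pairs) loadings
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    n_frames_used: int


def pairwise_distances(traj: TrackedTrajectory) -> tuple[list[tuple[str, str]], np.ndarray]:
    """One Euclidean distance per unordered part pair per frame (NaN-masked)."""
    pairs = list(combinations(traj.bodyparts, 2))
    n = traj.n_frames
    dist = np.empty((n, len(pairs)))
    pos = {bp: traj.position(bp) for bp in traj.bodyparts}
    for k, (a, b) in enumerate(pairs):
        d = pos[a] - pos[b]
        dist[:, k] = np.hypot(d[:, 0], d[:, 1])
    return pairs, dist


def pairwise_distance_pca(traj: TrackedTrajectory) -> PairwisePCA:
    """PCA of the pairwise-distance vectors across frames.

    Frames with any masked part are dropped; at least 3 complete frames and
    2 body parts are required.  Components come back in decreasing
    explained-variance order and their variances sum to the total variance.
    """
    if traj.n_parts < 2:
        raise InsufficientDataError("pairwise PCA needs at least 2 body parts")
    pairs, dist = pairwise_distances(traj)
    complete = ~np.isnan(dist).any(axis=1)
    data = dist[complete]
    if data.shape[0] < 3:
        raise InsufficientDataError(
            f"pairwise PCA needs >= 3 unmasked frames, have {data.shape[0]}"
        )
    pca = PCA()
    pca.fit(data)
    return PairwisePCA(
        pairs=pairs,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_frames_used=data.shape[0],
    )
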