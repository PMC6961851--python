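import numpy as np
import pytest

import handkin as hk

FPS = hk.DEFAULT_FPS


def _make_traj(parts, fps=FPS, view="front", units="mm"):
    """Build a trajectory directly from {part: (n, 2) array} mm coordinates."""
    names = tuple(parts)
    n = len(next(iter(parts.values())))
    x = np.column_stack([np.asarray(parts[p], dtype=float)[:, 0] for p in names])
    y = np.column_stack([np.asarray(parts[p], dtype=float)[:, 1] for p in names])
    return hk.TrackedTrajectory(
        view=view,
        bodyparts=names,
        x=x,
        y=y,
        likelihood=np.ones((n, len(names))),
        valid=np.ones((n, len(names)), dtype=bool),
        units=units,
        fps=fps if units == "mm" else None,
        mm_per_px=1.0 if units == "mm" else None,
    )


@pytest.fixture
def traj_factory():
    return _make_traj


@pytest.fixture(scope="session")
def default_session():
    """One 120 s synthetic session at generator defaults."""
    return hk.generate_session(hk.GeneratorParams(duration_s=120.0), seed=0)


@pytest.fixture(scope="session")
def session_features(default_session):
    """Calibrated front/ventral feature series of the default session."""
    s = default_session
    front = hk.calibrate(hk.mask_low_quality(s.front, 0.5), s.truth.calibration)
    ventral = hk.calibrate(hk.mask_low_quality(s.ventral, 0.5), s.truth.calibration)
    return hk.compute_features(front), hk.compute_features(ventral)
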