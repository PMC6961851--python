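"""Phase statistics, L-method k selection, mode clustering, densities, rise times."""

import numpy as np
import pytest

import handkin as hk
from handkin.kinematics import FeatureSeries


# ---------------------------------------------------------------------------
# Phase statistics
# ---------------------------------------------------------------------------

def test_phase_statistics_hand_example():
    # H 0.3 s, O 0.2 s, H 0.3 s, O 0.2 s, H 0.5 s at 10 fps
    eth = hk.ethogram_from_rows(
        [(0, "holding"), (3, "oromanual"), (5, "holding"), (8, "oromanual"), (10, "holding")],
        15,
    )
    ps = hk.phase_statistics(eth, fps=10.0)
    assert ps.switch_rate_hz == pytest.approx(4 / 1.5)
    assert ps.duty_cycle == pytest.approx(0.4 / 1.5)
    # only the three interior segments contribute durations
    assert sorted(ps.phase_durations_s["oromanual"]) == pytest.approx([0.2, 0.2])
    assert ps.phase_durations_s["holding"] == pytest.approx([0.3])


def test_phase_statistics_single_segment():
    ps = hk.phase_statistics(hk.ethogram_from_rows([(0, "holding")], 50), fps=10.0)
    assert ps.switch_rate_hz == 0.0
    assert ps.phase_durations_s["holding"] == []


def test_phase_statistics_equal_alternation_duty_half():
    rows = [(i * 5, "holding" if i % 2 == 0 else "oromanual") for i in range(20)]
    ps = hk.phase_statistics(hk.ethogram_from_rows(rows, 100), fps=20.0)
    assert ps.duty_cycle == pytest.approx(0.5)


def test_generator_truth_recovers_switch_rate_and_duty():
    """Phase statistics on true ethograms recover the generator's analytic
    switch rate (within 5 %) and duty cycle (within 0.02) at 120 s."""
    params = hk.GeneratorParams(duration_s=120.0)
    rates, duties = [], []
    for seed in range(4):
        truth = hk.generate_session(params, seed=seed).truth
        ps = hk.phase_statistics(truth.ethogram, params.fps)
        rates.append(ps.switch_rate_hz)
        duties.append(ps.duty_cycle)
        assert abs(ps.duty_cycle - params.analytic_duty_cycle) < 0.02
    assert np.mean(rates) == pytest.approx(params.analytic_switch_rate_hz, rel=0.05)


# ---------------------------------------------------------------------------
# L-method
# ---------------------------------------------------------------------------

def _lmethod_oracle(sse):
    """Independent brute-force two-line fit via explicit normal equations."""
    sse = np.asarray(sse, dtype=float)
    ks = np.arange(1, len(sse) + 1, dtype=float)

    def rmse(x, y):
        if len(x) == 1:
            return 0.0
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return float(np.sqrt(np.mean((y - A @ coef) ** 2)))

    errs = {}
    for c in range(2, len(sse)):
        nl, nr = c, len(sse) - c + 1
        errs[c] = (nl * rmse(ks[:c], sse[:c]) + nr * rmse(ks[c - 1 :], sse[c - 1 :])) / (nl + nr)
    best = min(errs.values())
    return min(c for c, e in errs.items() if e <= best + 1e-12)


@pytest.mark.parametrize(
    "sse, expected",
    [
        ([100, 10, 9.5, 9.2, 9.0, 8.9, 8.8, 8.7, 8.6, 8.5], 2),
        ([100, 55, 10, 9.6, 9.2, 8.8, 8.4, 8.0, 7.6, 7.2], 3),   # elbow built at k = 3
        (list(np.linspace(100, 10, 10)), 2),                      # linear: tie -> smallest
    ],
)
def test_select_k_lmethod(sse, expected):
    assert hk.select_k_lmethod(sse) == expected
    assert hk.select_k_lmethod(sse) == _lmethod_oracle(sse)


def test_select_k_lmethod_random_curves_match_oracle():
    rng = np.random.default_rng(42)
    for _ in range(20):
        sse = np.sort(rng.random(10))[::-1] * 100
        assert hk.select_k_lmethod(sse) == _lmethod_oracle(sse)


def test_select_k_lmethod_needs_four_points():
    with pytest.raises(hk.ParameterError):
        hk.select_k_lmethod([3, 2, 1])


# ---------------------------------------------------------------------------
# Mode clustering
# ---------------------------------------------------------------------------

def _features_from_points(pts, fps=294.1):
    n = len(pts)
    return FeatureSeries(
        t=np.arange(n) / fps, fps=fps, view="front", L=pts[:, 0], D=pts[:, 1]
    )


def test_cluster_two_blobs_recovers_means_and_labels():
    rng = np.random.default_rng(7)
    holding = rng.normal([5.1, 4.0], 0.3, size=(500, 2))
    oromanual = rng.normal([2.7, 6.0], 0.3, size=(500, 2))
    feats = _features_from_points(np.vstack([holding, oromanual]))
    res = hk.cluster_phases(feats, rng_seed=0)
    assert res.k_selected == 2
    order = np.argsort(res.centroids[:, 0])
    np.testing.assert_allclose(res.centroids[order[0]], [2.7, 6.0], atol=0.1)
    np.testing.assert_allclose(res.centroids[order[1]], [5.1, 4.0], atol=0.1)
    assert res.phase_labels[order[0]] == "oromanual"
    assert res.phase_labels[order[1]] == "holding"
    assert (res.assignments >= 0).sum() == 1000


def test_cluster_identical_samples_degenerate():
    feats = _features_from_points(np.tile([3.0, 4.0], (50, 1)))
    res = hk.cluster_phases(feats, rng_seed=0)
    assert res.degenerate and res.k_selected == 1


def test_cluster_sse_curve_non_increasing():
    rng = np.random.default_rng(3)
    feats = _features_from_points(rng.normal([4, 5], 1.0, size=(300, 2)))
    res = hk.cluster_phases(feats, rng_seed=1)
    assert (np.diff(res.sse_curve) <= 1e-6).all()


def test_cluster_insufficient_samples():
    feats = _features_from_points(np.random.default_rng(0).normal(size=(5, 2)))
    with pytest.raises(hk.InsufficientDataError):
        hk.cluster_phases(feats, k_max=10)


def test_cluster_agreement_with_generating_states(default_session, session_features):
    """Cluster assignments agree with the generating phase sequence >= 90 %."""
    front, _ = session_features
    res = hk.cluster_phases(front, rng_seed=0)
    assert res.k_selected == 2
    truth = default_session.truth.ethogram
    phase_true = np.empty(front.n_frames, dtype=object)
    for seg in truth.segments:
        phase_true[seg.start : seg.end] = seg.phase
    good = res.assignments >= 0
    pred = np.empty(front.n_frames, dtype=object)
    for c, label in res.phase_labels.items():
        pred[res.assignments == c] = label
    agreement = (pred[good] == phase_true[good]).mean()
    assert agreement >= 0.90


# ---------------------------------------------------------------------------
# Density maps and contours
# ---------------------------------------------------------------------------

def test_density_normalisation_and_peak_location():
    rng = np.random.default_rng(1)
    groups = {
        "m1": rng.normal([5, 5], 0.2, size=(400, 2)),
        "m2": rng.normal([12, 9], 0.2, size=(400, 2)),
    }
    maps, avg = hk.density_contours(groups)
    for name, dm in maps.items():
        assert dm.density.max() == pytest.approx(1.0)
        assert dm.contours, "10% contour must exist"
    iy, ix = np.unravel_index(np.argmax(maps["m1"].density), maps["m1"].density.shape)
    assert maps["m1"].x_grid[ix] == pytest.approx(5.0, abs=0.3)
    assert maps["m1"].y_grid[iy] == pytest.approx(5.0, abs=0.3)
    # contour encloses the cluster centre
    poly = maps["m1"].contours[0]
    assert poly[:, 0].min() < 5 < poly[:, 0].max()
    assert poly[:, 1].min() < 5 < poly[:, 1].max()
    # average map is the mean of the normalised per-group maps
    np.testing.assert_allclose(
        avg.density, (maps["m1"].density + maps["m2"].density) / 2, atol=1e-12
    )


def test_density_gaussian_contour_radius_matches_analytic():
    """For an isotropic Gaussian sample the 10 %-of-peak contour approximates
    a circle of radius sigma_total * sqrt(2 ln 10), where sigma_total folds in
    the kernel bandwidth."""
    rng = np.random.default_rng(2)
    n, sigma, centre = 2000, 1.0, np.array([10.0, 10.0])
    pts = rng.normal(centre, sigma, size=(n, 2))
    maps, _ = hk.density_contours({"g": pts})
    dm = maps["g"]
    h = sigma * n ** (-1 / 6)
    r_expect = np.sqrt(sigma**2 + h**2) * np.sqrt(2 * np.log(10))
    poly = max(dm.contours, key=len)
    radii = np.hypot(poly[:, 0] - centre[0], poly[:, 1] - centre[1])
    assert np.mean(radii) == pytest.approx(r_expect, rel=0.10)


def test_density_clips_outside_support_with_warning():
    pts = np.array([[5.0, 5.0], [25.0, 5.0], [6.0, 6.0]])
    with pytest.warns(UserWarning, match="clipped"):
        maps, _ = hk.density_contours({"g": pts})
    assert maps["g"].density.max() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Transition rise time
# ---------------------------------------------------------------------------

def _ramp_trace(fps, baseline, level, ramp, t_trans=1.0, t_total=1.2):
    t = np.arange(int(t_total * fps)) / fps
    y = np.full_like(t, baseline)
    on = t >= t_trans - ramp
    y[on] = baseline + (level - baseline) * np.minimum((t[on] - (t_trans - ramp)) / ramp, 1.0)
    return t, y


def test_rise_time_recovers_pure_ramp():
    t, y = _ramp_trace(1000.0, 5.0, 3.0, 0.100)
    d = hk.transition_rise_time(y, 1000.0, 1.0, t=t)
    assert d == pytest.approx(0.100, abs=1e-9)


@pytest.mark.parametrize("baseline, level, ramp", [(5, 3, 0.05), (2, 9, 0.2), (-1, 1, 0.12)])
def test_rise_time_any_slope_and_baseline(baseline, level, ramp):
    fps = 294.1
    t, y = _ramp_trace(fps, baseline, level, ramp)
    d = hk.transition_rise_time(y, fps, 1.0, t=t)
    assert d == pytest.approx(ramp, abs=1 / fps)


def test_rise_time_invariant_to_offset():
    fps = 294.1
    t, y = _ramp_trace(fps, 5.0, 3.0, 0.1)
    d1 = hk.transition_rise_time(y, fps, 1.0, t=t)
    d2 = hk.transition_rise_time(y + 100.0, fps, 1.0, t=t)
    assert d1 == pytest.approx(d2, abs=1e-9)


def test_rise_time_step_is_undefined():
    fps = 294.1
    t = np.arange(int(1.2 * fps)) / fps
    y = np.where(t < 1.0, 5.0, 3.0)
    with pytest.raises(hk.UndefinedResultError):
        hk.transition_rise_time(y, fps, 1.0, t=t)


def test_rise_time_flat_trace_is_undefined():
    fps = 294.1
    t = np.arange(int(1.2 * fps)) / fps
    with pytest.raises(hk.UndefinedResultError):
        hk.transition_rise_time(np.full_like(t, 4.0), fps, 1.0, t=t)


def test_rise_time_requires_coverage():
    with pytest.raises(hk.ParameterError):
        hk.transition_rise_time(np.ones(30), 294.1, 1.0)
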