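"""Geometric observables: axes, angles, distances, dimer detection, RMSF."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import tmdimer as td
from tmdimer import (
    helix_axis,
    tilt_angle,
    crossing_angle,
    interhelical_distance,
    detect_dimer,
    rmsf,
    compute_metrics,
    Trajectory,
)


def straight_rod(n=23, rise=0.15, direction=(0.0, 0.0, -1.0), origin=(0, 0, 0)):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return np.asarray(origin, dtype=float) + np.arange(n)[:, None] * rise * d


# ---------------------------------------------------------------------------
# helix axis

def test_axis_of_straight_rod_points_n_to_c():
    coords = straight_rod(direction=(0, 0, -1), origin=(0, 0, 3.3))
    assert np.allclose(helix_axis(coords), [0, 0, -1])


def test_axis_equivariant_under_rotation(rng):
    coords = straight_rod()
    rot = Rotation.from_euler("y", 45, degrees=True)
    assert np.allclose(helix_axis(rot.apply(coords)),
                       rot.apply(helix_axis(coords)), atol=1e-10)


def test_axis_robust_to_noise(rng):
    """Monte-Carlo: noisy rods stay within 3 degrees of the clean axis."""
    clean = straight_rod()
    axis0 = helix_axis(clean)
    for _ in range(50):
        noisy = clean + rng.normal(0.0, 0.05, clean.shape)
        assert crossing_angle(helix_axis(noisy), axis0) < 3.0


def test_axis_degenerate_inputs():
    with pytest.raises(ValueError, match="at least 3"):
        helix_axis(np.zeros((2, 3)))
    with pytest.raises(ValueError, match="degenerate"):
        helix_axis(np.ones((5, 3)))


# ---------------------------------------------------------------------------
# angles

@pytest.mark.parametrize("axis,expected", [
    ((0, 0, 1), 0.0),
    ((1, 0, 1), 45.0),
    ((0, 0, -1), 0.0),  # fold invariance
    ((1, 0, 0), 90.0),
])
def test_tilt_angle_worked_examples(axis, expected):
    a = np.asarray(axis, dtype=float)
    assert tilt_angle(a / np.linalg.norm(a)) == pytest.approx(expected, abs=1e-9)


def test_crossing_angle_worked_examples():
    assert crossing_angle([0, 0, 1], [0, 0, 1]) == pytest.approx(0.0)
    assert crossing_angle([0, 0, 1], [1, 0, 0]) == pytest.approx(90.0)


def test_angle_domain_errors():
    with pytest.raises(ValueError):
        tilt_angle([0.0, 0.0, 0.0])
    with pytest.raises(ValueError):
        crossing_angle([0.0, 0.0, 0.0], [0.0, 0.0, 1.0])


@settings(deadline=None, max_examples=50)
@given(st.floats(0.0, 90.0), st.floats(0.0, 360.0), st.integers(0, 10**6))
def test_fold_and_rotation_invariance(tilt, azim, seed):
    """theta(-v) = theta(v); crossing is invariant under a common rotation."""
    t, p = np.radians(tilt), np.radians(azim)
    v = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
    assert tilt_angle(-v) == pytest.approx(tilt_angle(v), abs=1e-9)
    rot = Rotation.random(rng=np.random.default_rng(seed))
    w = Rotation.from_euler("z", 77, degrees=True).apply(v)
    # arccos loses precision near parallel axes; 1e-5 deg covers that
    assert crossing_angle(rot.apply(v), rot.apply(w)) == pytest.approx(
        crossing_angle(v, w), abs=1e-5
    )


# ---------------------------------------------------------------------------
# interhelical distance and dimer detection

def test_distance_345_triangle():
    a = np.zeros((4, 3))
    b = np.zeros((4, 3)) + np.array([3.0, 4.0, 0.0])
    assert interhelical_distance(a, b) == pytest.approx(5.0)
    assert interhelical_distance(a, a) == 0.0
    assert interhelical_distance(a, b) == interhelical_distance(b, a)


def test_distance_minimum_image_lateral():
    a = np.zeros((1, 3))
    b = np.array([[9.0, 0.0, 0.0]])
    assert interhelical_distance(a, b, box=[10.0, 10.0, 10.0]) == pytest.approx(1.0)
    # z is never wrapped
    c = np.array([[0.0, 0.0, 9.0]])
    assert interhelical_distance(a, c, box=[10.0, 10.0, 10.0]) == pytest.approx(9.0)


def test_distance_empty_selection():
    with pytest.raises(ValueError, match="empty"):
        interhelical_distance(np.empty((0, 3)), np.zeros((2, 3)))


def test_detect_dimer_worked_examples():
    flags, first = detect_dimer([5.0, 5.0, 5.0])
    assert first is None and not flags.any()
    flags, first = detect_dimer([2.0, 1.2, 1.1])
    assert list(flags) == [False, True, True] and first == 1
    # default cutoff is 1.3 nm
    flags, _ = detect_dimer([1.3, 1.31])
    assert list(flags) == [True, False]


# ---------------------------------------------------------------------------
# RMSF

def _toy_traj(coords):
    import pandas as pd

    n = coords.shape[1]
    beads = pd.DataFrame({"chain": ["A"] * n, "res_id": range(1, n + 1),
                          "res_name": ["UNK"] * n, "bead": ["BB"] * n})
    return Trajectory(coords=coords, beads=beads)


def test_rmsf_constant_trajectory_is_zero():
    coords = np.tile(straight_rod(8), (5, 1, 1))
    values = rmsf(_toy_traj(coords), "A", superpose=False)["rmsf"]
    assert np.allclose(values, 0.0)


def test_rmsf_closed_form_displacement():
    base = straight_rod(8)
    delta = 0.3
    frames = np.stack([base, base])
    frames[0, 2, 0] -= delta
    frames[1, 2, 0] += delta
    values = rmsf(_toy_traj(frames), "A", superpose=False)["rmsf"].to_numpy()
    assert values[2] == pytest.approx(delta, abs=1e-12)
    assert np.allclose(np.delete(values, 2), 0.0)


def test_rmsf_superposition_removes_rigid_motion():
    base = straight_rod(8) + np.array([0.3, 0.1, 0.0])  # off-axis so rotation moves beads
    rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True)
    frames = np.stack([base, rot.apply(base) + 1.0])
    values = rmsf(_toy_traj(frames), "A", superpose=True)["rmsf"]
    assert np.all(values < 1e-6)


def test_rmsf_single_frame_error():
    with pytest.raises(ValueError, match="two frames"):
        rmsf(_toy_traj(straight_rod(8)[None]), "A")


def test_core_residues_less_flexible_than_termini(ir, xshape_run):
    traj, _ = xshape_run
    prof = rmsf(traj, "A")
    core = prof[prof.res_id.between(*ir.core_range)]["rmsf"].mean()
    term = prof[~prof.res_id.between(*ir.core_range)]["rmsf"].mean()
    assert core < term


# ---------------------------------------------------------------------------
# metric series on generator output

def test_measured_angles_match_ground_truth(ir, xshape_run, xshape_metrics):
    _, truth = xshape_run
    m = xshape_metrics
    bound = truth.bound
    dt = np.abs(m.tilt_a[bound] - truth.theta_a[bound])
    db = np.abs(m.tilt_b[bound] - truth.theta_b[bound])
    do = np.abs(m.omega[bound] - truth.omega[bound])
    for err in (dt, db, do):
        assert (err < 1.0).mean() >= 0.99
    dd = np.abs(m.d_hh[bound] - truth.d_hh[bound])
    assert (dd < 0.05).mean() >= 0.99


def test_metric_series_invariants(xshape_metrics):
    m = xshape_metrics
    assert np.all((m.tilt_a >= 0) & (m.tilt_a <= 90))
    assert np.all((m.omega >= 0) & (m.omega <= 90))
    assert np.all(m.d_hh > 0)
    assert np.array_equal(m.dimer, m.d_hh <= m.cutoff)


def test_metrics_symmetric_under_chain_exchange(ir, xshape_run):
    traj, _ = xshape_run
    sub = traj.subset_frames(np.arange(50))
    swapped = Trajectory(
        coords=sub.coords[:, td.chain_swap_map(sub.beads, ir.chains), :],
        beads=sub.beads, box=sub.box, times=sub.times,
    )
    a = compute_metrics(sub, ir)
    b = compute_metrics(swapped, ir)
    assert np.allclose(a.d_hh, b.d_hh)
    assert np.allclose(a.omega, b.omega)
    assert np.allclose(a.tilt_a, b.tilt_b)
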