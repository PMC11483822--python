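"""Kabsch RMSD, Daura clustering, averages, contact maps, shape labels."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import tmdimer as td
from tmdimer import (
    kabsch_rmsd,
    superpose_onto,
    pairwise_rmsd_matrix,
    chain_swap_map,
    daura_cluster,
    average_structure,
    contact_map,
    classify_shape,
)


def brute_force_daura(rmsd, cutoff):
    """Independent reimplementation of the greedy neighbour-count rule."""
    n = rmsd.shape[0]
    remaining = set(range(n))
    assignment = {}
    centers = []
    cid = 0
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if rmsd[i, j] <= cutoff or i == j)
            if count > best_count:
                best, best_count = i, count
        members = {j for j in remaining if rmsd[best, j] <= cutoff} | {best}
        for j in members:
            assignment[j] = cid
        centers.append(best)
        remaining -= members
        cid += 1
    return np.array([assignment[i] for i in range(n)]), centers


# ---------------------------------------------------------------------------
# Kabsch RMSD

def test_identity_and_rigid_motion_are_zero(rng):
    x = rng.normal(size=(10, 3))
    assert kabsch_rmsd(x, x) == 0.0
    rot = Rotation.from_euler("xyz", [12, 34, 56], degrees=True)
    y = rot.apply(x) + np.array([1.0, 2.0, 3.0])
    assert kabsch_rmsd(x, y) < 1e-9


def test_mirror_image_not_superposable(rng):
    x = rng.normal(size=(6, 3))
    y = x.copy()
    y[:, 0] *= -1.0  # reflection: a proper rotation cannot undo it
    assert kabsch_rmsd(x, y) > 0.05


def test_kabsch_matches_rotation_grid_oracle():
    """Planar 4-point toys: exhaustive 1-degree rotation search."""
    rng = np.random.default_rng(77)
    for _ in range(5):
        x = np.column_stack([rng.normal(size=(4, 2)), np.zeros(4)])
        angle = rng.uniform(0, 2 * np.pi)
        noise = np.column_stack([rng.normal(0, 0.05, (4, 2)), np.zeros(4)])
        rot = Rotation.from_euler("z", angle)
        y = rot.apply(x) + noise + np.array([0.5, -0.2, 0.0])

        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        best = np.inf
        for deg in np.arange(0.0, 360.0, 1.0):
            r = Rotation.from_euler("z", deg, degrees=True)
            best = min(best, np.sqrt(np.mean(np.sum((xc - r.apply(yc)) ** 2, -1))))
        assert kabsch_rmsd(x, y) <= best + 1e-12
        assert abs(kabsch_rmsd(x, y) - best) < 1e-3


def test_kabsch_input_validation():
    with pytest.raises(ValueError):
        kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
    with pytest.raises(ValueError):
        kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


def test_pairwise_matrix_matches_scipy_loop(rng):
    frames = rng.normal(size=(12, 7, 3))
    mat = pairwise_rmsd_matrix(frames)
    for i in range(12):
        for j in range(i, 12):
            assert mat[i, j] == pytest.approx(
                kabsch_rmsd(frames[i], frames[j]), abs=1e-8
            )


def test_chain_swap_reduces_rmsd_for_relabelled_homodimer(ir, rng):
    traj, _ = td.generate(ir, td.get_preset("ir_xshape"), n_frames=6, seed=8)
    swap = chain_swap_map(traj.beads, ir.chains)
    coords = traj.coords
    swapped = coords[0:1, swap, :]
    plain = pairwise_rmsd_matrix(np.concatenate([coords[:1], swapped]))
    with_swap = pairwise_rmsd_matrix(
        np.concatenate([coords[:1], swapped]), swap_map=swap
    )
    # relabelling is invisible once the swap mapping is considered
    assert with_swap[0, 1] < 1e-6
    assert plain[0, 1] > with_swap[0, 1]


# ---------------------------------------------------------------------------
# Daura clustering

def test_single_cluster_when_all_within_cutoff(rng):
    frames = rng.normal(size=(8, 5, 3)) * 0.01
    result = daura_cluster(frames, cutoff=1.0)
    assert result.n_clusters == 1
    assert result.sizes == [8]
    assert result.percentages[0] == pytest.approx(100.0)


def test_two_separated_groups_recovered(rng):
    a = rng.normal(size=(6, 5, 3)) * 0.01
    b = rng.normal(size=(4, 5, 3)) * 0.01 + np.array([0, 0, 30.0])
    b = b * np.array([1.0, 1.0, -1.0])  # different internal geometry
    b[:, :, 2] += rng.normal(size=(4, 1)) * 0.01
    b[:, 2, :] += 5.0  # distort one bead far away
    frames = np.concatenate([a, b])
    result = daura_cluster(frames, cutoff=1.0)
    assert result.n_clusters == 2
    assert set(result.assignments[:6]) == {0} and set(result.assignments[6:]) == {1}
    assert sum(result.sizes) == 10


def test_matches_brute_force_reference(rng):
    frames = rng.normal(size=(30, 4, 3))
    mat = pairwise_rmsd_matrix(frames)
    for cutoff in (0.4, 0.8, 1.2):
        ours = daura_cluster(frames, cutoff=cutoff, rmsd_matrix=mat)
        ref_assign, ref_centers = brute_force_daura(mat, cutoff)
        assert np.array_equal(ours.assignments, ref_assign)
        assert ours.centers == ref_centers


def test_invariant_under_global_rigid_motion(rng):
    frames = rng.normal(size=(15, 6, 3))
    rot = Rotation.from_euler("zyx", [40, 10, 70], degrees=True)
    moved = np.stack([rot.apply(f) + np.array([3.0, -1.0, 2.0]) for f in frames])
    a = daura_cluster(frames, cutoff=0.9)
    b = daura_cluster(moved, cutoff=0.9)
    assert np.array_equal(a.assignments, b.assignments)
    assert a.centers == b.centers


def test_cluster_count_non_increasing_in_cutoff(rng):
    frames = rng.normal(size=(25, 5, 3))
    mat = pairwise_rmsd_matrix(frames)
    counts = [
        daura_cluster(frames, cutoff=c, rmsd_matrix=mat).n_clusters
        for c in (0.2, 0.5, 0.8, 1.1, 1.5, 2.5)
    ]
    assert counts == sorted(counts, reverse=True)


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        daura_cluster(np.empty((0, 5, 3)))


# ---------------------------------------------------------------------------
# average structures

def test_average_of_single_frame_is_itself(rng):
    frame = rng.normal(size=(6, 3))
    assert np.allclose(average_structure(frame[None], frame), frame)


def test_average_of_symmetric_pair_is_center(rng):
    centre = rng.normal(size=(6, 3))
    delta = rng.normal(size=(6, 3)) * 0.01
    frames = np.stack([centre + delta, centre - delta])
    avg = average_structure(frames, centre)
    assert np.abs(avg - centre).max() < 1e-3


def test_average_converges_to_template(rng):
    template = rng.normal(size=(10, 3))
    frames = template[None] + rng.normal(0.0, 0.05, size=(100, 10, 3))
    avg = average_structure(frames, template)
    assert kabsch_rmsd(avg, template) < 0.02


# ---------------------------------------------------------------------------
# contact maps

def test_contact_map_dimensions_and_closed_form(ir):
    a = td.build_helix(ir, "A", 0.0, 0.0, (0.0, 0.0))
    b = td.build_helix(ir, "B", 0.0, 0.0, (1.0, 0.0))
    coords = np.concatenate([a, b])[None]
    traj = td.Trajectory(coords=coords, beads=td.make_bead_table(ir))
    cmap = contact_map(traj, ir, [True])
    n = ir.n_residues
    assert cmap.values.shape == (n, n)
    # vertical rods 1 nm apart: d(i, j) = sqrt(1 + (0.15*(i-j))^2)
    i = np.arange(n)
    expected = np.sqrt(1.0 + (0.15 * (i[:, None] - i[None, :])) ** 2)
    assert np.allclose(cmap.values, expected, atol=1e-12)


def test_contact_map_symmetric_for_symmetric_dimer(ir, xshape_run):
    traj, _ = xshape_run
    sub = traj.subset_frames(np.arange(200))
    flags = td.compute_metrics(sub, ir).dimer
    cmap = contact_map(sub, ir, flags)
    swapped = td.Trajectory(
        coords=sub.coords[:, chain_swap_map(sub.beads, ir.chains), :],
        beads=sub.beads, times=sub.times,
    )
    cmap2 = contact_map(swapped, ir, flags)
    assert np.allclose(cmap.values, cmap2.values.T, atol=1e-9)


def test_contact_map_requires_dimer_frames(ir, xshape_run):
    traj, _ = xshape_run
    with pytest.raises(ValueError, match="cutoff"):
        contact_map(traj.subset_frames(np.arange(10)), ir, [False] * 10)


# ---------------------------------------------------------------------------
# shape classification

def test_large_crossing_angle_is_x(ir):
    a = td.build_helix(ir, "A", 30.0, 0.0, (0.0, 0.0))
    b = td.build_helix(ir, "B", 30.0, 100.0, (1.0, 0.0))
    coords = np.concatenate([a, b])
    omega = td.crossing_angle(
        td.helix_axis(a[ir.range_mask("axis_range")]),
        td.helix_axis(b[ir.range_mask("axis_range")]),
    )
    assert omega > 15.0
    assert classify_shape(coords, ir, beads=td.make_bead_table(ir)) == "X"


def test_equal_end_separations_are_parallel(ir):
    a = td.build_helix(ir, "A", 5.0, 0.0, (0.0, 0.0))
    b = td.build_helix(ir, "B", 5.0, 0.0, (0.9, 0.0))
    coords = np.concatenate([a, b])
    assert classify_shape(coords, ir, beads=td.make_bead_table(ir)) == "parallel"


def test_vshape_preset_classified_v_in_most_replicas(igf):
    """Largest-cluster average structures of the V-shaped preset carry the
    V label in at least 90% of replicas."""
    labels = []
    for seed in range(10):
        traj, _ = td.generate(igf, td.get_preset("igf1r_vshape"),
                              n_frames=250, seed=seed)
        flags = td.compute_metrics(traj, igf).dimer
        idx = np.flatnonzero(flags)
        swap = chain_swap_map(traj.beads, igf.chains)
        res = daura_cluster(traj.coords[idx], cutoff=0.25, swap_map=swap)
        cid = int(np.argmax(res.sizes))
        members = np.flatnonzero(res.assignments == cid)
        centre = np.flatnonzero(res.frame_index == res.centers[cid])[0]
        avg = average_structure(traj.coords[idx][members],
                                traj.coords[idx][centre])
        labels.append(classify_shape(avg, igf, beads=traj.beads))
    assert labels.count("V") >= 9
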