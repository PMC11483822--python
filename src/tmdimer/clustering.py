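"""Superposition RMSD, Daura clustering, contact maps and packing shapes.

Dimerized frames are clustered with the greedy neighbour-count algorithm
of Daura et al.: pairwise minimal (Kabsch) RMSD is computed over the
backbone beads of both chains jointly, the frame with the most
neighbours within the cutoff (ties to the lower frame index) seeds a
cluster, it and its neighbours are removed, and the procedure repeats
until no frame remains.  For a homodimer the two chain labelings are
physically equivalent, so each pairwise RMSD is the smaller of the
direct and the chain-swapped bead mapping.

Packing shapes are labelled X (crossing angle above a threshold), V
(kink-splayed axes with one close end) or parallel, from the crossing
angle and the ratio of the N- and C-terminal end separations of the
membrane-core residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import helix_axis, crossing_angle

__all__ = [
    "DAURA_CUTOFF_NM",
    "kabsch_rmsd",
    "superpose_onto",
    "pairwise_rmsd_matrix",
    "ClusterResult",
    "daura_cluster",
    "average_structure",
    "ContactMap",
    "contact_map",
    "classify_shape",
]

#: Pairwise RMSD cutoff (nm) used for clustering dimer configurations.
DAURA_CUTOFF_NM = 0.9

#: Above this pairwise count, frames are strided down before clustering.
MAX_CLUSTER_FRAMES = 5000


def kabsch_rmsd(x, y) -> float:
    """Minimal RMSD (nm) of two matched bead sets over rigid motions.

    Optimal superposition by the standard SVD construction (via
    :class:`scipy.spatial.transform.Rotation`, which guards against
    reflections: the rotation determinant is +1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need two equally shaped sets of at least 3 beads")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    _, rssd = Rotation.align_vectors(xc, yc)
    return float(rssd / np.sqrt(x.shape[0]))


def superpose_onto(mobile, reference) -> np.ndarray:
    """Rigid-body fit of ``mobile`` onto ``reference`` (Kabsch); returns
    the transformed mobile coordinates."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    return rot.apply(mobile - mc) + rc


def _pairwise_rmsd(frames: np.ndarray, others: np.ndarray) -> np.ndarray:
    """All-vs-all minimal RMSD between two centred frame stacks."""
    n, m, _ = frames.shape
    traces = np.einsum("fni,fni->f", frames, frames)
    traces_o = np.einsum("fni,fni->f", others, others)
    cov = np.einsum("ink,jnl->ijkl", frames, others)  # (n, n, 3, 3)
    u, s, vt = np.linalg.svd(cov)
    det = np.linalg.det(u @ vt)
    s_signed = s.copy()
    s_signed[..., -1] *= np.sign(det)
    msd = (traces[:, None] + traces_o[None, :] - 2.0 * s_signed.sum(axis=-1)) / m
    return np.sqrt(np.clip(msd, 0.0, None))


def pairwise_rmsd_matrix(coords: np.ndarray, swap_map=None) -> np.ndarray:
    """Symmetric matrix of minimal pairwise RMSDs for a frame stack.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_beads, 3)
    swap_map : ndarray of int, optional
        Bead permutation realising the equivalent chain relabeling of a
        homodimer; when given, each entry is the smaller RMSD of the
        direct and permuted mappings.
    """
    coords = np.asarray(coords, dtype=float)
    centred = coords - coords.mean(axis=1, keepdims=True)
    mat = _pairwise_rmsd(centred, centred)
    if swap_map is not None:
        swapped = coords[:, swap_map, :]
        swapped = swapped - swapped.mean(axis=1, keepdims=True)
        mat = np.minimum(mat, _pairwise_rmsd(centred, swapped))
    return 0.5 * (mat + mat.T)  # enforce exact symmetry


def chain_swap_map(beads: pd.DataFrame, chains) -> np.ndarray:
    """Bead permutation exchanging the two chains of a homodimer."""
    ch = beads["chain"].to_numpy()
    a_idx = np.flatnonzero(ch == chains[0])
    b_idx = np.flatnonzero(ch == chains[1])
    if len(a_idx) != len(b_idx):
        raise ValueError("chain swap requires equally sized chains")
    perm = np.arange(len(beads))
    perm[a_idx] = b_idx
    perm[b_idx] = a_idx
    return perm


@dataclass
class ClusterResult:
    """Greedy RMSD clustering of dimerized frames.

    ``assignments`` maps each clustered frame to a cluster id; clusters
    are numbered 0, 1, ... in discovery order (decreasing neighbour
    count).  ``frame_index`` holds the original frame labels of the
    clustered frames.
    """

    assignments: np.ndarray
    centers: list
    sizes: list
    frame_index: np.ndarray
    cutoff: float
    average_structures: list | None = None
    shape_labels: list | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    @property
    def percentages(self) -> np.ndarray:
        sizes = np.asarray(self.sizes, dtype=float)
        return 100.0 * sizes / sizes.sum()

    def members(self, cluster_id: int) -> np.ndarray:
        return self.frame_index[self.assignments == cluster_id]

    def to_json_dict(self) -> dict:
        order = np.argsort(-np.asarray(self.sizes), kind="stable")
        clusters = []
        for rank, cid in enumerate(order):
            entry = {
                "rank": rank,
                "cluster_id": int(cid),
                "size": int(self.sizes[cid]),
                "percentage": round(float(self.percentages[cid]), 4),
                "center_frame": int(self.centers[cid]),
                "members": [int(f) for f in self.members(int(cid))],
            }
            if self.shape_labels is not None:
                entry["shape"] = self.shape_labels[cid]
            clusters.append(entry)
        return {
            "cutoff_nm": self.cutoff,
            "n_frames": int(len(self.assignments)),
            "n_clusters": self.n_clusters,
            "clusters": clusters,
        }


def daura_cluster(
    coords,
    cutoff: float = DAURA_CUTOFF_NM,
    swap_map=None,
    frame_index=None,
    rmsd_matrix=None,
) -> ClusterResult:
    """Greedy neighbour-count (Daura) clustering of a frame stack.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_beads, 3)
        Backbone beads of both chains for every frame to cluster.
    cutoff : float
        Pairwise RMSD neighbour cutoff in nm (default 0.9).
    swap_map : ndarray, optional
        Homodimer chain-swap permutation (see
        :func:`pairwise_rmsd_matrix`).
    frame_index : array-like, optional
        Original frame labels; defaults to 0..n-1.
    rmsd_matrix : ndarray, optional
        Precomputed pairwise matrix (cached by the pipeline).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[0] == 0:
        raise ValueError("need a non-empty (n_frames, n_beads, 3) stack")
    n = coords.shape[0]
    if n > MAX_CLUSTER_FRAMES:
        raise ValueError(
            f"{n} frames exceed the practical O(n^2) cap "
            f"({MAX_CLUSTER_FRAMES}); stride the frames first"
        )
    if frame_index is None:
        frame_index = np.arange(n)
    frame_index = np.asarray(frame_index)
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd_matrix(coords, swap_map=swap_map)
    neighbours = rmsd_matrix <= cutoff
    np.fill_diagonal(neighbours, True)

    assignments = np.full(n, -1, dtype=int)
    centers, sizes = [], []
    remaining = np.ones(n, dtype=bool)
    cid = 0
    while remaining.any():
        counts = (neighbours & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # ties -> lower frame index
        members = np.flatnonzero(neighbours[center] & remaining)
        assignments[members] = cid
        centers.append(int(frame_index[center]))
        sizes.append(int(len(members)))
        remaining[members] = False
        cid += 1
    return ClusterResult(
        assignments=assignments,
        centers=centers,
        sizes=sizes,
        frame_index=frame_index,
        cutoff=cutoff,
    )


def average_structure(frames, center) -> np.ndarray:
    """Per-bead mean coordinates after superposing every frame onto the
    cluster centre (medoid) frame."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("need a non-empty frame stack")
    center = np.asarray(center, dtype=float)
    fitted = np.stack([superpose_onto(f, center) for f in frames])
    return fitted.mean(axis=0)


@dataclass
class ContactMap:
    """Mean inter-residue centre-of-mass distances over dimerized frames."""

    res_a: np.ndarray
    res_b: np.ndarray
    values: np.ndarray  # (len(res_a), len(res_b)), nm
    n_frames: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[str(r) for r in self.res_b])
        df.insert(0, "res_id", self.res_a)
        return df


def contact_map(traj, system, dimer_flags) -> ContactMap:
    """Residue-pair mean distance matrix over dimerized frames.

    With one backbone bead per residue the residue centre of mass is the
    bead position; the matrix spans the full residue numbering of both
    chains and averages only over frames flagged as dimerized.
    """
    flags = np.asarray(dimer_flags, dtype=bool)
    if flags.shape != (traj.n_frames,):
        raise ValueError("dimer_flags must have one entry per frame")
    if not flags.any():
        raise ValueError(
            "no dimerized frames; check the d_HH cutoff before computing "
            "a contact map"
        )
    ch_a, ch_b = system.chains
    mask_a = traj.selection_mask(ch_a)
    mask_b = traj.selection_mask(ch_b)
    res_a = traj.beads.loc[mask_a, "res_id"].to_numpy()
    res_b = traj.beads.loc[mask_b, "res_id"].to_numpy()
    idx = np.flatnonzero(flags)
    total = np.zeros((mask_a.sum(), mask_b.sum()))
    for chunk in np.array_split(idx, max(1, len(idx) // 500)):
        a = traj.coords[chunk][:, mask_a, :]
        b = traj.coords[chunk][:, mask_b, :]
        total += np.linalg.norm(a[:, :, None, :] - b[:, None, :, :], axis=-1).sum(
            axis=0
        )
    return ContactMap(
        res_a=res_a, res_b=res_b, values=total / len(idx), n_frames=int(len(idx))
    )


def classify_shape(
    coords,
    system,
    beads=None,
    omega_threshold: float = 15.0,
    end_ratio_threshold: float = 1.3,
    traj=None,
) -> str:
    """Label a two-helix configuration as ``"X"``, ``"V"`` or ``"parallel"``.

    X when the crossing angle exceeds ``omega_threshold`` (default 15
    degrees, the published boundary of X-shaped packing); otherwise the
    separations of the N- and C-terminal membrane-core residues decide:
    parallel if max(s_N, s_C)/min(s_N, s_C) stays at or below
    ``end_ratio_threshold``, V otherwise.

    ``coords`` is a single frame ``(n_beads, 3)`` whose bead ordering is
    described by ``beads`` (or by ``traj.beads``).
    """
    coords = np.asarray(coords, dtype=float)
    if beads is None:
        if traj is None:
            raise ValueError("provide the bead table (beads= or traj=)")
        beads = traj.beads
    ch = beads["chain"].to_numpy()
    res = beads["res_id"].to_numpy()
    ch_a, ch_b = system.chains

    def select(chain, lo, hi):
        m = (ch == chain) & (res >= lo) & (res <= hi)
        if not m.any():
            raise ValueError(f"empty selection for chain {chain}")
        return coords[m]

    axis_a = helix_axis(select(ch_a, *system.axis_range))
    axis_b = helix_axis(select(ch_b, *system.axis_range))
    omega = crossing_angle(axis_a, axis_b)
    if omega > omega_threshold:
        return "X"
    core_lo, core_hi = system.core_range
    s_n = float(
        np.linalg.norm(
            select(ch_a, core_lo, core_lo)[0] - select(ch_b, core_lo, core_lo)[0]
        )
    )
    s_c = float(
        np.linalg.norm(
            select(ch_a, core_hi, core_hi)[0] - select(ch_b, core_hi, core_hi)[0]
        )
    )
    lo, hi = sorted([s_n, s_c])
    if lo < 1e-12:
        raise ValueError("degenerate geometry: coincident core ends")
    return "parallel" if hi / lo <= end_ratio_threshold else "V"
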