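"""Per-frame geometric observables for a two-helix membrane system.

The observables follow the conventions used throughout the membrane
protein simulation literature:

* **helix axis** -- principal direction (largest-variance eigenvector)
  of the centred backbone beads of the axis residue range, sign-fixed to
  point from the N- to the C-terminus;
* **tilt angle** theta = arccos(|axis . z|), folded to [0, 90] degrees,
  measured against the membrane normal (z);
* **crossing angle** Omega = arccos(|axis_A . axis_B|), the unsigned
  angle between the two helix axes, folded to [0, 90] degrees;
* **interhelical distance** d_HH -- Euclidean distance between the
  unweighted centroids of the two chains' d_HH residue selections, with
  the minimum-image convention applied laterally (x, y) when a box is
  present (helices never wrap through the membrane in z);
* **dimerized state** -- frames with d_HH at or below a cutoff, 1.3 nm
  by default;
* **RMSF** -- per-residue root-mean-square fluctuation of the backbone
  beads, optionally after iterated rigid-body superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DIMER_CUTOFF_NM",
    "helix_axis",
    "helix_axes",
    "tilt_angle",
    "crossing_angle",
    "interhelical_distance",
    "detect_dimer",
    "rmsf",
    "MetricSeries",
    "compute_metrics",
]

#: Interhelical-distance threshold (nm) defining the dimerized state.
DIMER_CUTOFF_NM = 1.3


def _as_unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"{name} must be a non-zero vector")
    return v / n


def helix_axes(coords: np.ndarray) -> np.ndarray:
    """Principal axes for a batch of bead sets.

    Parameters
    ----------
    coords : ndarray, shape (..., n_beads, 3)
        Backbone beads of the axis residue range, ordered N- to
        C-terminus.

    Returns
    -------
    ndarray, shape (..., 3)
        Unit axes pointing N -> C.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-2] < 3:
        raise ValueError("need at least 3 beads to fit a helix axis")
    centred = coords - coords.mean(axis=-2, keepdims=True)
    cov = np.einsum("...ni,...nj->...ij", centred, centred)
    scale = np.einsum("...ii->...", cov)
    if np.any(scale < 1e-20):
        raise ValueError("degenerate geometry: beads are coincident")
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[..., :, -1]  # largest-eigenvalue eigenvector
    nc = coords[..., -1, :] - coords[..., 0, :]  # N -> C end vector
    sign = np.sign(np.einsum("...i,...i->...", axis, nc))
    sign = np.where(sign == 0, 1.0, sign)
    return axis * sign[..., None]


def helix_axis(coords: np.ndarray) -> np.ndarray:
    """Unit helix axis (N -> C) of one bead set; see :func:`helix_axes`."""
    return helix_axes(np.asarray(coords, dtype=float))


def tilt_angle(axis, normal=(0.0, 0.0, 1.0)) -> float:
    """Tilt of a helix axis against the membrane normal, in [0, 90] deg.

    Invariant under the sign flip of either vector.
    """
    a = _as_unit(axis, "axis")
    n = _as_unit(normal, "normal")
    return float(np.degrees(np.arccos(np.clip(abs(a @ n), -1.0, 1.0))))


def crossing_angle(axis_a, axis_b) -> float:
    """Unsigned crossing angle between two helix axes, in [0, 90] deg."""
    a = _as_unit(axis_a, "axis_a")
    b = _as_unit(axis_b, "axis_b")
    return float(np.degrees(np.arccos(np.clip(abs(a @ b), -1.0, 1.0))))


def _folded_angles(dots: np.ndarray) -> np.ndarray:
    return np.degrees(np.arccos(np.clip(np.abs(dots), -1.0, 1.0)))


def interhelical_distance(coords_a, coords_b, box=None) -> float:
    """Distance between the unweighted centroids of two bead selections.

    All backbone beads carry equal mass.  With ``box`` (rectangular edge
    lengths, nm) the minimum-image convention is applied in x and y.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty selection")
    delta = b.mean(axis=0) - a.mean(axis=0)
    if box is not None:
        box = np.asarray(box, dtype=float)
        delta[:2] -= box[:2] * np.round(delta[:2] / box[:2])
    return float(np.linalg.norm(delta))


def detect_dimer(d_hh, cutoff: float = DIMER_CUTOFF_NM):
    """Flag dimerized frames and locate the first one.

    Returns ``(flags, first_dimer_frame)`` where the flag for frame i is
    ``d_hh[i] <= cutoff`` (no hysteresis) and ``first_dimer_frame`` is the
    smallest flagged index, or None if the helices never dimerize.
    """
    d = np.asarray(d_hh, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    flags = d <= cutoff
    first = int(np.argmax(flags)) if flags.any() else None
    return flags, first


def rmsf(traj, chain: str, superpose: bool = True) -> pd.DataFrame:
    """Per-residue RMSF of one chain's backbone beads.

    With ``superpose`` each frame is rigid-body fitted (Kabsch) onto the
    mean structure, and the fit is iterated twice (fit -> new mean ->
    fit) so the reference is self-consistent.

    Returns a DataFrame with columns ``res_id`` and ``rmsf`` (nm).
    """
    from .clustering import superpose_onto  # local import, avoids cycle

    mask = traj.selection_mask(chain)
    coords = traj.coords[:, mask, :]
    if coords.shape[0] < 2:
        raise ValueError("RMSF requires at least two frames")
    if superpose:
        fitted = coords
        for _ in range(2):
            mean = fitted.mean(axis=0)
            fitted = np.stack([superpose_onto(f, mean) for f in fitted])
        coords = fitted
    mean = coords.mean(axis=0)
    values = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=-1), axis=0))
    res_ids = traj.beads.loc[mask, "res_id"].to_numpy()
    return pd.DataFrame({"res_id": res_ids, "rmsf": values})


@dataclass
class MetricSeries:
    """Per-frame conformational metrics of a two-helix trajectory."""

    frame: np.ndarray
    time: np.ndarray
    d_hh: np.ndarray
    tilt_a: np.ndarray
    tilt_b: np.ndarray
    omega: np.ndarray
    dimer: np.ndarray
    cutoff: float = DIMER_CUTOFF_NM
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("tilt_a", "tilt_b", "omega"):
            vals = getattr(self, name)
            if np.any((vals < -1e-9) | (vals > 90.0 + 1e-9)):
                raise ValueError(f"{name} outside [0, 90] degrees")
        if np.any(self.d_hh <= 0):
            raise ValueError("d_hh must be positive")
        if not np.array_equal(self.dimer, self.d_hh <= self.cutoff):
            raise ValueError("dimer flags inconsistent with cutoff")

    @property
    def first_dimer_frame(self):
        return int(np.argmax(self.dimer)) if self.dimer.any() else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame,
                "time": self.time,
                "d_hh": self.d_hh,
                "tilt_a": self.tilt_a,
                "tilt_b": self.tilt_b,
                "omega": self.omega,
                "dimer": self.dimer.astype(int),
            }
        )


def compute_metrics(traj, system, cutoff: float = DIMER_CUTOFF_NM) -> MetricSeries:
    """Compute d_HH, per-helix tilt, crossing angle and dimer flags.

    Axes are fitted over ``system.axis_range``; d_HH uses
    ``system.dhh_range`` (the two ranges differ for IR, following the
    published convention, and are kept distinct deliberately).
    """
    ch_a, ch_b = system.chains
    ax_a = traj.selection_mask(ch_a, system.axis_range)
    ax_b = traj.selection_mask(ch_b, system.axis_range)
    dh_a = traj.selection_mask(ch_a, system.dhh_range)
    dh_b = traj.selection_mask(ch_b, system.dhh_range)

    axes_a = helix_axes(traj.coords[:, ax_a, :])
    axes_b = helix_axes(traj.coords[:, ax_b, :])
    z = np.array([0.0, 0.0, 1.0])
    tilt_a = _folded_angles(axes_a @ z)
    tilt_b = _folded_angles(axes_b @ z)
    omega = _folded_angles(np.einsum("fi,fi->f", axes_a, axes_b))

    delta = traj.coords[:, dh_b, :].mean(axis=1) - traj.coords[:, dh_a, :].mean(axis=1)
    if traj.box is not None:
        lat = traj.box[:, :2]
        delta[:, :2] -= lat * np.round(delta[:, :2] / lat)
    d_hh = np.linalg.norm(delta, axis=1)

    flags = d_hh <= cutoff
    return MetricSeries(
        frame=np.arange(traj.n_frames),
        time=np.asarray(traj.times, dtype=float),
        d_hh=d_hh,
        tilt_a=tilt_a,
        tilt_b=tilt_b,
        omega=omega,
        dimer=flags,
        cutoff=cutoff,
        metadata={
            "axis_range": list(system.axis_range),
            "dhh_range": list(system.dhh_range),
            "receptor": system.receptor_name,
        },
    )
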