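"""Shrake-Rupley solvent-accessible surface area and buried surface area.

Each bead is modelled as a sphere; a deterministic quasi-uniform point
set (Fibonacci sphere) is placed on every bead's solvent-expanded sphere
of radius ``r_i + probe`` and a point counts as exposed when it lies
outside every other bead's expanded sphere:

    area_i = 4 pi (r_i + probe)^2 * n_exposed / n_points

The interfacial buried surface area between two bead sets A and B is the
accessible area lost on complex formation,

    BSA = sasa(A) + sasa(B) - sasa(A u B),

without a factor 1/2 (the full lost area is reported; this convention is
deliberate and documented).  The deterministic point set makes repeated
evaluations bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SphereModel", "fibonacci_sphere", "sasa", "buried_surface_area"]


@dataclass(frozen=True)
class SphereModel:
    """Sphere parameters for SASA evaluation.

    Parameters
    ----------
    radius : float or ndarray
        Bead radius in nm (scalar, or one value per bead).  Default
        0.264 nm, a typical coarse-grained bead.
    probe : float
        Solvent probe radius in nm; default 0.185 nm.
    n_points : int
        Sphere points per bead; at least 92.  Default 960.
    """

    radius: float | np.ndarray = 0.264
    probe: float = 0.185
    n_points: int = 960

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.radius) <= 0):
            raise ValueError("bead radii must be positive")
        if self.probe < 0:
            raise ValueError("probe radius must be non-negative")
        if self.n_points < 92:
            raise ValueError("n_points must be at least 92")

    def radii(self, n_beads: int) -> np.ndarray:
        r = np.asarray(self.radius, dtype=float)
        if r.ndim == 0:
            return np.full(n_beads, float(r))
        if r.shape != (n_beads,):
            raise ValueError("per-bead radii must match the bead count")
        return r


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on the sphere (golden spiral)."""
    k = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k  # golden angle increments
    z = 1.0 - (2.0 * k + 1.0) / n_points
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(coords, model: SphereModel = SphereModel()) -> float:
    """Solvent-accessible surface area (nm^2) of a bead set."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] == 0:
        raise ValueError("need at least one bead")
    if np.asarray(model.radius).ndim == 0:
        # coincident beads describe one sphere; merging them keeps the
        # union area well defined (surface points of exact duplicates lie
        # exactly on each other's sphere)
        coords = np.unique(np.round(coords, 9), axis=0)
    n = coords.shape[0]
    radii = model.radii(n) + model.probe
    unit = fibonacci_sphere(model.n_points)
    total = 0.0
    # pairwise distances for neighbour pre-filtering
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    for i in range(n):
        neighbours = np.flatnonzero(
            (dist[i] < radii[i] + radii) & (np.arange(n) != i)
        )
        points = coords[i] + radii[i] * unit
        if neighbours.size:
            d2 = np.sum(
                (points[:, None, :] - coords[neighbours][None, :, :]) ** 2, axis=-1
            )
            exposed = np.all(d2 > radii[neighbours] ** 2, axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        total += 4.0 * np.pi * radii[i] ** 2 * frac
    return float(total)


def buried_surface_area(coords_a, coords_b, model: SphereModel = SphereModel()) -> float:
    """Interfacial buried surface area (nm^2) between two bead sets.

    ``sasa(A) + sasa(B) - sasa(A u B)``; non-negative up to point-sampling
    noise.
    """
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both bead sets must be non-empty")
    r = np.asarray(model.radius, dtype=float)
    if r.ndim != 0:
        raise ValueError(
            "per-bead radii are ambiguous for a complex; use a scalar radius"
        )
    both = np.vstack([a, b])
    return sasa(a, model) + sasa(b, model) - sasa(both, model)
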