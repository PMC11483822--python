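"""Boltzmann-inversion free-energy profiles along tilt or crossing angles.

The potential of mean force along an angle x is estimated from the
observed histogram by

    U(x) = -kB T ln P(x),

where P is the normalised bin probability, T the simulation temperature
and kB Boltzmann's constant (0.0019872041 kcal/mol/K).  Profiles use
fixed absolute bin edges [0, w, 2w, ..., 90] degrees so replicas always
align; each profile is shifted so its lowest finite value is zero, and
empty bins are marked +inf.  No Jacobian (sin theta) correction is
applied -- this is plain inversion of the observed histogram, and the
resulting profile is an apparent free energy along the chosen
coordinate.

Replica averaging averages *free energies* (not probabilities) bin-wise
over replicas, on bins finite in every replica; the averaged profile is
re-shifted to a zero minimum and carries the per-bin standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BOLTZMANN_KCAL",
    "PMFProfile",
    "histogram_pmf",
    "average_profiles",
    "find_minimum",
]

#: Boltzmann constant in kcal mol^-1 K^-1.
BOLTZMANN_KCAL = 0.0019872041

#: Upper edge of the angular domain in degrees.
MAX_ANGLE = 90.0


@dataclass
class PMFProfile:
    """Binned probability and free energy along one angle.

    ``free_energy`` is +inf exactly on empty bins and has minimum 0 over
    finite bins.  ``replica`` is an integer replica id or ``"mean"`` for
    averaged profiles, which also carry a per-bin ``sd``.
    """

    variable: str
    bin_edges: np.ndarray
    probability: np.ndarray
    free_energy: np.ndarray
    temperature: float = 300.0
    replica: int | str = 0
    sd: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variable not in ("theta", "omega"):
            raise ValueError("variable must be 'theta' or 'omega'")
        finite = np.isfinite(self.free_energy)
        if finite.any() and abs(self.free_energy[finite].min()) > 1e-9:
            raise ValueError("free energy must be shifted to a zero minimum")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "probability": self.probability,
                "free_energy": self.free_energy,
                **({"sd": self.sd} if self.sd is not None else {}),
            }
        )


def _edges(bin_width: float) -> np.ndarray:
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(MAX_ANGLE / bin_width))
    return np.arange(n_bins + 1, dtype=float) * bin_width


def histogram_pmf(
    samples,
    variable: str = "theta",
    bin_width: float = 2.0,
    temperature: float = 300.0,
    replica: int | str = 0,
) -> PMFProfile:
    """Free-energy profile from angle samples by Boltzmann inversion.

    Parameters
    ----------
    samples : array-like
        Angle samples in degrees, each in [0, 90].
    bin_width : float
        Width of the fixed absolute bins in degrees (default 2).
    temperature : float
        Temperature in kelvin entering kB*T (default 300).
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("need at least one sample")
    if np.any((samples < 0) | (samples > MAX_ANGLE)):
        raise ValueError("samples must lie in [0, 90] degrees")
    edges = _edges(bin_width)
    counts, _ = np.histogram(samples, bins=edges)
    prob = counts / counts.sum()
    with np.errstate(divide="ignore"):
        energy = np.where(
            prob > 0, -BOLTZMANN_KCAL * temperature * np.log(prob), np.inf
        )
    energy = energy - energy[np.isfinite(energy)].min()
    return PMFProfile(
        variable=variable,
        bin_edges=edges,
        probability=prob,
        free_energy=energy,
        temperature=temperature,
        replica=replica,
    )


def average_profiles(profiles) -> PMFProfile:
    """Bin-wise mean (and sd) of free energies over replica profiles.

    All profiles must share the variable, bin edges and temperature.
    Bins empty in any replica are +inf in the mean; finite bins are
    averaged and the result re-shifted to a zero minimum.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to average")
    ref = profiles[0]
    for p in profiles[1:]:
        if p.variable != ref.variable:
            raise ValueError("profiles measure different variables")
        if not np.array_equal(p.bin_edges, ref.bin_edges):
            raise ValueError("profiles have mismatched bins")
        if p.temperature != ref.temperature:
            raise ValueError("profiles have mismatched temperatures")
    energies = np.stack([p.free_energy for p in profiles])
    finite = np.isfinite(energies).all(axis=0)
    if not finite.any():
        raise ValueError("no bin is finite in every replica")
    mean = np.full(ref.free_energy.shape, np.inf)
    sd = np.full(ref.free_energy.shape, np.nan)
    mean[finite] = energies[:, finite].mean(axis=0)
    sd[finite] = energies[:, finite].std(axis=0, ddof=0)
    mean[finite] -= mean[finite].min()
    prob = np.stack([p.probability for p in profiles]).mean(axis=0)
    return PMFProfile(
        variable=ref.variable,
        bin_edges=ref.bin_edges.copy(),
        probability=prob,
        free_energy=mean,
        temperature=ref.temperature,
        replica="mean",
        sd=sd,
    )


def find_minimum(profile: PMFProfile):
    """Bin centre and value of the global finite free-energy minimum.

    Ties break toward the smaller bin centre.
    """
    finite = np.isfinite(profile.free_energy)
    if not finite.any():
        raise ValueError("profile has no finite bins")
    energy = np.where(finite, profile.free_energy, np.inf)
    idx = int(np.argmin(energy))  # argmin returns the first, smallest centre
    return float(profile.bin_centers[idx]), float(profile.free_energy[idx])
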