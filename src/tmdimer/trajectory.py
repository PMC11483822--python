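"""In-memory trajectory container for coarse-grained bead coordinates.

Coordinates are stored in nanometres throughout the package; angstroms
appear only at the PDB file boundary.  A :class:`Trajectory` couples an
``(n_frames, n_beads, 3)`` coordinate array with a per-bead metadata
table (chain label, residue index/name, bead name), per-frame rectangular
box lengths and strictly increasing time stamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "make_bead_table"]

#: Default save interval (ns) assumed when a file format carries no times.
DEFAULT_DT = 0.05


def make_bead_table(system, bead_name: str = "BB") -> pd.DataFrame:
    """Backbone-bead metadata table for the two chains of a system.

    One bead per residue, chain A first then chain B, each chain ordered
    N- to C-terminus.
    """
    rows = []
    for chain in system.chains:
        for res_id in system.residues:
            rows.append(
                {
                    "chain": chain,
                    "res_id": int(res_id),
                    "res_name": system.residue_name(int(res_id)),
                    "bead": bead_name,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class Trajectory:
    """Ordered frames of bead coordinates with metadata.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_beads, 3)
        Bead positions in nm.
    beads : pandas.DataFrame
        One row per bead with columns ``chain``, ``res_id``, ``res_name``,
        ``bead``; identical ordering in every frame.
    box : ndarray, shape (n_frames, 3), optional
        Rectangular box edge lengths in nm.
    times : ndarray, shape (n_frames,), optional
        Strictly increasing frame times in ns; defaults to multiples of
        0.05 ns (the conventional 50 ps save interval).
    """

    coords: np.ndarray
    beads: pd.DataFrame
    box: np.ndarray | None = None
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_beads, 3)")
        if self.coords.shape[0] == 0:
            raise ValueError("trajectory must contain at least one frame")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if len(self.beads) != self.coords.shape[1]:
            raise ValueError(
                f"bead table has {len(self.beads)} rows but frames have "
                f"{self.coords.shape[1]} beads"
            )
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float) * DEFAULT_DT
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_frames,):
                raise ValueError("times must have one entry per frame")
            if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
                raise ValueError("times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape == (3,):
                self.box = np.tile(self.box, (self.n_frames, 1))
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def chain_mask(self, chain: str) -> np.ndarray:
        return (self.beads["chain"] == chain).to_numpy()

    def selection_mask(self, chain: str, res_range=None) -> np.ndarray:
        """Boolean bead mask for one chain, optionally a residue interval."""
        mask = self.chain_mask(chain)
        if res_range is not None:
            res = self.beads["res_id"].to_numpy()
            mask = mask & (res >= res_range[0]) & (res <= res_range[1])
        if not mask.any():
            raise ValueError(
                f"empty selection: chain {chain!r}, residues {res_range}"
            )
        return mask

    def subset_frames(self, index) -> "Trajectory":
        index = np.asarray(index)
        return Trajectory(
            coords=self.coords[index],
            beads=self.beads,
            box=None if self.box is None else self.box[index],
            times=np.asarray(self.times)[index],
        )
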