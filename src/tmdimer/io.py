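"""Trajectory and table I/O.

Two plain-text trajectory formats are supported, both read and written
through :mod:`biotite`:

* ``gro`` -- concatenated GROMACS GRO frames (coordinates already in nm;
  frame times are carried in the ``t=`` field of each title line, the
  GROMACS convention),
* ``pdb`` -- multi-``MODEL`` PDB (angstrom coordinates, divided by 10 on
  read; chain identifiers preserved).

GRO has no chain field, so chains are recovered from discontinuities in
the residue numbering (a drop in residue index starts a new chain), per
the two-chain layout this package writes.

Analysis outputs are persisted as CSV (flat per-frame/per-bin records)
or JSON (nested results such as cluster listings).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.gro import GROFile
from biotite.structure.io.pdb import PDBFile

from .trajectory import Trajectory, DEFAULT_DT

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "write_table",
    "TrajectoryParseError",
    "TrajectoryStructureError",
]


class TrajectoryParseError(ValueError):
    """A record in a trajectory file could not be parsed."""


class TrajectoryStructureError(ValueError):
    """Frames of a trajectory file are structurally inconsistent."""


_FORMATS = ("gro", "pdb")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = {"gro_multi": "gro", "pdb_models": "pdb"}.get(fmt, fmt)
        if fmt not in _FORMATS:
            raise ValueError(f"unknown trajectory format {fmt!r}; use one of {_FORMATS}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def _scan_gro(lines: list[str], path: Path) -> tuple[int, list[float | None]]:
    """Validate the block structure of a concatenated GRO file.

    Returns the common bead count and the per-frame times parsed from the
    ``t=`` title fields (None where absent).  Raises with a 1-based line
    number on malformed or inconsistent records.
    """
    times: list[float | None] = []
    n_beads = None
    i = 0
    n_lines = len(lines)
    while i < n_lines and lines[i].strip() == "" and i == n_lines - 1:
        break
    while i < n_lines:
        if lines[i].strip() == "" and all(s.strip() == "" for s in lines[i:]):
            break  # trailing blank lines
        title = lines[i]
        t = None
        if "t=" in title:
            try:
                t = float(title.rsplit("t=", 1)[1].split()[0])
            except (ValueError, IndexError):
                t = None
        times.append(t)
        if i + 1 >= n_lines:
            raise TrajectoryParseError(
                f"{path}: line {i + 2}: expected bead count after title"
            )
        try:
            count = int(lines[i + 1].strip())
        except ValueError:
            raise TrajectoryParseError(
                f"{path}: line {i + 2}: malformed bead-count record "
                f"{lines[i + 1].strip()!r}"
            ) from None
        if n_beads is None:
            n_beads = count
        elif count != n_beads:
            raise TrajectoryStructureError(
                f"{path}: line {i + 2}: frame {len(times)} declares {count} "
                f"beads, expected {n_beads}"
            )
        block_end = i + 2 + count  # atom lines, then one box line
        if block_end >= n_lines:
            raise TrajectoryStructureError(
                f"{path}: line {n_lines}: truncated frame {len(times)} "
                f"(expected {count} atom records and a box line)"
            )
        for j in range(i + 2, block_end):
            line = lines[j]
            if len(line.rstrip("\n")) < 44:
                raise TrajectoryParseError(
                    f"{path}: line {j + 1}: atom record too short"
                )
            for col in (line[20:28], line[28:36], line[36:44]):
                try:
                    float(col)
                except ValueError:
                    raise TrajectoryParseError(
                        f"{path}: line {j + 1}: malformed coordinate field "
                        f"{col.strip()!r}"
                    ) from None
        i = block_end + 1
    if n_beads is None:
        raise TrajectoryParseError(f"{path}: no frames found")
    return n_beads, times


def _chains_from_res_ids(res_ids: np.ndarray) -> np.ndarray:
    """Assign chain labels from residue-index discontinuities."""
    labels = np.empty(len(res_ids), dtype=object)
    chain_idx = 0
    labels[0] = "A"
    for i in range(1, len(res_ids)):
        if res_ids[i] < res_ids[i - 1]:
            chain_idx += 1
        labels[i] = chr(ord("A") + chain_idx)
    return labels


def _stack_to_trajectory(stack, *, angstrom: bool, times=None) -> Trajectory:
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    if angstrom:
        coords = coords / 10.0
    chain_ids = np.asarray(stack.chain_id)
    res_ids = np.asarray(stack.res_id, dtype=int)
    if np.all(chain_ids == "") or len(set(chain_ids)) == 1 and chain_ids[0] == "":
        chain_ids = _chains_from_res_ids(res_ids)
    beads = pd.DataFrame(
        {
            "chain": chain_ids.astype(object),
            "res_id": res_ids,
            "res_name": np.asarray(stack.res_name, dtype=object),
            "bead": np.asarray(stack.atom_name, dtype=object),
        }
    )
    box = None
    if stack.box is not None:
        box = np.einsum("fii->fi", np.asarray(stack.box, dtype=float))
        if angstrom:
            box = box / 10.0
    return Trajectory(coords=coords, beads=beads, box=box, times=times)


def read_trajectory(path, format: str | None = None) -> Trajectory:
    """Read a trajectory from a concatenated-GRO or multi-model PDB file.

    Parameters
    ----------
    path : path-like
        Input file.
    format : {"gro", "pdb"}, optional
        Inferred from the file suffix when omitted.  The aliases
        ``gro_multi`` and ``pdb_models`` are accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "gro":
        # normalise line endings / trailing whitespace before fixed-width
        # parsing so CRLF files and padded lines read identically
        lines = [ln.rstrip() for ln in path.read_text().splitlines()]
        _, raw_times = _scan_gro(lines, path)
        try:
            import io as _io

            stack = GROFile.read(_io.StringIO("\n".join(lines) + "\n")).get_structure()
        except Exception as exc:  # biotite failure after our structural scan
            raise TrajectoryParseError(f"{path}: {exc}") from exc
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        if any(t is None for t in raw_times):
            times = None
        else:
            times = np.asarray(raw_times, dtype=float)
            if len(times) > 1 and not np.all(np.diff(times) > 0):
                times = None
        # biotite returns GRO coordinates in angstrom (x10 internally)
        return _stack_to_trajectory(stack, angstrom=True, times=times)
    else:
        try:
            stack = PDBFile.read(str(path)).get_structure()
        except Exception as exc:
            msg = str(exc)
            low = msg.lower()
            if ("atoms" in low and "model" in low) or "inconsisten" in low:
                raise TrajectoryStructureError(f"{path}: {msg}") from exc
            raise TrajectoryParseError(f"{path}: {msg}") from exc
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        return _stack_to_trajectory(stack, angstrom=True, times=None)


def _trajectory_to_stack(traj: Trajectory) -> struc.AtomArrayStack:
    n = traj.n_beads
    arr = struc.AtomArray(n)
    arr.coord = np.zeros((n, 3))
    arr.chain_id = traj.beads["chain"].to_numpy().astype("U4")
    arr.res_id = traj.beads["res_id"].to_numpy()
    arr.res_name = traj.beads["res_name"].to_numpy().astype("U5")
    arr.atom_name = traj.beads["bead"].to_numpy().astype("U6")
    arr.element = np.full(n, "C", dtype="U2")
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = traj.coords * 10.0  # nm -> angstrom for biotite
    if traj.box is not None:
        box = np.zeros((traj.n_frames, 3, 3))
        for k in range(3):
            box[:, k, k] = traj.box[:, k] * 10.0
        stack.box = box
    return stack


def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as concatenated GRO frames or a multi-model PDB.

    Round-trips through :func:`read_trajectory` within the fixed-point
    precision of the format (1e-3 nm for GRO, 1e-4 nm for PDB).
    """
    if not isinstance(traj, Trajectory):
        raise TypeError("traj must be a Trajectory")
    path = Path(path)
    fmt = _infer_format(path, format)
    stack = _trajectory_to_stack(traj)
    if fmt == "gro":
        f = GROFile()
        f.set_structure(stack)
        # stamp GROMACS-style times into the title lines
        lines = f.lines
        n = traj.n_beads
        block = n + 3  # title, count, atoms, box
        for frame in range(traj.n_frames):
            idx = frame * block
            lines[idx] = f"tmdimer frame {frame} t= {traj.times[frame]:.5f}"
        f.write(str(path))
    else:
        f = PDBFile()
        f.set_structure(stack)
        f.write(str(path))


def write_table(records, path) -> None:
    """Persist analysis records as CSV (flat) or JSON (nested).

    ``records`` may be a pandas DataFrame, a list of flat dicts, or any
    object exposing ``to_frame()`` (written as CSV) or ``to_json_dict()``
    (written as JSON).  The target format follows the file suffix.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if hasattr(records, "to_json_dict") and suffix == ".json":
        payload = records.to_json_dict()
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return
    if hasattr(records, "to_frame"):
        frame = records.to_frame()
    elif isinstance(records, pd.DataFrame):
        frame = records
    elif isinstance(records, (list, tuple)):
        if len(records) == 0:
            raise ValueError("cannot write an empty record list")
        frame = pd.DataFrame(list(records))
    elif isinstance(records, dict) and suffix == ".json":
        path.write_text(json.dumps(records, indent=2, sort_keys=True) + "\n")
        return
    else:
        raise TypeError(f"cannot serialise records of type {type(records).__name__}")
    if suffix == ".json":
        path.write_text(
            json.dumps(frame.to_dict(orient="records"), indent=2, sort_keys=True)
            + "\n"
        )
    else:
        frame.to_csv(path, index=False)
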