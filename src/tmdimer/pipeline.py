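"""End-to-end orchestration: generate/load -> metrics -> PMF -> clustering.

A single :class:`RunConfig` (YAML on disk) carries every tunable used by
any stage, with its default; :func:`run` executes the full workflow and
writes, under the output directory:

* ``metrics_rep<k>.csv``   -- per-frame d_HH, tilts, crossing, dimer flag
* ``pmf_theta_rep<k>.csv`` / ``pmf_omega_rep<k>.csv`` and the
  replica-averaged ``pmf_theta_mean.csv`` / ``pmf_omega_mean.csv``
* ``clusters.json``        -- Daura clusters with sizes and shape labels
* ``cluster<r>_average.pdb`` -- averaged structures of the largest clusters
* ``contact_map.csv``      -- residue-pair mean distances (dimer frames)
* ``bsa_rep<k>.csv``       -- buried surface area on strided frames
* ``summary.json``         -- machine-readable digest of the run

Identical configuration and seeds give a byte-identical summary.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .systems import TMDSystem, get_system
from .trajectory import Trajectory
from .io import read_trajectory, write_trajectory, write_table
from .geometry import compute_metrics, DIMER_CUTOFF_NM
from .free_energy import histogram_pmf, average_profiles, find_minimum
from .clustering import (
    daura_cluster,
    pairwise_rmsd_matrix,
    chain_swap_map,
    average_structure,
    contact_map,
    classify_shape,
    DAURA_CUTOFF_NM,
)
from .sasa import SphereModel, buried_surface_area
from .synthetic import generate, get_preset, GeneratorPreset

__all__ = ["RunConfig", "run", "load_config", "save_config"]

log = logging.getLogger("tmdimer")


@dataclass
class RunConfig:
    """Complete, serialisable description of one analysis run."""

    system: str | dict = "IR"
    preset: str | None = "O1"
    preset_overrides: dict = field(default_factory=dict)
    trajectories: list = field(default_factory=list)  # input files, if not generating
    seeds: list = field(default_factory=lambda: [1, 2, 3])
    n_frames: int = 4000
    dt: float = 0.05
    dimer_cutoff: float = DIMER_CUTOFF_NM
    bin_width: float = 2.0
    temperature: float = 300.0
    cluster_cutoff: float = DAURA_CUTOFF_NM
    max_cluster_frames: int = 300
    n_average_structures: int = 2
    omega_threshold: float = 15.0
    end_ratio_threshold: float = 1.3
    sasa_radius: float = 0.264
    sasa_probe: float = 0.185
    sasa_points: int = 960
    bsa_stride: int = 100
    save_trajectories: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def resolve_system(self) -> TMDSystem:
        if isinstance(self.system, str):
            return get_system(self.system)
        return TMDSystem.from_dict(self.system)

    def resolve_preset(self) -> GeneratorPreset | None:
        if self.preset is None:
            return None
        base = get_preset(self.preset)
        if self.preset_overrides:
            from dataclasses import replace

            base = replace(base, **self.preset_overrides)
        return base


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def _round_floats(obj, ndigits: int = 6):
    """Round floats recursively so the summary JSON is byte-stable."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; returns the summary dict.

    Replica trajectories come either from the generator (``preset`` +
    ``seeds``) or from input files (``trajectories``).  A stage failure
    aborts only the stages downstream of it; the summary then records
    the error under ``"errors"``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stderr = logging.StreamHandler(sys.stderr)
    log.addHandler(stderr)

    try:
        return _run_inner(config, out)
    finally:
        log.removeHandler(handler)
        log.removeHandler(stderr)
        handler.close()


def _run_inner(config: RunConfig, out: Path) -> dict:
    system = config.resolve_system()
    summary: dict = {
        "version": __version__,
        "receptor": system.receptor_name,
        "config": config.to_dict(),
        "replicas": [],
        "errors": [],
    }
    log.info("tmdimer %s | system %s", __version__, system.receptor_name)

    # --- inputs: generate or load -----------------------------------------
    replicas: list[tuple[str, Trajectory]] = []
    if config.trajectories:
        for path in config.trajectories:
            p = Path(path)
            if not p.exists():
                raise FileNotFoundError(f"input trajectory not found: {p}")
        for k, path in enumerate(config.trajectories):
            replicas.append((f"rep{k}", read_trajectory(path)))
            log.info("loaded %s", path)
    else:
        preset = config.resolve_preset()
        if preset is None:
            raise ValueError("config needs either a preset or input trajectories")
        for k, seed in enumerate(config.seeds):
            traj, truth = generate(
                system, preset, n_frames=config.n_frames, dt=config.dt, seed=seed
            )
            log.info(
                "generated replica %d (seed %d, association frame %s)",
                k, seed, truth.association_frame,
            )
            if config.save_trajectories:
                path = out / f"rep{k}.gro"
                write_trajectory(traj, path)
                truth.save(out / f"rep{k}.truth.json")
            replicas.append((f"rep{k}", traj))

    # --- metrics ------------------------------------------------------------
    all_metrics = []
    theta_profiles, omega_profiles = [], []
    for k, (label, traj) in enumerate(replicas):
        series = compute_metrics(traj, system, cutoff=config.dimer_cutoff)
        write_table(series, out / f"metrics_{label}.csv")
        all_metrics.append(series)
        rep_summary = {
            "replica": label,
            "n_frames": int(traj.n_frames),
            "first_dimer_frame": series.first_dimer_frame,
            "n_dimer_frames": int(series.dimer.sum()),
        }
        summary["replicas"].append(rep_summary)

        dimer = series.dimer
        if dimer.any():
            theta = np.concatenate([series.tilt_a[dimer], series.tilt_b[dimer]])
            prof_t = histogram_pmf(
                theta, "theta", config.bin_width, config.temperature, replica=k
            )
            prof_o = histogram_pmf(
                series.omega[dimer], "omega", config.bin_width,
                config.temperature, replica=k,
            )
            write_table(prof_t, out / f"pmf_theta_{label}.csv")
            write_table(prof_o, out / f"pmf_omega_{label}.csv")
            theta_profiles.append(prof_t)
            omega_profiles.append(prof_o)

    # --- replica-averaged PMFs ----------------------------------------------
    try:
        if len(theta_profiles) >= 2:
            mean_t = average_profiles(theta_profiles)
            mean_o = average_profiles(omega_profiles)
            write_table(mean_t, out / "pmf_theta_mean.csv")
            write_table(mean_o, out / "pmf_omega_mean.csv")
            summary["pmf"] = {
                "theta_minimum_deg": find_minimum(mean_t)[0],
                "omega_minimum_deg": find_minimum(mean_o)[0],
            }
        elif theta_profiles:
            summary["pmf"] = {
                "theta_minimum_deg": find_minimum(theta_profiles[0])[0],
                "omega_minimum_deg": find_minimum(omega_profiles[0])[0],
            }
    except Exception as exc:
        summary["errors"].append(f"stage 'pmf' failed: {exc}")
        log.error("stage 'pmf' failed: %s", exc)

    # --- clustering over pooled dimer frames --------------------------------
    try:
        pooled, frame_labels = [], []
        for k, ((label, traj), series) in enumerate(zip(replicas, all_metrics)):
            idx = np.flatnonzero(series.dimer)
            if idx.size:
                pooled.append(traj.coords[idx])
                frame_labels.extend((k, int(i)) for i in idx)
        if not pooled:
            raise ValueError("no dimerized frames in any replica")
        coords = np.concatenate(pooled)
        if coords.shape[0] > config.max_cluster_frames:
            stride = int(np.ceil(coords.shape[0] / config.max_cluster_frames))
            coords = coords[::stride]
            frame_labels = frame_labels[::stride]
        beads = replicas[0][1].beads
        swap = chain_swap_map(beads, system.chains)
        result = daura_cluster(coords, cutoff=config.cluster_cutoff, swap_map=swap)
        order = np.argsort(-np.asarray(result.sizes), kind="stable")
        shapes, averages = [None] * result.n_clusters, {}
        for rank, cid in enumerate(order[: config.n_average_structures]):
            members = np.flatnonzero(result.assignments == cid)
            centre_local = int(
                np.flatnonzero(result.frame_index == result.centers[cid])[0]
            )
            avg = average_structure(coords[members], coords[centre_local])
            shapes[cid] = classify_shape(
                avg, system, beads=beads,
                omega_threshold=config.omega_threshold,
                end_ratio_threshold=config.end_ratio_threshold,
            )
            avg_traj = Trajectory(coords=avg[None], beads=beads)
            write_trajectory(avg_traj, out / f"cluster{rank}_average.pdb")
            averages[int(cid)] = rank
        result.shape_labels = shapes
        write_table(result, out / "clusters.json")
        summary["clusters"] = {
            "n_clusters": result.n_clusters,
            "cutoff_nm": config.cluster_cutoff,
            "sizes_percent": [round(float(p), 4) for p in result.percentages],
            "shapes": shapes,
        }
    except Exception as exc:
        summary["errors"].append(f"stage 'clustering' failed: {exc}")
        log.error("stage 'clustering' failed: %s", exc)

    # --- contact map ---------------------------------------------------------
    try:
        label, traj = replicas[0]
        cmap = contact_map(traj, system, all_metrics[0].dimer)
        write_table(cmap, out / "contact_map.csv")
        summary["contact_map"] = {
            "n_frames": cmap.n_frames,
            "min_distance_nm": float(cmap.values.min()),
        }
    except Exception as exc:
        summary["errors"].append(f"stage 'contacts' failed: {exc}")
        log.error("stage 'contacts' failed: %s", exc)

    # --- buried surface area -------------------------------------------------
    try:
        model = SphereModel(
            radius=config.sasa_radius, probe=config.sasa_probe,
            n_points=config.sasa_points,
        )
        bsa_means = []
        for (label, traj), series in zip(replicas, all_metrics):
            mask_a = traj.chain_mask(system.chains[0])
            mask_b = traj.chain_mask(system.chains[1])
            idx = np.arange(0, traj.n_frames, config.bsa_stride)
            rows = []
            for i in idx:
                value = buried_surface_area(
                    traj.coords[i, mask_a], traj.coords[i, mask_b], model
                )
                rows.append(
                    {"frame": int(i), "time": float(traj.times[i]),
                     "bsa_nm2": value}
                )
            write_table(rows, out / f"bsa_{label}.csv")
            bsa_means.append(float(np.mean([r["bsa_nm2"] for r in rows])))
        summary["bsa"] = {"stride": config.bsa_stride, "replica_means_nm2": bsa_means}
    except Exception as exc:
        summary["errors"].append(f"stage 'bsa' failed: {exc}")
        log.error("stage 'bsa' failed: %s", exc)

    payload = _round_floats(summary)
    (out / "summary.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    log.info("summary written to %s", out / "summary.json")
    return payload
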