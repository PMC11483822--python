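# tmdimer

Analysis of transmembrane-helix (TMD) dimerization in coarse-grained
membrane trajectories — built for the insulin receptor (IR) and
insulin-like growth-factor-1 receptor (IGF1R) TMD pairs, and usable for
any two-helix membrane system.

Receptor tyrosine kinases of the insulin family carry a single
membrane-spanning α-helix per protomer; whether and how these helices
dimerize (X-shaped, V-shaped or parallel packing) bears directly on how
the receptor transmits its activation signal across the membrane.
`tmdimer` computes the standard observables of that problem from bead
trajectories and, because production-scale simulation data of this kind
is rarely deposited, ships a ground-truth-labelled synthetic trajectory
generator so every stage of the analysis is verifiable at desk scale.

## What it computes

For a pair of helices A and B with backbone beads in a planar membrane
(normal = z):

* **d_HH** — distance between the centres of mass of the two helices'
  membrane-core residues; frames with d_HH ≤ 1.3 nm are *dimerized*.
* **Tilt θ** — angle between a helix axis (principal component of its
  backbone beads, N→C) and the membrane normal: θ = arccos |a · ẑ|,
  folded to [0°, 90°].
* **Crossing Ω** — unsigned inter-axis angle, Ω = arccos |a_A · a_B|.
* **Free-energy profiles** — Boltzmann inversion of the binned angle
  distribution over dimerized frames, U(x) = −k_B T ln P(x), shifted to
  a zero minimum, averaged over replicas.
* **Clusters and packing shapes** — greedy neighbour-count (Daura)
  clustering of dimerized frames at a pairwise Kabsch-RMSD cutoff
  (0.9 nm default), with chain-swap symmetry for homodimers; cluster
  averages labelled X / V / parallel.
* **Contact maps** — residue-pair mean centre-of-mass distances over
  dimerized frames.
* **RMSF** per residue and **buried surface area** (Shrake–Rupley,
  deterministic Fibonacci point set), BSA = SASA(A) + SASA(B) −
  SASA(A∪B).

Trajectories are read and written as concatenated GRO frames or
multi-model PDB; analysis outputs are CSV/JSON.  See `docs/methods.md`
for the model, conventions, generator design and limitations.

## Worked example

Generate one replica started from the published O1 initial orientation
(helices 7.2 nm apart, both tilted 45°), watch it diffuse, bind and
stay bound, and invert its tilt histogram:

```python
import numpy as np
import tmdimer as td

ir = td.ir_system()                       # IR TMD pair, residues 940-988
traj, truth = td.generate(ir, td.get_preset("O1"), n_frames=4000, seed=1)
m = td.compute_metrics(traj, ir)

print(f"association frame (truth): {truth.association_frame}")
print(f"first dimerized frame (d_HH <= 1.3 nm): {m.first_dimer_frame}")
print(f"dimerized frames: {int(m.dimer.sum())} of {traj.n_frames}")

theta = np.concatenate([m.tilt_a[m.dimer], m.tilt_b[m.dimer]])
centre, value = td.find_minimum(td.histogram_pmf(theta, "theta"))
print(f"tilt PMF minimum: {centre:.0f} deg ({value:.3f} kcal/mol)")
```

prints

```
association frame (truth): 1488
first dimerized frame (d_HH <= 1.3 nm): 1489
dimerized frames: 2511 of 4000
tilt PMF minimum: 29 deg (0.000 kcal/mol)
```

The helices meet after ~74 ns of diffusive search (frame 1488 at 50 ps
per frame), remain dimerized for every subsequent frame, and the
free-energy profile over the bound frames has its minimum in the bin
containing the 30° tilt of the X-shaped packing mode — the value the
generator was asked to produce, recovered by the analysis chain.

The same workflow runs from the shell:

```bash
tmdimer run --config config.yaml --seed 1 --out results/
```

writing per-replica metric CSVs, per-replica and averaged PMFs, cluster
JSON with averaged structures as PDB, a contact map, BSA series and a
machine-readable `summary.json` (identical config + seeds give a
byte-identical summary).  Subcommands `generate`, `metrics`, `pmf`,
`cluster`, `contacts` and `bsa` expose each stage separately over
standard file formats.

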