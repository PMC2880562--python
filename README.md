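# quatdyn

Trajectory-analysis toolkit for the **quaternary dynamics of stacked-trimer
protein assemblies** — built around the hexameric C-terminal domain of the
bacterial arginine repressor (ArgRC), whose two trimers rotate against each
other about a shared 3-fold axis, and whose rotation is gated by
arginine–aspartate salt bridges that the free L-arginine ligand competes
for.  The package is for computational structural biologists who have
coordinate trajectories (or multi-model PDB ensembles) of such assemblies
and want the standard quaternary observables without gluing together a
dozen one-off scripts.

## What it computes

* **Superposition & metrics** — weighted Kabsch fits, RMSD/RMSF series,
  radius of gyration, COM distances.
* **Covariance & PCA** — 3N×3N displacement covariance
  C_ij = ⟨(x_i−x̄_i)(x_j−x̄_j)⟩ under two referencing modes: whole-assembly
  mean referencing, or *trimer referencing* (fit on one trimer, deviations
  from the initial structure), which unmasks rigid inter-trimer motion as
  coherent correlation blocks; atom-pair maps C_xx+C_yy+C_zz, fused
  two-simulation panels, principal components and extreme conformations.
* **Quasi-harmonic entropy** — the Schlitter bound
  S ≤ (k_B/2)·ln det[1 + (k_B T e²/ħ²) σ] on the mass-weighted covariance
  σ, a singularity-corrected variant with the six rigid-body modes
  projected out, and regularized entropy differences between states.
* **Inter-trimer rotation** — per-frame signed angle/axis of one trimer
  relative to the other (fixed-partition Kabsch measurement; positive =
  clockwise viewed down the 3-fold axis from the top-trimer side),
  oscillation amplitude and spectral cycle time.
* **H-bonds & salt bridges** — geometric detection that works on
  heavy-atom-only models, per-frame occupancy, persistence (>50% rule),
  and the three inter-trimer census variants (persistent / total without
  ligand / total with ligand).
* **Interface Δδ metrics** — the six diagonal Gly103–Asp128 Cα pocket
  distances, normalization to the holo-crystal reference (9.8 Å),
  0.1 Å-bin histograms, sidechain dihedral series with circular stats.
* **LIE energetics** — ΔG = α·Δ⟨V_LJ⟩ + β·Δ⟨V_elec⟩ with α = 0.18,
  β = 0.50 and free-ligand/water references (−4.63, −453.458) kJ/mol;
  nonbonded binding enthalpies; a minimal Coulomb+LJ evaluator for
  synthetic systems.
* **Reaction coordinate** — per-ligation-state assembly of entropy,
  bond counts, and estimated free-energy levels, with linear
  interpolation between the 2- and 6-ligand anchors.
* **Synthetic hexamer generator** — a seeded ground-truth generator of
  oscillating two-trimer pseudo-structures (rotation process, core→surface
  motion gradient, θ-gated hydrogen bonds, pocket geometry solved in
  closed form, ligand brake, Gaussian energy series) so every stage is
  testable without MD.

See `docs/methods.md` for the models, conventions, and numerical choices.

## Worked example

Generate an oscillating apo-like hexamer and recover its rotation:

```python
import quatdyn as q

spec = q.GeneratorSpec(n_frames=10_000, seed=1)   # 13° ± 3°, 250 ps period
model, traj, truth = q.generate(spec)

stats = q.oscillation_stats(q.rotation_series(traj))
print(f"mean {stats.mean_angle:.2f} deg, "
      f"amplitude {stats.amplitude_std:.2f} deg, "
      f"cycle {stats.cycle_time:.0f} ps")

dist = q.pair_distances(traj, q.default_pair_scheme(model))
dd = q.delta_delta(dist, reference_distance=9.8)
print(f"mean pocket deviation {dd.delta.mean():.2f} A")
```

prints

```
mean 13.00 deg, amplitude 3.00 deg, cycle 250 ps
mean pocket deviation 1.63 A
```

i.e. the analysis recovers the generator's 13° mean trimer rotation, its
3° oscillation amplitude and 250 ps cycle time, and the ~1.6 Å opening of
the six diagonal pocket distances relative to the 9.8 Å ligand-bound
reference.  The same functions run on real data:

```bash
quatdyn rotation --traj ensemble.pdb --top-chains DEF --out rotation.tsv
quatdyn hbonds   --traj ensemble.pdb --ligand ARG --out hbonds.tsv
quatdyn lie      --bound energies.tsv
```

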