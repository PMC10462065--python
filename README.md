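# loopstate

Trajectory analysis of GPCR-style receptor dynamics centered on the
rotational state of an intracellular loop (ICL2): geometric per-frame
metrics, a helicity + rotation-state classifier, hydrogen-bond and
water-bridge frequency tables, backbone-dihedral PCA, and a synthetic
trajectory generator with exact ground truth for validating every stage.

## What it computes

- **Structure / trajectory I/O** (`loopstate.structure`): PDB v3
  reader/writer (single and multi-model), altloc resolution to highest
  occupancy, a small deterministic selection grammar
  (`"resid 110-118 and backbone"`), and an author-number ↔ generic
  position-code map (`BWMap`).
- **Superposition** (`loopstate.superpose`): unweighted Kabsch fit with
  reflection correction (always a proper rotation), plain/superposed RMSD,
  whole-trajectory alignment, and batched variants for the vectorized
  pipeline.
- **Geometry metrics** (`loopstate.metrics`): TM5 vertical shift (probe CA
  projected on the TM4 130→141 CA axis), named-atom pair distances, the
  loop rotation angle (tip−base vector measured as `atan2(v_z, v_y)` in
  the aligned frame, raw and reference-offset), local backbone RMSD and
  the residues-111–118 multi-RMSD collective variable, Gα helix-5
  displacement, and loop end-to-end distance.
- **H-bond network** (`loopstate.hbonds`): geometric detection
  (D–A ≤ 3.5 Å, D–H…A ≥ 110° when hydrogens exist, heavy-only mode for
  crystal structures), water-mediated bridges, and fraction-of-frames
  frequency tables with replica mean ± 68% CI (SEM).
- **State classifier** (`loopstate.states`): a frame is helical when it
  has ≥ 3 backbone i,i+4 H-bonds or loop backbone RMSD < 2 Å; helical
  frames are PR when `45 < a < 120` and `195 − 20·a < d < 13` (strict, as
  printed), otherwise NR; occupancy statistics across replicas; a fully
  vectorized `state_trace` pipeline.
- **Dihedral PCA** (`loopstate.dpca`): phi/psi extraction for a residue
  window, covariance PCA (sklearn-backed) on helical frames, projection,
  and an optional sin/cos embedding.
- **Synthetic data** (`loopstate.synth`): ideal-helix builder from set
  torsions, a receptor-like scaffold on which every metric resolves, and a
  two-state Markov trajectory generator (default rotation states 40° apart)
  with optional unfolding episodes, planted water bridges, Gaussian noise,
  per-frame global rigid motion, and a controllable Gα displacement — all
  returning ground-truth labels/angles, reproducible from `(spec, seed)`.

## CLI

```bash
# generate a synthetic two-state dataset with ground truth
loopstate synth --out data_dir --n-frames 500 --n-replicas 5 --seed 1 \
    --noise-sigma 0.3 --p-pr-to-nr 0.03 --p-nr-to-pr 0.07

# run the full analysis (per-frame traces, occupancy, optional PCA)
loopstate analyze --ref data_dir/reference.pdb \
    --traj data_dir/replica_00.pdb --traj data_dir/replica_01.pdb \
    --out results --pca

# vertical-shift metric between two structures
loopstate crystal-shift a.pdb b.pdb
```

`analyze` also accepts `--config config.yaml` (keys mirror
`loopstate.config.RunConfig`; every threshold and residue range is a
config default, so robustness experiments are one-line edits). Outputs:
per-replica trace CSVs, `occupancy.json`, optional
`hbond_frequency.csv` / `pca_model.json`, and a `manifest.json` with
input hashes, seed and frame counts.

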