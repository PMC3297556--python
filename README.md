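# tcrdyn

Trajectory analysis of pMHC–TCR dynamics:

* **model_io** — PDB reading/writing (single- and multi-MODEL, optional DCD
  via MDAnalysis), atom selection, hydrogen-to-heavy-atom attachment.
* **geometry** — Kabsch superposition with reflection correction,
  rotation angle/axis extraction, iterative average structure, trajectory
  alignment.
* **flexibility** — per-residue RMSF profiles about the average structure,
  mean B-factor summaries, pairwise RMSD between structures.
* **interface** — geometric hydrogen-bond detection (donor/acceptor distance
  ≤ 3.5 Å and donor–H–acceptor angle ≥ 150° by default, boundaries
  inclusive), heavy-atom contacts, salt-bridge flags, chemically-equivalent
  site merging (Arg Nη1/2, Asp Oδ1/2, Glu Oε1/2). Distance-only mode for
  hydrogen-free crystal references. Inputs are assumed pre-imaged — there is
  no periodic-boundary handling.
* **footprint** — per-bond persistence (% of frames), classification into
  crystal_and_md / novel_short_lived / novel_long_lived (≥ 50 %) /
  crystal_only, table building, cross-complex conservation reports, and a
  packaged reference footprint fixture
  (`src/tcrdyn/data/reference_footprint.csv`, see the notes file beside it).
* **motion** — per-frame rigid-body rocking angle/axis of a TCR subunit
  relative to the MHC frame, cleft-axis direction decomposition
  (parallel/orthogonal/mixed), docking-angle difference between two
  complexes.
* **synthetic** — generators with known ground truth: Gaussian-fluctuating
  chains (expected RMSF = √3·σ), scripted hydrogen-bond schedules, and
  rigid rocking complexes. Pure functions of their seed.
* **cli** — `tcrdyn` command with verbs `simulate`, `rmsf`, `hbonds`,
  `footprint`, `motion`, `report`. All thresholds are config keys
  (YAML, see `tcrdyn <verb> --help`); outputs carry a provenance header.

## CLI quick start

```bash
# generate a synthetic rocking trajectory and analyse it
cat > rock.yaml <<'EOF'
kind: rocking
n_frames: 100
rocking: {amplitude_deg: 12.0, period: 100, axis: [0, 0, 1]}
EOF
tcrdyn simulate --spec rock.yaml --out rock.pdb
tcrdyn motion --traj rock.pdb --out motion.csv

# RMSF from a fluctuating-chain trajectory
cat > fluct.yaml <<'EOF'
kind: fluctuating
n_frames: 2000
n_residues: 20
sigmas: [0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5,
         0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
seed: 1
EOF
tcrdyn simulate --spec fluct.yaml --out fluct.pdb
tcrdyn rmsf --traj fluct.pdb --no-align --out rmsf.csv

# classified footprint from the packaged reference fixture
tcrdyn footprint --reference-fixture --out-csv footprint.csv --out-json footprint.json
```

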