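# endstate

End-state binding free-energy analysis for receptor–ligand complexes,
exercised on fully synthetic toy systems so every stage is verifiable
without molecular-dynamics runs:

- **MM/GBSA enthalpy** under the single-trajectory protocol: Lennard-Jones
  and Coulomb cross terms, OBC-II generalized-Born polar solvation, and a
  `γ·SASA + β` non-polar term (Shrake–Rupley quadrature), with per-residue
  decomposition.
- **Interaction entropy**: `kT·ln⟨exp(ΔE_int/kT)⟩` over mean-centered
  gas-phase interaction-energy fluctuations, preceded by minimum-RMSF
  window selection and a single-pass k·σ outlier filter.
- **Free-energy perturbation** over a coupling-parameter schedule
  (exponential averaging per window, Beutler-style softcore pair mixing),
  validated against harmonic-toy closed forms.
- **Structural analyses**: Kabsch RMSD/RMSF, hydrogen-bond occupancy with
  distance + angle criteria, group-distance series/histograms, and
  lowest-energy-frame selection.
- **Synthetic data**: seeded generators for multi-chain protein-ring +
  ssRNA toy complexes with exact contact-occupancy ground truth, Gaussian /
  AR(1) energy series with regime changes and injected outliers, and exact
  Boltzmann samples of a harmonic mutation toy.

## Command line

One subcommand per pipeline stage:

```sh
endstate simulate --out demo --seed 1            # write a worked example
endstate report   --config demo/config.yaml     # full pipeline -> demo/results/
endstate ie       --series demo/wt_traj1.csv --window-ns 1 --out ie.tsv
endstate energy   --pdb demo/wt.pdb --params demo/wt.params.csv --out frames.tsv
endstate mmgbsa   --pdb demo/wt.pdb --params demo/wt.params.csv --out-prefix wt
endstate fep      --dataset demo/fep --out fep.tsv
endstate hbonds   --pdb demo/wt.pdb --params demo/wt.params.csv \
                  --donor A:1:OH --acceptor R:1:OP2 --out hb.tsv
```

`report` reads a YAML config (systems, trajectories, wild/mutant pairs,
hydrogen-bond and distance specs; unknown keys rejected) and writes
`summary.tsv`, a 0.1-rounded `report.tsv` with per-system averages,
`ddg.tsv`, per-residue/hydrogen-bond/distance tables, and a `manifest.json`
recording every default. Reruns with the same seed are byte-identical.

## Layout

```
src/endstate/
  io.py          domain types; PDB / parameter-table / series / FEP I/O
  selections.py  chain:resi:atoms selector expressions
  synth.py       synthetic toy complexes, energy series, FEP samples
  energetics.py  LJ, Coulomb, GB (OBC-II), SASA, non-polar terms
  mmgbsa.py      single-trajectory enthalpy + per-residue decomposition
  entropy.py     window scan, outlier filter, interaction entropy, ΔG/ΔΔG
  fep.py         per-window exponential averages, softcore mixing
  structure.py   RMSD/RMSF, hydrogen bonds, distances, lowest-energy frame
  pipeline.py    validated run config, full pipeline, demo fixtures
  cli.py         `endstate` entry point
```

Input formats are plain text: multi-model PDB for coordinate frames, a CSV
parameter table (`chain,resi,resn,atom,charge,rmin_half,epsilon,born_radius,group`),
two-column CSV energy series, and a FEP directory of per-window CSVs with a
`schedule.json`.
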