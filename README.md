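# nsalign

Non-sequential protein structure alignment. Residue correspondence between two
superposed Cα traces is cast as a partial linear sum assignment problem with
explicit gap states (one gap row and one gap column absorb unmatched
residues), relaxed with an entropy term, and solved by a log-domain
semi-relaxed Sinkhorn iteration. Because no chain-order constraint is imposed,
circular permutations and segment swaps are recovered naturally.

Components:

- `nsalign.structio` — Cα PDB reading/writing, rigid-matrix files in the
  TM-align `-m` text dialect, alignment reports.
- `nsalign.geometry` — Kabsch superposition, rigid transforms, distance
  tables, TM-score.
- `nsalign.scoring` — SP-score similarity kernel (α = 0.3, d0 = 4 Å, hard
  cutoff at 2·d0), gap-augmented similarity matrix and its non-negative cost
  transform.
- `nsalign.solver` — semi-relaxed Sinkhorn solver (defaults λ = 100,
  tol = 1e-6, Tmax = 5000), row/column argmax inference with conflict
  elimination, TM-score direction selection, and an exact LSAP-reduction
  oracle (`exact_plsap`). `gap_modeling=False` gives the classical-assignment
  ablation (no gap states, shorter chain fully matched).
- `nsalign.superpose` — fragment-pair Kabsch seeding plus alternating
  assignment/re-superposition refinement (a simple built-in stand-in for
  external superposition engines; import their matrix via `--matrix` for
  full fidelity).
- `nsalign.metrics` — Nali, RMSD, structure overlap (boundary-inclusive,
  default 3.5 Å) and its threshold curve (3.0–7.0 Å, step 0.5), EQR and
  agreement against a reference alignment.
- `nsalign.synthetic` — ground-truthed fixtures: ideal helical Cα traces,
  circular permutation / segment swap with known truth maps, Gaussian
  coordinate noise, and letter-string toy similarity problems.

## CLI

```sh
# align two PDB chains (built-in seeding + alternating refinement)
nsalign align query.pdb target.pdb --output-prefix run --json

# use an external rigid superposition (TM-align -m dialect), single pass
nsalign align query.pdb target.pdb --matrix rot.txt --output-prefix run

# coverage-fidelity sweep over the sharpness parameter
nsalign sweep query.pdb target.pdb --lambdas 10,50,100,300 --out sweep.tsv

# reference-dependent evaluation of a map written by align
nsalign evaluate --map run.tsv --ref reference.tsv --json

# ground-truthed synthetic fixture (two PDBs + truth TSV)
nsalign synth --n 60 --mode circular --cut 30 --sigma 0.3 --seed 7 \
    --output-prefix fix
```

Key flags: `--lambda` (sharpness, default 100; larger = sharper, closer to
the exact assignment), `--epsilon` (cost-transform margin, 0.5), `--tmax`
(5000), `--gap-score` (0), `--no-gap` (classical-assignment ablation),
`--mode auto|row|col` (inference direction; auto picks the higher TM-score),
`--alpha`/`--d0` (SP-score), `--so-threshold` (3.5 Å), `--ref`
(reference TSV for EQR/agreement).

Outputs: `<prefix>.tsv` (header plus a `query_res  target_res  distance`
map in author residue numbering) and `<prefix>.json` (single-line metrics
record: nali, rmsd, so, so_curve, eqr, agreement, sp, tm, config).

Exit codes: 0 success, 2 ran but nothing alignable, 1 error.

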