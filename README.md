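# parafit

Software models of two bioinformatics fitness functions and of the
fine-grained parallel schedules used to evaluate them:

- **Gene-selection fitness** `F(x) = w1*A(x) + w2*(M - R(x))/M` for
  cancer classification, where `A(x)` is the leave-one-out
  cross-validation accuracy of a pluggable classifier on the selected
  genes (default: deterministic nearest-centroid) and `R(x)` the subset
  size. Maximized.
- **Mean Squared Residue (MSR)** of a bicluster (submatrix) of a gene
  expression matrix, with every intermediate (row/column/overall means,
  residues) exposed. Lower is better; exactly additive blocks score 0.
- **Dataflow-schedule simulator**: macro-step schedules for two MSR
  parallelization models (`f` = partially parallelized, 6 macro-steps,
  row-parallel/column-sequential residues; `a` = fully parallelized, 5
  macro-steps) and for the gene-selection circuit (4 macro-steps, 3
  concurrent operations in step 1); per-version operator budgets
  (adders/multipliers/dividers/int-to-float converters); a pairwise
  comparator reduction tree (`NC = NF/2`); and a cycle-level
  latency/speedup model for evaluating a population on `NF` parallel
  fitness units. Every schedule trace is numerically executable and
  reproduces the direct fitness value exactly — a schedule is a
  reordering, never a re-definition.
- **Evolutionary driver**: a seeded generational GA (tournament
  selection, uniform crossover, bit-flip mutation, elitism) exercising
  both fitness functions, reporting simulated sequential vs parallel
  evaluation latency.
- **Synthetic data**: seeded generators for matrices with planted
  constant/additive/shifted biclusters and for balanced two-class
  datasets with a small informative gene subset, both returning ground
  truth.

Matrices are delimited text (TSV by default), rows = experimental
conditions/samples, columns = genes, with an optional header row of gene
ids and an optional leading column of condition ids. Labels are a
two-column TSV (`sample_id<TAB>class`). All arithmetic is double
precision.

## CLI

All subcommands print JSON to stdout (with the effective config echoed
for reproducibility) and diagnostics to stderr.

```sh
# MSR of a matrix or of a bicluster of it
parafit msr matrix.tsv
parafit msr matrix.tsv --rows 1,2,3 --cols 4,5,6 --breakdown

# gene-selection fitness on a labeled dataset
parafit select-fitness matrix.tsv labels.tsv --mask 0101100 --w1 0.75 --w2 0.25

# schedule simulation: steps, cycles, speedup, operator budget
parafit schedule msr-f8x8 --nf 8 --population 64 --trace trace.json
parafit schedule gene-selection

# evolutionary runs
parafit evolve-bicluster matrix.tsv --config ea.yaml --history hist.tsv
parafit evolve-select matrix.tsv labels.tsv --seed 1 --generations 100

# synthetic data
parafit synth bicluster --spec plant.yaml --out data/run1
parafit synth dataset --spec dataset.yaml --out data/run2
```

Circuit versions are named `msr-<f|a><I>x<J>` (e.g. `msr-f8x8`,
`msr-a4x4`) or `gene-selection`; top-level controller names like
`controller-f16x8-NF6-NC3` can be parsed with
`parafit.parse_controller_name`.

### YAML configs

`--config ea.yaml` for the evolve commands accepts any `EAConfig` field
(`population_size`, `generations`, `crossover_rate`, `mutation_rate`,
`tournament_size`, `seed`, `eval_NF`, `elitism`, `w1`, `w2`,
`classifier`, `min_rows`, `min_cols`, `bicluster_objective`,
`coherence_penalty`); command-line flags override the file. `--latency`
for `schedule` accepts `add`, `multiply`, `divide`, `convert`,
`compare` (cycles per operation) and optional `clock_ns`. `synth`
specs: for `bicluster` — `shape`, `rows`, `cols`, `structure`
(constant/additive/shifted), `signal`, `noise_sd`, `seed`; for
`dataset` — `N`, `M`, `k`, `effect`, `seed`.

## Notes

- The latency model's per-operator cycle counts are placeholders
  (config-overridable); the simulator predicts structure, batching and
  relative speedups, not hardware clock figures.
- `A(x)` is treated as a precomputed operand by the schedule simulator
  (the fitness circuit receives it as an input), so classifier time is
  excluded from the latency model.
- The EA's bicluster objective defaults to pure MSR minimization
  (`bicluster_objective: msr`). For recovering planted biclusters use
  `coherence`, which scores `vol_frac * (var - penalty * MSR)` — the
  additive (row+column effect) variance captured by the block — since
  pure MSR cannot distinguish an additive block from same-noise i.i.d.
  background.
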