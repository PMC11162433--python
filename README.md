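# ionnet

Neural genome-interpretation models for multi-task quantitative-trait
(ionome-style) prediction under dataset underdetermination, with a
population-stratification-aware evaluation protocol.

The package covers the full pipeline:

- **encoding** — gene-centric variant encoding: each genome becomes a
  `samples × genes × 17` tensor of variant-type counts, with carrier-frequency
  MAF filtering and three normalisation dialects (none, global per-feature
  z-score, per-gene frequency).
- **networks** — the architecture family: a shared per-gene compressor, a dense
  trunk, a knowledge-sparsified trunk whose only trainable trunk weights are
  gene→pathway edges from an annotation map (plus a dummy node for unannotated
  genes), a transfer-learning head (dense → affine layer-norm → tanh → dense),
  and a GPS-coordinates-only baseline. Parameter accounting is exact and
  contract-tested (e.g. the sparsified trunk has `E + 1 + P·H` weights).
- **training** — masked-MSE multi-task regression with RMSprop, L2 weight
  decay and a plateau learning-rate schedule (×1/3 after 3 consecutive
  non-improving epochs), plus two transfer-learning schemes: frozen feature
  extractor and warm-start fine-tuning.
- **evaluation** — random / country-stratified / leakage-safe CV planners with
  a machine-checkable audit, intra-country Pearson aggregation, a
  replicate-based Pearson noise ceiling, Simpson's-paradox diagnostics
  (pooled vs within-group correlation), and confusion-matrix metrics
  (macro F1, multi-class MCC).
- **synthetic** — stratified population generator (country-shifted Poisson
  variant counts, causal-gene phenotypes with tunable genetic/country/noise
  variance fractions, replicates, country-clustered GPS) and a two-level
  Simpson's-paradox dataset constructor.
- **workbench / CLI** — one declarative config drives encode → build → CV
  train loop → evaluate, fully seeded and reproducible.

The networks run on a small numpy engine with hand-written gradients
(verified against finite differences and a dense-layer oracle in the test
suite); no deep-learning framework is required.

## CLI

```bash
ionnet simulate --out data/ --seed 4 --n-samples 200 --n-genes 100
ionnet encode data/variants.tsv --out tensor --standardization global-z
ionnet run --config experiment.yaml --out runs/exp1
ionnet audit --config experiment.yaml
ionnet report runs/exp1
```

Example `experiment.yaml`:

```yaml
variant: masked           # dense | masked | frozen-head | fine-tune | gps
variants_path: data/variants.tsv
phenotypes_path: data/phenotypes.csv
replicates_path: data/replicates.csv
pathways_path: data/pathways.tsv
cv_mode: random-kfold     # or country-stratified
k: 5
hidden: 50
min_n: 50
train:
  epochs: 50
  batch_size: 10
  lr: 0.01
  l2: 1.0e-4
seed: 42
```

A synthetic run needs no files — put a `synthetic:` block in the config
instead of the paths (see `ionnet.synthetic.SyntheticConfig` for the knobs).

## Layout

```
src/ionnet/
  encoding.py    variant tables -> standardized count tensors
  nn.py          numpy layers (dense, masked-sparse, layer-norm) + gradients
  networks.py    architecture specs, mask construction, model builders
  training.py    RMSprop loop, LR plateau schedule, transfer learning
  evaluation.py  CV planners, intra-country metrics, noise ceiling, Simpson
  synthetic.py   stratified population + Simpson dataset generators
  workbench.py   experiment orchestration and leakage audits
  cli.py         command-line entry points
```
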