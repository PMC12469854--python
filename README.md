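# senosynergy

Toolkit for discovering synergistic senolytic drug combinations from aging
genomics. It covers the full workflow:

- **deg_sets** — threshold differential-expression tables (strict
  |log2FC| > 1, adjusted p < 0.05 by default) into up/down gene sets, with
  intersection and inclusion–exclusion bookkeeping.
- **geneset_assembly** — build a target-gene universe from six curated
  sources (two DEG contrasts plus GenAge / LongevityMap / CellAge /
  Aging Atlas–style tables), apply per-source filters, deduplicate
  case-insensitively, and convert IDs through a user-supplied mapping.
- **enrichment** — hypergeometric over-representation analysis against GMT
  collections with Benjamini–Hochberg correction and a ≥2-hit reporting rule.
- **feature_fusion** — binary drug–target vectors over the universe, fused
  combination rows `[x_A | x_B | x_cell]`, and z-score standardization
  (population std, fitted once on training rows).
- **synergy_model** — an attention-based regressor: the three semantic
  blocks become a 3-token sequence (per-block embedding + token-type offset),
  two post-norm multi-head self-attention blocks (8 heads), mean pooling, and
  a 256→128→1 ReLU/dropout head. Trained with Adam (lr 0.003, batch 128) on
  MSE, up to 100 epochs with patience-10 early stopping, drug-order swap
  augmentation, and order-symmetrized prediction. Implemented in pure NumPy
  with hand-written backprop — deterministic and bit-reproducible per seed.
- **combo_pipeline** — enumerate all unordered senolytic pairs, keep pairs
  whose members both appear in the training drug table, predict, and rank
  scores strictly above a threshold (default 8).
- **dock_report** — parse Vina-style docking mode tables (TSV or aligned
  stdout, Unicode minus accepted), pick the reference mode by minimum
  affinity, and classify remaining modes by RMSD lower bound.
- **synthetic_data** — seeded generators for every input class, including
  combination labels from a known ground-truth synergy function
  `S = β0 + β1·|T_A∩T_B| + β2·h_A·h_B + ε`, so the whole pipeline is
  testable offline.
- **fixtures** — plain-text snapshots of small published result tables
  (common DEG lists, pathway enrichment, top predictions, docking modes,
  the 63-compound senolytic list) shipped as package data.

## CLI

```bash
senosynergy simulate --config sim.yaml --seed 5 --out fixtures/   # synthetic inputs + truth.json
senosynergy deg-filter --table de.tsv --out-prefix results/deg
senosynergy assemble --config sources.yaml --out-prefix results/universe
senosynergy enrich --study genes.txt --gmt terms.gmt --universe universe.txt --out enr.tsv
senosynergy train --combos combos.tsv --targets drug_targets.tsv \
    --universe universe.txt --expression expr.tsv --seed 0 --model-out model.npz
senosynergy predict --drugs senolytics.txt --targets drug_targets.tsv \
    --universe universe.txt --expression expr.tsv --model model.npz \
    --cell-line MEAN --threshold 8 --out ranked.tsv
senosynergy dock-report --modes vina_modes.tsv --out dock.json
```

`--cell-line MEAN` scores combinations in the mean expression context over
all cell lines in the matrix; any column name selects a specific profile.

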