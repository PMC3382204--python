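# netprio

Candidate-gene prioritization from combined network topological features on a
protein–protein interaction (PPI) network.

Given a PPI network and a set of known disease genes, `netprio`:

1. builds the **test gene pool** from expression profiles (global median
   normalization → per-gene t-test → cross-profile intersection → restriction
   to disease-locus genes);
2. partitions network genes into **positive** (known disease), **negative**
   (neither disease nor differentially expressed) and **test** sets;
3. computes six per-gene topological features relative to the disease set —
   degree (D), disease-neighbor count (N) and ratio (R), betweenness (B),
   clustering coefficient (C), mean shortest-path length to disease genes (M);
4. **screens** features by Wilcoxon rank-sum disparity plus repeated balanced
   SVM cross-validation (fresh equal-size negative sample every round,
   per-split z-scoring, precision/TPR/FPR over held-out folds);
5. exhaustively evaluates all 2^n − 1 **combinations** of the retained
   features (paired negative draws across subsets) and picks the optimum;
6. **predicts candidates**: many randomized training rounds on positives vs
   fresh balanced negatives, classifying the test set each time; candidates
   are genes called positive in at least an `agreement` fraction of rounds
   (1.0 = strict intersection).

A synthetic-data module generates scale-free networks with a planted dense
disease module and matching expression matrices, so the whole pipeline is
testable end-to-end without any external data.

## CLI

All verbs share `--config cfg.yaml --outdir DIR [--seed N] [--verbose]`:

```bash
netprio generate --config cfg.yaml --outdir fixtures/   # synthetic fixtures
netprio features --config cfg.yaml --outdir run/        # feature matrix only
netprio screen   --config cfg.yaml --outdir run/        # + per-feature screening
netprio combos   --config cfg.yaml --outdir run/        # + combination search
netprio run      --config cfg.yaml --outdir run/        # full pipeline
```

Example config (synthetic route):

```yaml
synthetic:
  n_background: 2000
  n_disease: 60        # seed disease genes (positives)
  n_hidden: 40         # withheld planted genes, the recovery target
  attach_m: 3
  module_p: 0.15
  cross_p: 0.005
  n_decoy_de: 160      # background genes planted as DE + locus decoys
  n_case: 8
  n_control: 8
  effect: 4.0
  sigma: 1.0
  n_profiles: 3
alpha: 0.05
p_min: 0.55
t_min: 0.55
f_max: 0.45
agreement: 0.95
n_rounds_screen: 200
n_rounds_predict: 300
cv_folds: 10
optima_rule: youden
svm: {kernel: rbf, C: 1.0, gamma: scale}
seed: 1
```

For real data replace `synthetic:` with:

```yaml
inputs:
  network: edges.tsv          # 2-column TSV ('#' comments; SIF also accepted)
  positives: disease.txt      # one gene per line
  loci: loci_genes.txt        # locus regions pre-resolved to gene lists
  expression: [a.tsv, b.tsv]  # or a precomputed list: de_genes: de.txt
```

Expression TSV: gene rows, first header row = sample IDs, second header row =
group labels (`case`/`control`).

Outputs per run: `features.tsv`, `screening.tsv`, `combos.tsv`,
`predictions.tsv` and a machine-readable `summary.json` (byte-reproducible
for a fixed config + seed).

## Library use

```python
from netprio import (generate_network, build_feature_matrix, build_partition,
                     evaluate_feature_set, enumerate_combinations,
                     predict_candidates)
```

Every stochastic operation takes an explicit `seed`; a pipeline master seed is
expanded into independent per-stage streams.
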