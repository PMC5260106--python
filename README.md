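# rwrscreen

Semi-supervised drug screening on a weighted drug–protein bipartite network.

Two random walks with restart are started from effective and ineffective
seed drugs (optionally reinforced by phenotype-associated gene proteins).
After convergence of

```
P(t+1) = (1 - alpha) * T * P(t) + alpha * L'      with  T = D^-1 A,  P(0) = L'
```

every node is scored by the odds of the two stationary distributions,
`F(i) = P*(i, effective) / P*(i, ineffective)`; nodes with `F > theta` are
called effective.  The package also implements the companion drug–drug
similarity measures (chemical cosine, target-sharing Jaccard, noisy-OR
integration), a kNN baseline on `1 - S` distances, k-fold cross-validated
recall–precision evaluation, a paired mean-similarity contrast test, and a
synthetic planted-module data generator so everything is testable offline.

## Command line

All commands write a `*.manifest.json` (or `manifest.json` in output
directories) echoing parameters and versions, so runs are reproducible.

```bash
# generate synthetic data (network TSV + JSON sidecar, labels, attributes)
rwrscreen simulate --seed 3 --out sim/

# assemble a network from an interaction TSV (STITCH-style columns:
# chemical, protein, experimental, database, textmining, prediction,
# combined_score; raw scores on a 0-1000 scale by default)
rwrscreen build-net --interactions links.tsv --orthologs orth.tsv --out net.tsv

# rank all nodes by F-ratio
rwrscreen screen --network sim/network.tsv --labels sim/labels.tsv \
    --alpha 0.5 --epsilon 1e-9 --theta 2.0 --out ranked.tsv

# 5-fold cross-validation with recall-precision curves
rwrscreen evaluate --network sim/network.tsv --labels sim/labels.tsv \
    --k 5 --seed 42 --out cv/

# drug-drug similarity (chemical | target | integrated)
rwrscreen similarity --attributes sim/attributes.csv \
    --network sim/network.tsv --kind integrated --out S.csv

# mean-similarity contrast of screened drugs vs the seed sets
rwrscreen contrast --similarity S.csv --screened ids.txt \
    --labels sim/labels.tsv --out contrast.tsv
```

Labels TSV has columns `id` and `class` in
`{effective, ineffective, aging_gene}`.  Ortholog TSV has columns
`source`, `target`, `n_methods`; interactions whose protein lacks an
ortholog supported by at least `--min-methods` (default 2) prediction
methods are dropped.

## Library layout

| module | contents |
| --- | --- |
| `rwrscreen.network` | interaction/ortholog ingestion, evidence filter, ortholog mapping, bipartite assembly, largest-component pruning, row-stochastic transition matrix, TSV+sidecar serialization |
| `rwrscreen.propagation` | label matrix, power iteration with restart, dense closed-form oracle, F-ratio, threshold classification and ranking |
| `rwrscreen.similarity` | constant-attribute removal, cosine, target Jaccard, noisy-OR integration, `1 - S` distance |
| `rwrscreen.evaluation` | stratified k-fold splitting, leakage-free cross-validation, threshold-swept precision/recall, kNN baseline, paired one-sided t contrast |
| `rwrscreen.synthetic` | planted-module network/label/attribute generator with tunable class separation |
| `rwrscreen.cli` | the `rwrscreen` entry point |

## Notable conventions

- Scores are normalized to `[0, 1]` internally; the transition matrix is
  invariant to uniform edge-weight rescaling, so the raw score scale is
  presentation-only (`--scale`).
- The evidence filter keeps interactions with strictly positive
  experimental or curated-database scores; text mining or predicted
  evidence alone never qualifies.  A stricter cutoff is available via
  `--evidence-threshold`.
- The restart probability `alpha` has no canonical published value; the
  default is 0.5 and it is an explicit parameter everywhere.
- F-ratio division policy at zero: `0/0 -> 0`, `x/0 -> +inf`; an optional
  pseudocount regularizes both.
- Raw chemical cosine may be negative; it is reported as-is but floored at
  0 when entering the noisy-OR integration or the kNN distance.
- Empty-prediction precision is reported as 1.0 (standard PR convention).
- Cross-validation is stratified by default; `--no-stratified` reproduces a
  plain random split.  Curves are averaged both threshold-wise on a shared
  grid and recall-wise on a common recall grid (`pr_curve_threshold.tsv`,
  `pr_curve_recall.tsv`).
- An SVM baseline is deliberately out of scope (plain off-the-shelf
  classifier with internal tuning, nothing method-specific).

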