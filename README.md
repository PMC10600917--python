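# maprfe — stability-aware biomarker selection for microbiome case/control studies

Microbiome classifiers are easy to fit and hard to trust: 16S abundance
tables have hundreds of correlated, sparse, compositional taxa, so
recursive feature elimination (RFE) run twice on resampled versions of the
same cohort returns two different biomarker lists. `maprfe` addresses the
*stability* of the selection, not just its accuracy. It implements:

- **Similarity-kernel mapping** — before RFE, the data are transformed with
  the row-stochastic operator **P = D⁻¹(I + α(S − I))**, where S is a
  feature×feature similarity matrix (Pearson or Bray–Curtis,
  2·Σmin(A,B)/(ΣA+ΣB)) estimated on an *external unlabeled cohort* and
  α ∈ [0,1] is tuned by cross-validated MCC. Correlated taxa are smoothed
  toward each other, so the SVM spreads its weight over them instead of
  picking one arbitrarily.
- **Bootstrapped linear-SVM RFE** — B bootstrap replicates; per replicate,
  C tuned by 5-fold CV MCC, features eliminated one at a time by smallest
  |weight|, out-of-bag samples scoring the MCC-vs-k curve; rank 1 = last
  eliminated.
- **Rank-stability evaluation** — SRCC (1 − 6Σd²/(n³−n)), rank-Pearson,
  Hamming, Bray–Curtis dissimilarity and Euclidean distance averaged over
  all B(B−1)/2 replicate pairs; common-feature curves at all/66%/50%
  consistency thresholds; a noise-injection filtering score.
- **ΔMCC biomarker count** — the smallest k after which the MCC curve's
  increments stay below ε for a run of consecutive steps.
- **An 8-model classification suite** (logistic, linear SVM, random forest,
  XGBoost, perceptron, MLP-1/2/3) tuned by CV MCC and reported with MCC,
  AUC, accuracy, specificity, sensitivity, PPV, NPV at threshold 0.5.
- **Shapley explanations** of the selected panel (exact coalition
  enumeration up to 14 features, seeded permutation sampling beyond).
- **A synthetic cohort generator** (latent-Gaussian → softmax →
  multinomial, correlated feature blocks, structural zeros) so the entire
  pipeline is testable without any data download.

Inputs are TSV (samples × taxa, plus taxonomy and metadata TSVs) or
BIOM-1.0 JSON abundance tables.

## Worked example

Compare the three pipeline variants (no mapping, Pearson mapping,
Bray–Curtis mapping) on a simulated cohort with duplicated informative
feature blocks, under shared bootstrap splits:

```python
from maprfe.pipeline import RunConfig, compare_mappings

cfg = RunConfig(
    simulation=dict(n_samples=200, n_features=40, n_informative=6,
                    block_sizes=[2, 2, 2], effect_size=1.0),
    bootstraps=10, C_grid=[1.0],
    seeds=dict(simulate=7, split=1, bootstrap=2, noise=3, classify=4, explain=5),
)
print(compare_mappings(cfg).round(3).to_string(index=False))
```

```
    mapping  srcc  pearson  hamming  bray_curtis_dissimilarity  euclidean  peak_mcc  optimal_k
       none 0.249    0.249    0.973                      0.277     89.157     0.303          7
    pearson 0.133    0.133    0.968                      0.294     95.458     0.290          5
bray_curtis 0.308    0.308    0.963                      0.265     85.379     0.317         18
```

Reading the table: higher SRCC/Pearson and lower Hamming/dissimilarity/
Euclidean mean more reproducible rankings across bootstrap replicates.
Bray–Curtis mapping improves every stability index over the unmapped run
while the peak MCC of the internal-test curve is essentially unchanged
(0.317 vs 0.303) — stability without a performance cost. Pearson-based
mapping is *less* stable here, consistent with its sign-mixing rows making
P a non-convex combination.

The same stages are exposed on the command line:

```bash
maprfe simulate --n-samples 300 --n-features 80 --seed 1 --outdir sim/
maprfe rfe --abundance sim/abundance.tsv --metadata sim/metadata.tsv \
           --external sim/external.tsv --mapping braycurtis \
           --bootstraps 20 --seed 1 --outdir rfe_out/
maprfe stability --ranks rfe_out/ranks.tsv --out stability.json
maprfe run-all --config run.yaml --outdir run/
```

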