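# Methods

`maprfe` selects microbiome biomarkers for binary case/control phenotypes
with an emphasis on *rank stability*: the property that rerunning feature
selection on a resampled cohort returns (nearly) the same ordered feature
list. This note documents the model, the defaults, the synthetic study
conditions, and the numerical choices.

## The selection model

**Bootstrapped SVM-RFE.** The training cohort is resampled with replacement
B times (default B = 100; analyses in this repository use B = 20 at desk
scale, see *Problem sizes*). Within each replicate, a linear SVM is fit on
the in-bag samples, its regularization parameter C tuned once by stratified
5-fold cross-validated MCC, and features are eliminated one at a time by
smallest absolute weight |w_j| until one remains. Reversing the elimination
order gives a rank permutation per replicate (rank 1 = most important).
Out-of-bag samples serve as the internal test set: for every k, the SVM is
refit on the top-k features and scored by MCC; the across-replicate mean
defines the MCC-vs-k curve and its argmax the optimal feature number.

**Similarity-kernel mapping.** High-dimensional abundance data make feature
selection underconstrained: strongly correlated taxa are near-exchangeable
for the classifier, so RFE picks one of them arbitrarily per replicate —
the main source of rank instability. Before RFE, the data can be
transformed with

    P = D^-1 (I + α (S − I)),      X' = X Pᵀ,

where S is a feature × feature similarity matrix (Pearson correlation or
Bray–Curtis similarity, 2·Σmin(A,B)/(ΣA+ΣB)) computed on an *external,
unlabeled* cohort (so no label information leaks into the transformation),
D re-normalizes rows, and α ∈ [0, 1] sets the mapping strength. P is
row-stochastic, so each mapped feature is a convex combination of the
features similar to it when S ≥ 0; correlated taxa are smoothed toward each
other and receive similar weights, stabilizing the elimination order. α is
tuned per replicate by 5-fold cross-validated MCC over the grid
{0.01, 0.05, 0.10, …, 1.00}; ties resolve to the smallest α (least
transformation, least information loss). α = 0 gives P = I exactly and the
implementation short-circuits the multiplication, so the mapped pipeline
with grid {0} is bit-identical to the unmapped one under shared seeds.

The matrix side of the product is a design choice (it is not forced by the
formula): we apply P to each sample's feature vector, X' = X Pᵀ, so that
row-stochasticity yields the convex-combination reading above.

**Stability evaluation.** Five indexes are averaged over all B(B−1)/2
replicate pairs of rank permutations: Spearman rank correlation in its
distinct-integer closed form 1 − 6Σd²/(n³−n), Pearson correlation of rank
vectors (identical to SRCC on permutations — used as an internal
cross-check), Hamming distance (fraction of disagreeing positions),
Bray–Curtis dissimilarity of rank vectors, and Euclidean distance. The
common-feature curve counts, for every top-r cutoff, the features present
in the top-r set of at least a threshold number of replicates (all, ~2/3,
or half of B); it is nondecreasing in r and anti-monotone in the threshold
by construction, and both laws are asserted at run time. The
noise-injection experiment appends uniform(0,1) features to the min-max
scaled data, reruns the pipeline, and reports
mean(global rank of noise) − mean(global rank of real); positive scores
mean noise is correctly demoted. "Global rank" here is the per-feature mean
rank across replicates.

**Biomarker count.** The MCC-vs-k curve typically saturates; the ΔMCC rule
returns the smallest k whose next `window` consecutive increments
|MCC(k+1) − MCC(k)| all stay below ε (defaults ε = 0.005, window = 5). A
curve that never settles returns n with an explicit warning.

**Classification suite.** Eight models are tuned by grid search maximizing
5-fold stratified CV MCC: L2 logistic regression (C ∈ 2^{−5,−3,−1,1,3,5},
lbfgs, tol 1e-4); linear SVM (squared-hinge, C ∈ 2^{−5..15 step 2}; an rbf
kernel is available behind a flag because the printed description of this
model family is self-contradictory); random forest (100 trees, Gini,
unlimited depth, min_samples_split = 2, min_samples_leaf = 2, √p features
per split); an XGBoost *regressor* (200 trees, depth 20, subsample 0.2,
colsample 0.5, min split loss 1, learning rate ∈ {0.005…0.5}, L1 α ∈
{1e-3…10}) thresholded at 0.5; a perceptron; and MLP regressors with 1–3
hidden layers of width equal to the input feature count (ReLU, LBFGS,
convergence tolerance 1e-4, learning-rate and L2 grids shared with
XGBoost). Under LBFGS the learning-rate grid entries are inert, so the
search reduces to the L2 grid with deterministic tie-breaking to the first
grid entry. LBFGS-optimized ReLU networks can initialize with every hidden
unit dead and return a constant predictor; such degenerate fits are
detected (flat training output) and retried with a reseeded initialization,
at most five times, deterministically. Metrics: MCC (zero by convention on
a degenerate denominator), AUC, accuracy, specificity, sensitivity, PPV,
NPV, all at decision threshold 0.5; AUC is reported as missing for a
single-class truth.

**Shapley explanation.** Attributions use the marginal (interventional)
value function: v(C) is the model's mean output over background rows with
the coordinates in C replaced by the explained sample's values. The exact
estimator enumerates all 2^k coalitions with the Shapley kernel weights
s!(k−1−s)!/k! and is the default up to k = 14 (the biomarker-panel scale);
beyond that a permutation-sampling estimator (unbiased, seeded) is used.
The background is fixed to the training set; the explained set may vary.
The summary ranks features by mean |attribution| (lexicographic tie-break)
with a sign direction from the correlation between feature value and
attribution.

## Preprocessing

Each cohort is processed independently: taxa are aggregated by summing
counts within identical lineages truncated at the chosen rank; taxa with
more than 99% zeros are removed (a taxon at exactly 99% is kept); counts
are transformed as y_ij = log2((x_ij + c)/g_i) with pseudocount c = the
global minimum nonzero count and g_i the geometric mean of the shifted
sample — rows sum to zero (clr property), asserted to 1e-9. When multiple
cohorts are combined, only their common features are kept. Min-max scaling
is fit on training data only; test/external values are clipped to [0, 1]
and constant features map to 0. The external cohort used for S passes the
same chain and is then restricted and ordered to the working feature set.

The pseudocount is interpreted as *global minimum nonzero count, added to
all entries*; per-sample and zeros-only variants exist in the literature,
and the global-all-entries form was chosen because it keeps the transform a
rigid translation in log space and leaves zero patterns comparable across
samples.

## Synthetic study conditions

The generator emulates the aspects of 16S data this pipeline is sensitive
to; its defaults are the study conditions used throughout the tests and the
acceptance script:

| parameter | default | meaning |
|---|---|---|
| n_samples | 300 | cohort size (cases + controls) |
| n_features | 80 | taxa after filtering |
| n_informative | 8 | features carrying the class signal |
| effect_size | 1.0 | latent log-scale shift added for cases |
| block_sizes | (2,2,2,2) | duplicated informative blocks |
| within_block_correlation | 0.8 | latent equicorrelation inside a block |
| sequencing_depth | 2000 | multinomial total per sample |
| zero_inflation | 0.05 | independent structural-zero probability |
| case_fraction | 0.5 | class balance |

Per sample, a latent Gaussian vector with block-diagonal equicorrelation is
drawn (block members share a common factor), the case effect is added to
the informative coordinates, a softmax over per-feature baselines plus the
latent vector gives a composition, counts are multinomial at the configured
depth, and entries are independently zeroed. The baselines and block layout
depend only on the config seed, so the unlabeled external cohort (drawn
with a second seed and no class effect) shares the correlation structure —
the role an external dataset plays when building S.

Sparsity is deliberately produced mostly by undersampling rare taxa at
moderate depth rather than by heavy independent zeroing: uniform structural
zeros across abundant taxa inject bimodal log-scale variance that erases
the nominal effect size, which matches neither real 16S zeros (concentrated
in rare taxa) nor the generator's contract of a class-separating
informative subset. At the defaults, overall sparsity is ≈ 11% and a linear
SVM reaches cross-validated MCC ≈ 0.5, in the range reported for real IBD
cohorts.

What the generator does *not* emulate: phylogenetic signal, batch effects
between studies, overdispersion beyond the latent Gaussian, and
presence/absence signal. Passing tests therefore demonstrate the pipeline's
statistical behavior under compositional, correlated, sparse counts — not
performance on any particular real cohort.

## Problem sizes and numerical choices

Desk-scale analyses (tests, acceptance script) use B = 20 bootstrap
replicates, 80-feature cohorts, and a single C = 1 for the RFE SVM; the
full C grid and B = 100 remain the library defaults for real use. These
sizes keep a complete two-pipeline comparison (with α tuning inside every
replicate) to a few minutes while leaving all structural conclusions
unchanged.

Tie-breaks are fixed and deterministic throughout: equal |weight| during
elimination removes the feature later in the current ordering; equal mean
MCC prefers smaller k; equal global rank orders by feature id; equal
grid-search scores keep the earlier grid entry; equal α keeps the smaller
α. Degenerate cases: Pearson similarity of an exactly-constant feature is 0
off-diagonal (not NaN, detected by max = min rather than a std tolerance);
Bray–Curtis similarity of two all-zero features is 1 and of a zero vs
nonzero feature is 0; a vanishing row sum in I + α(S − I) (possible with
strongly negative Pearson entries) raises an error naming the feature.
Bootstrap draws are redrawn (≤ 100 times) until both classes appear in-bag
and out-of-bag. The noise-injection experiment extends S with an identity
block for the injected features — uniform noise is uncorrelated with
everything in expectation, and the external cohort cannot supply those rows.

## Known limitations

- The MCC-vs-k curve refits one SVM per (replicate, k); cost grows
  quadratically with the feature count. The curve can be skipped when only
  ranks are needed (the noise experiment does).
- Stability indexes compare full rank permutations; they do not weight the
  top of the list more heavily.
- The external-similarity fallback (when the external cohort's own
  prevalence filter removes a working feature) recomputes the transform on
  the unfiltered cohort, which slightly changes the pseudocount.
- Shapley sampling error is O(1/√permutations) per feature; the default
  2,000 permutations targets ~0.05 absolute error at biomarker scale.
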