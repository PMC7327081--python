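# Methods

## Model and assumptions

The staging model assumes that tumor samples of one stage share a
collection of stage-specific co-expressed gene modules that samples of
other stages (and control tissue) lack. Operationally this becomes a
perturbation test: a reference co-expression network is frozen per
stage, and a new sample is scored by whether each edge's Pearson
correlation survives recomputation over the reference samples plus that
sample. A sample whose expression is linearly consistent with a stage's
reference cloud leaves that stage's edges intact; a sample that sits
off an edge's regression structure pulls the expanded-set correlation
down and deletes the edge from its perturbed copy of the network.

Assumptions worth making explicit:

- **Correlations are estimated on log-scale expression.** Raw-count
  matrices (detected as non-negative integer matrices with a maximum
  above 50, overridable with `assume_counts`) are converted to
  log2(CPM + 1) first; correlation on raw counts is dominated by
  library size.
- **One added sample must be able to move a correlation computed over
  the reference set.** With r reference samples, a single point
  roughly contributes weight 1/r to the correlation, so perturbation
  is informative only when the sample's displacement from the
  reference cloud is several in-group standard deviations, or when r
  is modest (the 30% reference fraction of typical stage cohorts gives
  r in the tens). This is inherent to the single-sample perturbation
  idea, not an implementation artifact.
- **Stage networks are comparable because DEG sets are balanced** to
  the same size n (the minimum across stages) before network
  construction, ranking each stage's DEGs by expression variance over
  that stage's tumor samples.

## Pipeline parameters

| Parameter | Default | Meaning |
|---|---|---|
| `logfc_cut` | 2.5 | strict lower bound on abs. log2 fold change (stage vs control) |
| `p_cut` (DE) | 0.05 | strict upper bound on the Welch-t p-value |
| `tau` | 0.7 | strict lower bound on an edge's abs. Pearson correlation |
| `p_cut` (network) | 0.05 | significance of the t transform t = ρ√(n−2)/√(1−ρ²) |
| fractions | 0.3/0.4/0.3 | reference / training / test split per stage |
| `cv_folds` × `cv_repeats` | 3 × 100 | stratified CV geometry for classifier tuning |
| `n_iterations` | 10 | independent split/train/test repetitions averaged |
| `alpha` | 0.05 | BH-adjusted enrichment call threshold |

Both cutoff comparisons are strict (`>` / `<`): a gene at log2 FC
exactly 2.5, or a pair at ρ exactly 0.7, does not pass.

## Differential expression

The built-in test is Welch's two-sample t per gene on log2-scale
values. A negative-binomial count model (edgeR and kin) is a deliberate
non-goal; instead `degs_from_table` imports any external DE table with
gene/logFC/p-value columns through the identical thresholds, so a
count-model upstream can be swapped in without touching later stages.
No multiple-testing correction is applied at this step: the DEG filter
is a screen feeding the network stage, not an inference endpoint, and
the downstream protocol is evaluated on held-out samples. Genes
constant in both groups are dropped with a log notice rather than
erroring the run.

Variance ranking for DEG balancing uses, by default, all of a stage's
tumor samples — which lets test-sample variance influence gene
selection. `strict_split=True` restricts both the DE test and the
variance ranking to reference + training samples, removing that
leakage at the cost of slightly noisier DEG calls; the default
reproduces the protocol as specified, the strict variant is the honest
alternative for method evaluation.

## Networks and perturbation vectors

Edges are all canonical (lexicographically ordered) DEG pairs with
|ρ| > tau and p < p_cut over the reference samples. The edge list
order is frozen at construction and is the positional contract of the
perturbation vector: position i of a sample's vector refers to edge i,
holding the expanded-set ρ when |ρ| stays above tau and exactly 0.0
otherwise. Design choices here:

- **The stored value is the expanded-set ρ, not the reference ρ.** The
  reference value is constant across samples and carries no
  per-sample signal.
- **Only reference edges occupy vector slots** (fixed layout).
  Pairs sub-threshold in the reference but supra-threshold after
  adding the sample are ignored by default; `layout="all-pairs"`
  semantics can be had by passing every candidate pair as node genes,
  but the fixed reference layout is what keeps feature vectors
  comparable across samples and is the default contract.
- **Significance is not re-tested on the expanded set**: edge removal
  depends only on |ρ_expanded| ≤ tau. Adding one sample changes the
  degrees of freedom by one, making a re-test nearly redundant.
- Per-gene sums and per-edge cross-products over the reference set are
  precomputed, so perturbing with one sample costs O(edges).

A layout manifest (stage, gene_a, gene_b per position) with a SHA-256
checksum travels with every feature matrix; the classifier records the
checksum at fit time and refuses to predict features built under a
different manifest.

## Classification and evaluation

Backends map the protocol's six learner families onto scikit-learn:
boosted decision trees (default; per-split feature subsampling
`max_features="sqrt"` keeps fitting fast on thousands of edge
features), bagged trees, random forest, a wider-subspace random forest
variant, extremely randomized shallow trees, and Gaussian naive Bayes.
Hyperparameters are selected by repeated stratified CV (accuracy
objective) over small per-backend grids; the winning configuration is
refit on all training data. The default grids hold one configuration
each — the repeated CV then serves as a stable training-accuracy
estimate — and any grid can be supplied explicitly.

The confusion matrix is oriented rows = predicted, columns = annotated.
Sensitivity of stage s is TP_s over its annotated column total;
specificity is one-vs-rest TN/(TN+FP); Cohen's κ uses expected
agreement from the row/column marginal products. Split rounding gives
floor(0.3 n) to reference and test and the remainder to training.
All per-iteration seeds derive from one master seed via
`numpy.random.SeedSequence`, so a protocol run is reproducible from a
single integer.

## Synthetic data

The generator plants, per stage, `modules_per_stage` disjoint gene
modules of `module_size` genes. Within its own stage's samples a
module gene follows

    x = mu + d_g * delta + lam * f + sigma * eps

with a shared per-sample module factor f ~ N(0,1), per-gene shift
direction d_g drawn from {−1, +1}, and lam = sigma·√(rho/(1−rho)) so
the population correlation of any two module genes equals `rho =
within_module_correlation` exactly. Everywhere else (other stages,
controls, non-module genes) expression is N(mu, sigma²) noise. Defaults:
300 genes, 60 samples per group, two modules of 15 genes per stage,
rho = 0.9, |delta| = 3 (log2), sigma = 0.3, baseline mu = 5.

Two defaults deserve justification:

- **Random per-gene shift directions.** Real stage-specific modules
  contain both up- and down-regulated members, and direction-mixed
  modules are what make the planted signal *perturbable*: for a gene
  pair with discordant shifts, a sample lacking the module lands
  perpendicular to the pair's correlation axis and breaks the edge,
  while concordant pairs are barely affected. A generator shifting all
  module genes identically would place off-stage samples exactly on
  every edge's correlation axis — strengthening the edges it should
  disrupt — and would misrepresent the geometry the method relies on.
- **sigma = 0.3** (log2 residual SD within a homogeneous group,
  typical of well-expressed genes) keeps the |delta| = 3 shift at ten
  in-group SDs, the strong-signal regime the staging claim is stated
  for.

`shared_modules=True` plants the *same* modules (same genes, same
shift directions) in all four stages: stage samples become identically
distributed and the dataset is a stage-uninformative null on which the
classifier must fall to chance. `as_counts=True` exponentiates to
pseudo-counts for testing the count-detection path.

What the generator does **not** emulate: negative-binomial count
dispersion, library-size variation, batch effects, correlated
module overlap between stages, tumor purity gradients, and any
within-stage heterogeneity. Passing tests therefore demonstrate that
the pipeline recovers the structure it assumes when that structure is
present and cleanly separable — not that real cohorts meet those
assumptions.

## Gene-pair enrichment

Within one regulation direction, the universe holds N = C(d, 2) pairs
of the d same-direction DEGs, K of them co-expressed; mixed-direction
co-expressed pairs are tracked but belong to neither universe. A
pathway contributes its intersection with the DEG set: n pairs, k
co-expressed. Significance is the hypergeometric upper tail
P(X ≥ k) — the point mass P(X = k) alone is not a significance level
(it vanishes for every k as N grows) and is kept only as a
`point_mass` compatibility flag. Across pathways, Benjamini–Hochberg
at alpha = 0.05 is the default call; a raw-p mode exists. A pathway
disjoint from the universe (n = 0) gets p = 1 by convention.

Stage evolution partitions the control-enriched set: *persistent*
(enriched in control and all four stages), *disappeared at s*
(enriched in control and every stage before s, absent from s onward),
and an explicit *intermittent* bucket for non-monotone patterns, so
the three classes exactly tile the control-enriched set. *Emergent*
pathways are absent in control and enriched in stages 1–2 (early)
or 3–4 (advanced); a pathway can appear in both windows.

## Numerical notes and degenerate inputs

- Correlations are clipped to [−1, 1]; |ρ| = 1 maps to p = 0.
- Constant genes: dropped from node sets (network), skipped (DE) —
  correlation against a constant vector is undefined, and
  `pearson_pcc` raises on it rather than returning NaN.
- A sample whose addition makes an edge gene constant yields an
  undefined expanded correlation; the edge is treated as lost (0.0).
- Variance ties during DEG balancing break by gene identifier;
  edge order ties cannot occur (pairs are unique).
- Missing values are never imputed; a non-finite expression cell is a
  hard error naming the gene and sample.

## Problem sizes used in the shipped checks

The test-suite and the acceptance script exercise the pipeline at desk
scale: 300 genes, 60 samples per group (100 per group for DEG/edge
recovery rates), two protocol iterations with 3-fold × 10-repeat CV,
and enumeration-based oracles up to N = 12 pair universes. These sizes
keep a full run in the minutes range on one core while leaving every
statistical conclusion (accuracy ≥ 0.9 with planted signal, chance
accuracy on the null, sub-1e-10 planted-pathway enrichment)
comfortably away from its threshold.

## Known limitations

- Welch's t on log2(CPM+1) is a pragmatic DE stand-in; for shallow
  libraries or low counts import a count-model DE table instead.
- The default protocol reproduces the variance-ranking leakage noted
  above; use `strict_split` for unbiased method assessment.
- Perturbation sensitivity decays as the reference set grows (one
  sample's influence is ~1/r); very large reference cohorts would need
  a windowed or weighted variant that is out of scope here.
- The enrichment statistic conditions on the observed DEG and CEG
  sets; it does not propagate uncertainty from those screens.
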