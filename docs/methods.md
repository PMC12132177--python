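# Methods

## Model

The predictor treats expression imputation as a regression over
(subject, gene, tissue) triples. Its input concatenates three
representations:

1. **Tissue embedding.** The tissue ontology is an undirected rooted tree;
   all nodes (internal and leaf) participate in a graph-convolutional
   stack with one-hot input features, H₀ = I and
   H_{k+1} = ReLU(Â H_k W_k), the last layer linear. The operator is the
   symmetric-normalized adjacency with self loops,
   Â = D^{-1/2}(A + I)D^{-1/2}, whose spectrum lies in [−1, 1]; this is the
   standard first-order graph-convolution propagation rule. Only leaf
   embeddings feed the predictor, but internal nodes shape them — that is
   the point of using the hierarchy. Default: 2 layers, widths (64, 32).

2. **Gene embedding.** Pretrained so that ρ(e_g, e_h), the Pearson
   correlation across embedding coordinates, approximates ρ(x_g, x_h), the
   correlation of the two genes' expression across atlas leaf tissues,
   averaged over atlas subjects (subjects are cycled round-robin over
   optimization steps; gene pairs are sampled uniformly). The loss is the
   squared difference per pair; the optimizer is Adam (lr 1e-3). Genes
   with zero across-tissue variance for a subject are skipped for that
   subject with a logged warning. The embedding is frozen after
   pretraining. Default width 32 at desk scale (configurable; correlation
   needs ≥ 2 coordinates).

3. **Subject profile.** The gene's expression across the composite
   (coarse) tissues: all composites for the base model, all but the target
   for the extended per-composite models. Atlas subjects have no measured
   composite profile, so theirs is constructed by averaging each
   composite's subordinate leaves — the only construction consistent with
   the input contract.

The MLP applies two blocks of ReLU hidden layers then a linear scalar
head; the desk-scale default is (128, 64) + (32, 16). Loss is mean squared
error over minibatches of 1024 triples, shuffled per epoch with the run
seed, optimized with Adam. Fine-tuning on cohort composite values updates
all trainable weights (graph stack + MLP) at a 10× lower learning rate and
propagates gradients through the leaf-averaging that defines a composite
prediction. The per-composite extended models are trained independently of
the base model and of each other.

All numerics are plain numpy with hand-derived gradients; identical seed
and configuration reproduce bitwise-identical weights.

## Two-step imputation

A subject profile with one missing composite goes straight to that
composite's extended model. With several missing, for each target
composite the *other* missing slots are first filled by per-gene
ordinary-least-squares models fitted on the complete-profile cohort
subjects (predictors = exactly the observed composites; fits are cached
per (target, predictor-subset) because the subset lattice is
combinatorial; a rank-deficient design falls back to ridge with penalty
1e-6), then the extended model predicts the target's subordinate leaves
and averages them. Observed entries are never altered. Subjects with fewer
than 5 observed composites are refused by default (configurable, with an
explicit override flag).

## Evaluation statistics

- **Per-gene Spearman** between predicted and held-out expression across
  subjects; ties by average rank; constant vectors yield NaN and are
  excluded from summaries but counted.
- **Differential stability (DS)**: per gene, the mean over unordered
  subject pairs of the Pearson correlation between the two subjects'
  across-tissue vectors. Zero-variance vectors skip the pair (reported);
  the score is invariant to per-subject positive-scale affine transforms.
- **ARI** between gene-module partitions, with a label-permutation null:
  the first partition's labels are shuffled over genes (module sizes
  preserved by construction) and the add-one estimator
  p = (1 + #{perm ≥ obs}) / (1 + n_perm) keeps p > 0. Identical trivial
  partitions score 1 by the degenerate-denominator convention. A
  convenience partition generator (average linkage on 1 − |Pearson| with a
  fixed cluster count) exists only to produce test inputs; it is not a
  weighted co-expression network analysis.

## Genetic downstream chain

- **cis-eQTL scan**: per (gene, cis-variant) additive OLS with t-test
  nominal p, plus a per-gene min-p permutation p (expression shuffled
  across subjects, add-one estimator). This deliberately reimplements the
  testing logic, not production eQTL software: no adaptive permutations or
  beta-approximated tails. Monomorphic variants are skipped and counted.
- **LD clumping**: greedy best-p lead selection, removing variants within
  the window (default 10,000 kb) with dosage r² > 0.001; r² comes from the
  analysis cohort itself, not an external panel. Ties break by variant id.
- **Sharing statistics**: the reference tissue is the one with maximum
  |β|; sharing by sign counts tissues matching its sign (zero = not
  shared); sharing by magnitude additionally requires |β| within a factor
  of two. The pairwise matrix applies the magnitude rule per tissue pair.
- **Wald-ratio MR**: β_outcome / β_exposure with first-order delta-method
  SE (|se_outcome / β_exposure|; exposure uncertainty ignored) and normal
  p. Allele harmonization is forward-strand-only: swapped effect/other
  alleles negate the outcome beta, incompatible allele sets drop the
  record, palindromic pairs pass with a warning.
- **FDR**: Benjamini–Hochberg applied once across the full
  variant × tissue × trait family.
- **Colocalization**: per-variant Wakefield log-ABFs with prior effect SD
  0.15 (quantitative) / 0.2 (binary), evidence sums for the five causal
  configurations (the two-distinct-variants term computed in log space as
  S₁S₂ − Σᵢ ABF₁ᵢABF₂ᵢ), combined with two prior settings — fixed
  (p1 = p2 = 1e-4, p12 = 1e-5) and region-size (p1 = p2 = 1/n_variants,
  p12 = p1/10). A region colocalizes when either setting gives PP4 > 0.7.
  Regions are 100 kb windows centered on the lead variant.
- **Overlap / enrichment**: gene-set overlap uses the exact upper-tail
  hypergeometric probability computed in log space; trait-by-region
  enrichment uses a one-sided Fisher exact test on the collapsed 2×2 table
  (a deliberate simplification — the stratified alternative is not
  implemented).

## Synthetic data: what it emulates and what it does not

The generators plant exactly the structures the evaluations measure, and
nothing else:

- per-gene tissue archetypes evolve by Brownian motion along the ontology
  tree (child = parent + N(0, step²)), giving tree-local tissue
  correlation;
- each gene mixes the shared archetype with an independent per-subject
  Brownian pattern via a stability weight ρ_g ∈ [0, 1], so DS is planted
  and recoverable;
- per-(subject, gene) scalar shifts create cross-subject signal that any
  imputer should recover; independent Gaussian noise is added on top;
- genotypes are LD blocks copied from latent haplotype pairs with
  per-haplotype flip probability; GWAS summary statistics are marginal OLS
  on a simulated phenotype with planted causal variants, shared or not
  with the eQTL variant.

Defaults (chosen once as a realistic desk scale): depth-4 binary tree (16
leaves, 31 nodes) with 6 composites, 6 atlas subjects, 40 cohort subjects,
200 genes, 500 variants, archetype and subject Brownian step 0.5, subject
signal weight 0.5, noise SD 0.3, ρ_g ~ U[0, 1]. Binary traits are
simulated with quantitative machinery and only labelled binary (their
coloc prior SD differs); microarray noise, realistic allele-frequency
spectra and reference-panel LD are not modelled. Passing tests therefore
demonstrate that the implementation recovers the structures it assumes —
not that those assumptions hold in any particular real data set.

## Numerical choices and degenerate inputs

Quantile normalization uses the mean of order statistics pooled across
genes as the reference; genes with fewer observed cells (missing tissues)
draw from it by linear interpolation of the quantile function; ties
receive the mean of their reference values; constant genes collapse to the
reference mean; all-missing genes are skipped with a warning. The
operation is idempotent to floating tolerance. Expression TSV readers use
round-trip float parsing so write/read cycles are bit-exact. Weight
initialization is He-scaled Gaussian from the run seed; stage seeds in the
pipeline are derived by hashing (global seed, stage name).

## Problem sizes

The test suite and the acceptance script run the full study at the
generator defaults above, with embedding width 32 (120 pretraining steps),
graph stack (64, 32), MLP (128, 64, 32, 16), and 25 + 10 training epochs —
sizes chosen so a complete run takes well under a minute on one CPU while
every recovery margin stays wide. All widths, depths and epoch counts are
configuration parameters.

## Known limitations

Single-instrument MR only (no multi-SNP estimators or Steiger filtering);
single-causal-variant coloc (no fine-mapping-based multi-signal variant);
no cross-build coordinate conversion — all inputs must share one genome
build; the extended models share no weights with the base model; the
hierarchical ontology is assumed correct and fixed.
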