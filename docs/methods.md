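# Methods

This note documents the statistical procedures implemented in `micropat`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Statistical primitives (`micropat.stats`)

* **Fisher exact test** — two-sided by the probability-mass convention: the
  p-value sums hypergeometric probabilities (fixed margins) of all tables at
  most as probable as the observed one. Delegated to
  `scipy.stats.fisher_exact`; the test suite checks it against exhaustive
  enumeration on all tables with total ≤ 40.
* **BH FDR** — Benjamini–Hochberg step-up (`statsmodels.multipletests`),
  applied within each analysis family separately (per arm for maturation,
  across BGCs per run, across pathways, across support edges), never pooled
  across stages.
* **clr transform** — `clr(x)_i = ln x_i − mean_j ln x_j`. A pseudocount
  (default 0.5) is added to every entry *only when the vector contains
  zeros*, so zero-free compositions are transformed exactly. The transform is
  scale-invariant and its output sums to zero.
* **Median-of-ratios normalization** — per-sample size factors as the median
  ratio of each gene's count to that gene's geometric mean across samples,
  restricted to genes with no zero anywhere; factors are centered to
  geometric mean 1. This is a deterministic normalization for count panels
  in the DESeq2 family of size-factor estimators.
* **Empirical p-values** — `p = (1 + #{|null| ≥ |obs|}) / (B + 1)`. The +1
  correction keeps p in (0, 1] and is the standard bias-avoiding estimator
  for resampling tests.

## BGC presence calling (`micropat.bgc`)

The Lander–Waterman model treats shotgun reads as a Poisson process along the
reference, giving the probability a base is covered at least once as
`E = 1 − exp(−N·L_read/L_BGC)`. "Actual coverage" is interpreted as breadth
(fraction of bases covered ≥ 1×), the only reading under which the ratio
against a coverage *probability* is dimensionally coherent. A cluster is
present when breadth/E ≥ 0.75 (inclusive); pairs with no reads have E = 0
and are defined absent (ratio 0). Missing (sample, BGC) coverage rows are
imputed as zero reads and the imputation count is logged, since sparse
aligner outputs omit empty rows.

Enrichment builds one 2×2 table per BGC (treatment × presence), tests it
two-sided, and BH-corrects across *all* tested BGCs, including degenerate
all-present/all-absent ones (p = 1), for reproducible multiplicity
accounting. Direction is the group with the higher presence frequency,
reported only when q < 0.15.

Homology collapsing uses average-linkage agglomeration on 1 − similarity,
cut where linkage similarity falls below the threshold (default 0.5).
Similarity defaults to the Jaccard index of ORF-family sets; an external
amino-acid-identity matrix can be supplied instead, since sequence alignment
itself is out of scope. BGCs are processed in lexicographic id order so ties
break deterministically.

A note on the coverage formula: the expected-coverage expression is
sometimes printed without the minus sign in the exponent; as a probability
it requires the negative exponent, which is what this package computes.

## Maturation classification (`micropat.maturation`)

Within each arm, samples from both timepoints are normalized together
(median-of-ratios; a unit pseudocount is added only if no gene is usable),
log2(x+1)-transformed, and each gene tested t0 vs t1 with Welch's t-test;
BH runs across genes within the arm and a gene's direction is the sign of
its log2 fold-change when q < α (default 0.05).

The five primary classes form a partition: III (both arms significant, same
direction), IV (both arms significant, opposite directions), I_only
(control only), V (perturbed arm only), NC (neither). Because the
traditional classes I ("maturing in control") and II ("maturing under
perturbation") overlap III–V, they are emitted as marginal flags
(`marginal_I`, `marginal_II`) rather than bins; `marginal_II` always equals
III + IV + V. "Altered maturation" (IV) is operationalized as opposite
significant directions — direction is the only attribute the two-arm test
encodes, so a same-direction magnitude change falls in III. Normalization is
per-arm to mirror the arm-wise testing.

Pathway over-representation tests each gene set with a 2×2 table (class
membership × set membership over the panel universe), two-sided Fisher and
BH across pathways. Two-sided p-values mean depletion can also yield small
p; the `significant` flag does not distinguish the two, but the overlap
column does.

## Association networks (`micropat.network`)

1. **Filtering** — taxa are kept when their overall mean relative abundance
   exceeds 0.01% (strict inequality) and they are present in at least one
   sample.
2. **Transforms** — clr per sample for taxa; median-of-ratios + log2(x+1)
   for expression.
3. **Variance decomposition** — within-cell centering over the sex ×
   treatment strata removes between-cell differences and keeps within-cell
   variation. With one sample per mouse per timepoint, mouse-level centering
   would zero the data, so the stratum is the finest usable grouping.
   Singleton strata are rejected. The operation is idempotent.
4. **Sparse PLS** — components are extracted from the empirical
   cross-covariance `M = X'Y/(n−1)` by alternating soft-thresholded power
   iterations (penalized-matrix-decomposition style): starting from the
   dense leading right singular vector, each half-step soft-thresholds the
   raw weight vector at `λ · max|weight|` on that side and renormalizes,
   iterating to a fixed sparse pair (w, c). The component score t = Xw is
   projected out of both blocks (W2A deflation) and the procedure repeats
   for K components, with K defaulting to the number of singular values of
   M above 1e-8 of the largest. Coefficients follow the classical PLS2
   formula `B = W(P'W)⁻¹C'`, masked to the union of the per-component
   supports `supp(w_k) × supp(c_k)`, so the nonzero pattern is edge-sparse
   on both sides. λ is a fraction in [0, 1]: λ = 0 is the dense model
   (reaching ordinary least squares predictions at full K), λ ≥ 1 the empty
   one.

   Thresholding both weight vectors, rather than the taxa side alone, is a
   deliberate choice: one-sided sparsity yields a row-dense coefficient
   support (every gene attached to each selected taxon), which carries no
   edge-level information for stability selection or FDR control. The
   alternating iterations also make the selected support far more stable
   under subsampling than single-shot thresholding of a mixed singular
   vector. One consequence is that the support is only *approximately*
   nested along λ: the deflation path can switch components as λ moves,
   producing occasional one-to-two-edge violations of monotonicity.
5. **StARS** — for each of 50 stratified subsamples of size
   `min(⌊10√n⌋, ⌊0.8n⌋)` (without replacement) and each λ on a decreasing
   grid starting at the empty model (default 20 points from 1.0 to 0.05),
   the support is recorded. With θ the per-edge selection frequency, the
   instability `D(λ) = mean over all p·q candidate edges of 2θ(1−θ)` is
   monotonized by a running supremum from the sparsest end, and the densest
   λ with monotonized D ≤ β (default 0.05, the original StARS default) is
   selected; if none qualifies the sparsest λ is used.
6. **Bootstrap significance** — B resamples (default 5000; a 500-resample
   smoke profile is used in the test suite) drawn with replacement within
   each stratum to preserve the design; the model is refit at the selected
   λ on each resample. Each support edge's null reference is its bootstrap
   coefficient distribution recentred at zero — the standard bootstrap-test
   construction, chosen because the notion of "empirical p-value" needs an
   explicit null. BH runs across support edges; edges with q < 0.05 are the
   reported network. StARS is not refit inside the bootstrap (the selected
   λ is reused).
7. **Export** — a bipartite graph: taxon nodes carry mean relative
   abundance and family annotation, edges carry coefficient, sign
   (positive/negative association), empirical p, q, and width
   `−log10(empirical p)`. Node and edge insertion order is sorted, so
   GraphML output is byte-identical across runs on identical inputs.

## Synthetic data (`micropat.synthetic`)

The generators reproduce the statistical structure the analyses assume, at
the study's design scale: a 2 (sex) × 2 (treatment) crossing with one sample
per mouse per postnatal-day timepoint (6 mice per cell by default for the
metagenomics arm, 8 for the expression panel, 12 for the network stage).

* **Taxa counts** — Dirichlet-multinomial around log-normal baseline
  proportions (overdispersion 0.005 ≈ concentration 200, in the range real
  16S data show) with 4 over- and 4 under-represented taxa in the perturbed
  group at ±2 log2 units, renormalized; row sums equal the sequencing depth
  (50 000) exactly.
* **Expression counts** — negative binomial (dispersion 0.05, NanoString-like
  panel of 547 genes, log-normal baseline means) with planted classes
  30/30/20/20 of I_only/III/IV/V shifting means by ±2 log2 units between the
  timepoints in the arms each class prescribes. Class II is not planted
  separately: it is by definition the union III ∪ IV ∪ V.
* **BGC reference** — groups share a 9-family ORF core plus one private
  family per member (within-group Jaccard 9/11 ≈ 0.82), with disjoint family
  pools across groups (between-group Jaccard 0), bracketing the ≥ 0.8 / ≤ 0.2
  homology contrast the clustering tests rely on.
* **Read coverage** — uniform read starts clipped at the 3′ end (a read at
  least as long as the cluster covers it entirely). Because the closed-form
  coverage probability assumes an effectively infinite reference, agreement
  tests use `L_read/L_BGC ≤ 0.01`, where edge effects are below the test
  tolerance.
* **Paired taxa–gene data** — row-centered Gaussian latent taxa signals
  (so the clr of the exported composition recovers them exactly up to
  multinomial noise), gene responses through a sparse coefficient matrix
  (25 edges of magnitude 1, random signs) plus sex × treatment offsets
  (sd 0.5) and Gaussian noise (sd 0.5); taxa exported as multinomial counts
  of the softmax composition, genes as exponentiated counts.

What the generators do **not** emulate: phylogenetic correlation between
taxa, sequencing error and mapping ambiguity, batch effects, library-size
variation beyond the size-factor model, zero inflation beyond the
compositional sampling, and longitudinal within-mouse correlation. Passing
recovery tests therefore demonstrate correctness of the inference machinery
under the stated model, not robustness to every artifact of real data.

## Numerical choices

* Singular values are called nonzero above 1e-8 of the largest; coefficient
  support above 1e-12 absolute.
* Fisher ties are resolved with a 1e-7 relative tolerance (inside scipy).
* Degenerate Welch inputs (both groups zero-variance) return p = 1 on a tie
  and p = 0 otherwise, rather than NaN.
* Clustering tie-breaks: BGCs sorted lexicographically before linkage.
* One master seed fans out to all subsample and bootstrap streams through
  `numpy.random.default_rng`; every generator is bit-reproducible given
  (parameters, seed).

## Problem sizes used in the test suite

The acceptance-style checks run 20 seeds for maturation recovery (547 genes,
8 mice per cell), 20 seeds for network recovery with the 500-resample
bootstrap smoke profile, 5 null network seeds, and 4 null datasets
(~2580 pooled edge tests) for p-value calibration; the read-coverage law is
checked over 200 replicates and the Fisher oracle over 500 random tables.
These sizes give Monte-Carlo error comfortably below the test tolerances.

## Known limitations

* The sPLS variant is one of several defensible ones (deflation scheme and
  the sides carrying sparsity differ across the literature); conclusions
  about exact coefficient values should not be ported across variants.
* The bootstrap p-value floor is 1/(B+1); with the 500-resample smoke
  profile, BH at 0.05 cannot discriminate below ~0.002, which matters when
  the support is large.
* StARS instability is averaged over all candidate edges; with small
  taxa × gene panels the default β = 0.05 is a meaningfully stricter
  constraint than in the large graphical-model settings StARS came from.
* The maturation classifier handles exactly two timepoints; time-course
  models are out of scope.
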