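# Methods

## Problem setting

Two-phase microbiome study designs profile every subject with cheap 16S
rRNA amplicon sequencing (phase 1) and carry only an informative
subsample into expensive shotgun metagenomic sequencing (phase 2). The
choice of that subsample is consequential: it determines which community
types, diversity extremes and phenotype contrasts phase 2 can see, and it
can differ depending on whether phase-1 reads were resolved into amplicon
sequence variants (ASVs) or operational taxonomic units (OTUs). This
package implements the selection strategies, the agreement analysis
between ASV- and OTU-based selections, and the differential-representation
screen used to quantify the bias each strategy introduces.

## Diversity metrics

Beta diversity between samples *i* and *j* is the Bray-Curtis
dissimilarity

    BC_ij = 1 − 2 C_ij / (S_i + S_j),

with C_ij = Σ_f min(x_if, x_jf) and S_i = Σ_f x_if. On
relative-frequency rows (S_i = S_j = 1) this reduces to
1 − Σ_f min(p_f, q_f), which the tests assert against random simplex
vectors, and it coincides with `scipy.spatial.distance.braycurtis`
(|x−y| form), used as an independent oracle.

Alpha diversity uses the Simpson family. On counts the finite-sample
Gini-Simpson index is D = 1 − Σ_f k_f(k_f−1) / (K(K−1)) (k_f organisms of
species f, K total); on relative abundances λ = Σ_f p_f² and D = 1 − λ.
The *diverse* strategy ranks by inverse Simpson 1/λ; because 1/λ and
1 − λ are both strictly decreasing in λ, the choice between them cannot
change any selection, which a test asserts. Shannon entropy
H = −Σ p ln p (natural log, 0·ln 0 := 0) is reported for summaries.

## Selection strategies

All strategies consume a relative-frequency table; samples are kept in
ascending sample-ID order and every tie breaks by that order, which makes
every method deterministic without seeds.

- **representative** — PAM k-medoids on the Bray-Curtis matrix; the k
  medoids are the subsample. PAM here is deterministic BUILD seeding
  followed by best-improvement SWAP; after single swaps converge, the
  search widens to 2- and 3-exchanges while the move count stays under a
  fixed cap (50 000), a variable-neighbourhood refinement that removes
  the rare single-swap local optima on small instances while leaving the
  classic O(k(n−k)) SWAP behaviour at cohort scale.
- **diverse** — top k by inverse Simpson.
- **extreme** — agglomerative clustering (average linkage by default) on
  the inverted dissimilarity d′ = 1 − BC; samples are enumerated in the
  order of the merge step at which each leaf first joins another cluster
  (most mutually dissimilar samples merge first under d′), and the first
  k are selected. d′ is a strictly decreasing transform of BC, so it is
  order-equivalent to the additive inverse −BC while staying
  non-negative; for single, complete and average linkage the dendrogram
  topology is identical.
- **discriminant / distinct** — for each sample, the Bray-Curtis
  distance to the arithmetic-mean composition (centroid) of the opposite
  phenotype class; discriminant takes the k smallest (ascending),
  distinct the k largest (descending).
- **pca / spca** — centered, unscaled (covariance-based) PCA of the
  samples; ⌊k/3⌋ samples from each extreme of PC1, then ⌊k/6⌋ from each
  PC2 extreme among the samples not yet selected, with any remainder
  allocated one at a time alternating PC1-top, PC1-bottom, PC2-top,
  PC2-bottom. The sparse variant uses cardinality-constrained sparse
  components: hard-thresholded power iteration (keep the `keep_count`
  largest-magnitude loadings per iteration) with projection deflation,
  initialized from the dense PCA solution and sign-aligned to it, which
  is deterministic and reduces exactly to dense PCA when `keep_count`
  equals the feature count. Default `keep_count` is ⌈0.1 · n_features⌉.
  PCA sign indeterminacy is harmless because both extremes of each axis
  are sampled symmetrically.

The ranking strategies (diverse, discriminant, distinct) are nested
across k by construction — increasing the subsample size never changes
the rank order — and the tests assert this. Representative and extreme
selections carry no such guarantee.

## Agreement analysis

Two selections over the same cohort are compared by their overlap
fraction |A∩B|/k (denominator max(k_A, k_B) when sizes differ, flagged as
asymmetric) and, for any number of labelled selections, by UpSet-style
exclusive intersection counts: each sample in the union is assigned to
the exact subset of selections containing it, so the counts partition
the union. A membership-pattern table can be exported for external UpSet
plotting.

## Differential-representation screen

The screen is the two-class core of the LEfSe procedure: a per-feature
Kruskal-Wallis rank-sum test (tie-corrected chi-square approximation,
1 df) at α = 0.05 with no multiple-testing correction (the LEfSe
convention; Benjamini-Hochberg is available behind a flag), followed by
an LDA effect size for the features that pass. For the effect size,
relative abundances are rescaled to parts-per-million (the LEfSe
convention that puts log10 effects on its familiar 0–6 scale), a fraction
(default 2/3) of samples is drawn per bootstrap round (redrawn, bounded
retries, if a class drops below two samples), a one-dimensional LDA is
fitted, and each feature's effect is

    effect_f = (|μ₁f − μ₀f| + |w_f|·|m₁ − m₀|) / 2,

the average of its raw class-mean difference and its share |w_f| of the
class separation along the unit discriminant axis (m_c the projected
class means). The reported score is log10(1 + effect) averaged over
rounds (default 30); significance requires score ≥ 2.0 (LEfSe's default
threshold, configurable since published analyses rarely state it).
Subclass (pairwise Wilcoxon) stages of full LEfSe are deliberately
omitted: the designs this package targets have a single dichotomous
class. Constant features receive p = 1 by convention. Note that the LDA
stage is only meaningful downstream of the KW screen — at ppm scale even
noise features have sizeable absolute mean differences, which is exactly
why LEfSe screens first.

## Phenotype handling

Phenotype labels are dichotomous (case/control). Samples with missing
labels are imputed to a reference class — by default "control",
reflecting the study convention that subjects without a recorded allergy
are assumed to have none — and the imputed set is recorded so downstream
analyses can exclude or sensitivity-test them.

## Synthetic cohort generator

There is no public generative model for the cohorts this design targets,
so the generator uses the field-standard Dirichlet-multinomial
construction. A base mean composition is drawn once from a uniform
Dirichlet over the simplex (giving the long-tailed rank-abundance shape
of real communities). A chosen number of affected features have their
mean multiplied by exp(±effect_log_fold) in the case class (alternating
over/under, renormalized); affected features are drawn from the
more-abundant half of the base composition, since a fold change planted
on an effectively unobserved taxon is undetectable by any method and
would only dilute power estimates. Per-sample compositions are drawn
from Dirichlet(concentration · n_features · class_mean), so
`concentration` is the mean per-feature Dirichlet weight (default 0.2,
i.e. total weight ≈ 65 for 326 features — moderate between-sample
variation). Sequencing depth is negative-binomial (mean 20 000,
dispersion 3), counts multinomial given composition and depth. The
OTU-level table sums ASV counts within a randomly drawn many-to-one
ASV→OTU map with every group non-empty, so per-sample totals are
conserved exactly — emulating how taxonomic merging degrades feature
granularity without changing library size.

Defaults (199 samples, 326 ASV-level features, 110 OTU groups, 35% case
fraction, 20 affected features at log-fold 1) mirror the scale of a
three-country infant-gut cohort. Known divergences from real data: the
synthetic communities are more even (mean Shannon ≈ 4.3 versus ≈ 1.9
typical of infant gut at this feature resolution) because the base
composition is a single uniform-Dirichlet draw; there is no phylogenetic
or taxonomic structure, no zero-inflation beyond what the
Dirichlet-multinomial produces, and no batch or longitudinal effects.
Passing tests therefore demonstrate algorithmic correctness and
statistical calibration, not that any strategy is optimal on real gut
communities.

`plant_diversity_gradient` generates samples whose symmetric-Dirichlet
concentration is linearly interpolated between `low` and `high`, so true
evenness rises with sample index; it is the harness for verifying that
diverse selection recovers planted high-evenness samples. Adjacent
samples on such a gradient are only statistically separable when the
feature count is large (the Simpson statistic concentrates) and depth
noise is small; the recovery test uses 1000 features at depth 5·10⁴.

## Numerical and design choices

- Relative-mode inference tolerance on row sums is 1e-6 (files printed
  at six decimals must round-trip); the invariant check on constructed
  relative tables is 1e-9.
- Taxonomic collapse strips rank prefixes (`g__` etc.) before comparing
  semicolon-delimited prefixes, so Silva- and Greengenes-style strings
  collapse identically; the collapse rank is a parameter because
  "identical taxonomy" depends on the rank the upstream pipeline kept.
- On-disk tables default to features-as-rows TSV (the QIIME/BIOM
  convention), with a BIOM 1.0 JSON reader (read-only). The
  distance-matrix writer uses the square lsmat-style TSV.
- Inverse Simpson of a sample whose counts are all singletons is
  infinite in the finite-sample form (D = 1); such samples rank first in
  diverse selection, which is the intended limit behaviour.
- The pipeline writes a manifest (config hash, seed, per-stage status
  and wall time, output paths) and is byte-identical under rerun with
  the same config and seed; the only stochastic stage, the LDA
  bootstrap, is driven entirely by the configured seed.
- Problem sizes in the test-suite experiments (cohorts of 24–100
  samples, 40–1000 features; 200 enumerable medoid instances; 1000 null
  features for calibration) were chosen so each property is measured
  with comfortable statistical margin on a laptop-class machine.

## Known limitations

- PAM optimality is guaranteed only where exhaustive enumeration is
  feasible; at cohort scale the variable-neighbourhood refinement never
  engages and the result is a single-swap local optimum, as in standard
  PAM.
- The original microPITA tool documents its extreme selection only
  briefly; the merge-order reading implemented here is this package's
  documented behaviour, not asserted equivalence to that tool.
- The LDA effect size follows LEfSe's published conventions but is not a
  line-for-line port; thresholds are configurable for that reason.
- Whether sparse PCA in published analyses standardized features is
  rarely stated; both variants here use the covariance (unscaled) form
  for consistency with the dense method.
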