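# Methods

This note documents the models, conventions and design choices behind
floramorph: what each statistic assumes, which defaults matter, what the
synthetic-data generator does and does not emulate, and the numerical
details a user reproducing or extending the analysis needs.

## Mean character difference

The dissimilarity between two taxa is the mean of per-character differences
over the characters scored in both (*N*′). Conventions:

* **Normalisation is dataset-relative.** Numeric ranges and ordered step
  maxima are recomputed from the observed, resolved, log-transformed matrix
  of each analysis run. Adding or removing taxa therefore changes the
  normalisation of every numeric/ordered character; this is intentional
  (distances are meaningful within one dataset, not across datasets) and is
  why the fossil analysis re-resolves and re-normalises over the enlarged
  taxon set.
* **Binary/unordered characters** contribute 0 when the states match and 1
  otherwise; state comparison is exact string equality after
  whitespace/case normalisation.
* **Constant characters** (zero observed range) contribute 0 for every
  pair; a zero range with differing values is impossible by construction
  and raises an internal error rather than silently dividing by zero.
* **Missing data** shrink *N*′ per pair. A pair with *N*′ = 0 is carried as
  NaN (undefined), never as 0. Every downstream statistic documents its
  masking: group disparity and Dchar drop undefined entries, ordination
  refuses matrices containing them (the caller drops the offending taxa),
  the Mantel test masks a pair in both matrices when it is undefined in
  either, and the module test drops pairs with no applicable character in a
  given subset.
* **Polymorphic cells** (sets like `red|white`, inclusive integer ranges
  like `4-6`) are resolved by a uniform seeded draw before analysis.
  Integer-set semantics for ranges reflect that organ counts are integers.
  At the ~2% polymorphism rate of the emulated dataset, re-resolution with
  another seed perturbs downstream statistics well below their Monte-Carlo
  error.
* **Log transforms** (natural log) apply to flagged heavy-tailed counts.
  The base is irrelevant downstream because range normalisation cancels it;
  non-positive values on a flagged character are a hard error.

## Ordination

Classical PCoA: Gower double-centring of −½*D*², symmetric
eigendecomposition, coordinates scaled by √λ on axes with λ above a
relative tolerance of 1e−9 × max|λ|. Mean-character-difference matrices are
generally non-Euclidean, so negative eigenvalues occur; they are dropped
without Cailliez/Lingoes correction (matching common practice and keeping
axis variance shares interpretable as fractions of the positive spectrum),
and their absolute mass is reported so the user can judge the distortion.
Axis signs follow the convention that each axis's largest-magnitude
coordinate is positive. Embedding fidelity is the Pearson correlation
between the original dissimilarities and the Euclidean distances among the
first *k* coordinates, over all pairs; it is non-decreasing in *k*.

## Disparity statistics

* **D̄** (mean within-group pairwise dissimilarity) is size-robust and is
  the primary per-group statistic; groups of fewer than two taxa are
  undefined.
* **R** (within-group maximum) grows with sample size, so it is also
  reported rarefied: the mean of the maxima over 1000 subsamples of 10 taxa
  drawn without replacement (10 being the emulated study's minimum workable
  group size); groups of ≤ 10 taxa keep their plain R. 1000 replicates put
  the Monte-Carlo s.e. of the rarefied R well below the bootstrap s.e. of
  the statistic itself.
* **Bootstrap standard errors** resample taxa with replacement (1000
  replicates); self-pairs arising from duplicated draws are excluded, which
  makes the s.e. of a degenerate constant statistic exactly 0.
* **Partial disparity** follows Foote's additive decomposition over all
  positive PCoA axes: summed squared coordinates of a group's members
  divided by total taxon count (the grand centroid is the origin after
  centring). Using all positive axes — the obvious alternative would be a
  fixed axis cutoff — is what makes group contributions sum exactly
  (to < 1e−10) to total disparity.

## Permutation tests

PERMANOVA uses the standard partition of squared dissimilarities
(SS_within per group scaled by 1/n_g) and the pseudo-*F* with (a − 1,
N − a) degrees of freedom, permuting group labels; p-values use the
(#extreme + 1)/(n_perm + 1) convention so p is never 0. Defaults: 10 000
permutations for the overall test (the emulated study's choice), Bonferroni
min(1, p × n_pairs) for the pairwise post hoc. Both PERMANOVA and the
Mantel test also support exhaustive enumeration of all distinct label
arrangements (used for exact-p verification at small N; the identity
arrangement is included and no +1 correction is applied, so the p is
exact). The Mantel correlation is Pearson's r over defined pairs with 999
permutations by default, one-sided toward positive association — the
question asked of it here is whether module disparity *increases* with
whole-flower disparity; a two-sided alternative is available. Disparity
against clade attributes (species richness, stem age) uses classical
two-sided Spearman tests on per-family statistics.

## Module-comparison test

Character sets of different sizes cannot be compared by D̄ directly, so a
module with *k* characters is compared against D̄ computed on random
*k*-subsets drawn without replacement from the full character set (1000
subsets), the module's own characters included in the pool — the null is
"a generic subset of this flower's characters", not "the complement". The
tail (higher/lower) is chosen by the side of the null median the
observation falls on; the reported pseudo *p* is the fraction of null
values at least as extreme as the observation plus 0.025, so the two-tailed
decision at the 97.5th/2.5th percentile matches the usual 0.05 threshold
and p is floored at 0.025. Ties between null values and the observation
count as extreme; consequently a degenerate module containing every
character yields the maximal pseudo-p rather than the floor. At 1000
subsets the Monte-Carlo s.e. of a p near 0.05 is about 0.007.

## Synthetic-data generator

Each taxon × character cell derives from a latent Gaussian
*z* = *s*·(divergence·(clade + family effect) + σ_family·noise), with the
per-module multiplier *s* scaling the whole latent value. Latent values are
cut into categorical states by thresholds fixed at the nominal latent
standard deviation, with baseline state frequencies skewed toward a modal
state (modal frequency ≈ 0.7, minor binary states 5–20%) — the regime
typical of morphology matrices, where most taxa share a common state.
Because the thresholds are fixed, a multiplier > 1 widens the latent
distribution and balances the states (raising per-character differences and
state entropy) while < 1 concentrates them; the effect is monotone but
saturates at the uniform-state ceiling, which is why deflated modules are
easier to detect than inflated ones. Ordinary counts map through the latent
CDF (1–10) so they respond to the same dial; the two heavy-tailed,
log-flagged counts are exponential in *z* (1 to several hundred) and, after
the log transform, are deliberately scale-invariant to the dial.

Default conditions mirror the emulated dataset: 22 families (sample sizes
2–55, totalling 381) in 10 clades, 9 fossils, 37 characters in the 5/12/13/7
module split with two log-flagged counts, 13.4% missing cells (MCAR; 10.5%
for fossils), 2.2% polymorphic cells, family divergence 1.0, module
multipliers 0.7 (perianth), 1.4 (androecium), 1.0 elsewhere — producing the
depressed-perianth / inflated-androecium / neutral-gynoecium regime.
Family species richness is tied loosely to sample size and within-family
latent spread rises mildly with log richness (slope 0.3), producing a
positive disparity–richness correlation; stem ages are drawn uniformly on
60–110 Ma and uncorrelated with anything. Fossils draw their own latent
effects, shrunk toward the global centroid by the centrality parameter
(default 0.8), so they contribute near-minimal partial disparity.

What the generator does **not** emulate: phylogenetic character evolution
(no tree; family/clade effects are exchangeable draws), character
correlations beyond shared group structure (real matrices have more, which
is why the synthetic PCoA spreads variance across more axes than a real
dataset would), informative missingness, and any specific real character's
state distribution. Passing tests therefore demonstrate correctness of the
statistics and recoverability of known effects, not biological realism of
any particular number.

## Problem sizes and determinism

The test suite runs entirely on synthetic data: calibration checks use 500
null simulations per test (small matrices, 199–400 permutations/iterations
each), parameter-recovery checks use 3 divergence levels × 20 replicates
and 50 power replicates (androecium multiplier 2.5, six families of eight
taxa — a strong known effect detected in ≥ 80% of replicates). The
acceptance script runs the full study-scale pipeline (381 + 9 taxa, 10 000
PERMANOVA permutations, 999 Mantel permutations, 1000 module-test subsets,
1000 rarefaction/bootstrap replicates). One run seed fans out to named
per-stage child seeds (SHA-256 of seed:stage, reduced below 2³¹), so stages
are independently reproducible and toggling the fossil analysis leaves
extant-only results bit-identical.

## Known limitations

* Undefined pairs are handled by masking, not imputation; datasets much
  sparser than ~15% missing can leave subsets (especially small modules)
  with many masked pairs, and the module test's per-subset masking then
  makes null values slightly heteroscedastic.
* The rarefied-R bootstrap draws one subsample per bootstrap replicate, a
  noisy but unbiased s.e. estimator; increase replicates if the s.e. itself
  is of interest.
* PERMANOVA permutes labels freely (exchangeability under the null); no
  restricted permutation schemes (e.g. within-clade) are provided.
* The exhaustive permutation modes enumerate label arrangements and are
  only practical below ~10 taxa.
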