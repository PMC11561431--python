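# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing
results.

## Data model and harmonization

The unit of analysis is a complete questionnaire response: 5-point Likert
items (stored as integers 1..5 after harmonization, 1 = most favorable),
categorical demographics, and one ordered intention item.  A codebook
declares each item's role (`predictor`, `outcome`, `followup`,
`demographic`), scale, and reverse-coding flag; reverse-coded items are
mapped `v → 6 − v` on input (an involution, so applying the codebook twice
is safe).  Missing data are handled by complete-case analysis: respondents
missing any predictor, demographic or outcome value are dropped and
counted, never imputed — this matches how cross-sectional panel studies of
this kind typically report "completers".  Follow-up items are exempt from
the completeness requirement because they are routed to a subset of
respondents (here: those with a positive intention); including them would
delete the entire complementary group.

The intention outcome is dichotomized as positive = {very willing,
willing} (harmonized codes 1–2) versus neutral/negative = {neutral,
unwilling, very unwilling}.  Standard deviations use the sample (n−1)
convention throughout.

## Importance screening

A random-forest classifier predicts the dichotomized intention from all
predictor and demographic columns (Likert items as numeric 1..5,
demographics one-hot).  The ensemble is built explicitly: each of
`n_trees` trees (default 1000, minimum 100) is a CART tree grown without
depth limit on a bootstrap resample, considering ⌊√p⌋ candidate predictors
per split.  Rows not drawn into a tree's bootstrap are its out-of-bag
(OOB) set, which serves two purposes:

* **Performance** — each respondent is classified by majority vote of the
  trees for which they are OOB (vote ties go to neutral/negative).  pmc
  (probability of misclassification), sensitivity and specificity come
  from the resulting confusion counts, so the identity
  `pmc = prev·(1−sens) + (1−prev)·(1−spec)` holds exactly; AUC is computed
  from the OOB vote fractions.
* **Importance** — for each tree and predictor, the OOB error is
  recomputed after permuting that predictor's OOB values; the importance
  is the mean increase over trees, in pmc units (unscaled — not divided by
  its standard error).  Ties in the resulting ranking break by item id
  ascending.

Determinants are the top-`top_k` ranked predictors (default 20).  The
"elbow" (largest relative importance drop) is reported as advisory output
but never applied automatically, since the visual cut of an importance
ranking is a judgment call.

## Clustering of determinants

Item dissimilarity is `D = 1 − |ρ|` with ρ the Spearman rank correlation
using midranks for ties (Likert data is heavily tied; midranks are the
standard convention).  The absolute value makes strongly anti-correlated
items maximally similar; after harmonization this is rarely triggered, but
it is a real property of the measure: an item and its mirror have `D = 0`.
Constant items are rejected with an error naming the item (ρ undefined).

Agglomeration is average linkage (UPGMA), written out explicitly with the
Lance–Williams update so that the tie-break is deterministic: among
candidate pairs at the same minimal average dissimilarity, the pair whose
combined sorted member-id tuple is lexicographically smallest merges
first.  The implementation is cross-checked in the tests against both
scipy's average linkage (merge heights, cophenetic distances) and a
brute-force oracle that recomputes every pairwise average at every step.
Average linkage heights are monotone for reducible dissimilarities; the
dendrogram asserts monotonicity and emits a warning rather than silently
reordering if it is ever violated.

Cutting the tree at k uses the first p−k merges, which guarantees that
partitions at successive k are nested.  For each cut, from the *original*
dissimilarity matrix (not the cophenetic distances):

* compactness(k) = max within-cluster D (singletons contribute nothing),
* separation(k)  = min between-cluster D,

and the chosen k minimizes the signed difference
`compactness(k) − separation(k)` over k = 2..p−1, ties toward smaller k.
A good cut has tight clusters (small compactness) far apart (large
separation), i.e. the difference as negative as possible; degenerate cuts
(splitting a tight block, or fusing two distant blocks) push the two
quantities together.  Clustering quality overall is summarized by the
cophenetic correlation coefficient (Pearson correlation between the
p(p−1)/2 raw and tree-implied distances; 1 for an ultrametric input).

Per-cluster profiles report the member list, `mean_clus`/`sd_clus` (mean
and SD over respondents of the per-respondent mean of member items) and
`rho_clus` (mean pairwise Spearman ρ among members; omitted for
singletons).  Cluster *naming* is a human judgment and out of scope: the
package emits member lists only.

## Change potential

For each determinant and each cluster (cluster score = per-respondent mean
of member items):

* Cohen's `d = (mean_neutral/negative − mean_positive) / s_pooled`, pooled
  SD `√(((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2))`.  The sign convention makes d
  positive when positive-intention respondents score more favorably
  (lower).  The 95% CI uses the Hedges–Olkin normal approximation
  `SE(d) = √(1/n₁ + 1/n₂ + d²/(2(n₁+n₂)))` — at n ≈ 3000 the difference
  from an exact noncentral-t interval is negligible.
* Group-mean CIs are t-based.
* `PCI = |1 − mean| · d²`, computed from the full-sample mean.  Reported
  tables round to 2 decimals; machine output keeps full precision, and
  every emitted record satisfies the identity to 1e-12 by construction.

CIBER-style plots show, per entity, the jittered score distribution
colored by intention group with both group-mean CIs (left panel) and the
CI of d (right panel); item-level plots are ordered by the importance
ranking, cluster-level plots by dendrogram order.  Jitter is seeded and
SVG output strips volatile metadata, so plots are byte-reproducible.

## Synthetic data generator

The generator is a single-factor-per-block Gaussian copula.  Block k has a
latent factor `f_k ~ N(0,1)`; an item in block k is
`z = λ_k f_k + √(1−λ_k²) ε + shift` discretized at fixed thresholds
(default −1.2, −0.4, 0.4, 1.2) into 1..5, so the latent within-block
correlation is λ².  Noise items are pure `ε + shift`.  The default shift
of −0.55 skews scores toward the favorable end (item means ≈ 2.2–2.5),
matching the right-skewed distributions typical of acceptability items.
The intention latent is `L = −Σ effect_k f_k + ε`, dichotomized at the
empirical cut that yields the target positive rate (default 76%); the
5-level raw intention is reconstructed around that cut so dichotomization
reproduces the planted positive set exactly.  The default design mirrors
the structure of a large determinant study: 3000 respondents, 20 signal
items in 9 blocks of sizes (2,3,2,1,4,2,2,1,3) — including two intentional
singleton blocks — plus 40 noise items, loadings 0.8, and block effects
between 0.45 and 1.0 chosen to span item-level d values of roughly
0.3–1.1.

Because the mapping from a latent effect to the observed Cohen's d after
discretization has no closed form, `effect_for_target_d` calibrates it by
a large common-random-numbers Monte-Carlo estimate (n = 400 000, fixed
internal seed) and Brent root-finding; the result is deterministic for
fixed arguments.

What the generator does *not* emulate: questionnaire wording, the joint
distribution of demographics, panel weighting, response styles
(acquiescence, straight-lining), item-specific threshold shifts, or
missingness mechanisms.  Passing tests therefore demonstrate that the
pipeline recovers structure of this idealized kind — block-correlated
ordinal items with a monotone latent link to intention — not that it is
robust to the full messiness of real panel data.

## Reproducibility and numerics

One master seed drives everything: the generator derives named child
streams per stage (items, intention) so stages can be re-run
independently; the forest seeds its bootstrap, tree and permutation
streams from the config seed; plot jitter is seeded.  With fixed seed and
row order every numeric output is bit-reproducible; permuting respondents
changes results only through seed-controlled Monte-Carlo noise.

Problem sizes used by the simulation-based test-bench: cluster-count
recovery uses 50 replicates per planted K ∈ {2, 3, 9} at n = 1000 and
loading 0.85; the forest screen uses 50 replicates at n = 1000 with 300
trees (plus one n = 2000, 500-tree fit for the AUC check); effect-size
recovery uses 20 replicates at n = 3000; the end-to-end study-shaped
property uses 5 seeds at n = 3000 with 300 trees.  These sizes keep the
full suite at a few minutes on one CPU while leaving the Monte-Carlo
margins comfortably wide of the pass thresholds.

The pipeline writes every artifact with a manifest (stage content keys,
seed, config); a re-run recomputes only stages whose inputs changed, and
CSV artifacts are byte-identical across identical runs.

## Known limitations

* The importance measure inherits the known behaviors of permutation
  importance: correlated predictors share importance (a duplicated signal
  column halves both copies' scores), and one-hot demographic levels are
  ranked individually rather than as a block.
* The k rule assumes the planted/real clusters are reasonably separated;
  with overlapping blocks it tends toward coarser solutions.
* `D = 1 − |ρ|` treats anti-correlated items as similar by design; users
  who harmonize incorrectly will see spuriously tight clusters.
* Bivariate d and PCI are unconditional by intent: they rank targets
  without adjusting for the other determinants, and say nothing about the
  effect an actual intervention on a determinant would have.
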