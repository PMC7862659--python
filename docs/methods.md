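# Methods

`tuberome` implements a complete desk-scale version of a two-route screen
for bacterial taxa associated with potato tuber storage stability: which
OTUs in the tuber microbiome predict whether a batch of tubers sprouts
early or late, and do candidate isolates actually change sprouting in
vitro?

## Study design and data model

The design is a crossed factorial: potato cultivar (up to four: Agata,
Fabiola, Hermes, Lady Claire) x soil of origin (potting soil plus four
farmland soils) x storage timepoint (harvest T2 through sprouting T7, plus
sprout tissue), with three replicate tubers per cell. Each cultivar x soil
combination is a *batch*; its tubers share one storage phenotype,
`storage_days` — the number of days from harvest until the batch sprouted
(observed range in the motivating experiment: roughly 135–169 days).
Counts are 16S rRNA amplicon reads clustered into OTUs; library sizes are
in the 10^3–10^5 range and all analyses treat counts as compositional
(per-sample relative abundances).

## Pipeline

1. **rOTU filtering.** An OTU is "reproducibly occurring" when (a) its
   mean per-sample relative abundance is >= 0.01% and (b) it is present
   (count > 0) in at least 2 of the 3 replicates of at least one design
   cell. Both rules are logged per OTU. The abundance statistic is
   configurable (`mean`, `max`, `pooled`) because the 0.01% rule is stated
   without a statistic in the field's usual shorthand; mean per-sample
   relative abundance is the most common reading.
2. **Alpha diversity.** Counts are rarefied once (without replacement) to
   the minimum sample total by default; observed richness and the
   Gini–Simpson index (1 − Σp²) are computed per sample. Factor effects are
   tested with a one-way permutation ANOVA per factor (marginal tests,
   classic F statistic, p = (1 + #{F* ≥ F}) / (1 + n_perm), default 9999
   permutations).
3. **Beta diversity.** Bray–Curtis dissimilarities; Anderson-style
   PERMANOVA (pseudo-F from partitioned squared distances, R² = SS_between
   / SS_total, unrestricted label permutation by default with an optional
   strata argument); principal-coordinates analysis with negative
   eigenvalues reported but excluded from coordinates, and a constrained
   (CAP) step that rotates the PCoA axes retaining ≥ 85% of positive
   eigenvalue mass with a linear discriminant.
4. **Stability classes.** Batches are split into short/medium/long storers
   by tertiles of the distinct batch-level storage days; ties at a cut
   point fall to the lower class, and the earliest-sprouting tertile is
   "short".
5. **Random-forest indicator selection (varSelRF-style).** A forest is fit
   on relative abundances against the stability classes; OTUs are ranked
   once by *unscaled OOB permutation importance* (mean decrease in
   accuracy, the ranking varSelRF itself uses); the least-important 20%
   are dropped and the forest refit, recording the OOB error, down to two
   OTUs; the smallest set whose OOB error is within one standard error
   (SE = sqrt(e(1−e)/n)) of the path minimum is selected. The driver runs
   this within each storage timepoint (T2, T6, T7) *and* once on all
   samples pooled, each run with independently derived randomness, and
   unions the selections, recording each OTU's stratum of origin. The
   union matters: the 1-SE rule is deliberately parsimonious, so any
   single run returns one minimal near-optimal subset of a redundant
   indicator block; pooling independent runs covers the block without
   admitting weak candidates. Gini (impurity)
   importance is available via a flag but is not the default: it
   preferentially ranks abundant, many-valued features under the null,
   which both inflates false selections and misses planted effects.
6. **Correlation network.** OTUs whose modal count occupies strictly more
   than two-thirds of the samples (usually zeros) are dropped — such
   columns carry almost no rank information. Spearman correlations (average
   ranks; two-sided p from the t approximation, permutation p by flag) are
   computed over all remaining rOTU pairs plus one extra node holding the
   batch storage days. Edges with |r| < 0.5 or p > 0.001 are zeroed. The
   absolute-value reading is the default so that taxa *negatively*
   associated with storage time (short-storage indicators) survive; a
   positive-only mode implements the literal unsigned cut.
7. **Key OTUs.** An OTU is a key OTU when it is in the pooled RF selection
   AND retains at least one network edge. A direct storage-node edge fixes
   the direction label by its sign (positive → "long", negative →
   "short"); otherwise the stability class with maximal mean relative
   abundance decides (typically "medium"). Reports are ordered by
   |r_storage|, then RF rank.
8. **Sprouting assay.** Bud discs are scored on the first principal BBCH
   stages (00/01/02/03/05; 00 = dormant, 03 = dormancy break, 05 =
   sprouting with root initiation). Reporting follows the bench convention
   (stage sums per treatment x repetition, averaged over repetitions);
   inference is a one-way linear model on disc-level stages, ANOVA, and
   estimated-marginal-mean contrasts of every treatment against the 10%
   tryptic-soy-broth control with Dunnett-style many-to-one adjustment
   (multivariate-t rectangle probabilities on the contrast correlation
   matrix; cross-checked against scipy.stats.dunnett in the one-factor
   case; Bonferroni fallback by flag). Treatments with a significantly
   negative contrast at α = 0.05 are flagged as sprouting inhibitors.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
raw sequencing:

* **Baseline community**: a log-normal rank-abundance profile (σ = 1.5)
  over `n_otus` taxa (default 500).
* **Counts**: per sample, q ~ Dirichlet(precision × p_sample), counts ~
  Multinomial(library, q), libraries log-uniform in 5,000–50,000 (the
  motivating data average ~34k reads/sample and rarefy near 6.8k).
  Dirichlet precision defaults to 5000, i.e. replicate-level compositional
  noise with CV ≈ 0.2 for a taxon at 0.5% abundance.
* **Planted storage indicators**: `n_long` + `n_short` OTUs (default
  10 + 10) at indicator-like base abundances (0.25–1% relative abundance),
  whose log expected abundance is linear in the batch's storage days with
  slope ±`effect_size` (default 0.02/day, about a two-fold swing across a
  135–169-day spread). Because storage days are a batch attribute, the
  same planted signal is visible to both selection routes — the forest via
  the derived tertile classes and the network via the storage-days node.
* **Community succession**: a random subset (default 50 OTUs) follows
  per-OTU temporal trajectories — log-offset 0 at the first timepoint,
  independent draws at later timepoints with per-OTU lognormal(ln 0.4,
  0.4) magnitude scaled by `shift_strength`. This moves the community as a
  whole between harvest and sprouting (PERMANOVA on timepoint is strongly
  significant) without locking all shift OTUs into one mutually
  correlated block, which no real succession does and which would flood
  the co-occurrence network with a single clique.
* **Truth**: planted identities, batch days and exact expected
  compositions are returned for recovery tests; with `effect_size = 0` and
  `shift_strength = 0` every sample shares one expected composition.

What the generator deliberately does **not** emulate: batch-level
compositional effects (a soil signature shared by replicates). Real data
have them, and they would let the forest partially learn batch identity —
and hence the batch-derived stability class — from features unrelated to
storage. Passing recovery and null-calibration tests here therefore shows
the statistical machinery is sound under the stated model, not that the
procedure is immune to batch confounding in field data. Likewise taxonomy
strings are placeholders and no sequence-level artefacts (chimeras,
contamination) exist.

## Numerical choices

* Ties rule: the tie fraction is held exactly as the fraction 2/3 and the
  comparison is strict — an OTU tied in exactly two-thirds of samples is
  retained. Decimal approximations (66.66%) would misclassify the boundary.
* Permutation p-values always include the identity permutation:
  p = (1 + hits) / (1 + n_perm), so p ≥ 1/(n_perm + 1).
* Spearman p-values use the t approximation; constant nodes yield r = 0,
  p = 1 with a warning (they cannot occur after the ties filter).
* PCoA eigenvalues below 1e-10 of the spectrum's magnitude are treated as
  zero; negative eigenvalue mass above 5% of the positive mass triggers a
  warning rather than a Lingoes/Cailliez correction.
* The RF elimination path drops ceil(0.2 × current) OTUs per step and is
  seed-deterministic: one generator drives the per-fit forest seeds and
  the importance permutations.
* Forest sizes: the API default is a 2000-tree ranking forest (a
  desk-scale compromise against varSelRF's 5000) with path refits the same
  size by default; `n_trees_iterat` mirrors varSelRF's smaller iterated
  forests. The test suite and the acceptance script run the simulation
  studies with a 600-tree ranking forest and 100-tree refits, the size at
  which the ranking is stable on 27-sample strata while a 30-run
  simulation study stays within desk compute; ranking quality, not OOB
  error precision, is the binding constraint.

## Known limitations

* Per-stratum selection on 27-sample strata with ~450 candidate OTUs is an
  extreme p >> n regime. With impurity importances the OOB errors along
  the elimination path drop far below chance even on label-permuted data
  (feature-selection bias); the permutation-importance default keeps the
  null path near the majority-class error, but the selected-set OOB error
  is still optimistically biased — it is a selection criterion here, never
  an error estimate.
* The key-OTU definition intersects the RF route with *any* surviving
  network edge. Under a strong community succession the network contains
  real OTU–OTU edges unrelated to storage, so a false RF selection that
  happens to be a succession taxon can become a false key OTU; the
  observed false-positive rate at the default conditions is about one key
  OTU per null study, dominated by such coincidences (the storage node
  itself acquires no false edges in any observed null run).
* EMM contrasts assume homoscedastic stages across treatments; ordinal
  stages are treated as numeric scores, as is conventional for BBCH sums.
* The Dunnett adjustment integrates the multivariate-t over an
  equicorrelated rectangle; for heavily unbalanced designs the contrast
  correlation matrix is used exactly, but degenerate (zero-variance)
  responses fall back to p = 1.
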