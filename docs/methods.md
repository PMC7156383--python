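# Methods

This document records the model assumptions, parameter conventions, numerical
choices and known limitations of the `metastrat` package. Every empirical
claim below is computed by the test suite (`tests/`) or the acceptance script
(`scripts/acceptance.py`); nothing is asserted that the code does not measure.

## Consensus clustering

- **Resampling.** For each candidate k, `n_resamples` (default 250) random
  subsamples of `subsample_fraction` (default 0.8) of the items are drawn
  without replacement and clustered by agglomerative clustering (Euclidean
  distance, average linkage, tree cut at exactly k groups). The consensus
  matrix entry M[i,j] is (# times i,j co-clustered) / (# times i,j were
  co-sampled). Pairs never co-sampled are imputed at 0.5 (maximal
  uncertainty) with a warning; with default parameters this does not occur.
- **Final partition.** The consensus matrix is itself clustered (average
  linkage on 1 − M) and cut at k; item ordering for heatmap export comes from
  the same tree.
- **Optimal k (NED).** For each k, NED = sqrt( Σ_{i<j} (M_ij − P_ij)² /
  (n(n−1)/2) ), where P is the perfect 0/1 co-membership matrix implied by
  the final partition at that k. The chosen k minimizes NED; ties break
  toward smaller k. If *no* candidate reaches NED < 0.3, the result carries a
  `weak_structure` flag and a warning.
- **Preprocessing.** log2(x + 1) then gene-wise z-scoring with population
  (ddof = 0) standard deviation; zero-variance genes stay at 0.
- **Cluster naming.** Sample clusters are re-indexed so cluster 1 has the
  highest mean primary-signature (OXPHOS) expression; clusters whose primary
  means lie within 0.25× the overall spread of cluster means are treated as
  tied and ordered by ascending secondary (glycolysis) mean. The tolerance is
  scale-free; with zero spread the secondary ordering decides everything.
- **Determinism.** Each k consumes its own stream,
  `default_rng([seed mod 2^31, k])`, so adding or removing candidate k values
  does not perturb the others.

### When the NED criterion works — and when it does not

The criterion identifies the true k when *coarser merges are ambiguous under
resampling*: if two true clusters are equidistant from a third, which pair
merges at k−1 flips from subsample to subsample and the k−1 consensus is
smeared, while the true-k consensus is crisp. The synthetic generator plants
exactly this geometry (see below). Conversely:

- With *hierarchically separable* centers (one pair much closer than the
  others), the coarser merge is also stable, NED is ~0 at several k, and the
  smaller-k tie-break wins. The criterion then under-reports k by design.
- On *high-dimensional structureless data*, average linkage stably peels
  outlier singletons off one giant blob; that degenerate partition is
  reproducible across subsamples, so NED stays low and the weak-structure
  flag does **not** fire (measured: NED ≈ 0.03 at k = 2 on a flat synthetic
  cohort). The flag is reliable on low-dimensional noise-like data (e.g.
  evenly spaced ring points give NED 0.44/0.37 at k = 2/3) but must not be
  read as a general test for the absence of structure.

## Single-sample gene-set scoring (ssGSEA)

- Genes are ranked by decreasing linear expression, ties broken by gene
  symbol (lexicographic) so scoring is fully deterministic; ranks run N
  (highest) down to 1.
- ES = Σ_pos (P_in(pos) − P_out(pos)), where P_in is the in-set ECDF weighted
  by rank^α (α = 0.75) and P_out the unweighted out-of-set ECDF.
- Sets are scored on their intersection with the matrix (matched gene counts
  recorded in provenance); an empty intersection or a set covering the whole
  universe is an error.
- Optional normalization divides by the global (all samples × all sets) score
  range; z-scores use population standard deviation and error on
  zero-variance signatures. The combined immune score is
  z(cytotoxic) − z(Treg).
- A tissue-specific contamination panel is derived from a genes × tissues
  mean table as genes with target-tissue mean ≥ 10× the maximum over all
  other tissues (boundary inclusive); marker lists can additionally be
  filtered by a ≥ 4× specificity ratio.

## Survival analysis

- Kaplan–Meier curves and the (multivariate) log-rank test are computed via
  `lifelines`; both are verified against explicit risk-set-loop oracles in
  the test suite. Deaths precede censorings at tied times.
- Median survival is the smallest event time with S(t) ≤ 0.5 (+1e-12
  numerical slack); undefined (NaN) if the curve never reaches 0.5.
- The cluster report gives per-cluster KM medians, pairwise log-rank p-values
  against the reference cluster (raw and BH-adjusted across the pairwise
  family), and one pooled reference-vs-all-others row.
- Note on tolerances: with exponential event times, ~20% uniform censoring
  and n = 150 per cluster, the KM median has a sampling error of roughly
  10% of ln2/λ, so a 15% agreement band is met by typical seeds but not by
  all (observed max relative error 17.7% at one seed in
  `results/acceptance.json`).

## Group statistics

- Differential expression: per-gene two-sided Welch t-test on log2(x + 1);
  identical groups yield t = 0, p = 1 by convention; BH adjustment at the
  requested FDR. Either group may pool several clusters.
- Fold annotation: geometric-mean ratio (exp of mean log(x + pseudocount));
  genes are `up` / `down` / `unchanged` at a 1.4× threshold.
- Impactful mutations: SIFT = deleterious OR PolyPhen ∈ {probably_damaging,
  possibly_damaging}; labels are parsed case-insensitively with
  space/underscore equivalence and optional parenthesized scores.
- Mutation–cluster association: Pearson chi-square without continuity
  correction on mutated/not × (cluster-of-interest vs rest) tables (or the
  full k-way table); degenerate tables (zero margin) are flagged and excluded
  from the BH family rather than contributing p = NaN to it.
- Continuous covariates by cluster: one-way ANOVA + Tukey HSD + a Spearman
  trend statistic of value against cluster index; clusters with < 2 samples
  are excluded with a warning.
- Correlation screen: vectorized Pearson r of each gene against a score,
  p-values from the t distribution, constant genes NaN, output sorted by |r|.
- Calibration (measured by tests): under the global null the BH screen's mean
  false-discovery proportion equals its family-wise error and stays within
  Monte-Carlo error of the nominal 0.05; the null Tukey family-wise error is
  at or below nominal. These are independence-assuming guarantees; strongly
  correlated genes are not simulated.

## Contamination mixture model

- Cell-class mean profiles combine *arithmetically* on linear values
  (mixtures of cells add linearly); observed fold changes between sample
  groups are *geometric-mean* ratios. This mild inconsistency mirrors the
  framing the analysis is modeled on and is deliberate.
- Expected fold change for contamination fraction f:
  (f·T + (1−f)·M) / M per gene, with a pseudocount guard; f is a fixed
  modeling bound (typically 0.5), never inferred from the data.
- Classification on x = log2(observed FC), y = log2(expected FC), with zero
  tolerance log2(1.05): if |y| ≤ tol the model predicts no change and the
  gene is `not_explainable` iff |x| > tol; if |y − x| ≤ tol the gene sits on
  the identity band and is `potentially_explainable` (boundary assigned to
  the contamination explanation, i.e. conservatively); otherwise the gene is
  `not_explainable` iff the expected change overshoots the observed one in
  the same direction (y > x when both up, y < x when both down) or the signs
  disagree. x ≈ 0 adopts y's sign. Classification depends only on ratios and
  is therefore scale-invariant.
- Profiles can be estimated from annotated single cells: T-cells are ssGSEA
  z-scored on immune signatures, consensus-clustered with the optimal-k
  criterion, and the subcluster with the highest cytotoxic score provides the
  T-cell profile (single T-cell inputs skip subclustering).
- Measured recovery: on a pseudobulk cohort with true f = 0.5 in one group,
  regressing x on y gives slope 1.00 and intercept 0.00 (within ±0.1) with
  ≥ 95% of genes `potentially_explainable`; a planted 2× tumor-intrinsic
  block evaluated against an f = 0 model is flagged `not_explainable` for
  100% of the block.

## Synthetic cohort generator

Scope: the generator exists to give every pipeline stage planted ground truth
at desk scale. It is not a biological simulator; effect structure is block-
wise and noise is i.i.d. log-normal.

- **Expression.** 200 tumors (+20 normals) by default over gene blocks
  OXPHOS (59), glycolysis (59), pentose-phosphate (20) and background (125),
  plus immune markers (3 × 15), muscle markers (28) and four mutation-carrier
  genes. Tumor subtype c shifts the three metabolic blocks by
  `block_shift_scale` (1.25) × vertex_c, where the four vertices
  (+1,−1,−1), (+1,+1,+1), (−1,−1,+1), (−1,+1,−1) form a regular tetrahedron:
  all pairwise center distances are equal, so every coarser merge is
  resampling-ambiguous and the NED criterion has a pronounced minimum at the
  true k. Gaussian noise (sd 1.0) is added on the log2 scale and values are
  returned as 2^(·) − 1, clipped at 0.
- **Clinical.** Exponential survival with per-cluster hazards (default
  0.005, 0.03, 0.015, 0.02 per month ⇒ medians ln2/λ ≈ 139, 23, 46, 35
  months); independent Uniform(0, T_max) censoring where T_max solves the
  target overall censoring probability (default 0.2) by Brent root-finding.
- **Immune & contamination.** A linear cytotoxic-minus-Treg gradient across
  clusters (+1.5 → −1.5); per-sample muscle contamination fractions
  Uniform(0.05, 0.15); mtDNA copy number declining across clusters
  (500 → 200).
- **Mutations.** Per-cluster Bernoulli rates (TP53 0.6 everywhere, CASP8
  0.15, MTG1 0.35 in cluster 1 vs 0.05 elsewhere, NEUT1 0.10) with SIFT /
  PolyPhen labels drawn from controlled vocabularies.
- **Gene sets.** GMT-exportable sets including the 59+59 = 118-gene combined
  two-pathway signature, the 138-gene clustering signature (adds the PPP
  block), three 15-gene immune sets and the 28-gene muscle panel; a separate
  genes × 46-tissue mean table plants exactly 28 muscle-specific genes at the
  10× threshold for panel-derivation tests.
- **Determinism.** One master seed; every stage draws from
  `default_rng([master_seed, tag])` with fixed per-stage tags, so adding a
  stage never perturbs another stage's stream. All seeds are taken modulo
  2^31.

## Pipeline

`run_pipeline` sequences simulate → cluster → score → survival → DE →
association → correlation → mixture, writing every artifact as TSV plus a
`manifest.json` with SHA-256 checksums, parameters and seeds; a stage failure
aborts with the stage name recorded and partial outputs persisted. Re-running
an identical config reproduces byte-identical artifacts (tested). Config
files are YAML with strict unknown-key rejection and documented defaults
(resamples 250, subsample fraction 0.8, ssGSEA α 0.75).

## Limitations

- No real-data cohort is analyzed at desk scale; external download adapters
  are out of scope and published cohort-level numbers are not reproduced
  here.
- The NED optimal-k criterion assumes merge-ambiguous cluster geometry and
  can under-report k on hierarchically separable data; its weak-structure
  flag is insensitive to high-dimensional structureless data (see above).
- Statistical calibration checks use independent genes and samples; the
  behavior of BH/Tukey under strong correlation is not characterized.
- The mixture model is two-component with a fixed contamination fraction;
  it neither infers f nor models more than one contaminating cell class at a
  time.
- KM medians at n = 150/cluster carry ~10% sampling error, so tight
  (≤ 15%) agreement bands are seed-dependent.
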