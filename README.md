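# metastrat

Metabologenomic tumor stratification: resampling consensus clustering with an
automatic cluster-number criterion, single-sample gene-set scoring, survival
comparison, mutation/covariate association, and a cell-admixture
("contamination") model that asks whether bulk differential expression can be
explained by immune-cell content rather than tumor-intrinsic biology. A
deterministic synthetic-cohort generator with planted ground truth makes every
stage testable at desk scale.

## Scientific problem

Bulk tumor expression cohorts are routinely stratified by clustering a
metabolic gene signature (e.g. OXPHOS + glycolysis + pentose-phosphate genes),
and the resulting subtypes are then compared for survival, mutations, immune
infiltration and mitochondrial content. Three recurring methodological
problems are addressed here:

1. **How many clusters?** Consensus clustering (repeatedly clustering random
   80% subsamples and recording how often each sample pair co-clusters) yields
   a consensus matrix per candidate k. We select k by the *normalized
   Euclidean distance* (NED) between the consensus matrix and the ideal 0/1
   matrix implied by its own partition — the k whose consensus is closest to
   "theoretical perfection" wins, with ties going to the smaller k and a
   weak-structure flag when no k gets close.
2. **Are subtype differences real or admixture?** A two-component mixture
   model (tumor cells + T-cells at fraction *f*) predicts the fold change each
   gene *would* show if one subtype simply contained more T-cells. Comparing
   observed and expected log fold changes classifies every gene as
   `potentially_explainable` or `not_explainable` by contamination.
3. **Is the pipeline statistically honest?** Every statistic (ssGSEA, KM,
   log-rank, Welch/BH, chi-square, Pearson/Tukey) is validated against naive
   independent re-implementations, and BH/Tukey calibration is checked on
   null simulations.

## Worked example

Simulate a 200-tumor cohort with four planted metabolic subtypes, recover
them, and run the downstream analyses (all numbers below are the actual
output of this code at these seeds):

```python
import pandas as pd
import metastrat as ms

cohort = ms.generate_cohort(ms.CohortConfig(master_seed=11))
tumors = list(cohort.truth_labels.index)
signature = cohort.gene_sets["clustering_signature"].genes
X = cohort.expression.subset_samples(tumors).subset_genes(signature)

res = ms.two_way_cluster(
    X, sample_k_range=range(2, 9), gene_k_range=[3], n_resamples=250, seed=11,
    signature_genes=cohort.gene_sets["oxphos"].genes,
    secondary_genes=cohort.gene_sets["glycolysis"].genes,
)
res.chosen_k                                   # 4
{k: round(v.ned, 3) for k, v in res.per_k.items()}
# {2: 0.315, 3: 0.178, 4: 0.0, 5: 0.006, 6: 0.033, 7: 0.019, 8: 0.044}
```

The NED profile has a sharp minimum at the planted k = 4; the recovered
partition (four clusters of 50) matches the planted labels with adjusted Rand
index 1.0. Cluster 1 is, by convention, the high-OXPHOS / low-glycolysis
cluster.

Immune scoring (ssGSEA z-scores, cytotoxic minus Treg) declines across
clusters, reproducing the planted immune gradient:

```python
labels = pd.Series(res.labels, index=tumors)
scores = ms.ssgsea_table(cohort.expression.subset_samples(tumors), cohort.gene_sets)
comb = ms.combined_subtractive_score(scores, "cytotoxic_cells", "treg_cells")
comb.values.groupby(labels).mean().round(2)    # 1: 1.53, 2: 0.75, 3: -0.80, 4: -1.49
```

Survival separates the clusters (planted exponential hazards; months):

```python
ms.cluster_survival_report(cohort.clinical, labels, reference_cluster=1)
#               n  n_events  median_survival  p_vs_reference  p_vs_reference_bh
# 1            50        30            105.0             NaN                NaN
# 2            50        42             20.9        4.87e-10           1.46e-09
# 3            50        45             54.6        1.26e-05           1.26e-05
# 4            50        43             46.0        6.06e-06           9.09e-06
# pooled_2+3+4 150      130             38.3        1.68e-09                NaN
```

Differential expression of cluster 1 versus the rest recovers the entire
138-gene planted signature at FDR 0.05 (138/138 significant):

```python
de = ms.welch_tests_by_gene(X, labels, 1, [2, 3, 4], fdr=0.05)
int(de.table["significant"].sum())             # 138
```

The same analysis is available end to end from the command line:

```bash
metastrat run-all --config config.yaml      # simulate -> cluster -> score ->
                                            # survival -> DE -> assoc -> mixture
```

with per-stage subcommands (`simulate`, `cluster`, `score`, `survival`, `de`,
`assoc`, `correlate`, `mixture`) writing TSV artifacts plus a checksummed
`manifest.json`; re-running the same config reproduces byte-identical outputs.

## Reproduction

Run the full test suite (about 5 minutes on one CPU; the acceptance tests in
`tests/test_acceptance.py` cover planted-structure recovery over 20 seeds,
oracle equivalence on 100 random instances per statistic, survival and mixture
fidelity, null calibration, and exact gene-list counts):

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

Recompute the headline quantities into a JSON report (about 5 minutes):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Representative values at seed 1: optimal-k success rate 0.95 (19/20 seeds),
mean ARI 0.97, all oracle deviations < 1e-14, mixture regression slope 0.998 /
intercept 0.005 with 98.2% of genes explainable under true contamination,
intrinsic upregulation flagged not-explainable for 100% of the planted block,
null BH false-discovery proportion 0.10 (within Monte-Carlo error of 0.05),
null Tukey family-wise error 0.04.

See `docs/methods.md` for model assumptions, parameter conventions, and known
limitations.
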