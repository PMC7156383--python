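"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator plants every feature the downstream analysis looks for, with
full ground truth: sample clusters that differ in coordinated metabolic gene
blocks (an oxidative-phosphorylation-like block, a glycolysis-like block and a
pentose-phosphate-like block), overall survival whose hazard is a non-monotone
(threshold) function of cluster, immune-subset marker genes declining across
clusters, a muscle-contaminated sample subset, matched normal samples,
mitochondrial copy numbers trending with cluster, mutation tables with impact
annotations, and per-cell-type mean profiles for the contamination mixture
model.

Planted geometry. The k default cluster centers sit at vertices of a regular
simplex in (OXPHOS, glycolysis, PPP) block-shift space: each pair of centers
differs in exactly two of the three blocks, so all pairwise center distances
are equal. Under resampling, any grouping into fewer than k clusters is then
ambiguous (there is no preferred coarser merge), while the k-way cut is stable
- which is exactly the regime in which a consensus-based distance-to-perfection
criterion exhibits a pronounced minimum at the true k. Cluster 1 is the
high-OXPHOS / low-glycolysis vertex, matching the convention that cluster 1 is
the highest-signature cluster.

Expression is generated on the log2 scale (per-gene baseline + per-cluster
block shift + Gaussian residual) and exponentiated to linear RSEM-like units;
multiplicative log-normal noise keeps geometric-mean ratios unbiased. All child
random streams derive from the master seed by fixed tags, so each component
regenerates stably on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    MutationTable,
)

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_pseudobulk_mixture",
    "generate_single_cells",
    "generate_tissue_means",
    "make_cell_profiles",
]


class ConfigError(ValueError):
    pass


# canonical simplex vertices over (oxphos, glycolysis, ppp); row order is the
# final cluster order 1..4 (descending OXPHOS, ties broken by ascending glycolysis)
_VERTICES = np.array(
    [
        [+1.0, -1.0, -1.0],  # cluster 1: high OXPHOS, low glycolysis
        [+1.0, +1.0, +1.0],  # cluster 2: high everything
        [-1.0, -1.0, +1.0],
        [-1.0, +1.0, -1.0],
    ]
)

_SEED_MOD = 2**31


@dataclass
class CohortConfig:
    n_tumor_samples: int = 200
    n_normal_samples: int = 20
    k_true: int = 4
    # (oxphos-like, glycolysis-like, ppp-like, background) block sizes; the
    # combined oxphos+glycolysis signature is 118 genes by default
    genes_per_block: tuple[int, int, int, int] = (59, 59, 20, 125)
    block_shift: np.ndarray | None = None  # k x 3 log2 shifts; default simplex
    block_shift_scale: float = 1.25  # log2 units
    noise_sd: float = 1.0  # log2-scale residual sd
    hazard_by_cluster: tuple[float, ...] | None = None  # months^-1, non-monotone allowed
    censoring_rate: float = 0.2
    immune_gradient: tuple[float, ...] | None = None  # per-cluster log2 shift
    n_immune_markers: int = 15  # per subset (cytotoxic, CD8, Treg)
    muscle_fraction_range: tuple[float, float] = (0.05, 0.15)
    n_muscle_genes: int = 28
    mtdna_mean_by_cluster: tuple[float, ...] | None = None
    contamination_fraction: float = 0.0  # cytotoxic admixture applied to cluster 1
    mutation_rate_by_gene: dict | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ConfigError("k_true must be >= 2")
        if not 0 <= self.contamination_fraction <= 1:
            raise ConfigError("contamination_fraction must be in [0, 1]")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigError("censoring_rate must be in [0, 1)")
        if self.block_shift is None:
            if self.k_true > len(_VERTICES):
                raise ConfigError(
                    f"no default geometry for k_true={self.k_true}; pass block_shift"
                )
            self.block_shift = self.block_shift_scale * _VERTICES[: self.k_true]
        self.block_shift = np.asarray(self.block_shift, dtype=float)
        if self.block_shift.shape != (self.k_true, 3):
            raise ConfigError("block_shift must have shape (k_true, 3)")
        if not np.all(np.isfinite(self.block_shift)):
            raise ConfigError("block_shift must be finite")
        if self.hazard_by_cluster is None:
            default_hazards = (0.005, 0.03, 0.015, 0.02)
            if self.k_true > len(default_hazards):
                raise ConfigError("pass hazard_by_cluster for k_true > 4")
            self.hazard_by_cluster = default_hazards[: self.k_true]
        if len(self.hazard_by_cluster) != self.k_true:
            raise ConfigError("hazard_by_cluster length must equal k_true")
        if any(h <= 0 for h in self.hazard_by_cluster):
            raise ConfigError("hazards must be > 0")
        if self.immune_gradient is None:
            self.immune_gradient = tuple(np.linspace(1.5, -1.5, self.k_true))
        if len(self.immune_gradient) != self.k_true:
            raise ConfigError("immune_gradient length must equal k_true")
        if self.mtdna_mean_by_cluster is None:
            self.mtdna_mean_by_cluster = tuple(np.linspace(500, 200, self.k_true))
        if len(self.mtdna_mean_by_cluster) != self.k_true:
            raise ConfigError("mtdna_mean_by_cluster length must equal k_true")
        if self.mutation_rate_by_gene is None:
            # MTG1 is planted as cluster-1 enriched to exercise association tests
            self.mutation_rate_by_gene = {
                "TP53": 0.6,
                "CASP8": 0.15,
                "MTG1": {1: 0.35, "other": 0.05},
                "NEUT1": 0.10,
            }


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix  # tumors + normals, linear scale
    truth_labels: pd.Series  # tumor sample -> cluster 1..k
    clinical: ClinicalTable  # tumors only
    immune_truth: pd.Series  # tumor sample -> planted cytotoxic intensity (log2 shift)
    mtdna: pd.Series  # tumor sample -> copy number
    mutations: MutationTable
    cell_profiles: pd.DataFrame  # gene x {tumor_cell, cytotoxic_t_cell} linear means
    gene_sets: GeneSetCollection
    config: CohortConfig = field(repr=False, default=None)


def _rng(master_seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(master_seed) % _SEED_MOD, tag])


def _gene_universe(cfg: CohortConfig) -> dict[str, list[str]]:
    n_ox, n_gly, n_ppp, n_bg = cfg.genes_per_block
    blocks = {
        "oxphos": [f"OXP{i:03d}" for i in range(1, n_ox + 1)],
        "glycolysis": [f"GLY{i:03d}" for i in range(1, n_gly + 1)],
        "ppp": [f"PPP{i:03d}" for i in range(1, n_ppp + 1)],
        "cytotoxic": [f"CYT{i:03d}" for i in range(1, cfg.n_immune_markers + 1)],
        "cd8": [f"CD8_{i:03d}" for i in range(1, cfg.n_immune_markers + 1)],
        "treg": [f"TRG{i:03d}" for i in range(1, cfg.n_immune_markers + 1)],
        "muscle": [f"MUS{i:03d}" for i in range(1, cfg.n_muscle_genes + 1)],
        "mutation": ["TP53", "CASP8", "MTG1", "NEUT1"],
        "background": [f"BGD{i:03d}" for i in range(1, n_bg + 1)],
    }
    return blocks


def _gene_set_collection(blocks: dict[str, list[str]]) -> GeneSetCollection:
    coll = GeneSetCollection()
    coll.add(GeneSet("oxphos", blocks["oxphos"], category="oxidative_phosphorylation"))
    coll.add(GeneSet("glycolysis", blocks["glycolysis"], category="glycolysis"))
    coll.add(GeneSet("ppp", blocks["ppp"], category="ppp"))
    coll.add(
        GeneSet(
            "oxphos_glycolysis",
            blocks["oxphos"] + blocks["glycolysis"],
            category="combined_metabolic",
        )
    )
    coll.add(
        GeneSet(
            "clustering_signature",
            blocks["oxphos"] + blocks["glycolysis"] + blocks["ppp"],
            category="combined_metabolic",
        )
    )
    coll.add(GeneSet("cytotoxic_cells", blocks["cytotoxic"], category="immune_subset"))
    coll.add(GeneSet("cd8_t_cells", blocks["cd8"], category="immune_subset"))
    coll.add(GeneSet("treg_cells", blocks["treg"], category="immune_subset"))
    coll.add(GeneSet("muscle", blocks["muscle"], category="muscle"))
    return coll


def _baselines(blocks: dict[str, list[str]], master_seed: int) -> pd.Series:
    rng = _rng(master_seed, 1)
    genes = [g for names in blocks.values() for g in names]
    base = rng.uniform(3.0, 8.0, size=len(genes))
    return pd.Series(base, index=genes)


def make_cell_profiles(cfg: CohortConfig) -> pd.DataFrame:
    """Per-gene linear mean expression for tumor cells and cytotoxic T-cells.

    T-cells carry strongly elevated cytotoxic/CD8 markers, moderately reduced
    OXPHOS-block expression, and broad background differences (log-normal
    spread) that give the expected-fold-change axis real dynamic range.
    """
    blocks = _gene_universe(cfg)
    base = _baselines(blocks, cfg.master_seed)
    rng = _rng(cfg.master_seed, 2)
    delta = pd.Series(0.0, index=base.index)
    delta[blocks["oxphos"]] = -1.5
    delta[blocks["glycolysis"]] = 0.5
    delta[blocks["cytotoxic"]] = 5.0
    delta[blocks["cd8"]] = 5.0
    delta[blocks["treg"]] = 1.0
    delta[blocks["muscle"]] = -2.0
    delta[blocks["background"]] = rng.normal(0.0, 1.2, size=len(blocks["background"]))
    tumor = np.exp2(base)
    tcell = np.exp2(base + delta)
    return pd.DataFrame({"tumor_cell": tumor, "cytotoxic_t_cell": tcell}, index=base.index)


def _censoring_horizon(hazards: np.ndarray, censoring_rate: float) -> float:
    """Uniform(0, T_max) censoring horizon giving the requested censoring rate.

    For T ~ Exp(lam) and C ~ U(0, m), P(censored) = (1 - exp(-lam m)) / (lam m),
    decreasing in m; solved for the cluster-averaged hazard.
    """
    if censoring_rate <= 0:
        return np.inf

    def frac_censored(m):
        lam = hazards
        return float(np.mean((1.0 - np.exp(-lam * m)) / (lam * m))) - censoring_rate

    lo, hi = 1e-6, 1e8
    return brentq(frac_censored, lo, hi)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort with ground truth; deterministic given master_seed."""
    cfg = config
    blocks = _gene_universe(cfg)
    base = _baselines(blocks, cfg.master_seed)
    genes = list(base.index)
    coll = _gene_set_collection(blocks)
    k = cfg.k_true

    n_t, n_n = cfg.n_tumor_samples, cfg.n_normal_samples
    tumor_ids = [f"TUM{i:04d}" for i in range(1, n_t + 1)]
    normal_ids = [f"NRM{i:04d}" for i in range(1, n_n + 1)]
    labels = (np.arange(n_t) % k) + 1  # balanced assignment

    # --- expression (log2 scale), tag 3 ---
    rng = _rng(cfg.master_seed, 3)
    n_genes = len(genes)
    L = np.tile(base.to_numpy()[:, None], (1, n_t + n_n))
    gene_pos = {g: i for i, g in enumerate(genes)}
    block_rows = {
        name: np.array([gene_pos[g] for g in blocks[name]])
        for name in ("oxphos", "glycolysis", "ppp", "cytotoxic", "cd8", "treg", "muscle")
    }
    for j, lab in enumerate(labels):
        sh = cfg.block_shift[lab - 1]
        L[block_rows["oxphos"], j] += sh[0]
        L[block_rows["glycolysis"], j] += sh[1]
        L[block_rows["ppp"], j] += sh[2]
        grad = cfg.immune_gradient[lab - 1]
        L[block_rows["cytotoxic"], j] += grad
        L[block_rows["cd8"], j] += grad
    # muscle-contaminated tumor subset
    frac = rng.uniform(*cfg.muscle_fraction_range)
    n_cont = int(round(frac * n_t))
    contaminated = rng.choice(n_t, size=n_cont, replace=False)
    for j in contaminated:
        L[block_rows["muscle"], j] += 3.0
    L += rng.normal(0.0, cfg.noise_sd, size=(n_genes, n_t + n_n))
    values = np.clip(np.exp2(L) - 1.0, 0.0, None)

    # optional cytotoxic T-cell admixture into cluster 1 (linear mixing)
    profiles = make_cell_profiles(cfg)
    if cfg.contamination_fraction > 0:
        f = cfg.contamination_fraction
        tcell = profiles["cytotoxic_t_cell"].to_numpy()[:, None]
        c1 = np.where(labels == 1)[0]
        values[:, c1] = (1 - f) * values[:, c1] + f * tcell

    sample_ids = tumor_ids + normal_ids
    meta = pd.DataFrame(
        {
            "tissue_class": ["tumor"] * n_t + ["normal"] * n_n,
            "cohort": "synthetic",
        },
        index=sample_ids,
    )
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids), meta)
    truth = pd.Series(labels, index=tumor_ids, name="cluster")

    # --- survival, tag 4 ---
    rng_s = _rng(cfg.master_seed, 4)
    haz = np.array([cfg.hazard_by_cluster[lab - 1] for lab in labels])
    t_event = rng_s.exponential(1.0 / haz)
    t_max = _censoring_horizon(np.array(cfg.hazard_by_cluster), cfg.censoring_rate)
    c_time = rng_s.uniform(0.0, t_max, size=n_t) if np.isfinite(t_max) else np.full(n_t, np.inf)
    os_time = np.minimum(t_event, c_time)
    os_event = (t_event <= c_time).astype(int)
    os_time = np.maximum(os_time, 1e-6)
    races = rng_s.choice(["white", "black", "asian"], size=n_t, p=[0.7, 0.2, 0.1])
    tp53 = rng_s.choice(["mut", "wt"], size=n_t, p=[0.6, 0.4])
    hpv = rng_s.choice(["pos", "neg"], size=n_t, p=[0.2, 0.8])
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "race": races,
                "tp53_status": tp53,
                "hpv_status": hpv,
            },
            index=pd.Index(tumor_ids, name="sample_id"),
        )
    )

    # --- mtDNA, tag 5 ---
    rng_m = _rng(cfg.master_seed, 5)
    means = np.array([cfg.mtdna_mean_by_cluster[lab - 1] for lab in labels])
    mtdna = pd.Series(
        np.clip(rng_m.normal(means, 0.15 * means), 1.0, None), index=tumor_ids, name="mtdna"
    )

    # --- mutations, tag 6 ---
    rng_mu = _rng(cfg.master_seed, 6)
    rows = []
    for gene, rate in cfg.mutation_rate_by_gene.items():
        for j, sid in enumerate(tumor_ids):
            lab = labels[j]
            r = rate if np.isscalar(rate) else rate.get(lab, rate.get("other", 0.0))
            if rng_mu.random() < r:
                sift = rng_mu.choice(["deleterious", "tolerated", "missing"], p=[0.5, 0.35, 0.15])
                polyphen = rng_mu.choice(
                    ["probably_damaging", "possibly_damaging", "benign", "missing"],
                    p=[0.3, 0.2, 0.35, 0.15],
                )
                rows.append(
                    {
                        "gene": gene,
                        "sample_id": sid,
                        "variant_classification": "Missense_Mutation",
                        "sift_label": sift,
                        "polyphen_label": polyphen,
                    }
                )
    mut_df = pd.DataFrame(
        rows,
        columns=["gene", "sample_id", "variant_classification", "sift_label", "polyphen_label"],
    )
    mutations = MutationTable(mut_df)

    immune_truth = pd.Series(
        [cfg.immune_gradient[lab - 1] for lab in labels], index=tumor_ids, name="cytotoxic_shift"
    )

    return SyntheticCohort(
        expression=expr,
        truth_labels=truth,
        clinical=clinical,
        immune_truth=immune_truth,
        mtdna=mtdna,
        mutations=mutations,
        cell_profiles=profiles,
        gene_sets=coll,
        config=cfg,
    )


def generate_pseudobulk_mixture(
    cell_profiles: pd.DataFrame,
    f: float,
    n_samples: int,
    noise_sd: float = 0.2,
    seed: int = 0,
    sample_prefix: str = "MIX",
) -> ExpressionMatrix:
    """Bulk samples that are a linear mixture f * T-cell + (1 - f) * tumor.

    Noise is multiplicative log-normal, 2^N(0, noise_sd), so the per-gene
    geometric mean across samples is an unbiased (in log) estimate of the
    mixture mean.
    """
    if not 0 <= f <= 1:
        raise ValueError("f must be in [0, 1]")
    rng = np.random.default_rng(int(seed) % _SEED_MOD)
    mean = (
        f * cell_profiles["cytotoxic_t_cell"].to_numpy()
        + (1 - f) * cell_profiles["tumor_cell"].to_numpy()
    )
    noise = np.exp2(rng.normal(0.0, noise_sd, size=(len(mean), n_samples)))
    values = mean[:, None] * noise
    ids = [f"{sample_prefix}{i:04d}" for i in range(1, n_samples + 1)]
    meta = pd.DataFrame({"tissue_class": "tumor", "cohort": "pseudobulk"}, index=ids)
    return ExpressionMatrix(pd.DataFrame(values, index=cell_profiles.index, columns=ids), meta)


def generate_single_cells(
    cfg: CohortConfig,
    n_tumor_cells: int = 120,
    n_t_cells: int = 80,
    cytotoxic_fraction: float = 0.5,
    cell_noise_sd: float = 0.8,
) -> tuple[ExpressionMatrix, pd.Series, pd.Series]:
    """Single-cell matrix with tumor cells and T-cells (cytotoxic + regulatory).

    Returns (expression, annotations tumor/t_cell, T-cell subtype truth).
    Cytotoxic T-cells carry the cytotoxic and CD8 marker blocks; regulatory
    T-cells the Treg block. Used to exercise cytotoxic-subset recovery.
    """
    blocks = _gene_universe(cfg)
    base = _baselines(blocks, cfg.master_seed)
    rng = _rng(cfg.master_seed, 7)
    n_cyt = int(round(cytotoxic_fraction * n_t_cells))
    profiles = []
    ann, subtype, ids = [], [], []
    tumor_delta = pd.Series(0.0, index=base.index)
    tcell_common = pd.Series(0.0, index=base.index)
    tcell_common[blocks["oxphos"]] = -1.5
    tcell_common[blocks["muscle"]] = -2.0
    for i in range(n_tumor_cells):
        profiles.append(base + tumor_delta)
        ann.append("tumor")
        subtype.append("na")
        ids.append(f"TC{i:04d}")
    for i in range(n_t_cells):
        d = tcell_common.copy()
        if i < n_cyt:
            d[blocks["cytotoxic"]] += 4.0
            d[blocks["cd8"]] += 4.0
            subtype.append("cytotoxic")
        else:
            d[blocks["treg"]] += 4.0
            subtype.append("treg")
        profiles.append(base + d)
        ann.append("t_cell")
        ids.append(f"LC{i:04d}")
    M = np.stack([p.to_numpy() for p in profiles], axis=1)
    M = M + rng.normal(0.0, cell_noise_sd, size=M.shape)
    values = np.clip(np.exp2(M) - 1.0, 0.0, None)
    meta = pd.DataFrame({"tissue_class": "tumor", "cohort": "scrna"}, index=ids)
    expr = ExpressionMatrix(pd.DataFrame(values, index=base.index, columns=ids), meta)
    return expr, pd.Series(ann, index=ids), pd.Series(subtype, index=ids)


def generate_tissue_means(
    seed: int = 0,
    n_specific: int = 28,
    n_other_genes: int = 120,
    n_tissues: int = 46,
    target_tissue: str = "skeletal_muscle",
    fold: float = 10.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Genes x tissues mean-expression table with a planted target-specific panel.

    Exactly ``n_specific`` genes exceed ``fold`` times the maximum of every
    other tissue; the remaining genes are constructed to fall below the
    threshold (some enriched but under the fold cut). Returns the table and the
    planted panel gene names.
    """
    rng = np.random.default_rng(int(seed) % _SEED_MOD)
    tissues = [target_tissue] + [f"tissue{i:02d}" for i in range(1, n_tissues)]
    spec_genes = [f"MSP{i:03d}" for i in range(1, n_specific + 1)]
    other_genes = [f"OTH{i:03d}" for i in range(1, n_other_genes + 1)]
    rows = []
    for _ in spec_genes:
        target = rng.uniform(500, 2000)
        max_other = target / (fold * rng.uniform(1.3, 3.0))
        others = rng.uniform(0.05, 1.0, size=n_tissues - 1) * max_other
        others[rng.integers(n_tissues - 1)] = max_other
        rows.append(np.concatenate([[target], others]))
    for i, _ in enumerate(other_genes):
        if i % 3 == 0:  # enriched in target but below the fold threshold
            target = rng.uniform(100, 500)
            max_other = target / (fold * rng.uniform(0.3, 0.9))
        else:
            target = rng.uniform(1, 100)
            max_other = rng.uniform(0.5, 2.0) * target
        others = rng.uniform(0.05, 1.0, size=n_tissues - 1) * max_other
        others[rng.integers(n_tissues - 1)] = max_other
        rows.append(np.concatenate([[target], others]))
    df = pd.DataFrame(rows, index=spec_genes + other_genes, columns=tissues)
    return df, spec_genes
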