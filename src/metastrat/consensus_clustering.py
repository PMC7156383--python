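"""Resampling-based hierarchical consensus clustering with a distance-to-perfection
criterion for the number of clusters.

The consensus matrix follows the Monti et al. resampling scheme: items are
repeatedly subsampled without replacement, each subsample is clustered by
agglomerative hierarchical clustering (Euclidean distance, average linkage by
default), and the consensus entry M_ij is the fraction of co-sampled resamples
in which items i and j landed in the same cluster.

The number of clusters is chosen by the NED score: the root-mean-square
Euclidean distance, over unordered item pairs, between the consensus matrix and
the "theoretically perfect" 0/1 matrix implied by the final partition. NED = 0
means every pair is either always or never co-clustered exactly as the partition
says; 0.5 is the value of a maximally uninformative consensus. The k minimizing
NED is selected, ties broken toward smaller k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .io_formats import ExpressionMatrix, to_log2

__all__ = [
    "ConsensusMatrix",
    "ClusteringResult",
    "base_cluster",
    "build_consensus_matrix",
    "consensus_labels",
    "ned_score",
    "select_optimal_k",
    "two_way_cluster",
    "preprocess_for_clustering",
]

# NED at or above this value for every candidate k is reported as weak structure:
# 0.3 sits well above the near-zero scores of reproducible partitions and below
# the 0.5 of a maximally uninformative consensus.
WEAK_STRUCTURE_NED = 0.3

DEFAULT_N_RESAMPLES = 250
DEFAULT_SUBSAMPLE_FRACTION = 0.8


@dataclass
class ConsensusMatrix:
    M: np.ndarray
    co_sample_counts: np.ndarray
    k: int
    n_resamples: int
    subsample_fraction: float

    @property
    def n(self) -> int:
        return self.M.shape[0]


@dataclass
class PerKResult:
    consensus: ConsensusMatrix
    labels: np.ndarray  # 1..k
    ned: float


@dataclass
class ClusteringResult:
    per_k: dict[int, PerKResult]
    chosen_k: int
    labels: np.ndarray  # labels at chosen_k, 1..k
    item_order: np.ndarray  # consensus-ordered permutation at chosen_k
    weak_structure: bool = False
    item_ids: list[str] | None = None
    # filled by two_way_cluster
    gene_result: "ClusteringResult | None" = None
    ned_by_k: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ned_by_k = {k: r.ned for k, r in self.per_k.items()}


def base_cluster(
    X_sub: np.ndarray, k: int, metric: str = "euclidean", linkage_method: str = "average"
) -> np.ndarray:
    """Agglomerative clustering of the rows of ``X_sub``, tree cut to exactly k groups.

    Returns integer labels in 1..k.
    """
    X_sub = np.asarray(X_sub, dtype=float)
    n = X_sub.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of items {n}")
    if k == n:
        return np.arange(1, n + 1)
    Z = linkage(pdist(X_sub, metric=metric), method=linkage_method)
    return cut_tree(Z, n_clusters=k).ravel() + 1


def build_consensus_matrix(
    X: np.ndarray,
    k: int,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    seed: int | np.random.Generator = 0,
    metric: str = "euclidean",
    linkage_method: str = "average",
) -> ConsensusMatrix:
    """Tally co-clustering over resampled runs of the base learner.

    Each resample draws ceil(fraction * n) items without replacement, clusters
    them with :func:`base_cluster`, and increments pairwise co-cluster and
    co-sample counts. M = co_cluster / co_sample elementwise; pairs never drawn
    together are imputed at 0.5 (uninformative) with a warning; the diagonal is 1.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not (0 < subsample_fraction <= 1):
        raise ValueError("subsample_fraction must be in (0, 1]")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = int(np.ceil(subsample_fraction * n))
    co_cluster = np.zeros((n, n), dtype=np.int64)
    co_sample = np.zeros((n, n), dtype=np.int64)
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        labels = base_cluster(X[idx], k, metric=metric, linkage_method=linkage_method)
        eq = (labels[:, None] == labels[None, :]).astype(np.int64)
        block = np.ix_(idx, idx)
        co_cluster[block] += eq
        co_sample[block] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        M = co_cluster / co_sample
    never = co_sample == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(
            f"{int(never.sum()) // 2} item pairs never co-sampled; consensus imputed at 0.5"
        )
        M[never] = 0.5
    np.fill_diagonal(M, 1.0)
    return ConsensusMatrix(M, co_sample, k, n_resamples, subsample_fraction)


def consensus_labels(M: ConsensusMatrix | np.ndarray, k: int) -> np.ndarray:
    """Final partition: average-linkage tree on dissimilarity 1 - M, cut at k."""
    mat = M.M if isinstance(M, ConsensusMatrix) else np.asarray(M, dtype=float)
    Z = _consensus_linkage(mat)
    return cut_tree(Z, n_clusters=k).ravel() + 1


def _consensus_linkage(mat: np.ndarray) -> np.ndarray:
    D = 1.0 - mat
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)  # symmetrize against fp jitter
    return linkage(squareform(D, checks=False), method="average")


def ned_score(M: ConsensusMatrix | np.ndarray, labels: np.ndarray) -> float:
    """Root-mean-square distance of the consensus matrix from the perfect matrix.

    The perfect matrix P has P_ij = 1 iff i and j share a label (diagonal 1).
    The score is sqrt( sum_{i<j} (M_ij - P_ij)^2 / (n(n-1)/2) ); 0 is perfection.
    """
    mat = M.M if isinstance(M, ConsensusMatrix) else np.asarray(M, dtype=float)
    labels = np.asarray(labels)
    n = mat.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length does not match consensus matrix size")
    P = (labels[:, None] == labels[None, :]).astype(float)
    iu = np.triu_indices(n, k=1)
    diff = mat[iu] - P[iu]
    return float(np.sqrt(np.mean(diff**2)))


def select_optimal_k(
    X: np.ndarray,
    k_range,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    seed: int = 0,
    metric: str = "euclidean",
    linkage_method: str = "average",
    item_ids: list[str] | None = None,
) -> ClusteringResult:
    """Evaluate each candidate k and pick the one minimizing the NED score.

    Ties are broken toward smaller k. Every per-k consensus matrix, partition
    and score is retained. If no candidate achieves NED below the weak-structure
    threshold the result is flagged as weak structure.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range must be non-empty")
    if min(k_range) < 2:
        raise ValueError("every k must be >= 2")
    per_k: dict[int, PerKResult] = {}
    for k in k_range:
        rng = np.random.default_rng([int(seed) % (2**31), k])
        cm = build_consensus_matrix(
            X,
            k,
            n_resamples=n_resamples,
            subsample_fraction=subsample_fraction,
            seed=rng,
            metric=metric,
            linkage_method=linkage_method,
        )
        labels = consensus_labels(cm, k)
        per_k[k] = PerKResult(cm, labels, ned_score(cm, labels))
    chosen_k = min(k_range, key=lambda k: (per_k[k].ned, k))
    best = per_k[chosen_k]
    order = leaves_list(_consensus_linkage(best.consensus.M))
    weak = all(r.ned >= WEAK_STRUCTURE_NED for r in per_k.values())
    if weak:
        warnings.warn(
            "no candidate k reached a reproducible consensus (weak structure); "
            "chosen_k is reported but should not be interpreted"
        )
    return ClusteringResult(
        per_k=per_k,
        chosen_k=chosen_k,
        labels=best.labels,
        item_order=order,
        weak_structure=weak,
        item_ids=item_ids,
    )


def preprocess_for_clustering(X: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount) then gene-wise z-scoring (population sd).

    Zero-variance genes are left at 0 after centering.
    """
    L = to_log2(X, pseudocount)
    mu = L.mean(axis=1)
    sd = L.std(axis=1, ddof=0)
    Z = L.sub(mu, axis=0)
    nonzero = sd > 0
    Z.loc[nonzero] = Z.loc[nonzero].div(sd[nonzero], axis=0)
    return Z


def relabel_by_signature(
    labels: np.ndarray,
    primary: np.ndarray,
    secondary: np.ndarray | None = None,
    tie_rel_tol: float = 0.25,
) -> np.ndarray:
    """Re-index clusters 1..k by descending per-cluster mean of ``primary``.

    Cluster means separated by less than ``tie_rel_tol`` times the overall
    spread of cluster means are treated as tied (clusters whose primary
    signature is effectively the same up to sampling noise) and ordered by
    ascending mean of ``secondary``. Used so that cluster 1 is the partition
    cell with the highest primary and lowest secondary signature expression,
    matching the field's heatmap convention.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    prim = {c: float(np.mean(primary[labels == c])) for c in uniq}
    sec = {
        c: float(np.mean(secondary[labels == c])) if secondary is not None else 0.0 for c in uniq
    }
    tol = tie_rel_tol * (max(prim.values()) - min(prim.values()))
    # walk clusters by descending primary mean; a gap <= tol chains the next
    # cluster into the current tier, a larger gap starts a new tier
    by_prim = sorted(uniq, key=lambda c: -prim[c])
    tiers: list[list] = []
    for c in by_prim:
        if tiers and prim[tiers[-1][-1]] - prim[c] <= tol:
            tiers[-1].append(c)
        else:
            tiers.append([c])
    ordered = [c for tier in tiers for c in sorted(tier, key=lambda c: (sec[c], c))]
    mapping = {old: new for new, old in enumerate(ordered, start=1)}
    return np.array([mapping[c] for c in labels])


def two_way_cluster(
    X: ExpressionMatrix,
    sample_k_range,
    gene_k_range,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    seed: int = 0,
    signature_genes: list[str] | None = None,
    secondary_genes: list[str] | None = None,
) -> ClusteringResult:
    """Two-way consensus clustering: samples on columns, genes on rows.

    The matrix is preprocessed (log2, gene-wise z-score); samples are clustered
    in that gene space and genes in the transposed space, each with its own
    optimal-k search. Sample clusters are re-indexed by descending mean
    expression over ``signature_genes`` (default: all genes), so cluster 1 is
    the highest-signature cluster; ``secondary_genes`` break ties by ascending
    mean. Gene clusters are re-indexed by descending mean expression.
    """
    Z = preprocess_for_clustering(X)
    sample_res = select_optimal_k(
        Z.values.T,
        sample_k_range,
        n_resamples=n_resamples,
        subsample_fraction=subsample_fraction,
        seed=int(seed) % (2**31),
        item_ids=list(Z.columns),
    )
    gene_res = select_optimal_k(
        Z.values,
        gene_k_range,
        n_resamples=n_resamples,
        subsample_fraction=subsample_fraction,
        seed=(int(seed) + 1) % (2**31),
        item_ids=list(Z.index),
    )
    sig = Z.index if signature_genes is None else Z.index.intersection(signature_genes)
    primary = Z.loc[sig].mean(axis=0).to_numpy()
    secondary = None
    if secondary_genes is not None:
        sec_idx = Z.index.intersection(secondary_genes)
        if len(sec_idx):
            secondary = Z.loc[sec_idx].mean(axis=0).to_numpy()
    sample_res.labels = relabel_by_signature(sample_res.labels, primary, secondary)
    gene_res.labels = relabel_by_signature(gene_res.labels, Z.mean(axis=1).to_numpy())
    sample_res.gene_result = gene_res
    return sample_res
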