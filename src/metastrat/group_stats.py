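"""Between-cluster statistics: per-gene Welch t-tests with BH control,
geometric-mean fold-ratio annotation, mutation-cluster association, covariate
trends across clusters, and the genome-wide correlation screen against a
signature score.

Conventions: differential testing runs on log2(x+1) values; fold annotation on
linear values via ratios of group geometric means with a pseudocount; the
mutation association uses Pearson chi-square without continuity correction on a
mutated/not x cluster-of-interest/others table; BH families default to FDR 0.05
for expression and 0.01 for mutation association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, MutationTable, to_log2

__all__ = [
    "DifferentialResult",
    "FoldAnnotation",
    "welch_tests_by_gene",
    "bh_adjust",
    "gm_ratio_annotation",
    "mutation_cluster_association",
    "impactful_filter",
    "covariate_by_cluster",
    "correlate_genes_with_score",
]


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # per gene: mean_a, mean_b, t_stat, p_raw, p_adj, significant, direction
    fdr: float
    group_a: object
    group_b: object


@dataclass
class FoldAnnotation:
    table: pd.DataFrame  # per gene: ratio, fold_class
    fold_threshold: float
    pseudocount: float


def _group_columns(X: ExpressionMatrix, labels: pd.Series, group) -> list[str]:
    labels = pd.Series(labels)
    members = labels.index[labels.isin(group if isinstance(group, (list, tuple, set)) else [group])]
    return [s for s in X.sample_ids if s in set(members)]


def welch_tests_by_gene(
    X: ExpressionMatrix,
    labels: pd.Series | dict,
    group_a,
    group_b,
    fdr: float = 0.05,
    pseudocount: float = 1.0,
) -> DifferentialResult:
    """Two-sided Welch t-test per gene on log2(x + pseudocount), BH-adjusted.

    ``group_a`` / ``group_b`` are cluster labels or lists of labels (so a
    cluster can be compared to several clusters pooled).
    """
    labels = pd.Series(labels)
    cols_a = _group_columns(X, labels, group_a)
    cols_b = _group_columns(X, labels, group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    L = to_log2(X, pseudocount)
    A = L[cols_a].to_numpy()
    B = L[cols_b].to_numpy()
    t_stat, p_raw = stats.ttest_ind(A, B, axis=1, equal_var=False)
    # identical groups give 0/0 -> nan; by convention no evidence of difference
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    p_adj, flags = bh_adjust(p_raw, fdr)
    tbl = pd.DataFrame(
        {
            "mean_a": A.mean(axis=1),
            "mean_b": B.mean(axis=1),
            "t_stat": t_stat,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": flags,
            "direction": np.where(A.mean(axis=1) >= B.mean(axis=1), "up", "down"),
        },
        index=X.values.index,
    )
    return DifferentialResult(table=tbl, fdr=fdr, group_a=group_a, group_b=group_b)


def bh_adjust(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or not np.all(np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    _, p_adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return p_adj, p_adj <= fdr


def gm_ratio_annotation(
    X: ExpressionMatrix,
    labels: pd.Series | dict,
    numerator_group,
    denominator_group,
    pseudocount: float = 1.0,
    fold_threshold: float = 1.4,
) -> FoldAnnotation:
    """Per-gene ratio of group geometric means of (linear value + pseudocount).

    Classes: ``up`` when ratio >= fold_threshold, ``down`` when
    ratio <= 1/fold_threshold, otherwise ``unchanged``.
    """
    labels = pd.Series(labels)
    cols_n = _group_columns(X, labels, numerator_group)
    cols_d = _group_columns(X, labels, denominator_group)
    if not cols_n or not cols_d:
        raise ValueError("both groups must be non-empty")
    logv = np.log(X.values + pseudocount)
    gm_n = np.exp(logv[cols_n].mean(axis=1))
    gm_d = np.exp(logv[cols_d].mean(axis=1))
    ratio = gm_n / gm_d
    cls = np.where(
        ratio >= fold_threshold, "up", np.where(ratio <= 1.0 / fold_threshold, "down", "unchanged")
    )
    tbl = pd.DataFrame({"ratio": ratio, "fold_class": cls}, index=X.values.index)
    return FoldAnnotation(table=tbl, fold_threshold=fold_threshold, pseudocount=pseudocount)


def impactful_filter(mutations: MutationTable) -> MutationTable:
    """Keep mutations with SIFT deleterious OR PolyPhen probably/possibly damaging.

    Rows missing both annotations are treated as non-impactful and dropped.
    """
    df = mutations.data
    keep = (df["sift_label"] == "deleterious") | df["polyphen_label"].isin(
        ["probably_damaging", "possibly_damaging"]
    )
    return MutationTable(df[keep].reset_index(drop=True))


def mutation_cluster_association(
    mutations: MutationTable,
    labels: pd.Series | dict,
    genes=None,
    fdr: float = 0.01,
    cluster_of_interest: int = 1,
    layout: str = "one_vs_rest",
    yates: bool = False,
) -> pd.DataFrame:
    """Per-gene chi-square association between mutation status and cluster.

    Default table layout: mutated/not x (cluster_of_interest vs all others);
    ``layout='k_way'`` uses the full mutated/not x cluster table. Degenerate
    tables (a zero margin, e.g. a gene mutated in no sample) are flagged and
    excluded from the BH family.
    """
    labels = pd.Series(labels)
    samples = labels.index
    if genes is None:
        genes = sorted(mutations.data["gene"].unique())
    mut_by_gene = {
        g: set(mutations.data.loc[mutations.data["gene"] == g, "sample_id"]) for g in genes
    }
    if layout == "one_vs_rest":
        group_of = labels.eq(cluster_of_interest).map({True: "interest", False: "rest"})
    elif layout == "k_way":
        group_of = labels.astype(str)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    group_names = sorted(group_of.unique())
    rows = []
    for g in genes:
        mutated = np.array([s in mut_by_gene[g] for s in samples])
        table = np.array(
            [
                [int((mutated & (group_of == gn).to_numpy()).sum()) for gn in group_names],
                [int((~mutated & (group_of == gn).to_numpy()).sum()) for gn in group_names],
            ]
        )
        degenerate = (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any()
        if degenerate:
            rows.append({"gene": g, "n_mutated": int(mutated.sum()), "chi_square": np.nan,
                         "p_raw": np.nan, "degenerate": True})
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
        rows.append({"gene": g, "n_mutated": int(mutated.sum()), "chi_square": float(chi2),
                     "p_raw": float(p), "degenerate": False})
    out = pd.DataFrame(rows).set_index("gene")
    out["p_adj"] = np.nan
    out["significant"] = False
    ok = ~out["degenerate"]
    if ok.any():
        p_adj, flags = bh_adjust(out.loc[ok, "p_raw"].to_numpy(), fdr)
        out.loc[ok, "p_adj"] = p_adj
        out.loc[ok, "significant"] = flags
    return out


def covariate_by_cluster(values: pd.Series | dict, labels: pd.Series | dict) -> dict:
    """Per-cluster summary of a numeric covariate with ANOVA, Tukey HSD, and a
    monotone-trend statistic (Spearman of value vs cluster index).

    Clusters with fewer than 2 samples are excluded with a warning.
    """
    values = pd.Series(values, dtype=float)
    labels = pd.Series(labels).loc[values.index]
    groups, used = [], []
    for c in sorted(pd.unique(labels)):
        v = values[labels == c].to_numpy()
        if v.size < 2:
            warnings.warn(f"cluster {c} has < 2 samples; excluded from the comparison")
            continue
        groups.append(v)
        used.append(c)
    if len(used) < 2:
        raise ValueError("need >= 2 clusters with >= 2 samples")
    f_stat, f_p = stats.f_oneway(*groups)
    summary = pd.DataFrame(
        {
            "cluster": used,
            "n": [g.size for g in groups],
            "mean": [g.mean() for g in groups],
            "ci95_half_width": [
                stats.t.ppf(0.975, g.size - 1) * g.std(ddof=1) / np.sqrt(g.size) for g in groups
            ],
        }
    ).set_index("cluster")
    mask = labels.isin(used)
    tuk = pairwise_tukeyhsd(values[mask].to_numpy(), labels[mask].to_numpy())
    tukey = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
    rho, rho_p = stats.spearmanr(labels[mask].to_numpy(dtype=float), values[mask].to_numpy())
    return {
        "summary": summary,
        "anova_F": float(f_stat),
        "anova_p": float(f_p),
        "tukey": tukey,
        "trend_spearman_rho": float(rho),
        "trend_spearman_p": float(rho_p),
    }


def correlate_genes_with_score(X: ExpressionMatrix, score: pd.Series | dict) -> pd.DataFrame:
    """Pearson correlation (r and p) of every gene with a per-sample score,
    sorted by |r| descending. Constant genes are reported with missing r."""
    score = pd.Series(score, dtype=float)
    common = [s for s in X.sample_ids if s in score.index]
    if len(common) < 3:
        raise ValueError("need at least 3 samples with scores")
    V = X.values[common].to_numpy(dtype=float)
    y = score.loc[common].to_numpy(dtype=float)
    n = len(common)
    Vc = V - V.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Vc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Vc @ yc) / (sx * sy)
    const = sx == 0
    r = np.where(const, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2 * stats.t.sf(np.abs(t), df=n - 2))
    p = np.where(const, np.nan, p)
    out = pd.DataFrame({"r": r, "p": p}, index=X.values.index)
    return out.reindex(out["r"].abs().sort_values(ascending=False, na_position="last").index)
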