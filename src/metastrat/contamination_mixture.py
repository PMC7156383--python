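"""T-cell contamination mixture model: can the expression differences of the
high-signature cluster be explained purely by admixed cytotoxic T-cells?

Given per-gene mean linear expression of tumor cells and cytotoxic T-cells
(from annotated single-cell data), the expected bulk fold change under a
contamination fraction f is

    expected_fc(g) = (f * tcell_mean(g) + (1 - f) * tumor_mean(g)) / tumor_mean(g)

(mixtures add on the linear scale, so cell-class means are arithmetic).
Observed fold changes are ratios of group geometric means between the cluster
of interest and a comparator group. Each gene is classified on the
(log2 observed, log2 expected) plane: points in the region the quadrant /
identity-line rule marks as inconsistent with contamination are
``not_explainable``; everything else, including points on (or within a small
tolerance band of) the identity line, is ``potentially_explainable``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus_clustering import select_optimal_k
from .io_formats import ExpressionMatrix, GeneSetCollection
from .group_stats import DifferentialResult, gm_ratio_annotation
from .ssgsea_scoring import ssgsea_table, zscore_scores

__all__ = [
    "CellMeanProfiles",
    "MixtureModelResult",
    "cell_profiles_from_annotated_sc",
    "expected_mixture_fc",
    "classify_explainability",
    "mixture_report",
    "ZERO_CHANGE_TOL",
]

# log2 tolerance treated as "no change" / "on the identity line": a 5% fold change
ZERO_CHANGE_TOL = float(np.log2(1.05))

POTENTIALLY_EXPLAINABLE = "potentially_explainable"
NOT_EXPLAINABLE = "not_explainable"


@dataclass
class CellMeanProfiles:
    profiles: pd.DataFrame  # gene x {tumor_cell, cytotoxic_t_cell} linear means
    n_tumor_cells: int
    n_cytotoxic_cells: int

    def __post_init__(self) -> None:
        for col in ("tumor_cell", "cytotoxic_t_cell"):
            if col not in self.profiles.columns:
                raise ValueError(f"profiles missing column {col!r}")
        if (self.profiles[["tumor_cell", "cytotoxic_t_cell"]].to_numpy() < 0).any():
            raise ValueError("cell means must be >= 0")


@dataclass
class MixtureModelResult:
    table: pd.DataFrame  # per gene: expected_fc, observed_fc, significant, explainability
    fraction: float
    summary: pd.DataFrame  # counts by (category x class x significance)


def cell_profiles_from_annotated_sc(
    sc_matrix: ExpressionMatrix,
    annotations: pd.Series,
    immune_sets: GeneSetCollection,
    cytotoxic_signature: str = "cytotoxic_cells",
    k_range=(2, 3),
    n_resamples: int = 50,
    seed: int = 0,
) -> CellMeanProfiles:
    """Arithmetic per-gene means for tumor cells and the cytotoxic T-cell subset.

    T-cells are sub-clustered by consensus clustering of their per-cell immune
    signature scores; the cluster with the highest mean cytotoxic score is
    taken as the cytotoxic subset. With a single T-cell, sub-clustering is
    skipped and that cell is used directly (flagged by n_cytotoxic_cells = 1).
    """
    annotations = pd.Series(annotations).loc[sc_matrix.sample_ids]
    tumor_ids = list(annotations.index[annotations == "tumor"])
    tcell_ids = list(annotations.index[annotations == "t_cell"])
    if not tumor_ids or not tcell_ids:
        raise ValueError("annotations must include both tumor and t_cell cells")
    if len(tcell_ids) == 1:
        cytotoxic_ids = tcell_ids
    else:
        tcells = sc_matrix.subset_samples(tcell_ids)
        scores = ssgsea_table(tcells, immune_sets)
        z = zscore_scores(scores).z_view
        res = select_optimal_k(z.to_numpy(), k_range, n_resamples=n_resamples, seed=seed)
        labels = pd.Series(res.labels, index=z.index)
        if cytotoxic_signature not in z.columns:
            raise ValueError(f"no {cytotoxic_signature!r} signature among immune sets")
        mean_by_cluster = z[cytotoxic_signature].groupby(labels).mean()
        best = mean_by_cluster.idxmax()
        cytotoxic_ids = list(labels.index[labels == best])
        rest = mean_by_cluster.drop(best)
        if len(rest) and float(mean_by_cluster[best]) <= float(rest.max()) + 1e-12:
            raise ValueError("no cytotoxic subset distinguishable among T-cell clusters")
    prof = pd.DataFrame(
        {
            "tumor_cell": sc_matrix.values[tumor_ids].mean(axis=1),
            "cytotoxic_t_cell": sc_matrix.values[cytotoxic_ids].mean(axis=1),
        }
    )
    return CellMeanProfiles(prof, n_tumor_cells=len(tumor_ids), n_cytotoxic_cells=len(cytotoxic_ids))


def expected_mixture_fc(
    profiles: CellMeanProfiles | pd.DataFrame, f: float, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene fold change expected from f T-cell / (1 - f) tumor admixture."""
    if not 0 <= f <= 1:
        raise ValueError("f must be in [0, 1]")
    df = profiles.profiles if isinstance(profiles, CellMeanProfiles) else profiles
    tumor = df["tumor_cell"].to_numpy(dtype=float) + pseudocount
    tcell = df["cytotoxic_t_cell"].to_numpy(dtype=float) + pseudocount
    if (tumor <= 0).any():
        raise ValueError("tumor means must be > 0 after pseudocount")
    fc = (f * tcell + (1 - f) * tumor) / tumor
    return pd.Series(fc, index=df.index, name="expected_fc")


def classify_explainability(
    expected_fc: float, observed_fc: float, significant_flag: bool = True
) -> str:
    """Classify one gene's (observed, expected) fold-change pair.

    Work with x = log2(observed), y = log2(expected). Rules, in order:

    1. expected essentially unchanged (|y| <= log2(1.05)): contamination
       predicts no change, so any observed change beyond the same tolerance is
       ``not_explainable``.
    2. points within the tolerance band of the identity line are
       ``potentially_explainable`` (the boundary belongs to the contamination
       explanation - conservative).
    3. otherwise the quadrant rule: ``not_explainable`` when y > x in quadrants
       I and III (both changes in the same direction) or y < x in quadrants II
       and IV (opposite directions); an x within the zero tolerance adopts the
       sign of y for quadrant assignment.

    The significance flag is carried through by the caller for reporting; it
    does not alter the geometric classification.
    """
    if expected_fc <= 0 or observed_fc <= 0:
        raise ValueError("fold changes must be > 0")
    x = float(np.log2(observed_fc))
    y = float(np.log2(expected_fc))
    if abs(y) <= ZERO_CHANGE_TOL:
        return NOT_EXPLAINABLE if abs(x) > ZERO_CHANGE_TOL else POTENTIALLY_EXPLAINABLE
    if abs(y - x) <= ZERO_CHANGE_TOL:
        return POTENTIALLY_EXPLAINABLE
    sx = np.sign(x) if abs(x) > ZERO_CHANGE_TOL else np.sign(y)
    sy = np.sign(y)
    same_direction = sx == sy
    if same_direction:  # quadrants I and III
        return NOT_EXPLAINABLE if y > x else POTENTIALLY_EXPLAINABLE
    return NOT_EXPLAINABLE if y < x else POTENTIALLY_EXPLAINABLE  # quadrants II and IV


def mixture_report(
    X: ExpressionMatrix,
    labels: pd.Series | dict,
    profiles: CellMeanProfiles | pd.DataFrame,
    f: float,
    de_result: DifferentialResult | None = None,
    cluster_of_interest: int = 1,
    comparator=None,
    genes=None,
    gene_categories: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> MixtureModelResult:
    """Expected-vs-observed fold-change table with explainability classes.

    Observed fold changes are cluster-of-interest vs comparator (default: all
    other clusters) geometric-mean ratios; expected fold changes come from the
    mixture model at fraction ``f``. A differential-expression result may be
    supplied to carry per-gene significance into the summary counts.
    """
    labels = pd.Series(labels)
    clusters = sorted(pd.unique(labels))
    if comparator is None:
        comparator = [c for c in clusters if c != cluster_of_interest]
    prof_df = profiles.profiles if isinstance(profiles, CellMeanProfiles) else profiles
    if genes is None:
        genes = [g for g in X.gene_ids if g in prof_df.index]
    Xg = X.subset_genes(genes)
    observed = gm_ratio_annotation(
        Xg, labels, [cluster_of_interest], comparator, pseudocount=pseudocount
    ).table["ratio"]
    expected = expected_mixture_fc(prof_df.loc[genes], f, pseudocount=pseudocount)
    sig = pd.Series(False, index=pd.Index(genes))
    if de_result is not None:
        sig = de_result.table["significant"].reindex(genes).fillna(False).astype(bool)
    classes = [
        classify_explainability(expected[g], observed[g], bool(sig[g])) for g in genes
    ]
    tbl = pd.DataFrame(
        {
            "expected_fc": expected.loc[genes],
            "observed_fc": observed.loc[genes],
            "significant": sig,
            "explainability": classes,
        },
        index=pd.Index(genes, name="gene"),
    )
    if gene_categories is not None:
        tbl["category"] = gene_categories.reindex(genes).fillna("other")
    else:
        tbl["category"] = "all"
    summary = (
        tbl.groupby(["category", "explainability", "significant"], observed=True)
        .size()
        .rename("n_genes")
        .reset_index()
    )
    return MixtureModelResult(table=tbl, fraction=f, summary=summary)
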