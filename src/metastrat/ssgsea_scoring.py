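"""Single-sample gene-set enrichment scoring and derived signature scores.

The per-sample enrichment statistic is the Barbie-style running sum: genes are
ranked by decreasing linear expression (ties broken lexicographically by gene
symbol), in-set genes contribute their rank weight r^alpha to a weighted
empirical CDF, out-of-set genes contribute a uniform step, and the score is the
sum over all ranked positions of the difference between the two CDFs.

Also here: per-signature Z-scoring across a cohort, subtractive combined scores
(e.g. cytotoxic-minus-Treg), derivation of tissue-specific marker panels from a
tissue-mean table, and a leukocyte-specificity filter for immune marker sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = [
    "ScoreTable",
    "CombinedScore",
    "ScoringError",
    "ssgsea_single",
    "ssgsea_table",
    "zscore_scores",
    "combined_subtractive_score",
    "derive_tissue_specific_panel",
    "filter_markers_by_specificity",
]

DEFAULT_ALPHA = 0.75


class ScoringError(ValueError):
    pass


@dataclass
class ScoreTable:
    """Samples x signatures enrichment scores with optional normalized / Z views."""

    scores: pd.DataFrame  # index sample_id, columns signature names
    normalized: pd.DataFrame | None = None
    z_view: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def signatures(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class CombinedScore:
    values: pd.Series  # sample -> z(minuend) - z(subtrahend)
    minuend: str
    subtrahend: str


def ssgsea_single(
    expr_values: pd.Series | dict, gene_set: GeneSet, alpha: float = DEFAULT_ALPHA
) -> float:
    """Enrichment score of one gene set in one sample's linear expression vector.

    Ranks are 1..N with N the highest-expressed gene; the in-set ECDF is
    weighted by rank^alpha, the out-of-set ECDF is unweighted. Deterministic:
    expression ties are broken by gene symbol order.
    """
    if not isinstance(expr_values, pd.Series):
        expr_values = pd.Series(expr_values)
    genes = expr_values.index.to_numpy(dtype=object)
    vals = expr_values.to_numpy(dtype=float)
    n = len(genes)
    in_set_mask = np.isin(genes, np.array(gene_set.genes, dtype=object))
    m = int(in_set_mask.sum())
    if m == 0:
        raise ScoringError(f"gene set {gene_set.name!r} shares no genes with the sample")
    if m == n:
        raise ScoringError(
            f"gene set {gene_set.name!r} covers every gene; out-of-set ECDF undefined"
        )
    # decreasing expression, ties by symbol: sort ascending on (-value, symbol)
    order = np.lexsort((genes.astype(str), -vals))
    in_sorted = in_set_mask[order]
    ranks = np.arange(n, 0, -1, dtype=float)  # position 0 (highest expr) -> rank N
    w = np.where(in_sorted, np.abs(ranks) ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_sorted) / (n - m)
    return float(np.sum(p_in - p_out))


def ssgsea_table(
    X: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = False,
) -> ScoreTable:
    """Score every sample against every gene set.

    Set genes absent from the matrix are skipped (intersection scoring) and the
    per-set match count is recorded in provenance. With ``normalize=True`` all
    raw scores are additionally divided by the global (max - min) of the table.
    """
    universe = X.values.index
    matched: dict[str, int] = {}
    cols: dict[str, np.ndarray] = {}
    # Rank computations vectorized across samples per set via a shared ordering
    # would break symbol tie-handling per sample; sample vectors differ, so we
    # score sample-by-sample.
    for gs in sets:
        present = [g for g in gs.genes if g in universe]
        if not present:
            raise ScoringError(f"gene set {gs.name!r} shares no genes with the matrix")
        matched[gs.name] = len(present)
        sub = GeneSet(name=gs.name, genes=present, category=gs.category)
        col = np.empty(X.shape[1])
        for j, s in enumerate(X.values.columns):
            col[j] = ssgsea_single(X.values[s], sub, alpha=alpha)
        cols[gs.name] = col
    scores = pd.DataFrame(cols, index=X.values.columns)
    scores.index.name = "sample_id"
    normalized = None
    if normalize:
        rng_ = scores.values.max() - scores.values.min()
        if rng_ == 0:
            raise ScoringError("cannot normalize: all scores identical")
        normalized = scores / rng_
    return ScoreTable(
        scores=scores,
        normalized=normalized,
        provenance={"alpha": alpha, "genes_matched": matched, "set_sizes": {g.name: len(g) for g in sets}},
    )


def zscore_scores(S: ScoreTable) -> ScoreTable:
    """Per-signature Z-transform across samples (population sd)."""
    if len(S.scores) < 2:
        raise ScoringError("Z-scoring requires at least 2 samples")
    mu = S.scores.mean(axis=0)
    sd = S.scores.std(axis=0, ddof=0)
    zero = sd[sd == 0]
    if len(zero):
        raise ScoringError(f"zero-variance signature(s): {list(zero.index)}")
    z = (S.scores - mu) / sd
    return ScoreTable(scores=S.scores, normalized=S.normalized, z_view=z, provenance=dict(S.provenance))


def combined_subtractive_score(S: ScoreTable, minuend: str, subtrahend: str) -> CombinedScore:
    """Elementwise z(minuend) - z(subtrahend), e.g. cytotoxic minus Treg."""
    for name in (minuend, subtrahend):
        if name not in S.scores.columns:
            raise KeyError(f"unknown signature {name!r}")
    z = S.z_view if S.z_view is not None else zscore_scores(S).z_view
    return CombinedScore(values=z[minuend] - z[subtrahend], minuend=minuend, subtrahend=subtrahend)


def derive_tissue_specific_panel(
    tissue_means: pd.DataFrame,
    target_tissue: str,
    fold_threshold: float = 10.0,
    name: str | None = None,
) -> GeneSet:
    """Genes whose mean in the target tissue is >= fold_threshold times the
    maximum mean over every other tissue (boundary inclusive).

    ``tissue_means`` is genes x tissues of linear means. Mirrors the derivation
    of a skeletal-muscle contamination panel from normal-tissue atlases.
    """
    if target_tissue not in tissue_means.columns:
        raise KeyError(f"target tissue {target_tissue!r} not in table")
    if tissue_means.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    target = tissue_means[target_tissue]
    others = tissue_means.drop(columns=[target_tissue]).max(axis=1)
    keep = target >= fold_threshold * others
    genes = list(tissue_means.index[keep])
    panel_name = name or f"{target_tissue}_specific"
    if not genes:
        warnings.warn(
            f"no genes pass the {fold_threshold}-fold {target_tissue} specificity filter"
        )
        # bypass the non-empty invariant: an empty panel is a legal (warned) outcome
        gs = GeneSet.__new__(GeneSet)
        gs.name, gs.genes, gs.category, gs.description = panel_name, [], "tissue_panel", ""
        return gs
    return GeneSet(name=panel_name, genes=genes, category="tissue_panel")


def filter_markers_by_specificity(
    markers: GeneSetCollection,
    leukocyte_expr: pd.Series,
    background_expr: pd.Series,
    ratio_threshold: float = 4.0,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Retain marker genes whose leukocyte/background mean-expression ratio is
    at least ``ratio_threshold``; returns the filtered collection and a removal
    report (gene, set, ratio, kept).

    The default threshold of 4 is a configurable stand-in for the specificity
    cut used when curating immune-subset lists against non-leukocyte tissue.
    """
    records = []
    out = GeneSetCollection()
    for gs in markers:
        kept = []
        for g in gs.genes:
            in_leuk = g in leukocyte_expr.index
            in_bg = g in background_expr.index
            if not in_leuk and not in_bg:
                warnings.warn(f"marker {g} absent from both profiles; dropped")
                records.append({"set": gs.name, "gene": g, "ratio": np.nan, "kept": False})
                continue
            leuk = float(leukocyte_expr.get(g, 0.0))
            bg = float(background_expr.get(g, 0.0))
            ratio = np.inf if bg == 0 else leuk / bg
            keep = ratio >= ratio_threshold
            records.append({"set": gs.name, "gene": g, "ratio": ratio, "kept": bool(keep)})
            if keep:
                kept.append(g)
        if kept:
            out.add(GeneSet(name=gs.name, genes=kept, category=gs.category))
        else:
            warnings.warn(f"set {gs.name!r} lost all genes to the specificity filter")
    return out, pd.DataFrame.from_records(records)
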