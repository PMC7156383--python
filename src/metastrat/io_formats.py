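"""Shared data model and readers/writers for the tabular formats the pipeline touches.

Expression matrices are gene-major TSV (first column gene symbols, header row of
sample identifiers), gene sets are GMT, mutations arrive as tab-separated MAF-like
tables with configurable column names, and clinical / mitochondrial-copy-number
tables are plain TSV with a declared column map.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "ClinicalTable",
    "MutationTable",
    "FormatError",
    "ValidationError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_maf",
    "read_clinical_tsv",
    "to_log2",
    "from_log2",
]

SIFT_LABELS = ("deleterious", "tolerated")
POLYPHEN_LABELS = ("probably_damaging", "possibly_damaging", "benign")
MISSING = "missing"


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Linear, non-negative gene x sample expression with sample annotations.

    ``values`` is a genes-by-samples DataFrame in linear RSEM-like units.
    ``sample_meta`` is indexed by sample id with at least ``tissue_class``
    (``tumor`` or ``normal``) and ``cohort`` columns.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(
                {"tissue_class": "tumor", "cohort": "cohort"},
                index=self.values.columns,
            )
        vals = np.asarray(self.values.values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("expression values must be finite")
        if (vals < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        missing = self.values.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValidationError(f"sample_meta missing samples: {list(missing)[:5]}")
        self.sample_meta = self.sample_meta.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[present], self.sample_meta.copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(samples)], self.sample_meta.loc[list(samples)].copy()
        )


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    category: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        self.sets[gs.name] = gs

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample overall survival: time in months (>0), event 1=death 0=censored."""

    data: pd.DataFrame  # index sample_id; columns os_time, os_event, + covariates

    def __post_init__(self) -> None:
        for col in ("os_time", "os_event"):
            if col not in self.data.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        if self.data.index.duplicated().any():
            raise ValidationError("clinical table has duplicate sample ids")
        t = self.data["os_time"].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or (t <= 0).any():
            raise ValidationError("os_time must be finite and positive")
        e = self.data["os_event"].to_numpy()
        if not np.isin(e, [0, 1]).all():
            raise ValidationError("os_event must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class MutationTable:
    """Rows of (gene, sample_id, variant_classification, sift_label, polyphen_label)."""

    data: pd.DataFrame

    REQUIRED = ("gene", "sample_id", "variant_classification", "sift_label", "polyphen_label")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValidationError(f"mutation table missing column {col!r}")
        bad_sift = ~self.data["sift_label"].isin(SIFT_LABELS + (MISSING,))
        bad_pp = ~self.data["polyphen_label"].isin(POLYPHEN_LABELS + (MISSING,))
        if bad_sift.any() or bad_pp.any():
            raise ValidationError("mutation table contains uncontrolled impact labels")

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------


def read_expression_tsv(
    path,
    orientation_hint: str = "genes_by_samples",
    sample_meta: pd.DataFrame | None = None,
    duplicate_rule: str = "max",
) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    The on-disk dialect is gene-major: first column gene symbols, header row of
    sample ids. ``orientation_hint='samples_by_genes'`` accepts the transposed
    dialect. Duplicate gene rows are collapsed by the per-sample maximum
    (``duplicate_rule='max'``; conservative for rank-based enrichment scoring).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse expression TSV {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"expression TSV {path} has no sample columns")
    if orientation_hint == "samples_by_genes":
        df = df.T
    elif orientation_hint != "genes_by_samples":
        raise ValueError(f"unknown orientation_hint {orientation_hint!r}")
    df = df.apply(pd.to_numeric)
    if df.index.duplicated().any():
        if duplicate_rule != "max":
            raise ValueError(f"unknown duplicate_rule {duplicate_rule!r}")
        warnings.warn("duplicate gene rows collapsed by per-sample maximum")
        df = df.groupby(level=0, sort=False).max()
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, sample_meta)


def write_expression_tsv(path, X: ExpressionMatrix) -> None:
    X.values.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.

    Within-set duplicate symbols are removed (first occurrence kept) with a warning.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) != len(genes):
                warnings.warn(f"gene set {name!r}: duplicate symbols removed")
            coll.add(GeneSet(name=name, genes=uniq, description=desc, category=desc))
    return coll


def write_gmt(path, coll: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description or gs.category or "na"] + gs.genes))
            fh.write("\n")


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

_LABEL_RE = re.compile(r"^\s*([A-Za-z_ ]+?)\s*(?:\(.*)?$")


def _parse_impact_label(cell, vocabulary: tuple[str, ...]) -> str:
    """Parse a SIFT/PolyPhen cell as a label prefix before an optional '(score)'.

    Case-insensitive; spaces and underscores are interchangeable. Unrecognized or
    empty cells map to ``missing``.
    """
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return MISSING
    text = str(cell).strip()
    if not text:
        return MISSING
    m = _LABEL_RE.match(text)
    if not m:
        return MISSING
    label = m.group(1).strip().lower().replace(" ", "_")
    return label if label in vocabulary else MISSING


def read_maf(
    path,
    gene_col: str = "Hugo_Symbol",
    sample_col: str = "Tumor_Sample_Barcode",
    class_col: str = "Variant_Classification",
    sift_col: str = "SIFT",
    polyphen_col: str = "PolyPhen",
) -> MutationTable:
    """Read a MAF-like tab-separated mutation table with configurable column names."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in (gene_col, sample_col):
        if col not in df.columns:
            raise FormatError(f"MAF {path} missing mandatory column {col!r}")
    n_in = len(df)
    sift_raw = df[sift_col] if sift_col in df.columns else pd.Series([None] * n_in)
    pp_raw = df[polyphen_col] if polyphen_col in df.columns else pd.Series([None] * n_in)
    sift = [_parse_impact_label(c, SIFT_LABELS) for c in sift_raw]
    pp = [_parse_impact_label(c, POLYPHEN_LABELS) for c in pp_raw]
    unrecognized = sum(
        1
        for raw, lab in zip(list(sift_raw) + list(pp_raw), sift + pp)
        if lab == MISSING and raw is not None and str(raw).strip() not in ("", "nan")
    )
    if unrecognized:
        warnings.warn(f"{unrecognized} unrecognized impact labels mapped to missing")
    out = pd.DataFrame(
        {
            "gene": df[gene_col].to_numpy(),
            "sample_id": df[sample_col].to_numpy(),
            "variant_classification": (
                df[class_col].to_numpy() if class_col in df.columns else ["unknown"] * n_in
            ),
            "sift_label": sift,
            "polyphen_label": pp,
        }
    )
    return MutationTable(out)


def write_maf(path, table: MutationTable) -> None:
    df = table.data.rename(
        columns={
            "gene": "Hugo_Symbol",
            "sample_id": "Tumor_Sample_Barcode",
            "variant_classification": "Variant_Classification",
            "sift_label": "SIFT",
            "polyphen_label": "PolyPhen",
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical / generic annotated TSV
# ---------------------------------------------------------------------------


def read_clinical_tsv(
    path,
    sample_col: str = "sample_id",
    time_col: str = "os_time",
    event_col: str = "os_event",
) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise FormatError(f"clinical TSV {path} missing column {col!r}")
    df = df.rename(columns={sample_col: "sample_id", time_col: "os_time", event_col: "os_event"})
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical_tsv(path, table: ClinicalTable) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def to_log2(X: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(value + pseudocount); returns a genes x samples DataFrame."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return np.log2(X.values + pseudocount)


def from_log2(L: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    return np.exp2(L) - pseudocount
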