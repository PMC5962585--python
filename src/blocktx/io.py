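"""Readers, writers and validation for expression matrices and companion tables.

The central container is a :class:`pandas.DataFrame` of log2 fold-changes with
RNA identifiers on the rows, experiment identifiers on the columns and ``NaN``
for missing cells.  Companion tables (experiment metadata, gene sets in GMT
format, TF→target maps, interaction edge lists, gene lengths) are read from
plain tab-delimited text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MatrixParseError",
    "MatrixValidationError",
    "MergeError",
    "GeneSetCollection",
    "TFTargetMap",
    "read_matrix",
    "write_matrix",
    "validate_matrix",
    "merge_matrices",
    "rpkm_from_log2cpm",
    "read_gene_sets",
    "write_gene_sets",
    "read_metadata",
    "read_tf_targets",
    "read_gene_lengths",
    "read_edges",
    "edges_of_type",
]

#: Tokens treated as missing cells, matched case-insensitively.
MISSING_TOKENS = frozenset({"", "na", "nan"})

#: PCL bookkeeping columns/rows dropped when ``dialect="pcl"``.
_PCL_DROP_COLUMNS = frozenset({"name", "gweight"})
_PCL_DROP_ROWS = frozenset({"eweight"})


class MatrixParseError(ValueError):
    """A matrix file could not be parsed (malformed header, bad cell)."""


class MatrixValidationError(ValueError):
    """A parsed matrix violates an invariant (duplicate ids, no data)."""


class MergeError(ValueError):
    """Experiment-id collision during a merge without prefixing enabled."""


def _is_missing(token: str) -> bool:
    return token.strip().lower() in MISSING_TOKENS


def read_matrix(path, dialect: str = "plain-tsv") -> pd.DataFrame:
    """Read a tab-delimited log2-ratio matrix.

    Parameters
    ----------
    path : str or path-like
        Tab-delimited file: header row of experiment ids, first column RNA
        ids.  Empty cells and (case-insensitive) ``NA``/``NaN`` tokens mark
        missing values.
    dialect : {"plain-tsv", "pcl"}
        The ``"pcl"`` dialect additionally drops the optional ``NAME`` and
        ``GWEIGHT`` columns and the ``EWEIGHT`` row of SPELL-style PCL files.

    Returns
    -------
    pandas.DataFrame
        Rows RNAs, columns experiments, ``NaN`` where missing.

    Raises
    ------
    MatrixParseError
        Malformed header or a non-numeric, non-missing cell (the error names
        the offending row and column).
    MatrixValidationError
        Duplicate RNA or experiment ids.
    """
    if dialect not in ("plain-tsv", "pcl"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise MatrixParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise MatrixParseError(f"{path}: line 1: header must contain at least one experiment id")

    keep = list(range(1, len(header)))
    if dialect == "pcl":
        keep = [j for j in keep if header[j].strip().lower() not in _PCL_DROP_COLUMNS]
    columns = [header[j] for j in keep]
    if len(set(columns)) != len(columns):
        raise MatrixValidationError(f"{path}: duplicate experiment ids in header")

    rna_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields_ = line.split("\t")
        rid = fields_[0].strip()
        if dialect == "pcl" and rid.strip().lower() in _PCL_DROP_ROWS:
            continue
        if len(fields_) != len(header):
            raise MatrixParseError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(fields_)}"
            )
        values = []
        for j in keep:
            token = fields_[j]
            if _is_missing(token):
                values.append(np.nan)
                continue
            try:
                x = float(token)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: line {lineno}, column {header[j]!r}: "
                    f"non-numeric cell {token!r}"
                ) from None
            if not math.isfinite(x):
                raise MatrixParseError(
                    f"{path}: line {lineno}, column {header[j]!r}: non-finite cell {token!r}"
                )
            values.append(x)
        rna_ids.append(rid)
        rows.append(values)
    if len(set(rna_ids)) != len(rna_ids):
        dup = sorted({r for r in rna_ids if rna_ids.count(r) > 1})
        raise MatrixValidationError(f"{path}: duplicate RNA ids: {dup[:5]}")
    return pd.DataFrame(rows, index=pd.Index(rna_ids, name="rna"), columns=columns, dtype=float)


def write_matrix(matrix: pd.DataFrame, path, missing_token: str = "NA") -> None:
    """Write a matrix as tab-delimited text, missing cells as ``missing_token``."""
    matrix.to_csv(path, sep="\t", na_rep=missing_token, index_label=matrix.index.name or "rna")


def validate_matrix(matrix: pd.DataFrame, min_rows: int = 2, min_cols: int = 2) -> pd.DataFrame:
    """Check the expression-matrix invariants and return the matrix unchanged.

    Requires unique row/column ids, at least ``min_rows`` × ``min_cols``
    shape and every stored value finite or NaN.
    """
    if matrix.index.has_duplicates:
        raise MatrixValidationError("duplicate RNA ids")
    if matrix.columns.has_duplicates:
        raise MatrixValidationError("duplicate experiment ids")
    if matrix.shape[0] < min_rows or matrix.shape[1] < min_cols:
        raise MatrixValidationError(
            f"matrix of shape {matrix.shape} below the minimum {min_rows}x{min_cols}"
        )
    values = matrix.to_numpy(dtype=float)
    if np.isinf(values).any():
        raise MatrixValidationError("matrix contains non-finite (inf) values")
    return matrix


def merge_matrices(
    matrices: Sequence[pd.DataFrame],
    dataset_ids: Sequence[str] | None = None,
    prefix: bool = False,
) -> pd.DataFrame:
    """Merge per-dataset matrices into a single matrix.

    The row set is the union of all RNA ids (first-appearance order); cells
    absent from a source dataset are missing.  Column order follows input
    order.  Experiment ids must be globally unique; with ``prefix=True``
    columns are renamed ``"<dataset>:<experiment>"`` using ``dataset_ids``.
    """
    if not matrices:
        raise MergeError("nothing to merge")
    if prefix:
        if dataset_ids is None or len(dataset_ids) != len(matrices):
            raise MergeError("prefix=True requires one dataset id per matrix")
        matrices = [
            m.rename(columns={c: f"{d}:{c}" for c in m.columns})
            for d, m in zip(dataset_ids, matrices)
        ]
    seen_cols: set[str] = set()
    for m in matrices:
        overlap = seen_cols.intersection(m.columns)
        if overlap:
            raise MergeError(
                f"colliding experiment ids (enable prefixing): {sorted(overlap)[:5]}"
            )
        seen_cols.update(m.columns)
    row_order: list[str] = []
    seen_rows: set[str] = set()
    for m in matrices:
        for r in m.index:
            if r not in seen_rows:
                seen_rows.add(r)
                row_order.append(r)
    merged = pd.concat([m.reindex(row_order) for m in matrices], axis=1)
    merged.index.name = "rna"
    return merged


def rpkm_from_log2cpm(log2cpm, length_bp):
    """log2 RPKM from log2 CPM: subtract log2 of the gene length in kilobases.

    Both arguments may be scalars or aligned arrays.  Lengths must be
    positive base-pair counts.
    """
    length = np.asarray(length_bp, dtype=float)
    if np.any(length <= 0):
        raise ValueError("gene length must be positive (base pairs)")
    out = np.asarray(log2cpm, dtype=float) - np.log2(length / 1000.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics).

    ``sets`` maps a set id to its members in file order; member uniqueness
    within a set is enforced on construction.
    """

    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for sid, members in self.sets.items():
            members = tuple(members)
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {sid!r} has duplicate members")
            clean[sid] = members
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def as_frozensets(self) -> dict[str, frozenset]:
        return {sid: frozenset(m) for sid, m in self.sets.items()}


def read_gene_sets(path) -> GeneSetCollection:
    """Read GMT lines: ``set_id<TAB>description<TAB>member...``."""
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise MatrixParseError(f"{path}: line {lineno}: not a GMT line")
            sid, desc, *members = parts
            if sid in sets:
                raise MatrixValidationError(f"{path}: duplicate set id {sid!r}")
            sets[sid] = tuple(m for m in members if m.strip())
            descriptions[sid] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, members in collection.sets.items():
            desc = collection.descriptions.get(sid, "")
            fh.write("\t".join([sid, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# companion tables


def read_metadata(path) -> pd.DataFrame:
    """Experiment metadata TSV with at least ``experiment_id`` and ``study_id``.

    Returns a frame indexed by experiment id.  Every experiment must appear
    exactly once and have a non-empty study id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"experiment_id", "study_id"}
    if not required.issubset(df.columns):
        raise MatrixParseError(f"{path}: metadata needs columns {sorted(required)}")
    if df["experiment_id"].duplicated().any():
        raise MatrixValidationError(f"{path}: duplicate experiment ids in metadata")
    if (df["study_id"].str.strip() == "").any():
        raise MatrixValidationError(f"{path}: empty study_id")
    return df.set_index("experiment_id")


@dataclass
class TFTargetMap:
    """Forward TF→targets map with its inverse gene→TFs view."""

    targets: dict[str, frozenset]

    @property
    def regulators(self) -> dict[str, frozenset]:
        inv: dict[str, set] = {}
        for tf, genes in self.targets.items():
            for g in genes:
                inv.setdefault(g, set()).add(tf)
        return {g: frozenset(s) for g, s in inv.items()}

    def regulators_of(self, gene: str) -> frozenset:
        return frozenset(tf for tf, genes in self.targets.items() if gene in genes)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "TFTargetMap":
        fwd: dict[str, set] = {}
        for tf, gene in pairs:
            fwd.setdefault(tf, set()).add(gene)
        return cls(targets={tf: frozenset(g) for tf, g in fwd.items()})


def read_tf_targets(path) -> TFTargetMap:
    """TF→target table: 2-column TSV with header (tf, target)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise MatrixParseError(f"{path}: expected at least 2 columns (tf, target)")
    tf_col, gene_col = df.columns[:2]
    return TFTargetMap.from_pairs(zip(df[tf_col], df[gene_col]))


def read_gene_lengths(path) -> pd.Series:
    """Gene→length (bp) table; lengths must be positive integers."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, keep_default_na=False)
    gene_col, len_col = df.columns[:2]
    lengths = pd.to_numeric(df[len_col], errors="raise")
    if (lengths <= 0).any():
        raise MatrixValidationError(f"{path}: non-positive gene length")
    if df[gene_col].duplicated().any():
        raise MatrixValidationError(f"{path}: duplicate gene id in length table")
    return pd.Series(lengths.to_numpy(), index=df[gene_col].to_numpy(), name="length_bp")


def read_edges(path) -> pd.DataFrame:
    """Interaction edge list: TSV with header (gene_a, gene_b, type∈{PPI,GI})."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise MatrixParseError(f"{path}: expected 3 columns (gene_a, gene_b, type)")
    df = df.rename(columns=dict(zip(df.columns[:3], ["gene_a", "gene_b", "type"])))
    bad = set(df["type"]) - {"PPI", "GI"}
    if bad:
        raise MatrixValidationError(f"{path}: unknown interaction types {sorted(bad)}")
    return df[["gene_a", "gene_b", "type"]]


def edges_of_type(edges: pd.DataFrame, kind: str) -> set[frozenset]:
    """Deduplicated undirected edges of one type, self-loops dropped."""
    sub = edges[edges["type"] == kind]
    return {
        frozenset((a, b))
        for a, b in zip(sub["gene_a"], sub["gene_b"])
        if a != b
    }
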