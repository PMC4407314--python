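"""Plain delimited-text I/O for expression matrices, labels, partitions and matrices.

All formats are UTF-8 delimited text (TSV by default, CSV supported). The
first column of an expression table holds gene identifiers; the remaining
columns are numeric expression values, one column per time point. Column
headers may carry the time stamps themselves (e.g. ``t0.0  t0.5  t2.0``),
which matters for irregularly sampled time courses.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression_table",
    "read_labels",
    "write_partition",
    "read_partition",
    "write_matrix",
    "read_matrix",
]

_NUM_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


@dataclass
class ExpressionMatrix:
    """A gene x time-point expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per row.
    time_stamps : ndarray of shape (p,)
        Strictly increasing time stamps (arbitrary units).
    values : ndarray of shape (n, p)
        Log-ratio expression values; no missing entries.
    """

    gene_ids: list[str]
    time_stamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.time_stamps = np.asarray(self.time_stamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n} rows of values"
            )
        if self.time_stamps.shape != (p,):
            raise ValueError(
                f"{self.time_stamps.size} time stamps for {p} columns of values"
            )
        if n < 2:
            raise ValueError(f"need at least 2 genes, got {n}")
        if p < 3:
            raise ValueError(f"need at least 3 time points, got {p}")
        if len(set(self.gene_ids)) != n:
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene id: {dup!r}")
        if np.any(np.diff(self.time_stamps) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain missing/non-finite entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def standardized(self) -> "ExpressionMatrix":
        """Per-gene standardization: subtract mean, divide by SD across time."""
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            flat = self.gene_ids[int(np.where(sd.ravel() == 0)[0][0])]
            raise ValueError(f"cannot standardize flat profile of gene {flat!r}")
        return ExpressionMatrix(
            list(self.gene_ids), self.time_stamps.copy(), (self.values - mu) / sd
        )


def _detect_delimiter(path: str) -> str:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    raise ValueError(
        f"could not auto-detect delimiter of {path!r} (tab and comma supported); "
        "pass delimiter= explicitly"
    )


def _parse_time_header(columns) -> np.ndarray:
    stamps = []
    for col in columns:
        m = _NUM_RE.search(str(col))
        if m is None:
            raise ValueError(f"header column {col!r} carries no parseable time stamp")
        stamps.append(float(m.group()))
    return np.asarray(stamps, dtype=float)


def read_expression_table(
    path: str,
    delimiter: str | None = None,
    header_is_time: bool = False,
    drop_missing: bool = False,
    standardize: bool = False,
) -> ExpressionMatrix:
    """Read a gene x time-point expression table from delimited text.

    The first column holds gene identifiers; remaining columns are numeric.
    Rows with missing values are rejected by default; ``drop_missing=True``
    drops them with a logged warning instead (mirrors the common microarray
    preprocessing step of excluding genes with missing observations).

    Parameters
    ----------
    path : str
        Input file path.
    delimiter : str, optional
        Column delimiter; auto-detected among tab and comma when omitted.
    header_is_time : bool
        Parse time stamps out of the header row (first numeric token per
        column). Otherwise stamps default to ``0, 1, ..., p-1``.
    drop_missing : bool
        Drop genes with missing values instead of raising.
    standardize : bool
        Standardize each gene profile (zero mean, unit SD across time).
    """
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[1] < 1:
        raise ValueError(f"{path!r}: no expression columns found")
    gene_ids = [str(g) for g in df.index]
    dupes = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate gene id in {path!r}: {dupes[0]!r}")

    try:
        values = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError):
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & df.notna()
        row, col = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {gene_ids[row]!r}, "
            f"column {df.columns[col]!r}: {df.iat[row, col]!r}"
        ) from None

    missing = ~np.isfinite(values)
    if missing.any():
        rows = np.unique(np.where(missing)[0])
        names = [gene_ids[i] for i in rows]
        if not drop_missing:
            raise ValueError(
                f"{len(rows)} gene(s) with missing values (e.g. {names[0]!r}); "
                "re-read with drop_missing=True to exclude them"
            )
        logger.warning("dropping %d gene(s) with missing values: %s", len(rows), names)
        keep = np.setdiff1d(np.arange(len(gene_ids)), rows)
        values = values[keep]
        gene_ids = [gene_ids[i] for i in keep]

    if header_is_time:
        time_stamps = _parse_time_header(df.columns)
    else:
        time_stamps = np.arange(values.shape[1], dtype=float)

    mat = ExpressionMatrix(gene_ids, time_stamps, values)
    return mat.standardized() if standardize else mat


def read_labels(path: str, delimiter: str | None = None) -> dict[str, str]:
    """Read a two-column gene -> class label file into a mapping."""
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str, comment="#")
    if df.empty:
        raise ValueError(f"label file {path!r} is empty")
    if df.shape[1] < 2:
        raise ValueError(f"label file {path!r} must have two columns")
    mapping: dict[str, str] = {}
    for gene, label in zip(df.iloc[:, 0], df.iloc[:, 1]):
        gene = str(gene)
        if gene in mapping:
            raise ValueError(f"gene {gene!r} appears twice in {path!r}")
        mapping[gene] = str(label)
    return mapping


def write_partition(labels, gene_ids: list[str], path: str) -> None:
    """Write a partition as a two-column TSV (gene_id, cluster index).

    Clusters are renumbered 1..K in order of first appearance so the file
    format is canonical regardless of internal label values.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot write an empty partition")
    if labels.size != len(gene_ids):
        raise ValueError(f"{labels.size} labels for {len(gene_ids)} genes")
    renum: dict = {}
    with open(path, "w", encoding="utf-8") as fh:
        for gene, lab in zip(gene_ids, labels.tolist()):
            idx = renum.setdefault(lab, len(renum) + 1)
            fh.write(f"{gene}\t{idx}\n")


def read_partition(path: str) -> tuple[list[str], np.ndarray]:
    """Read a partition file back; returns (gene_ids, integer labels)."""
    mapping = read_labels(path, delimiter="\t")
    genes = list(mapping)
    return genes, np.asarray([int(mapping[g]) for g in genes])


def write_matrix(matrix: np.ndarray, gene_ids: list[str], path: str) -> None:
    """Write a symmetric gene x gene matrix as TSV with ID header row/column."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got shape {matrix.shape}")
    if matrix.shape[0] != len(gene_ids):
        raise ValueError(f"{len(gene_ids)} ids for {matrix.shape[0]}x{matrix.shape[1]} matrix")
    if not np.allclose(matrix, matrix.T, atol=0):
        raise ValueError("matrix is not symmetric")
    # repr-precision floats survive the text round trip bit-exactly
    df = pd.DataFrame(matrix, index=gene_ids, columns=gene_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path: str) -> tuple[list[str], np.ndarray]:
    """Read a matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return [str(g) for g in df.index], df.to_numpy(dtype=float)
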