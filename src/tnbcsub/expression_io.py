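"""Reading, validation and pre-filtering of expression matrices.

An expression matrix is a pandas DataFrame with probe identifiers as the
index, sample identifiers as the columns, and finite log2-scale values.
Probe annotation is a DataFrame with columns ``probe_id`` and
``gene_symbol`` (one row per probe; a gene may own several probes).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_annotation",
    "validate_expression",
    "validate_annotation",
    "log2_transform",
    "filter_top_variance",
    "collapse_probes_to_genes",
]

GEO_TABLE_BEGIN = "!series_matrix_table_begin"
GEO_TABLE_END = "!series_matrix_table_end"


class ExpressionValidationError(ValueError):
    """Raised when a matrix or annotation violates its invariants."""


def validate_expression(E: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants and return the frame unchanged.

    Invariants: unique probe and sample identifiers, all values finite.
    """
    if E.index.has_duplicates:
        dupes = E.index[E.index.duplicated()].unique().tolist()
        raise ExpressionValidationError(f"duplicated probe ids: {dupes[:10]}")
    if E.columns.has_duplicates:
        dupes = E.columns[E.columns.duplicated()].unique().tolist()
        raise ExpressionValidationError(f"duplicated sample ids: {dupes[:10]}")
    values = E.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = int((~np.isfinite(values)).sum())
        raise ExpressionValidationError(f"{bad} non-finite expression values")
    return E


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check probe-annotation invariants (unique probes, non-empty symbols)."""
    if list(ann.columns[:2]) != ["probe_id", "gene_symbol"]:
        raise ExpressionValidationError(
            "annotation must have columns ['probe_id', 'gene_symbol'], "
            f"got {list(ann.columns)}"
        )
    if ann["probe_id"].duplicated().any():
        dupes = ann.loc[ann["probe_id"].duplicated(), "probe_id"].tolist()
        raise ExpressionValidationError(f"duplicated annotation probes: {dupes[:10]}")
    empty = ann["gene_symbol"].astype(str).str.strip() == ""
    if empty.any():
        raise ExpressionValidationError(
            f"{int(empty.sum())} probes with empty gene_symbol"
        )
    return ann


def _read_geo_series_matrix(path: Path) -> pd.DataFrame:
    lines = path.read_text().splitlines()
    try:
        begin = next(i for i, l in enumerate(lines) if l.strip() == GEO_TABLE_BEGIN)
        end = next(i for i, l in enumerate(lines) if l.strip() == GEO_TABLE_END)
    except StopIteration:
        raise ExpressionValidationError(
            f"{path}: missing {GEO_TABLE_BEGIN}/{GEO_TABLE_END} markers"
        ) from None
    if end <= begin + 1:
        raise ExpressionValidationError(f"{path}: empty series-matrix table")
    table = "\n".join(lines[begin + 1 : end])
    from io import StringIO

    E = pd.read_csv(StringIO(table), sep="\t", index_col=0)
    # GEO quotes identifiers; strip quotes from index and columns
    E.index = E.index.astype(str).str.strip('"')
    E.columns = E.columns.astype(str).str.strip('"')
    E.index.name = "probe_id"
    return E


def read_expression_table(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read an expression table (probes × samples).

    ``format='tsv'``: header row of sample ids, first column probe ids.
    ``format='geo_series_matrix'``: only the block between the
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers is
    parsed; all other header/metadata lines are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            E = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.ParserError as exc:
            raise ExpressionValidationError(f"{path}: {exc}") from exc
        E.index = E.index.astype(str)
        E.index.name = "probe_id"
    elif format == "geo_series_matrix":
        E = _read_geo_series_matrix(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return validate_expression(E)


def write_expression_table(E: pd.DataFrame, path: str | Path) -> None:
    """Write the TSV dialect read back by :func:`read_expression_table`.

    Uses repr-precision floats so a read/write round trip is exact.
    """
    E.to_csv(path, sep="\t", index_label="probe_id", float_format=None)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a two-column probe annotation TSV (probe_id, gene_symbol)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    return validate_annotation(ann)


def log2_transform(E: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Elementwise ``log2(value + offset)`` for raw-scale inputs.

    Normalisation itself is upstream of this package; only the log step is
    offered, for matrices deposited on the raw intensity scale.
    """
    if offset < 0:
        raise ValueError(f"offset must be >= 0, got {offset}")
    shifted = E.to_numpy(dtype=float) + offset
    if (shifted <= 0).any():
        raise ValueError(
            f"{int((shifted <= 0).sum())} values are non-positive after "
            f"offset {offset}; log2 undefined"
        )
    return pd.DataFrame(np.log2(shifted), index=E.index, columns=E.columns)


def filter_top_variance(E: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """Retain the ``ceil(fraction * n_probes)`` most variable probes.

    Sample variance uses the unbiased n−1 denominator.  Ties on variance are
    broken by ascending probe id; the retained probes keep their original
    row order.  With the HG-U133 Plus 2.0 probe count (54,675) and
    ``fraction=0.05`` this retains exactly 2,734 probes.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if E.shape[1] < 2:
        raise ValueError("variance filtering needs at least 2 samples")
    n_keep = math.ceil(fraction * E.shape[0])
    variances = E.var(axis=1, ddof=1)
    # sort by (-variance, probe_id): deterministic under ties
    order = pd.DataFrame({"v": variances, "p": variances.index.astype(str)})
    ranked = order.sort_values(["v", "p"], ascending=[False, True])
    keep = set(ranked.index[:n_keep])
    return E.loc[[p for p in E.index if p in keep]]


def collapse_probes_to_genes(E: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe rows to gene rows by the per-sample median.

    Every probe of ``E`` must appear in the annotation; genes measured by a
    single probe pass through unchanged.  When a gene is represented by
    multiple probes, the median of the probes is taken as the unique value
    for the gene, per sample.
    """
    validate_annotation(ann)
    mapping = ann.set_index("probe_id")["gene_symbol"]
    missing = [p for p in E.index if p not in mapping.index]
    if missing:
        raise ExpressionValidationError(
            f"{len(missing)} probes missing from annotation: {missing[:10]}"
        )
    genes = mapping.loc[E.index]
    collapsed = E.groupby(genes.to_numpy()).median()
    collapsed.index.name = "gene_symbol"
    return collapsed
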