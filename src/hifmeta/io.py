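"""Readers and writers for the plain-text formats used by the pipeline.

Formats:

* BED (peaks) — ``bed3`` (chrom, start, end) or ``bed5_count`` where column 5
  carries the read count under the peak.
* TSV tables — annotation (gene_id, chrom, tss, strand), diffexpr
  (gene_id, log2fc, padj), metadata (id + arbitrary columns) and scores
  (sample_id, score, n_genes_used).
* Expression matrices — dense TSV (genes x samples) or MatrixMarket triplet
  with gene/barcode sidecar files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .types import (
    AnalysisConfig,
    BindingSite,
    DiffExprRecord,
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    IsoformClass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_intervals",
    "write_intervals",
    "read_table",
    "write_table",
    "read_matrix",
    "write_matrix",
    "read_config",
    "write_config",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

_BED_DIALECTS = ("bed3", "bed5_count")


def read_intervals(path: str | Path, dialect: str = "bed5_count") -> list[BindingSite]:
    """Read a BED file into binding sites, preserving file order.

    ``bed3`` ignores any extra columns and sets count to 0; ``bed5_count``
    takes the count from column 5 (the BED score slot) when present.
    """
    if dialect not in _BED_DIALECTS:
        raise ValueError(f"dialect must be one of {_BED_DIALECTS}, got {dialect!r}")
    sites: list[BindingSite] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: malformed record, start {start} >= end {end}"
                )
            count = 0.0
            if dialect == "bed5_count" and len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    count = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric count") from exc
            sites.append(BindingSite(GenomicInterval(chrom, start, end), count=count))
    logger.info("read %d intervals from %s (dialect=%s)", len(sites), path, dialect)
    return sites


def write_intervals(
    sites: Iterable[BindingSite], path: str | Path, dialect: str = "bed5_count"
) -> None:
    """Write binding sites as BED. ``bed5_count`` emits name='.' and count."""
    if dialect not in _BED_DIALECTS:
        raise ValueError(f"dialect must be one of {_BED_DIALECTS}, got {dialect!r}")
    with open(path, "w") as fh:
        for s in sites:
            iv = s.interval
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{s.count:.12g}\n")


# ---------------------------------------------------------------------------
# Typed TSV tables
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "annotation": ["gene_id", "chrom", "tss", "strand"],
    "diffexpr": ["gene_id", "log2fc", "padj"],
    "metadata": ["id"],
    "scores": ["sample_id", "score", "n_genes_used"],
}


def read_table(path: str | Path, schema: str):
    """Read a TSV table with one of the known schemas.

    Returns a list of :class:`GeneAnnotation` for ``annotation``, a list of
    :class:`DiffExprRecord` for ``diffexpr`` and a :class:`pandas.DataFrame`
    for ``metadata`` and ``scores``.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"schema must be one of {sorted(_SCHEMAS)}, got {schema!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing} for schema {schema}")

    if schema == "annotation":
        if df["gene_id"].duplicated().any():
            dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise FormatError(f"{path}: duplicated gene_id(s) {dupes[:5]}")
        return [
            GeneAnnotation(r.gene_id, r.chrom, int(r.tss), r.strand)
            for r in df.itertuples(index=False)
        ]
    if schema == "diffexpr":
        if df["gene_id"].duplicated().any():
            dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise FormatError(f"{path}: duplicated gene_id(s) {dupes[:5]}")
        records = []
        for r in df.itertuples(index=False):
            padj = float(r.padj)
            if not (0.0 < padj <= 1.0):
                raise FormatError(f"{path}: padj {padj} outside (0, 1] for {r.gene_id}")
            records.append(DiffExprRecord(r.gene_id, float(r.log2fc), padj))
        return records
    if schema == "scores":
        out = df.copy()
        out["score"] = out["score"].astype(float)
        out["n_genes_used"] = out["n_genes_used"].astype(int)
        return out
    return df  # metadata: id column plus free-form extras


def write_table(obj, path: str | Path, schema: str) -> None:
    """Write a typed table back to TSV (inverse of :func:`read_table`)."""
    if schema not in _SCHEMAS:
        raise ValueError(f"schema must be one of {sorted(_SCHEMAS)}, got {schema!r}")
    if schema == "annotation":
        df = pd.DataFrame(
            [(a.gene_id, a.chrom, a.tss, a.strand) for a in obj],
            columns=_SCHEMAS["annotation"],
        )
    elif schema == "diffexpr":
        df = pd.DataFrame(
            [(r.gene_id, repr(r.log2fc), repr(r.padj)) for r in obj],
            columns=_SCHEMAS["diffexpr"],
        )
    else:
        df = pd.DataFrame(obj)
        if schema == "scores":
            df = df[_SCHEMAS["scores"] + [c for c in df.columns if c not in _SCHEMAS["scores"]]]
            df["score"] = [repr(float(v)) for v in df["score"]]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

_MATRIX_FORMATS = ("tsv_dense", "mtx_triplet")


def read_matrix(
    path: str | Path,
    format: str = "tsv_dense",
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
    layer: str = "normalized",
) -> ExpressionMatrix:
    """Read an expression matrix.

    ``tsv_dense``: genes in rows (first column = gene_id), samples in columns.
    ``mtx_triplet``: MatrixMarket coordinate file plus one-gene-per-line and
    one-barcode-per-line sidecar files; absent entries are zeros.
    """
    if format not in _MATRIX_FORMATS:
        raise ValueError(f"format must be one of {_MATRIX_FORMATS}, got {format!r}")
    if format == "tsv_dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            [str(g) for g in df.index],
            [str(s) for s in df.columns],
            layer,
        )
    if genes_path is None or barcodes_path is None:
        raise ValueError("mtx_triplet requires genes_path and barcodes_path sidecars")
    try:
        mat = scipy.io.mmread(path)
    except ValueError as exc:
        raise FormatError(f"{path}: bad MatrixMarket triplet file: {exc}") from exc
    genes = [line.strip() for line in open(genes_path) if line.strip()]
    barcodes = [line.strip() for line in open(barcodes_path) if line.strip()]
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if dense.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"{path}: declared shape {dense.shape} does not match sidecars "
            f"({len(genes)} genes, {len(barcodes)} barcodes)"
        )
    return ExpressionMatrix(dense, genes, barcodes, layer)


def write_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    format: str = "tsv_dense",
    genes_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> None:
    if format not in _MATRIX_FORMATS:
        raise ValueError(f"format must be one of {_MATRIX_FORMATS}, got {format!r}")
    if format == "tsv_dense":
        df = matrix.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.12g")
        return
    if genes_path is None or barcodes_path is None:
        raise ValueError("mtx_triplet requires genes_path and barcodes_path sidecars")
    sparse = scipy.sparse.coo_matrix(matrix.values)
    scipy.io.mmwrite(str(path), sparse)
    Path(genes_path).write_text("".join(g + "\n" for g in matrix.gene_ids))
    Path(barcodes_path).write_text("".join(b + "\n" for b in matrix.sample_ids))


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig(**data)


def write_config(cfg: AnalysisConfig, path: str | Path) -> None:
    data = {k: v for k, v in vars(cfg).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
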