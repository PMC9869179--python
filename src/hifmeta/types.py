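"""Core domain types shared by every pipeline stage.

All genomic coordinates are 0-based, half-open (BED semantics): an interval
``[a, a+1)`` has length 1.  Chromosome names are compared as exact strings;
no ``chr`` prefix normalization is performed anywhere.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IsoformClass",
    "GenomicInterval",
    "BindingSite",
    "ConsensusSite",
    "GeneAnnotation",
    "DiffExprRecord",
    "ExpressionMatrix",
    "SignatureSet",
    "AnalysisConfig",
]


class IsoformClass(str, enum.Enum):
    """Which HIF-alpha isoform(s) a binding site is attributed to."""

    HIF1 = "HIF1"
    HIF2 = "HIF2"
    SHARED = "SHARED"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval with an optional summit coordinate.

    Coordinates are 0-based; ``start`` inclusive, ``end`` exclusive.
    """

    chrom: str
    start: int
    end: int
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint (floor) of the interval."""
        return (self.start + self.end) // 2

    @property
    def anchor(self) -> int:
        """Summit if present, else the midpoint."""
        return self.summit if self.summit is not None else self.midpoint

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class BindingSite:
    """A called ChIP-seq peak with its read count."""

    interval: GenomicInterval
    count: float = 0.0
    isoform_class: IsoformClass = IsoformClass.UNCLASSIFIED

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")


@dataclass(frozen=True)
class ConsensusSite:
    """A replicate-supported, isoform-classified binding site.

    ``support`` lists the source labels (e.g. ``h1/rep1``) of every peak that
    contributed to the site; an alpha-isoform claim requires both replicates.
    """

    interval: GenomicInterval
    count: float
    isoform_class: IsoformClass
    support: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.isoform_class not in (
            IsoformClass.HIF1,
            IsoformClass.HIF2,
            IsoformClass.SHARED,
        ):
            raise ValueError(
                f"consensus sites must be classified, got {self.isoform_class}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene with its canonical TSS coordinate."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class DiffExprRecord:
    """Per-gene differential-expression summary for one condition."""

    gene_id: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise ValueError(f"log2fc must be finite, got {self.log2fc}")
        if not (0.0 < self.padj <= 1.0):
            raise ValueError(f"padj must lie in (0, 1], got {self.padj}")


_LAYERS = ("counts", "normalized", "log_normalized", "quantile")


class ExpressionMatrix:
    """A genes x samples (or genes x cells) numeric matrix.

    Thin wrapper over a dense :class:`numpy.ndarray` carrying the gene and
    sample identifiers plus a ``layer`` tag describing the normalization
    state of the values.
    """

    def __init__(
        self,
        values: np.ndarray,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        layer: str = "normalized",
    ) -> None:
        values = np.asarray(values, dtype=float)
        gene_ids = list(gene_ids)
        sample_ids = list(sample_ids)
        if values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"shape {values.shape} inconsistent with "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        if layer not in _LAYERS:
            raise ValueError(f"layer must be one of {_LAYERS}, got {layer!r}")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicated gene_ids")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicated sample_ids")
        if layer == "counts" and (values < 0).any():
            raise ValueError("counts layer must be non-negative")
        self.values = values
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.layer = layer
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self._gene_index[gene_id]]

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._gene_index[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[idx], list(gene_ids), self.sample_ids, self.layer
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, layer: str = "normalized") -> "ExpressionMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            [str(g) for g in frame.index],
            [str(s) for s in frame.columns],
            layer,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and self.layer == other.layer
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"layer={self.layer!r})"
        )


@dataclass
class SignatureSet:
    """An ordered gene list with provenance and published-signature flags."""

    genes: tuple[str, ...]
    provenance: Mapping[str, Mapping[str, bool]] = field(default_factory=dict)
    published_membership: Mapping[str, Mapping[str, bool]] = field(default_factory=dict)
    note: str = ""

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.genes)


@dataclass
class AnalysisConfig:
    """Thresholds and tuning parameters for the analysis chain."""

    padj_threshold: float = 0.05
    fc_threshold: float = 1.2
    k_nearest: int = 3
    background_percentile: float = 99.99
    corr_p_threshold: float = 1e-6
    gsea_nperm: int = 10000
    gsea_weight: float = 1.0
    min_lines: int | None = None  # None => number of cell lines supplied
    seed: int = 0
    chrom_aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.padj_threshold <= 1.0):
            raise ValueError("padj_threshold must lie in (0, 1]")
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        if self.k_nearest < 1:
            raise ValueError("k_nearest must be >= 1")
        if not (0.0 < self.background_percentile < 100.0):
            raise ValueError("background_percentile must lie in (0, 100)")
        if not (0.0 < self.corr_p_threshold <= 1.0):
            raise ValueError("corr_p_threshold must lie in (0, 1]")
        if self.gsea_nperm < 1:
            raise ValueError("gsea_nperm must be >= 1")
        if self.min_lines is not None and self.min_lines < 1:
            raise ValueError("min_lines must be >= 1")
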