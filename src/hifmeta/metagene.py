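"""Metagene scoring of bulk samples and single cells.

Bulk scoring is rank-based per cohort: each gene's values are replaced by
their (rank - 0.5)/n quantiles across samples so that highly expressed
genes cannot dominate, then the per-gene quantiles are summed.  Scores are
therefore cohort-relative and exactly invariant to any per-gene strictly
monotone transformation of the input.

Single-cell scoring offers the plain normalized mean over signature genes
and (default) an expression-matched control-bin subtraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

from .types import ExpressionMatrix, SignatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreTable",
    "gene_quantiles",
    "score_bulk",
    "score_cells",
    "dropout_fraction",
]


@dataclass
class ScoreTable:
    sample_or_cell_ids: list[str]
    score: np.ndarray
    n_genes_used: int
    method: str  # quantile_sum | normalized_mean | control_bin

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.sample_or_cell_ids),):
            raise ValueError("one score per id required")
        if not np.all(np.isfinite(self.score)):
            raise ValueError("scores must be finite")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_id": self.sample_or_cell_ids,
                "score": self.score,
                "n_genes_used": self.n_genes_used,
            }
        )


def _present_genes(matrix: ExpressionMatrix, genes: Sequence[str]) -> list[str]:
    present = [g for g in genes if matrix.has_gene(g)]
    missing = len(genes) - len(present)
    if missing:
        logger.warning(
            "%d of %d requested genes absent from matrix; dropped",
            missing, len(genes),
        )
    return present


def gene_quantiles(
    matrix: ExpressionMatrix, genes: Sequence[str] | None = None
) -> ExpressionMatrix:
    """Replace each gene's row by its (rank - 0.5)/n quantiles across samples.

    Ties receive average ranks, so an all-tied gene maps to 0.5 everywhere.
    Output values lie strictly inside (0, 1).
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile transform needs >= 2 samples")
    if genes is None:
        sub = matrix
    else:
        present = _present_genes(matrix, genes)
        if not present:
            raise ValueError("none of the requested genes present in matrix")
        sub = matrix.subset_genes(present)
    ranks = scipy.stats.rankdata(sub.values, axis=1, method="average")
    quantiles = (ranks - 0.5) / sub.n_samples
    return ExpressionMatrix(quantiles, sub.gene_ids, sub.sample_ids, layer="quantile")


def score_bulk(matrix: ExpressionMatrix, signature: SignatureSet) -> ScoreTable:
    """Sum of per-gene quantiles over signature genes, rescaled by coverage.

    With S signature genes of which G are present, score(sample) =
    (S / G) * sum_g quantile(g, sample), keeping scores comparable across
    datasets with different gene coverage.
    """
    present = _present_genes(matrix, signature.genes)
    if not present:
        raise ValueError("no signature gene present in matrix")
    quantiles = gene_quantiles(matrix, present)
    s, g = len(signature.genes), len(present)
    scores = (s / g) * quantiles.values.sum(axis=0)
    logger.info(
        "score_bulk: %d samples scored with %d/%d signature genes",
        matrix.n_samples, g, s,
    )
    return ScoreTable(list(matrix.sample_ids), scores, g, "quantile_sum")


def _lognormalize(counts: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """log2(1 + 1e4 * c / total) per cell; zero-total cells pass through as 0."""
    totals = counts.values.sum(axis=0)
    zero_cells = totals == 0
    if zero_cells.any():
        logger.warning(
            "%d cell(s) with zero total counts; scored 0 and retained",
            int(zero_cells.sum()),
        )
    safe_totals = np.where(zero_cells, 1.0, totals)
    normalized = np.log2(1.0 + 1e4 * counts.values / safe_totals)
    return normalized, zero_cells


def score_cells(
    counts: ExpressionMatrix,
    signature: SignatureSet,
    method: str = "control_bin",
    n_bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
) -> ScoreTable:
    """Per-cell signature score on log-normalized counts.

    ``normalized_mean`` is the mean over signature genes of
    ``log2(1 + 1e4 * c / total)``.  ``control_bin`` (default) subtracts the
    mean of a control gene pool sampled per signature gene from its
    average-expression bin (``n_bins`` bins, ``n_controls`` draws per gene,
    seeded), matching the expression distribution of the signature.
    """
    if counts.layer != "counts":
        raise ValueError(f"expected a counts-layer matrix, got {counts.layer!r}")
    if method not in ("normalized_mean", "control_bin"):
        raise ValueError(f"unknown method {method!r}")
    present = _present_genes(counts, signature.genes)
    if not present:
        raise ValueError("no signature gene present in matrix")

    normalized, zero_cells = _lognormalize(counts)
    gene_index = {g: i for i, g in enumerate(counts.gene_ids)}
    sig_idx = np.array([gene_index[g] for g in present])
    sig_mean = normalized[sig_idx].mean(axis=0)

    if method == "normalized_mean":
        scores = np.where(zero_cells, 0.0, sig_mean)
        return ScoreTable(list(counts.sample_ids), scores, len(present),
                          "normalized_mean")

    # expression-matched controls: bin genes by average normalized expression
    rng = np.random.default_rng(seed)
    avg = normalized.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(counts.n_genes, dtype=int)
    bin_of[order] = np.arange(counts.n_genes) * n_bins // counts.n_genes
    genes_in_bin = {b: np.flatnonzero(bin_of == b) for b in range(n_bins)}
    control_idx = []
    for gi in sig_idx:
        pool = genes_in_bin[bin_of[gi]]
        take = min(n_controls, pool.size)
        control_idx.append(rng.choice(pool, size=take, replace=False))
    control_idx = np.unique(np.concatenate(control_idx))
    control_mean = normalized[control_idx].mean(axis=0)
    scores = np.where(zero_cells, 0.0, sig_mean - control_mean)
    logger.info(
        "score_cells: %d cells, %d signature genes, %d control genes "
        "(%d bins x up to %d per gene)",
        counts.n_samples, len(present), control_idx.size, n_bins, n_controls,
    )
    return ScoreTable(list(counts.sample_ids), scores, len(present), "control_bin")


def dropout_fraction(counts: ExpressionMatrix, genes: Sequence[str]) -> float:
    """Fraction of cells with zero counts for every listed gene."""
    if not genes:
        raise ValueError("gene list must be non-empty")
    present = _present_genes(counts, genes)
    if not present:
        raise ValueError("none of the listed genes present in matrix")
    sub = counts.subset_genes(present)
    all_zero = (sub.values == 0).all(axis=0)
    return float(all_zero.mean())
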