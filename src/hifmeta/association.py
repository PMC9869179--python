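"""Association screens against the metagene score.

Includes the per-gene Pearson correlation screen (signature genes
excluded), cross-dataset sharing counts at a fixed significance threshold,
the pre-ranked GSEA with weighted running sum, covariate-adjusted
regression, and rank-sum group comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .derivation import RankSumResult, ranksum_test
from .metagene import ScoreTable
from .types import DiffExprRecord, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationRecord",
    "EnrichmentResult",
    "GroupComparisonResult",
    "correlate_with_score",
    "sharing_counts",
    "rank_score",
    "preranked_gsea",
    "adjusted_association",
    "compare_groups",
]

P_FLOOR = 1e-300  # adjusted p floored before taking logs


@dataclass(frozen=True)
class CorrelationRecord:
    gene_id: str
    r: float
    p_value: float
    n: int
    direction: str  # positive | negative

    def __post_init__(self) -> None:
        if self.direction not in ("positive", "negative"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    nes: float
    p_value: float
    n_perm: int
    seed: int


@dataclass(frozen=True)
class GroupComparisonResult:
    group_labels: tuple[str, str]
    medians: tuple[float, float]
    ranksum: RankSumResult


def correlate_with_score(
    matrix: ExpressionMatrix,
    scores: ScoreTable,
    exclude: set[str] | None = None,
) -> list[CorrelationRecord]:
    """Pearson correlation of each gene with the score across samples.

    Bulk (non-quantile) values are log2(x+1)-transformed first; quantile
    layers are correlated as-is.  Two-sided p-values come from the t
    statistic with n-2 degrees of freedom.  Zero-variance genes are
    omitted (they have no defined r).
    """
    if matrix.sample_ids != list(scores.sample_or_cell_ids):
        raise ValueError("matrix samples do not match score ids")
    n = matrix.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples")
    exclude = exclude or set()

    values = matrix.values
    if matrix.layer != "quantile":
        values = np.log2(values + 1.0)
    s = np.asarray(scores.score, dtype=float)
    s_centered = s - s.mean()
    s_ss = float(s_centered @ s_centered)
    if s_ss == 0.0:
        raise ValueError("score has zero variance")

    centered = values - values.mean(axis=1, keepdims=True)
    gene_ss = np.einsum("ij,ij->i", centered, centered)
    cov = centered @ s_centered
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(gene_ss * s_ss)
    records: list[CorrelationRecord] = []
    n_zero_var = 0
    for gi, gene in enumerate(matrix.gene_ids):
        if gene in exclude:
            continue
        if gene_ss[gi] == 0.0:
            n_zero_var += 1
            continue
        ri = float(np.clip(r[gi], -1.0, 1.0))
        if abs(ri) == 1.0:
            p = 0.0
        else:
            t = ri * np.sqrt((n - 2) / (1.0 - ri * ri))
            p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 2)
        records.append(
            CorrelationRecord(
                gene, ri, float(max(p, P_FLOOR)), n,
                "positive" if ri >= 0 else "negative",
            )
        )
    if n_zero_var:
        logger.warning(
            "correlate_with_score: %d zero-variance gene(s) omitted", n_zero_var
        )
    logger.info(
        "correlate_with_score: %d genes tested over %d samples "
        "(%d excluded as signature)",
        len(records), n, len(exclude),
    )
    return records


def sharing_counts(
    per_dataset_records: Sequence[Sequence[CorrelationRecord]],
    p_threshold: float = 1e-6,
) -> dict[tuple[str, int], int]:
    """Genes significant in >= m datasets, tallied per direction.

    Returns ``{(direction, m): count}`` for every m from 1 to the number of
    datasets, where a gene counts toward (direction, m) when it reaches
    ``p <= p_threshold`` with that direction in at least m datasets.
    Directions are never pooled.
    """
    if not per_dataset_records:
        raise ValueError("need at least one dataset")
    tallies: dict[tuple[str, str], int] = {}
    for records in per_dataset_records:
        for rec in records:
            if rec.p_value <= p_threshold:
                key = (rec.gene_id, rec.direction)
                tallies[key] = tallies.get(key, 0) + 1
    out: dict[tuple[str, int], int] = {}
    n_datasets = len(per_dataset_records)
    for m in range(1, n_datasets + 1):
        for direction in ("positive", "negative"):
            out[(direction, m)] = sum(
                1 for (_, d), c in tallies.items() if d == direction and c >= m
            )
    return out


def rank_score(de: Sequence[DiffExprRecord]) -> list[tuple[str, float]]:
    """Ranking statistic log2fc * (-log10 padj), sorted descending.

    Ties are broken lexicographically by gene_id.  Adjusted p-values are
    floored at 1e-300 before the log.
    """
    scored = [
        (r.gene_id, r.log2fc * (-np.log10(max(r.padj, P_FLOOR))))
        for r in de
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def _running_es(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float
) -> float:
    """Signed maximum deviation of the weighted GSEA running sum."""
    n = scores.size
    n_hits = int(hit_mask.sum())
    w = np.abs(scores[hit_mask]) ** weight
    total_w = w.sum()
    steps = np.full(n, -1.0 / (n - n_hits)) if n > n_hits else np.zeros(n)
    if total_w > 0:
        steps[hit_mask] = np.abs(scores[hit_mask]) ** weight / total_w
    else:  # all hit scores zero: spread hit mass evenly
        steps[hit_mask] = 1.0 / n_hits
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(
    ranked: Sequence[tuple[str, float]],
    gene_set: set[str],
    weight: float = 1.0,
    n_perm: int = 10000,
    seed: int = 0,
) -> EnrichmentResult:
    """Pre-ranked GSEA with weighted running sum and gene-label permutation.

    Hits increment the running sum by ``|score|^weight`` (normalized over
    hits); misses decrement by ``1/(N - |S|)``.  The null re-draws random
    gene sets of equal size; ``p = (1 + #{|ES_null| >= |ES|}) / (n_perm+1)``
    and NES divides ES by the mean |ES_null| of matching sign.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=float)
    hit_mask = np.array([g in gene_set for g in genes], dtype=bool)
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene_set does not intersect the ranked list")
    if n_hits == len(genes):
        raise ValueError("gene_set covers the entire ranked list")
    es = _running_es(scores, hit_mask, weight)

    rng = np.random.default_rng(seed)
    n = len(genes)
    es_null = np.empty(n_perm)
    for i in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_hits, replace=False)] = True
        es_null[i] = _running_es(scores, mask, weight)
    p = (1.0 + np.count_nonzero(np.abs(es_null) >= abs(es))) / (n_perm + 1.0)
    same_sign = es_null[np.sign(es_null) == np.sign(es)] if es != 0 else es_null
    denom = np.abs(same_sign).mean() if same_sign.size else np.abs(es_null).mean()
    nes = es / denom if denom > 0 else 0.0
    logger.info(
        "preranked_gsea: |set|=%d of %d ranked genes, ES=%.3f NES=%.3f p=%.4g "
        "(%d permutations)",
        n_hits, n, es, nes, p, n_perm,
    )
    return EnrichmentResult(es, float(nes), float(p), n_perm, seed)


def adjusted_association(
    gene_values: Sequence[float],
    scores: Sequence[float],
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """OLS of gene on score + covariates + intercept.

    Returns the score coefficient and its two-sided t-test p-value.  With
    no covariates this reduces to simple regression, whose p equals the
    Pearson correlation p for the same pair.
    """
    import statsmodels.api as sm

    y = np.asarray(gene_values, dtype=float)
    s = np.asarray(scores, dtype=float)
    if covariates is None:
        covariates = np.empty((y.size, 0))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    n = y.size
    if n <= cov.shape[1] + 2:
        raise ValueError("need n > number of covariates + 2")
    design = np.column_stack([np.ones(n), s, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def compare_groups(
    scores: ScoreTable,
    labels: Mapping[str, str],
    contrast: tuple[str, str],
) -> GroupComparisonResult:
    """Median scores and two-sided rank-sum between two labeled groups."""
    a_name, b_name = contrast
    present = set(labels.values())
    for name in contrast:
        if name not in present:
            raise ValueError(f"unknown group {name!r}; labels contain {sorted(present)}")
    a = [sc for sid, sc in zip(scores.sample_or_cell_ids, scores.score)
         if labels.get(sid) == a_name]
    b = [sc for sid, sc in zip(scores.sample_or_cell_ids, scores.score)
         if labels.get(sid) == b_name]
    if not a or not b:
        raise ValueError("both contrast groups must be non-empty")
    result = ranksum_test(a, b, alternative="two_sided")
    return GroupComparisonResult(
        group_labels=(a_name, b_name),
        medians=(float(np.median(a)), float(np.median(b))),
        ranksum=result,
    )
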