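"""Assignment of binding sites to nearby genes by TSS distance.

The distance anchor of a site is its summit when present, otherwise the
integer midpoint of its interval.  Distances are absolute base-pair
distances to the annotated TSS; strand is carried but does not enter the
distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import AnalysisConfig, ConsensusSite, DiffExprRecord, GeneAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "TargetAssignment",
    "k_nearest_genes",
    "tss_distances",
    "bound_upregulated",
]


@dataclass(frozen=True)
class TargetAssignment:
    """A (site, gene) pair with rank among that site's nearest genes."""

    site: ConsensusSite
    gene_id: str
    distance: int
    rank: int  # 1 = closest gene to the site


def _annotation_by_chrom(
    annotation: Sequence[GeneAnnotation],
) -> dict[str, tuple[np.ndarray, list[str]]]:
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for a in annotation:
        by_chrom.setdefault(a.chrom, []).append(a)
    out = {}
    for chrom, genes in by_chrom.items():
        tss = np.array([g.tss for g in genes], dtype=np.int64)
        ids = [g.gene_id for g in genes]
        out[chrom] = (tss, ids)
    return out


def k_nearest_genes(
    sites: Sequence[ConsensusSite],
    annotation: Sequence[GeneAnnotation],
    k: int = 3,
) -> list[TargetAssignment]:
    """For each site, the k genes with smallest |anchor - TSS| on its chromosome.

    Ties in distance are broken lexicographically by gene_id.  Chromosomes
    with fewer than k genes yield all of them; sites on chromosomes absent
    from the annotation are skipped with a warning.
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    index = _annotation_by_chrom(annotation)
    out: list[TargetAssignment] = []
    skipped = 0
    for site in sites:
        chrom = site.interval.chrom
        if chrom not in index:
            skipped += 1
            continue
        tss, ids = index[chrom]
        dist = np.abs(tss - site.interval.anchor)
        m = min(k, len(ids))
        # order by (distance, gene_id); lexsort's last key is primary
        gene_order = np.argsort(np.array(ids, dtype=object), kind="stable")
        gene_rank = np.empty(len(ids), dtype=np.int64)
        gene_rank[gene_order] = np.arange(len(ids))
        order = np.lexsort((gene_rank, dist))[:m]
        for rank, j in enumerate(order, start=1):
            out.append(
                TargetAssignment(site, ids[j], int(dist[j]), rank)
            )
    if skipped:
        logger.warning(
            "k_nearest_genes: skipped %d site(s) on chromosomes absent from annotation",
            skipped,
        )
    logger.info(
        "k_nearest_genes: %d sites x k=%d -> %d assignments",
        len(sites), k, len(out),
    )
    return out


def tss_distances(
    sites: Sequence[ConsensusSite],
    annotation: Sequence[GeneAnnotation],
) -> tuple[list[int], float]:
    """Nearest-TSS distance of every site, plus the median (midpoint rule)."""
    if not sites:
        raise ValueError("sites must be non-empty")
    nearest = [a for a in k_nearest_genes(sites, annotation, k=1)]
    distances = [a.distance for a in nearest]
    if not distances:
        raise ValueError("no site lies on an annotated chromosome")
    return distances, float(np.median(distances))


def bound_upregulated(
    sites: Sequence[ConsensusSite],
    annotation: Sequence[GeneAnnotation],
    de: Sequence[DiffExprRecord],
    cfg: AnalysisConfig | None = None,
) -> set[str]:
    """Genes within the k nearest of some site AND upregulated.

    Upregulation means ``padj < padj_threshold`` and
    ``log2fc > log2(fc_threshold)`` (strict inequalities).  Genes absent
    from the DE table are treated as not upregulated.
    """
    cfg = cfg or AnalysisConfig()
    de_map = {r.gene_id: r for r in de}
    assignments = k_nearest_genes(sites, annotation, k=cfg.k_nearest)
    near = {a.gene_id for a in assignments}
    missing = near - de_map.keys()
    if missing:
        logger.warning(
            "bound_upregulated: %d near-site gene(s) absent from DE table, "
            "treated as not upregulated", len(missing),
        )
    log2_fc_cut = math.log2(cfg.fc_threshold)
    out = {
        g
        for g in near
        if g in de_map
        and de_map[g].padj < cfg.padj_threshold
        and de_map[g].log2fc > log2_fc_cut
    }
    logger.info(
        "bound_upregulated: %d near-site genes, %d pass DE thresholds "
        "(padj<%g, log2fc>%g)",
        len(near), len(out), cfg.padj_threshold, log2_fc_cut,
    )
    return out
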