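"""Replicate-consensus, background-filtered, isoform-classified binding sites.

The chain for each cell line is::

    consensus_peaks(rep1, rep2)        # per ChIP target (HIF-1a, HIF-2a, ARNT)
    filter_by_background(..., 99.99)   # empirical percentile of background counts
    classify_isoform(h1, h2, arnt)     # anchor alpha peaks on beta (ARNT) peaks

Overlap everywhere means sharing at least 1 bp on the same chromosome.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .types import BindingSite, ConsensusSite, GenomicInterval, IsoformClass

logger = logging.getLogger(__name__)

__all__ = ["consensus_peaks", "filter_by_background", "classify_isoform"]


def consensus_peaks(
    rep1: Sequence[BindingSite], rep2: Sequence[BindingSite]
) -> list[BindingSite]:
    """Keep peaks supported by both replicates, merged per overlap component.

    Peaks from the two replicates are pooled and grouped into connected
    components of pairwise >=1 bp overlap; each component containing at
    least one peak from each replicate becomes one output site spanning the
    union of its members, with count = mean of member counts and summit =
    midpoint of the union.  Output is sorted by (chrom, start, end).
    """
    tagged = [(s, 0) for s in rep1] + [(s, 1) for s in rep2]
    tagged.sort(key=lambda t: (t[0].interval.chrom, t[0].interval.start, t[0].interval.end))
    out: list[BindingSite] = []
    component: list[tuple[BindingSite, int]] = []
    comp_end = -1
    comp_chrom = None

    def flush() -> None:
        if not component:
            return
        reps = {tag for _, tag in component}
        if reps == {0, 1}:
            start = min(s.interval.start for s, _ in component)
            end = max(s.interval.end for s, _ in component)
            count = float(np.mean([s.count for s, _ in component]))
            iv = GenomicInterval(comp_chrom, start, end, summit=(start + end) // 2)
            out.append(BindingSite(iv, count))

    for site, tag in tagged:
        iv = site.interval
        if component and iv.chrom == comp_chrom and iv.start < comp_end:
            component.append((site, tag))
            comp_end = max(comp_end, iv.end)
        else:
            flush()
            component = [(site, tag)]
            comp_chrom = iv.chrom
            comp_end = iv.end
    flush()
    logger.info(
        "consensus_peaks: %d + %d replicate peaks -> %d consensus sites",
        len(rep1), len(rep2), len(out),
    )
    return out


def filter_by_background(
    peaks: Sequence[BindingSite],
    background_counts: Sequence[float],
    percentile: float = 99.99,
) -> list[BindingSite]:
    """Retain peaks whose count strictly exceeds the background percentile.

    The threshold is the linear-interpolation empirical percentile of
    ``background_counts``.
    """
    background = np.asarray(background_counts, dtype=float)
    if background.size == 0:
        raise ValueError("background_counts must be non-empty")
    if not (0.0 < percentile < 100.0):
        raise ValueError(f"percentile must lie in (0, 100), got {percentile}")
    threshold = float(np.percentile(background, percentile))
    kept = [p for p in peaks if p.count > threshold]
    logger.info(
        "filter_by_background: threshold=%.6g (percentile %.4g of %d draws); "
        "kept %d of %d peaks",
        threshold, percentile, background.size, len(kept), len(peaks),
    )
    return kept


def _overlapping(site: BindingSite, others: Sequence[BindingSite]) -> list[BindingSite]:
    return [o for o in others if site.interval.overlaps(o.interval)]


def classify_isoform(
    h1: Sequence[BindingSite],
    h2: Sequence[BindingSite],
    arnt: Sequence[BindingSite],
) -> list[ConsensusSite]:
    """Classify sites as HIF1, HIF2 or SHARED, anchored on ARNT peaks.

    HIF binds DNA as an alpha/beta dimer, so each output site is anchored on
    one beta (ARNT) peak: alpha peaks overlapping that anchor determine the
    class, and ARNT peaks with no alpha overlap are dropped.  The output
    interval spans the anchor and all contributing alpha peaks; the count is
    the mean of contributing counts.
    """
    out: list[ConsensusSite] = []
    for i, anchor in enumerate(arnt):
        h1_hits = _overlapping(anchor, h1)
        h2_hits = _overlapping(anchor, h2)
        if not h1_hits and not h2_hits:
            continue
        if h1_hits and h2_hits:
            cls = IsoformClass.SHARED
        elif h1_hits:
            cls = IsoformClass.HIF1
        else:
            cls = IsoformClass.HIF2
        members = [anchor] + h1_hits + h2_hits
        start = min(m.interval.start for m in members)
        end = max(m.interval.end for m in members)
        summit = anchor.interval.summit
        if summit is not None and not (start <= summit < end):
            summit = None
        count = float(np.mean([m.count for m in members]))
        support = tuple(
            [f"arnt:{i}"]
            + [f"h1:{h1.index(m)}" for m in h1_hits]
            + [f"h2:{h2.index(m)}" for m in h2_hits]
        )
        out.append(
            ConsensusSite(
                GenomicInterval(anchor.interval.chrom, start, end, summit),
                count=count,
                isoform_class=cls,
                support=support,
            )
        )
    n_by_class = {
        cls.value: sum(1 for s in out if s.isoform_class is cls)
        for cls in (IsoformClass.HIF1, IsoformClass.HIF2, IsoformClass.SHARED)
    }
    logger.info(
        "classify_isoform: %d/%d ARNT anchors classified (%s)",
        len(out), len(arnt), n_by_class,
    )
    return out
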