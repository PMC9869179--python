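"""End-to-end chain from replicate peak lists to a consensus signature."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .derivation import derive_consensus
from .peaks import classify_isoform, consensus_peaks, filter_by_background
from .targets import bound_upregulated
from .types import (
    AnalysisConfig,
    BindingSite,
    ConsensusSite,
    DiffExprRecord,
    GeneAnnotation,
    SignatureSet,
)

logger = logging.getLogger(__name__)

__all__ = ["line_consensus_sites", "derive_signature_from_panel"]


def line_consensus_sites(
    line_peaks: Mapping[str, tuple[Sequence[BindingSite], Sequence[BindingSite]]],
    background_counts,
    cfg: AnalysisConfig | None = None,
) -> list[ConsensusSite]:
    """Replicate consensus + background filter + isoform classification.

    ``line_peaks`` maps ChIP target name (``h1``, ``h2``, ``arnt``) to its
    two replicate peak lists.
    """
    cfg = cfg or AnalysisConfig()
    filtered = {}
    for target in ("h1", "h2", "arnt"):
        rep1, rep2 = line_peaks[target]
        merged = consensus_peaks(rep1, rep2)
        filtered[target] = filter_by_background(
            merged, background_counts, cfg.background_percentile
        )
    return classify_isoform(filtered["h1"], filtered["h2"], filtered["arnt"])


def derive_signature_from_panel(
    peaks_by_line: Mapping[str, Mapping[str, tuple]],
    de_by_line: Mapping[str, Sequence[DiffExprRecord]],
    annotation: Sequence[GeneAnnotation],
    background_counts,
    cfg: AnalysisConfig | None = None,
) -> tuple[dict[str, set[str]], SignatureSet]:
    """Run the full per-line chain and intersect into a consensus signature.

    Returns the per-line HIF-bound/upregulated gene sets and the consensus
    over at least ``cfg.min_lines`` lines (default: all lines).
    """
    cfg = cfg or AnalysisConfig()
    per_line: dict[str, set[str]] = {}
    for line in peaks_by_line:
        sites = line_consensus_sites(peaks_by_line[line], background_counts, cfg)
        per_line[line] = bound_upregulated(sites, annotation, de_by_line[line], cfg)
        logger.info("line %s: %d bound+upregulated genes", line, len(per_line[line]))
    min_lines = cfg.min_lines if cfg.min_lines is not None else len(per_line)
    signature = derive_consensus(per_line, min_lines)
    return per_line, signature
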