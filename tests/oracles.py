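"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the implementations they check: overlap components
are found by pairwise graph search, nearest genes by full sort, rank-sum
p-values by explicit enumeration over label assignments, and the GSEA
running sum by a literal per-position loop.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np


def _overlaps(a, b) -> bool:
    return a[0] == b[0] and a[1] < b[3] and b[1] < a[3]
    # tuples are (chrom, start, rep_tag_unused, end) -- see caller


def overlap_components_oracle(rep1, rep2):
    """All-pairs connected components; returns union spans of components
    containing at least one peak from each replicate, with mean counts."""
    peaks = [(s.interval.chrom, s.interval.start, s.interval.end, s.count, 0) for s in rep1]
    peaks += [(s.interval.chrom, s.interval.start, s.interval.end, s.count, 1) for s in rep2]
    n = len(peaks)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = peaks[i], peaks[j]
            if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    out = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        tags = {peaks[u][4] for u in comp}
        if tags == {0, 1}:
            chrom = peaks[comp[0]][0]
            start = min(peaks[u][1] for u in comp)
            end = max(peaks[u][2] for u in comp)
            count = float(np.mean([peaks[u][3] for u in comp]))
            out.append((chrom, start, end, count))
    return sorted(out)


def classify_oracle(h1, h2, arnt):
    """Per-ARNT-anchor classification by exhaustive pairwise overlap."""
    out = []
    for a in arnt:
        has1 = any(a.interval.overlaps(s.interval) for s in h1)
        has2 = any(a.interval.overlaps(s.interval) for s in h2)
        if not has1 and not has2:
            continue
        cls = "SHARED" if (has1 and has2) else ("HIF1" if has1 else "HIF2")
        out.append((a.interval.chrom, a.interval.start, a.interval.end, cls))
    return out


def knn_oracle(sites, annotation, k):
    """All-pairs nearest genes, sorted by (distance, gene_id)."""
    out = []
    for site in sites:
        anchor = site.interval.anchor
        cands = [
            (abs(g.tss - anchor), g.gene_id)
            for g in annotation
            if g.chrom == site.interval.chrom
        ]
        cands.sort()
        for rank, (d, gid) in enumerate(cands[:k], start=1):
            out.append((site.interval.start, gid, d, rank))
    return out


def ranksum_exact_oracle(x: Sequence[float], y: Sequence[float],
                         alternative: str = "two_sided") -> float:
    """Exact rank-sum p by enumeration over all label assignments (no ties)."""
    pooled = sorted(list(x) + list(y))
    n, m = len(x), len(y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs_r = sum(ranks[v] for v in x)
    obs_u = obs_r - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, n + m + 1), n):
        us.append(sum(combo) - n * (n + 1) / 2)
    us = np.array(us, dtype=float)
    if alternative == "greater":
        return float(np.mean(us >= obs_u))
    if alternative == "less":
        return float(np.mean(us <= obs_u))
    p = 2.0 * min(np.mean(us >= obs_u), np.mean(us <= obs_u))
    return float(min(p, 1.0))


def gsea_es_oracle(scores: Sequence[float], hit_flags: Sequence[bool],
                   weight: float) -> float:
    """Literal per-position running sum; signed maximum deviation."""
    scores = list(scores)
    hit_flags = list(hit_flags)
    n = len(scores)
    n_hits = sum(hit_flags)
    total_w = sum(abs(s) ** weight for s, hflag in zip(scores, hit_flags) if hflag)
    running, best = 0.0, 0.0
    for s, hflag in zip(scores, hit_flags):
        if hflag:
            running += (abs(s) ** weight / total_w) if total_w > 0 else 1.0 / n_hits
        else:
            running -= 1.0 / (n - n_hits)
        if abs(running) > abs(best):
            best = running
    return best


def expected_overlap_mc(set_sizes: dict, universe_size: int, n_draws: int,
                        rng: np.random.Generator):
    """Monte-Carlo estimate of expected pattern counts under independent
    membership, with standard errors: returns {pattern: (estimate, se)}."""
    names = list(set_sizes)
    probs = np.array([set_sizes[nm] / universe_size for nm in names])
    draws = rng.random((n_draws, len(names))) < probs  # one row = one gene
    codes = draws @ (1 << np.arange(len(names)))
    counts = np.bincount(codes, minlength=2 ** len(names))
    out = {}
    for bits in range(2 ** len(names)):
        pattern = frozenset(nm for i, nm in enumerate(names) if bits >> i & 1)
        p_hat = counts[bits] / n_draws
        est = universe_size * p_hat
        se = universe_size * np.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n_draws)
        out[pattern] = (est, se)
    return out
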