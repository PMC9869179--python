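"""Synthetic panel, cohort, and single-cell datasets with planted truth.

Each generator is a pure function of ``(cfg, seed)``: calling it twice with
the same arguments yields identical outputs.  The planted structure mirrors
the real analysis chain:

* ``simulate_panel`` — per-cell-line differential-expression tables plus
  replicate ChIP peak lists for the two alpha isoforms and the beta subunit,
  with a promoter-proximal consensus gene set shared by every line and
  promoter-distal line-specific targets.
* ``simulate_cohort`` — a bulk expression matrix whose samples carry a
  latent activation level driving the signature genes, a small companion
  gene set, and a mutation label that shifts activation.
* ``simulate_cells`` — a sparse single-cell count matrix with per-cluster
  activation and negative-binomial sampling noise (dropout arises from the
  count model itself).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .types import (
    BindingSite,
    DiffExprRecord,
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    SignatureSet,
)

__all__ = [
    "PanelConfig",
    "CohortConfig",
    "SCConfig",
    "PlantedTruth",
    "PanelData",
    "CohortData",
    "CellData",
    "simulate_panel",
    "simulate_cohort",
    "simulate_cells",
]

CHIP_TARGETS = ("h1", "h2", "arnt")

_GENE_SPACING = 50_000  # fixed chr1 layout; only distances matter
_PEAK_HALFWIDTH = 200
_REPLICATE_JITTER = 25
_N_BACKGROUND = 100_000


@dataclass
class PanelConfig:
    n_lines: int = 6
    n_genes: int = 5000
    n_consensus: int = 48
    n_specific_per_line: int = 300
    consensus_log2fc_mean: float = 1.5
    specific_log2fc_mean: float = 1.0
    log2fc_sd: float = 0.3
    null_log2fc_sd: float = 0.2
    se: float = 0.15
    consensus_tss_distance_sd: int = 500
    specific_tss_distance_mean: int = 12000
    peak_count_signal: float = 50.0
    peak_count_background_mean: float = 2.0

    def __post_init__(self) -> None:
        if self.n_consensus + self.n_lines * self.n_specific_per_line >= self.n_genes:
            raise ValueError(
                "infeasible gene budget: n_consensus + n_lines * n_specific_per_line "
                "must be < n_genes"
            )
        for name in (
            "consensus_log2fc_mean", "specific_log2fc_mean", "log2fc_sd",
            "null_log2fc_sd", "se", "consensus_tss_distance_sd",
            "specific_tss_distance_mean", "peak_count_signal",
            "peak_count_background_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CohortConfig:
    n_samples: int = 300
    n_genes: int = 2000
    activation_sd: float = 1.0
    signature_loading_mean: float = 0.8
    signature_loading_sd: float = 0.2
    companion_fraction: float = 0.05
    companion_loading_mean: float = 0.5
    companion_loading_sd: float = 0.2
    noise_sd: float = 0.5
    mutation_fraction: float = 0.3
    mutation_effect: float = 1.0

    def __post_init__(self) -> None:
        for name in ("companion_fraction", "mutation_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("activation_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("signature_loading_sd", "companion_loading_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SCConfig:
    n_cells: int = 2000
    n_genes: int = 1500
    n_clusters: int = 4
    lib_size_mean: int = 5000
    nb_dispersion: float = 0.5
    activation_by_cluster: list[float] | None = None
    signature_loading_mean: float = 0.8
    signature_loading_sd: float = 0.2
    activation_cell_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.activation_by_cluster is None:
            self.activation_by_cluster = list(
                np.linspace(0.0, 2.0, self.n_clusters)
            )
        if len(self.activation_by_cluster) != self.n_clusters:
            raise ValueError(
                f"activation_by_cluster has {len(self.activation_by_cluster)} entries "
                f"for {self.n_clusters} clusters"
            )


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator, for recovery checks."""

    consensus_genes: set[str] = field(default_factory=set)
    specific_genes: dict[str, set[str]] = field(default_factory=dict)
    activation: dict[str, float] = field(default_factory=dict)
    mutation_labels: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for line, genes in self.specific_genes.items():
            if self.consensus_genes & genes:
                raise ValueError(
                    f"consensus genes overlap specific genes of {line}"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "consensus_genes": sorted(self.consensus_genes),
            "specific_genes": {k: sorted(v) for k, v in self.specific_genes.items()},
            "activation": self.activation,
            "mutation_labels": self.mutation_labels,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            consensus_genes=set(payload["consensus_genes"]),
            specific_genes={k: set(v) for k, v in payload["specific_genes"].items()},
            activation=payload["activation"],
            mutation_labels=payload["mutation_labels"],
        )


@dataclass
class PanelData:
    de_tables: dict[str, list[DiffExprRecord]]
    peaks: dict[str, dict[str, tuple[list[BindingSite], list[BindingSite]]]]
    annotation: list[GeneAnnotation]
    background_counts: np.ndarray
    truth: PlantedTruth


@dataclass
class CohortData:
    matrix: ExpressionMatrix
    metadata: "pd.DataFrame"  # noqa: F821 - imported lazily below
    truth: PlantedTruth


@dataclass
class CellData:
    counts: ExpressionMatrix
    metadata: "pd.DataFrame"  # noqa: F821
    truth: PlantedTruth


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    return multipletests(pvals, method="fdr_bh")[1]


def simulate_panel(cfg: PanelConfig, seed: int) -> PanelData:
    """Generate the six-cell-line panel with planted consensus targets."""
    rng = np.random.default_rng(seed)
    n = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    tss = (np.arange(n) + 1) * _GENE_SPACING
    annotation = [
        GeneAnnotation(g, "chr1", int(t), "+") for g, t in zip(gene_ids, tss)
    ]
    lines = [f"LINE{i + 1}" for i in range(cfg.n_lines)]

    planted = rng.choice(n, size=cfg.n_consensus + cfg.n_lines * cfg.n_specific_per_line,
                         replace=False)
    consensus_idx = planted[: cfg.n_consensus]
    specific_idx = {
        line: planted[cfg.n_consensus + i * cfg.n_specific_per_line:
                      cfg.n_consensus + (i + 1) * cfg.n_specific_per_line]
        for i, line in enumerate(lines)
    }

    de_tables: dict[str, list[DiffExprRecord]] = {}
    peaks: dict[str, dict[str, tuple[list[BindingSite], list[BindingSite]]]] = {}
    for line in lines:
        log2fc = rng.normal(0.0, cfg.null_log2fc_sd, size=n)
        log2fc[consensus_idx] = rng.normal(
            cfg.consensus_log2fc_mean, cfg.log2fc_sd, size=cfg.n_consensus
        )
        log2fc[specific_idx[line]] = rng.normal(
            cfg.specific_log2fc_mean, cfg.log2fc_sd, size=cfg.n_specific_per_line
        )
        z = log2fc / cfg.se
        pvals = 2.0 * scipy.stats.norm.sf(np.abs(z))
        padj = np.clip(_bh_adjust(np.clip(pvals, 1e-300, 1.0)), 1e-300, 1.0)
        de_tables[line] = [
            DiffExprRecord(g, float(f), float(p))
            for g, f, p in zip(gene_ids, log2fc, padj)
        ]

        # one parent peak per planted gene, jittered into 2 replicates x 3 targets
        line_peaks = {t: ([], []) for t in CHIP_TARGETS}
        planted_here = [
            (idx, abs(rng.normal(0.0, cfg.consensus_tss_distance_sd)))
            for idx in consensus_idx
        ] + [
            (idx, rng.exponential(cfg.specific_tss_distance_mean))
            for idx in specific_idx[line]
        ]
        for idx, dist in planted_here:
            sign = 1 if rng.random() < 0.5 else -1
            summit = max(int(tss[idx] + sign * round(dist)), _PEAK_HALFWIDTH)
            parent_start = summit - _PEAK_HALFWIDTH
            parent_end = summit + _PEAK_HALFWIDTH
            for target in CHIP_TARGETS:
                for rep in (0, 1):
                    start = parent_start + int(rng.integers(-_REPLICATE_JITTER,
                                                            _REPLICATE_JITTER + 1))
                    end = parent_end + int(rng.integers(-_REPLICATE_JITTER,
                                                        _REPLICATE_JITTER + 1))
                    start = max(start, 0)
                    end = max(end, start + 1)
                    s = min(max(summit, start), end - 1)
                    count = max(
                        cfg.peak_count_signal * (1.0 + rng.normal(0.0, 0.1)), 0.0
                    )
                    line_peaks[target][rep].append(
                        BindingSite(GenomicInterval("chr1", start, end, s), count)
                    )
        peaks[line] = {t: (list(r1), list(r2)) for t, (r1, r2) in line_peaks.items()}

    background = rng.exponential(cfg.peak_count_background_mean, size=_N_BACKGROUND)
    truth = PlantedTruth(
        consensus_genes={gene_ids[i] for i in consensus_idx},
        specific_genes={
            line: {gene_ids[i] for i in specific_idx[line]} for line in lines
        },
    )
    return PanelData(de_tables, peaks, annotation, background, truth)


def simulate_cohort(
    cfg: CohortConfig, seed: int, signature: SignatureSet
) -> CohortData:
    """Generate a bulk cohort with latent activation and mutation labels."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    sig_genes = list(signature.genes)
    if len(sig_genes) >= cfg.n_genes:
        raise ValueError("signature larger than simulated gene universe")
    n_filler = cfg.n_genes - len(sig_genes)
    gene_ids = sig_genes + [f"BULK{i:05d}" for i in range(n_filler)]
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]

    mutated = rng.random(cfg.n_samples) < cfg.mutation_fraction
    activation = rng.normal(0.0, cfg.activation_sd, cfg.n_samples)
    activation = activation + cfg.mutation_effect * mutated

    n_sig = len(sig_genes)
    non_sig_idx = np.arange(n_sig, cfg.n_genes)
    n_companion = int(round(cfg.companion_fraction * len(non_sig_idx)))
    companion_idx = rng.choice(non_sig_idx, size=n_companion, replace=False)

    loadings = np.zeros(cfg.n_genes)
    loadings[:n_sig] = np.abs(
        rng.normal(cfg.signature_loading_mean, cfg.signature_loading_sd, n_sig)
    )
    loadings[companion_idx] = np.abs(
        rng.normal(cfg.companion_loading_mean, cfg.companion_loading_sd, n_companion)
    )

    baseline = rng.uniform(2.0, 8.0, cfg.n_genes)
    log_expr = (
        baseline[:, None]
        + loadings[:, None] * activation[None, :]
        + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, cfg.n_samples))
    )
    values = np.exp2(log_expr)
    matrix = ExpressionMatrix(values, gene_ids, sample_ids, layer="normalized")
    metadata = pd.DataFrame(
        {
            "id": sample_ids,
            "group": np.where(mutated, "mutated", "wildtype"),
        }
    )
    truth = PlantedTruth(
        consensus_genes=set(sig_genes),
        specific_genes={"companion": {gene_ids[i] for i in companion_idx}},
        activation={s: float(a) for s, a in zip(sample_ids, activation)},
        mutation_labels={s: bool(m) for s, m in zip(sample_ids, mutated)},
    )
    return CohortData(matrix, metadata, truth)


def simulate_cells(cfg: SCConfig, seed: int, signature: SignatureSet) -> CellData:
    """Generate a single-cell count matrix with per-cluster activation."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    sig_genes = list(signature.genes)
    if len(sig_genes) >= cfg.n_genes:
        raise ValueError("signature larger than simulated gene universe")
    gene_ids = sig_genes + [f"SC{i:05d}" for i in range(cfg.n_genes - len(sig_genes))]
    cell_ids = [f"CELL{i:05d}" for i in range(cfg.n_cells)]

    clusters = rng.integers(0, cfg.n_clusters, size=cfg.n_cells)
    base = np.asarray(cfg.activation_by_cluster, dtype=float)
    activation = base[clusters] + rng.normal(0.0, cfg.activation_cell_sd, cfg.n_cells)

    n_sig = len(sig_genes)
    loadings = np.zeros(cfg.n_genes)
    loadings[:n_sig] = np.abs(
        rng.normal(cfg.signature_loading_mean, cfg.signature_loading_sd, n_sig)
    )
    baseline = rng.normal(0.0, 1.0, cfg.n_genes)
    log_mean = baseline[:, None] + loadings[:, None] * activation[None, :]
    prob = np.exp(log_mean - log_mean.max(axis=0, keepdims=True))
    prob /= prob.sum(axis=0, keepdims=True)
    mu = cfg.lib_size_mean * prob

    r = 1.0 / cfg.nb_dispersion  # var = mu + dispersion * mu^2
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p).astype(float)

    matrix = ExpressionMatrix(counts, gene_ids, cell_ids, layer="counts")
    metadata = pd.DataFrame(
        {"id": cell_ids, "cluster": [f"C{c}" for c in clusters]}
    )
    truth = PlantedTruth(
        consensus_genes=set(sig_genes),
        activation={c: float(a) for c, a in zip(cell_ids, activation)},
    )
    return CellData(matrix, metadata, truth)
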