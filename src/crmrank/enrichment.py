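"""Gene-set recovery-curve enrichment against a motif library.

Given a genome-wide gene ranking for one motif, the recovery curve counts
how many members of a coexpressed gene set have been encountered at or
before each rank.  Enrichment of a motif is the area under this curve over a
top fraction of the ranking (default 5%), normalized by set size times the
integration bound so the maximum is <= 1.  Significance is self-normalizing:
the same gene set is scored against every other motif of the library, and
the query AUC is standardized against those control AUCs (z-score).  No
additional multiple-testing correction is applied -- the z-vs-library
construction is the null.

The optimal cutoff is the rank where observed recovery most exceeds the
expected recovery, i.e. the per-rank mean of the control curves, in units of
their per-rank standard deviation, requiring at least three recovered genes.
Gene-set members at or above the cutoff form the leading edge: the predicted
direct targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ranking import GeneRanking
from .regions import GeneSet

logger = logging.getLogger(__name__)

DEFAULT_TOP_FRACTION = 0.05
DEFAULT_Z_THRESHOLD = 2.5
MIN_CONTROLS = 10
MIN_RECOVERED_AT_CUTOFF = 3
SD_FLOOR_Z = 1e-9  # floor on control-AUC sd in the z-score
SD_FLOOR_CURVE = 0.1  # floor on per-rank control-recovery sd


@dataclass
class RecoveryCurve:
    """Cumulative recovery of a gene set along one motif's gene ranking.

    ``y[i]`` is the number of set members at rank <= i+1; ``y`` has one entry
    per rank, is non-decreasing, and ends at the mappable set size ``m``.
    """

    model_id: str
    y: np.ndarray
    set_size: int
    member_mask: np.ndarray  # bool per rank position
    gene_order: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.y)


@dataclass
class ControlDistribution:
    """Library-control summaries for one gene set.

    ``aucs`` maps every library motif to its recovery AUC; ``mean_curve`` and
    ``sd_curve`` are the per-rank mean / sd of the control recovery counts
    (sd floored at a small positive constant).
    """

    aucs: dict[str, float]
    mean_curve: np.ndarray
    sd_curve: np.ndarray

    def __post_init__(self) -> None:
        if len(self.aucs) < MIN_CONTROLS:
            raise ValueError(f"need at least {MIN_CONTROLS} control motifs")
        self.sd_curve = np.maximum(self.sd_curve, SD_FLOOR_CURVE)


@dataclass
class EnrichmentResult:
    model_id: str
    auc: float
    z_score: float
    optimal_cutoff_rank: int  # 0 = no significant cutoff
    leading_edge: list[str] = field(default_factory=list)
    leading_edge_detail: pd.DataFrame | None = None
    significant: bool = False


@dataclass
class DiscoveryReport:
    """Per-motif enrichment results, sorted by AUC descending (stable)."""

    results: list[EnrichmentResult]
    gene_set_label: str
    z_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif_id": [r.model_id for r in self.results],
                "auc": [r.auc for r in self.results],
                "z_score": [r.z_score for r in self.results],
                "cutoff_rank": [r.optimal_cutoff_rank for r in self.results],
                "n_targets": [len(r.leading_edge) for r in self.results],
                "significant": [r.significant for r in self.results],
                "targets": [",".join(r.leading_edge) for r in self.results],
            }
        )

    @property
    def best(self) -> EnrichmentResult:
        return self.results[0]

    def significant_results(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.significant]


def recovery_curve(ranking: GeneRanking, gene_set: GeneSet) -> RecoveryCurve:
    """Step curve of cumulative gene-set recovery along the ranking.

    Set members absent from the ranking are dropped with a logged count;
    a set with no mappable member is an error.
    """
    order = ranking.gene_order()
    members = gene_set.gene_ids
    mask = np.fromiter((g in members for g in order), dtype=bool, count=len(order))
    m = int(mask.sum())
    n_dropped = len(members) - m
    if m == 0:
        raise ValueError(
            f"gene set {gene_set.label!r}: no member maps into the ranking"
        )
    if n_dropped:
        logger.warning(
            "gene set %s: %d ids not in ranking (dropped)", gene_set.label, n_dropped
        )
    return RecoveryCurve(
        model_id=ranking.model_id,
        y=np.cumsum(mask),
        set_size=m,
        member_mask=mask,
        gene_order=order,
    )


def auc(curve: RecoveryCurve, top_fraction: float = DEFAULT_TOP_FRACTION) -> float:
    """Normalized area under the recovery curve over the top fraction.

    Step integral of y over ranks 1..floor(top_fraction * n), divided by
    (m * bound) so a set recovered entirely at rank 1 approaches 1.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    bound = int(math.floor(top_fraction * curve.n_genes))
    if bound < 1:
        raise ValueError("top_fraction * n_genes must be >= 1")
    return float(curve.y[:bound].sum()) / (curve.set_size * bound)


def z_score(query_auc: float, controls: ControlDistribution, query_model_id: str) -> float:
    """Standardize a query AUC against the other library motifs' AUCs."""
    control_aucs = np.array(
        [a for mid, a in controls.aucs.items() if mid != query_model_id]
    )
    if control_aucs.size < MIN_CONTROLS:
        raise ValueError(f"need at least {MIN_CONTROLS} control AUCs")
    sd = control_aucs.std(ddof=1)
    return float((query_auc - control_aucs.mean()) / max(sd, SD_FLOOR_Z))


def optimal_cutoff(
    curve: RecoveryCurve,
    controls: ControlDistribution,
    max_rank: int | None = None,
) -> tuple[int, list[str]]:
    """Rank maximizing the standardized excess recovery, and its leading edge.

    cutoff = argmax over i <= max_rank of (y(i) - mu_i) / sigma_i subject to
    y(i) >= 3; ties prefer the smallest rank.  When no rank recovers three
    set members the result is (0, []) -- "no significant cutoff", not an
    error.  The leading edge lists set members in rank order.
    """
    n = curve.n_genes
    if max_rank is None:
        max_rank = int(math.floor(DEFAULT_TOP_FRACTION * n))
    if max_rank > n:
        raise ValueError("max_rank exceeds the number of ranked genes")
    max_rank = max(max_rank, 1)
    y = curve.y[:max_rank].astype(float)
    mu = controls.mean_curve[:max_rank]
    sd = controls.sd_curve[:max_rank]
    stat = (y - mu) / sd
    eligible = y >= MIN_RECOVERED_AT_CUTOFF
    if not eligible.any():
        return 0, []
    stat = np.where(eligible, stat, -np.inf)
    cutoff = int(np.argmax(stat)) + 1  # argmax returns the first maximum
    leading = [
        g for g, is_m in zip(curve.gene_order[:cutoff], curve.member_mask[:cutoff]) if is_m
    ]
    return cutoff, leading


def control_distribution(
    curves: dict[str, RecoveryCurve],
    top_fraction: float = DEFAULT_TOP_FRACTION,
    exclude: str | None = None,
) -> ControlDistribution:
    """Build library controls from per-motif recovery curves of one gene set."""
    ids = [mid for mid in curves if mid != exclude]
    if not ids:
        raise ValueError("no control curves")
    Y = np.stack([curves[mid].y for mid in ids]).astype(float)
    return ControlDistribution(
        aucs={mid: auc(curves[mid], top_fraction) for mid in curves},
        mean_curve=Y.mean(axis=0),
        sd_curve=Y.std(axis=0, ddof=0),
    )


def enrich_motif(
    query_model_id: str,
    curves: dict[str, RecoveryCurve],
    aucs: dict[str, float],
    top_fraction: float = DEFAULT_TOP_FRACTION,
    max_rank: int | None = None,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> EnrichmentResult:
    """Full enrichment result for one library motif (leave-one-out controls)."""
    others = [mid for mid in curves if mid != query_model_id]
    Y = np.stack([curves[mid].y for mid in others]).astype(float)
    controls = ControlDistribution(
        aucs=aucs,
        mean_curve=Y.mean(axis=0),
        sd_curve=Y.std(axis=0, ddof=0),
    )
    q_auc = aucs[query_model_id]
    z = z_score(q_auc, controls, query_model_id)
    cutoff, leading = optimal_cutoff(curves[query_model_id], controls, max_rank)
    return EnrichmentResult(
        model_id=query_model_id,
        auc=q_auc,
        z_score=z,
        optimal_cutoff_rank=cutoff,
        leading_edge=leading,
        significant=z >= z_threshold,
    )


def discover_motifs(
    rankings: dict[str, GeneRanking],
    gene_set: GeneSet,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    max_rank: int | None = None,
) -> DiscoveryReport:
    """Score a gene set against every library motif; rank motifs by AUC.

    Motifs with z >= ``z_threshold`` are flagged (never filtered).  Requires
    a library of at least 11 motifs so every query has >= 10 controls.
    """
    if len(rankings) < MIN_CONTROLS + 1:
        raise ValueError(f"need at least {MIN_CONTROLS + 1} motifs in the library")
    curves = {mid: recovery_curve(r, gene_set) for mid, r in rankings.items()}
    aucs = {mid: auc(c, top_fraction) for mid, c in curves.items()}
    results = [
        enrich_motif(mid, curves, aucs, top_fraction, max_rank, z_threshold)
        for mid in rankings
    ]
    results.sort(key=lambda r: (-r.auc, r.model_id))
    return DiscoveryReport(
        results=results, gene_set_label=gene_set.label, z_threshold=z_threshold
    )
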