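"""Cross-species rank integration by order statistics.

Each species' regions are ranked independently by cluster score (descending,
ties broken lexicographically by region id for reproducibility).  For every
reference region the per-species rank ratios r = R / n of its orthologs are
fused with the joint order-statistic probability

    Q(r_1 <= ... <= r_N) = N! * V_N,
    V_0 = 1,
    V_m = sum_{i=1..m} (-1)^(i-1) * V_{m-i} * r_{N-m+1}^i / i!

i.e. the probability that N sorted i.i.d. uniforms fall jointly below the
observed sorted ratios.  Small Q means a region ranks unexpectedly high in
several species at once.  Regions are re-ranked by ascending Q; a gene
inherits the rank of its best region.

Species with no ortholog for a region contribute a rank ratio of 1.0 by
default ("no evidence", keeping N fixed so Q stays comparable across
regions); alternatively they can be dropped (N reduced per region).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import OrthologyMap
from .scoring import RegionScore

logger = logging.getLogger(__name__)

MAX_SPECIES = 16  # recursion validated in float64 up to here
RATIO_FLOOR = 1e-12


@dataclass
class SpeciesRanking:
    """Per-region ranks of one species for one motif model.

    ``table`` columns: region_id, score, rank (1-based), ratio (rank / n).
    """

    species_id: str
    model_id: str
    table: pd.DataFrame

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def ratios(self) -> pd.Series:
        return self.table.set_index("region_id")["ratio"]


@dataclass
class IntegratedRegionRanking:
    """Reference-region ranking after cross-species integration.

    ``table`` columns: region_id, q, ref_ratio, rank (1-based, ascending q),
    n_species_used.
    """

    model_id: str
    reference_species: str
    table: pd.DataFrame


@dataclass
class GeneRanking:
    """Final gene ranking; ``table`` columns: gene_id, best_region_id, q, rank."""

    model_id: str
    table: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def gene_order(self) -> list[str]:
        return self.table["gene_id"].tolist()


def rank_per_species(scores: list[RegionScore]) -> SpeciesRanking:
    """Rank one species' region scores (descending; ties by region_id)."""
    if not scores:
        raise ValueError("no scores to rank")
    species = {s.species_id for s in scores}
    models = {s.model_id for s in scores}
    if len(species) != 1 or len(models) != 1:
        raise ValueError("rank_per_species expects one species and one model")
    ids = [s.region_id for s in scores]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region ids in scores")
    df = pd.DataFrame(
        {"region_id": ids, "score": [s.score_bits for s in scores]}
    ).sort_values(["score", "region_id"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    n = len(df)
    df["rank"] = np.arange(1, n + 1)
    df["ratio"] = df["rank"] / n
    return SpeciesRanking(species_id=species.pop(), model_id=models.pop(), table=df)


def rank_from_score_series(
    region_ids: np.ndarray, scores: np.ndarray, species_id: str, model_id: str
) -> SpeciesRanking:
    """Vectorized variant of :func:`rank_per_species` for batch pipelines."""
    rs = [
        RegionScore(region_id=str(r), species_id=species_id, model_id=model_id,
                    score_bits=float(s))
        for r, s in zip(region_ids, scores)
    ]
    return rank_per_species(rs)


def order_statistic_q(ratios) -> float:
    """Joint order-statistic probability for one ascending ratio vector."""
    r = np.asarray(ratios, dtype=float)
    _validate_ratios(r)
    return float(_q_batch(r[None, :])[0])


def _validate_ratios(r: np.ndarray) -> None:
    if r.ndim != 1 or r.size < 1:
        raise ValueError("ratios must be a non-empty 1-D collection")
    if r.size > MAX_SPECIES:
        raise ValueError(f"at most {MAX_SPECIES} species supported")
    if (r <= 0).any() or (r > 1).any():
        raise ValueError("ratios must lie in (0, 1]")
    if (np.diff(r) < 0).any():
        raise ValueError("ratios must be sorted ascending")


def _q_batch(r: np.ndarray) -> np.ndarray:
    """Vectorized Q over rows of an ascending ratio matrix (n_rows, N)."""
    n_rows, N = r.shape
    r = np.maximum(r, RATIO_FLOOR)
    V = [np.ones(n_rows)]
    inv_fact = [1.0 / math.factorial(i) for i in range(N + 1)]
    for m in range(1, N + 1):
        base = r[:, N - m]  # r_{N-m+1}, 1-based
        acc = np.zeros(n_rows)
        power = np.ones(n_rows)
        for i in range(1, m + 1):
            power = power * base
            term = V[m - i] * power * inv_fact[i]
            acc += term if (i % 2 == 1) else -term
        V.append(acc)
    q = math.factorial(N) * V[N]
    return np.clip(q, 0.0, 1.0)


def integrate_ranks(
    per_species: dict[str, SpeciesRanking],
    orthology: OrthologyMap,
    missing_policy: str = "penalize",
) -> IntegratedRegionRanking:
    """Fuse per-species rankings over the orthology map.

    missing_policy 'penalize' (default): a species with no ortholog
    contributes ratio 1.0 and N stays fixed at the number of species.
    'drop': the species is left out and N shrinks for that region.
    """
    if missing_policy not in ("penalize", "drop"):
        raise ValueError("missing_policy must be 'penalize' or 'drop'")
    ref = orthology.reference_species
    if ref not in per_species:
        raise ValueError(f"reference species {ref!r} missing from rankings")
    if not len(per_species[ref].table):
        raise ValueError("empty reference ranking")
    model_ids = {sr.model_id for sr in per_species.values()}
    if len(model_ids) != 1:
        raise ValueError("per-species rankings must share one model_id")
    model_id = model_ids.pop()

    species_ids = [s for s in orthology.species_ids if s in per_species]
    ratio_maps = {s: per_species[s].ratios() for s in species_ids}
    ref_ratios = ratio_maps[ref]

    region_ids = per_species[ref].table["region_id"].tolist()
    rows_q = np.empty(len(region_ids))
    n_used = np.empty(len(region_ids), dtype=int)
    if missing_policy == "penalize":
        # single vectorized Q over a dense (n_regions, N) matrix
        mat = np.ones((len(region_ids), len(species_ids)))
        for col, s in enumerate(species_ids):
            rmap = ratio_maps[s]
            for row, ref_id in enumerate(region_ids):
                ortho = orthology.orthologs(ref_id).get(s)
                if ortho is not None and ortho in rmap.index:
                    mat[row, col] = rmap[ortho]
        mat.sort(axis=1)
        rows_q = _q_batch(mat)
        n_used[:] = len(species_ids)
    else:
        for row, ref_id in enumerate(region_ids):
            ratios = []
            for s in species_ids:
                ortho = orthology.orthologs(ref_id).get(s)
                if ortho is not None and ortho in ratio_maps[s].index:
                    ratios.append(float(ratio_maps[s][ortho]))
            ratios.sort()
            rows_q[row] = _q_batch(np.array(ratios)[None, :])[0]
            n_used[row] = len(ratios)

    df = pd.DataFrame(
        {
            "region_id": region_ids,
            "q": rows_q,
            "ref_ratio": [float(ref_ratios[r]) for r in region_ids],
            "n_species_used": n_used,
        }
    ).sort_values(["q", "ref_ratio", "region_id"], kind="mergesort")
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return IntegratedRegionRanking(model_id=model_id, reference_species=ref, table=df)


def gene_ranking(
    integrated: IntegratedRegionRanking, region_to_gene: dict[str, str]
) -> GeneRanking:
    """Collapse the region ranking to genes via each gene's best region."""
    df = integrated.table.copy()
    unmapped = [r for r in df["region_id"] if r not in region_to_gene]
    if unmapped:
        raise ValueError(f"regions with no gene mapping: {unmapped[:5]}...")
    df["gene_id"] = df["region_id"].map(region_to_gene)
    best = df.drop_duplicates("gene_id", keep="first")  # df already rank-ordered
    mapped_genes = set(best["gene_id"])
    missing = [g for g in set(region_to_gene.values()) if g not in mapped_genes]
    if missing:
        logger.warning("%d genes have no ranked region; excluded", len(missing))
    out = best[["gene_id", "region_id", "q"]].rename(columns={"region_id": "best_region_id"})
    out = out.reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return GeneRanking(model_id=integrated.model_id, table=out)


# ---------------------------------------------------------------------------
# persistence (one directory per motif model, TSV inside)


def save_gene_ranking(ranking: GeneRanking, path) -> None:
    ranking.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_gene_ranking(path, model_id: str) -> GeneRanking:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "best_region_id": str})
    required = {"gene_id", "best_region_id", "q", "rank"}
    if not required <= set(table.columns):
        raise ValueError(f"ranking file {path} lacks columns {required - set(table.columns)}")
    return GeneRanking(model_id=model_id, table=table)
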