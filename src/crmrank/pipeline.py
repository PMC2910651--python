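"""Two-step orchestration: offline motif scoring/ranking, online enrichment.

Step one scores every species' regions for every library motif, ranks the
regions per species, integrates the ranks across species by order statistics
and collapses to a gene ranking per motif.  Rankings are persisted one
directory per motif so that step two -- scoring a gene set against the whole
library -- runs without touching sequence again.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .enrichment import DiscoveryReport, discover_motifs
from .pwm import MotifLibrary, Pwm
from .ranking import (
    GeneRanking,
    gene_ranking,
    integrate_ranks,
    load_gene_ranking,
    rank_from_score_series,
    save_gene_ranking,
)
from .regions import GeneSet, OrthologyMap, RegionSet
from .scoring import BackgroundModel, ClusterModel, cluster_scores_batch, estimate_background

logger = logging.getLogger(__name__)


def _encode_species(sequences: dict[str, str]):
    """Sorted region ids + right-padded int8 code matrix for one species."""
    from .scoring import encode_sequence

    ids = sorted(sequences)
    max_len = max(len(sequences[r]) for r in ids)
    codes = np.full((len(ids), max_len), 4, dtype=np.int8)
    for i, rid in enumerate(ids):
        s = sequences[rid]
        codes[i, : len(s)] = encode_sequence(s)
    return np.array(ids), codes


def score_library(
    sequences: dict[str, dict[str, str]],
    orthology: OrthologyMap,
    region_to_gene: dict[str, str],
    library: MotifLibrary,
    gap_penalty: float = 0.1,
    backgrounds: dict[str, BackgroundModel] | None = None,
    missing_policy: str = "penalize",
    species_subset: list[str] | None = None,
) -> dict[str, GeneRanking]:
    """Gene ranking per library motif from per-species region sequences.

    ``sequences`` maps species -> region_id -> sequence.  The background
    defaults to a per-species 0-order model estimated from that species'
    full region set.
    """
    species_ids = [s for s in orthology.species_ids if s in sequences]
    if species_subset is not None:
        species_ids = [s for s in species_ids if s in species_subset]
    if orthology.reference_species not in species_ids:
        raise ValueError("reference species has no sequences")
    if backgrounds is None:
        backgrounds = {
            s: estimate_background(sequences[s].values(), scope=s) for s in species_ids
        }
    encoded = {s: _encode_species(sequences[s]) for s in species_ids}

    sub_orthology = OrthologyMap(
        reference_species=orthology.reference_species,
        mapping=orthology.mapping,
        species_ids=species_ids,
    )
    rankings: dict[str, GeneRanking] = {}
    for pwm in library:
        t0 = time.perf_counter()
        model = ClusterModel(motifs=[pwm], gap_penalty_bits_per_base=gap_penalty)
        per_species = {}
        for s in species_ids:
            ids, codes = encoded[s]
            scores = cluster_scores_batch(model, backgrounds[s], codes)
            per_species[s] = rank_from_score_series(ids, scores, s, model.model_id)
        integrated = integrate_ranks(per_species, sub_orthology, missing_policy)
        rankings[pwm.motif_id] = GeneRanking(
            model_id=pwm.motif_id,
            table=gene_ranking(integrated, region_to_gene).table,
        )
        logger.info("scored motif %s in %.2fs", pwm.motif_id, time.perf_counter() - t0)
    return rankings


# ---------------------------------------------------------------------------
# persisted ranking layout: <out>/rankings/<motif_id>/gene_ranking.tsv


def save_rankings(rankings: dict[str, GeneRanking], outdir) -> None:
    outdir = Path(outdir)
    for motif_id, ranking in rankings.items():
        d = outdir / "rankings" / motif_id
        d.mkdir(parents=True, exist_ok=True)
        save_gene_ranking(ranking, d / "gene_ranking.tsv")


def ranking_exists(outdir, motif_id: str) -> bool:
    return (Path(outdir) / "rankings" / motif_id / "gene_ranking.tsv").exists()


def load_rankings(outdir) -> dict[str, GeneRanking]:
    root = Path(outdir) / "rankings"
    if not root.is_dir():
        raise FileNotFoundError(f"no rankings directory under {outdir}")
    out = {}
    for d in sorted(root.iterdir()):
        f = d / "gene_ranking.tsv"
        if f.exists():
            out[d.name] = load_gene_ranking(f, model_id=d.name)
    if not out:
        raise FileNotFoundError(f"no rankings found under {root}")
    return out


def run_enrichment(
    rankings: dict[str, GeneRanking],
    gene_set: GeneSet,
    z_threshold: float = 2.5,
    top_fraction: float = 0.05,
    max_rank: int | None = None,
) -> DiscoveryReport:
    return discover_motifs(
        rankings, gene_set, z_threshold=z_threshold,
        top_fraction=top_fraction, max_rank=max_rank,
    )


def write_manifest(outdir, config: dict, seed: int | None = None) -> None:
    """Reproducibility manifest: config, its hash, package version, seed."""
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "crmrank_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
    }
    Path(outdir).mkdir(parents=True, exist_ok=True)
    with open(Path(outdir) / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
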