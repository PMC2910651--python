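"""Synthetic multi-species region bundles with implanted motif clusters.

The generator emulates the statistical structure the whole pipeline assumes:
a reference "genome" of one fixed-length candidate region per gene, a subset
of target genes carrying a homotypic cluster of binding sites sampled from a
PWM inside a confined window, and orthologous regions in further species
produced by per-base substitution at a high background rate outside sites
and a low rate inside them (site conservation).  A "coexpressed" gene set is
the implanted targets diluted with a configurable fraction of non-targets,
mirroring the mixture of direct and indirect targets a perturbation
experiment yields.

Everything is a pure function of :class:`SyntheticSpec` (including its seed):
two runs with the same spec produce byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .pwm import BASES, MotifLibrary, Pwm
from .regions import GeneSet, GenomicRegion, OrthologyMap, RegionSet
from .scoring import SiteMatch

logger = logging.getLogger(__name__)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SyntheticSpec:
    """Generative parameters for one bundle (defaults are the study design)."""

    n_genes: int = 1000
    region_length_bp: int = 1000
    n_species: int = 4
    n_target_genes: int = 50
    sites_per_cluster: int = 3
    cluster_window_bp: int = 300
    background_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    bg_substitution_rate: float = 0.25
    site_substitution_rate: float = 0.03
    contamination: float = 0.5  # fraction of the gene set that are non-targets
    dropout: float = 0.0  # per-(region, species) missing-ortholog probability
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_target_genes <= self.n_genes:
            raise ValueError("n_target_genes must be in 1..n_genes")
        for rate in (self.bg_substitution_rate, self.site_substitution_rate,
                     self.contamination, self.dropout):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.site_substitution_rate > self.bg_substitution_rate:
            raise ValueError("sites must be at least as conserved as background")
        if self.region_length_bp < 1:
            raise ValueError("regions must have positive length")
        if self.n_species < 1:
            raise ValueError("need at least one species")

    @property
    def species_ids(self) -> list[str]:
        return ["ref"] + [f"sp{i}" for i in range(1, self.n_species)]


@dataclass
class ImplantLog:
    """Ground-truth site placements: one entry per site per species."""

    entries: list[dict] = field(default_factory=list)
    target_genes: list[str] = field(default_factory=list)

    def sites_for(self, species_id: str, region_id: str) -> list[dict]:
        return [
            e for e in self.entries
            if e["species_id"] == species_id and e["region_id"] == region_id
        ]

    def reference_sites(self) -> list[dict]:
        return [e for e in self.entries if e["species_id"] == "ref"]


@dataclass
class Bundle:
    """A complete synthetic experiment: sequences, orthology, truth, gene set."""

    spec: SyntheticSpec
    sequences: dict[str, dict[str, str]]  # species -> region_id -> sequence
    region_sets: dict[str, RegionSet]
    orthology: OrthologyMap
    implant_log: ImplantLog
    gene_set: GeneSet | None
    region_to_gene: dict[str, str]  # reference regions


def gene_id(i: int) -> str:
    return f"g{i:04d}"


def region_id_of(i: int) -> str:
    return f"r{i:04d}"


def _bg_probs(spec: SyntheticSpec) -> np.ndarray:
    f = np.maximum(np.asarray(spec.background_frequencies, dtype=float), 1e-4)
    return f / f.sum()


def sample_genome(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Reference-species region sequences: i.i.d. background draws."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    probs = _bg_probs(spec)
    base_arr = np.frombuffer("ACGT".encode(), dtype="S1")
    out: dict[str, str] = {}
    for i in range(spec.n_genes):
        draws = rng.choice(4, size=spec.region_length_bp, p=probs)
        out[region_id_of(i)] = base_arr[draws].tobytes().decode()
    return out


def sample_site(pwm: Pwm, rng: np.random.Generator) -> str:
    """One site drawn position-wise from the PWM probabilities."""
    return "".join(
        BASES[rng.choice(4, p=pwm.probs[j] / pwm.probs[j].sum())]
        for j in range(pwm.length)
    )


def _reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def implant_clusters(
    sequences: dict[str, str],
    pwm: Pwm,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], ImplantLog]:
    """Place homotypic site clusters into randomly chosen target regions.

    Targets are drawn without replacement; each receives
    ``sites_per_cluster`` non-overlapping sites at random strands inside one
    random window of ``cluster_window_bp``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    w = pwm.length
    if spec.cluster_window_bp < spec.sites_per_cluster * w:
        raise ValueError("cluster window too small for the requested sites")
    if spec.cluster_window_bp > spec.region_length_bp:
        raise ValueError("cluster window larger than the region")
    region_ids = sorted(sequences)
    target_idx = rng.choice(spec.n_genes, size=spec.n_target_genes, replace=False)
    target_idx.sort()
    log = ImplantLog(target_genes=[gene_id(i) for i in target_idx])
    out = dict(sequences)
    for i in target_idx:
        rid = region_id_of(i)
        seq = list(out[rid])
        win_start = int(rng.integers(0, spec.region_length_bp - spec.cluster_window_bp + 1))
        offsets = _sample_nonoverlapping_offsets(
            rng, spec.cluster_window_bp, w, spec.sites_per_cluster
        )
        for off in offsets:
            pos = win_start + off
            strand = "+" if rng.random() < 0.5 else "-"
            site = sample_site(pwm, rng)
            placed = site if strand == "+" else _reverse_complement(site)
            seq[pos : pos + w] = placed
            log.entries.append(
                {
                    "gene_id": gene_id(i),
                    "region_id": rid,
                    "species_id": "ref",
                    "offset": pos,
                    "strand": strand,
                    "site_seq": placed,
                    "motif_id": pwm.motif_id,
                }
            )
        out[rid] = "".join(seq)
    assert set(out) == set(region_ids)
    return out, log


def _sample_nonoverlapping_offsets(
    rng: np.random.Generator, window: int, width: int, k: int
) -> list[int]:
    """k non-overlapping site offsets inside [0, window - width]."""
    # draw gaps: distribute the slack uniformly between/around the k sites
    slack = window - k * width
    cuts = np.sort(rng.choice(slack + 1, size=k, replace=True))
    return [int(cuts[j] + j * width) for j in range(k)]


def evolve_orthologs(
    reference: dict[str, str],
    implant_log: ImplantLog,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, str]], OrthologyMap, ImplantLog]:
    """Per-species substituted copies of the reference regions.

    Each base substitutes with probability ``bg_substitution_rate`` outside
    logged sites and ``site_substitution_rate`` inside them, uniformly over
    the three alternatives (no indels, so orthology is positional).  With
    ``spec.dropout`` > 0, ortholog cells go missing at that rate.  The
    returned log gains one entry per site per non-reference species.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    base_arr = np.frombuffer("ACGT".encode(), dtype="S1")
    code = {b: i for i, b in enumerate("ACGT")}
    site_mask: dict[str, np.ndarray] = {}
    for e in implant_log.reference_sites():
        mask = site_mask.setdefault(
            e["region_id"], np.zeros(spec.region_length_bp, dtype=bool)
        )
        mask[e["offset"] : e["offset"] + len(e["site_seq"])] = True

    sequences: dict[str, dict[str, str]] = {"ref": dict(reference)}
    mapping: dict[str, dict[str, str]] = {
        rid: {"ref": rid} for rid in reference
    }
    full_log = ImplantLog(
        entries=list(implant_log.entries), target_genes=list(implant_log.target_genes)
    )
    region_sets: dict[str, list[str]] = {}
    for s in range(1, spec.n_species):
        sid = f"sp{s}"
        species_seqs: dict[str, str] = {}
        for rid in sorted(reference):
            if spec.dropout > 0 and rng.random() < spec.dropout:
                continue
            codes = np.array([code[b] for b in reference[rid]], dtype=np.int8)
            rates = np.full(len(codes), spec.bg_substitution_rate)
            if rid in site_mask:
                rates[site_mask[rid]] = spec.site_substitution_rate
            hit = rng.random(len(codes)) < rates
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()))
                codes[hit] = (codes[hit] + shift) % 4
            seq = base_arr[codes].tobytes().decode()
            orid = f"{rid}@{sid}"
            species_seqs[orid] = seq
            mapping[rid][sid] = orid
            for e in implant_log.sites_for("ref", rid):
                off, w = e["offset"], len(e["site_seq"])
                full_log.entries.append(
                    {**e, "species_id": sid, "region_id": orid,
                     "site_seq": seq[off : off + w]}
                )
        sequences[sid] = species_seqs
        region_sets[sid] = sorted(species_seqs)
    ortho = OrthologyMap(
        reference_species="ref", mapping=mapping, species_ids=spec.species_ids
    )
    return sequences, ortho, full_log


def ablate_sites(sequence: str, sites: list[SiteMatch], pwm: Pwm) -> str:
    """Disrupt predicted sites by mutating the motif's two most informative
    columns to a fixed non-consensus base.

    Column choice: highest information content, ties broken toward the motif
    center then leftmost; each chosen column's consensus base is replaced by
    its transition partner (A<->G, C<->T), mapped through the strand.  For a
    CANNTG-style degenerate E-box model this reproduces the classic
    CANNTG -> CGNNCG disruption.  Overlapping sites are processed
    left-to-right; a site overlapping an already-ablated one is skipped with
    a warning.
    """
    ic = pwm.information_content()
    w = pwm.length
    center = (w - 1) / 2.0
    order = sorted(range(w), key=lambda j: (-ic[j], abs(j - center), j))
    cols = sorted(order[: min(2, w)])
    consensus = pwm.consensus()
    seq = list(sequence)
    ablated: list[tuple[int, int]] = []
    for site in sorted(sites, key=lambda s: s.offset):
        span = (site.offset, site.offset + w)
        if span[1] > len(seq):
            raise ValueError(f"site at {site.offset} exceeds sequence bounds")
        if any(a < span[1] and span[0] < b for a, b in ablated):
            logger.warning("skipping overlapping site at offset %d", site.offset)
            continue
        for j in cols:
            repl = _TRANSITION[consensus[j]]
            if site.strand == "+":
                seq[site.offset + j] = repl
            else:
                seq[site.offset + (w - 1 - j)] = _COMPLEMENT[repl]
        ablated.append(span)
    return "".join(seq)


# ---------------------------------------------------------------------------
# motif library for fixtures


def implant_pwm(motif_id: str = "ebox_implant") -> Pwm:
    """Proneural-style E-box motif RACASCTGY (non-palindromic).

    Six strongly conserved core columns around the CANNTG theme plus three
    two-base degenerate columns (R, S, Y), giving ~11 bits of total
    information -- the shape of real basic-helix-loop-helix matrices.
    Sampled sites typically score 10-13 bits, comfortably above the 6-bit
    site-report threshold, while single-species background hits remain
    competitive enough that cross-species integration genuinely matters.
    """
    columns = {0: "AG", 1: "A", 2: "C", 3: "A", 4: "CG",
               5: "C", 6: "T", 7: "G", 8: "CT"}
    counts = np.full((len(columns), 4), 4.0)
    for j, allowed in columns.items():
        for b in allowed:
            counts[j, BASES.index(b)] = 188.0 if len(allowed) == 1 else 96.0
    return Pwm.from_counts(motif_id, counts)


def ebox_core_pwm(motif_id: str = "ebox_core") -> Pwm:
    """Degenerate proneural E-box model CANNTG (uniform middle columns)."""
    counts = np.full((6, 4), 1.0)
    counts[2] = counts[3] = 25.0  # N columns: flat
    for j, b in [(0, "C"), (1, "A"), (4, "T"), (5, "G")]:
        counts[j] = 1.0
        counts[j, BASES.index(b)] = 97.0
    return Pwm.from_counts(motif_id, counts)


def decoy_pwm(motif_id: str, rng: np.random.Generator, width: int = 8) -> Pwm:
    """Random plausible decoy motif: Dirichlet columns of moderate information."""
    probs = rng.dirichlet([0.7, 0.7, 0.7, 0.7], size=width)
    counts = np.round(probs * 100) + 1
    return Pwm.from_counts(motif_id, counts)


def make_library(
    n_motifs: int = 50,
    seed: int = 0,
    implanted: Pwm | None = None,
    width: int = 8,
) -> MotifLibrary:
    """Fixture library: the implanted motif (if any) plus random decoys."""
    rng = np.random.default_rng(seed + 1000)
    motifs: list[Pwm] = []
    if implanted is not None:
        motifs.append(implanted)
    while len(motifs) < n_motifs:
        motifs.append(decoy_pwm(f"decoy{len(motifs):03d}", rng, width))
    return MotifLibrary(motifs=motifs, library_id=f"synthetic_s{seed}")


# ---------------------------------------------------------------------------
# full bundle


def generate_bundle(
    spec: SyntheticSpec,
    pwm: Pwm | None = None,
    implant: bool = True,
) -> Bundle:
    """Sequences + orthology + ground truth + gene set from one spec."""
    if pwm is None:
        pwm = implant_pwm()
    ss = np.random.SeedSequence(spec.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    reference = sample_genome(spec, rngs[0])
    if implant:
        reference, log = implant_clusters(reference, pwm, spec, rngs[1])
    else:
        log = ImplantLog()
    sequences, orthology, full_log = evolve_orthologs(reference, log, spec, rngs[2])

    region_sets: dict[str, RegionSet] = {}
    region_to_gene: dict[str, str] = {}
    for sid, seqs in sequences.items():
        regions = []
        for orid in sorted(seqs):
            rid = orid.split("@")[0]
            gid = gene_id(int(rid[1:]))
            if sid == "ref":
                region_to_gene[orid] = gid
            regions.append(
                GenomicRegion(
                    region_id=orid,
                    gene_id=gid,
                    species_id=sid,
                    chrom=f"chr_{sid}",
                    start=0,
                    end=len(seqs[orid]),
                    kind="upstream",
                )
            )
        region_sets[sid] = RegionSet(species_id=sid, regions=regions)

    gene_set = make_gene_set(spec, full_log, rngs[3]) if implant else None
    return Bundle(
        spec=spec,
        sequences=sequences,
        region_sets=region_sets,
        orthology=orthology,
        implant_log=full_log,
        gene_set=gene_set,
        region_to_gene=region_to_gene,
    )


def make_gene_set(
    spec: SyntheticSpec, log: ImplantLog, rng: np.random.Generator
) -> GeneSet:
    """Targets diluted with non-targets at the spec's contamination fraction."""
    targets = list(log.target_genes)
    n_contaminants = int(round(len(targets) * spec.contamination / (1 - spec.contamination))) \
        if spec.contamination < 1 else 0
    non_targets = [gene_id(i) for i in range(spec.n_genes) if gene_id(i) not in set(targets)]
    picked = rng.choice(len(non_targets), size=min(n_contaminants, len(non_targets)),
                        replace=False)
    contaminants = [non_targets[i] for i in sorted(picked)]
    return GeneSet(label="synthetic_coexpressed", gene_ids=frozenset(targets + contaminants))


def random_gene_set(
    spec: SyntheticSpec, size: int, rng: np.random.Generator, label: str = "random_set"
) -> GeneSet:
    idx = rng.choice(spec.n_genes, size=size, replace=False)
    return GeneSet(label=label, gene_ids=frozenset(gene_id(i) for i in idx))


# ---------------------------------------------------------------------------
# on-disk bundle (FASTA per species, BED, TSV orthology, gene set, manifest)


def write_bundle(bundle: Bundle, outdir) -> None:
    from .regions import write_bed, write_orthology

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, seqs in bundle.sequences.items():
        with open(outdir / f"{sid}.fa", "w") as fh:
            for orid in sorted(seqs):
                fh.write(f">{orid}\n{seqs[orid]}\n")
        with open(outdir / f"{sid}.bed", "w") as fh:
            fh.write(write_bed(bundle.region_sets[sid]))
    with open(outdir / "orthology.tsv", "w") as fh:
        fh.write(write_orthology(bundle.orthology))
    if bundle.gene_set is not None:
        with open(outdir / "gene_set.txt", "w") as fh:
            fh.write("\n".join(sorted(bundle.gene_set.gene_ids)) + "\n")
    manifest = {
        "spec": asdict(bundle.spec),
        "target_genes": bundle.implant_log.target_genes,
        "implants": bundle.implant_log.entries,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
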