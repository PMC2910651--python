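"""Candidate regulatory regions, orthology maps, and gene sets.

The candidate search space is one fixed-width upstream region per gene plus
(optionally) one region per intron, where introns are the union over all
annotated transcripts with overlapping intervals merged.  Coordinates are
BED-style 0-based half-open throughout; GFF3 input (1-based closed) is
converted on read.

Cross-species orthology is an input here: a TSV with the reference region id
in the first column and one column per species giving the orthologous region
id in that species (blank = no ortholog).
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field

import gffutils

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicRegion:
    """A candidate region tied to exactly one gene of one species."""

    region_id: str
    gene_id: str
    species_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    kind: str = "upstream"  # "upstream" | "intron"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"region {self.region_id}: negative start {self.start}")
        if not self.start < self.end:
            raise ValueError(
                f"region {self.region_id}: start must be < end ({self.start}, {self.end})"
            )
        if self.kind not in ("upstream", "intron"):
            raise ValueError(f"region kind must be 'upstream' or 'intron', got {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """Regions of one species, unique by region_id."""

    species_id: str
    regions: list[GenomicRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate region ids in species {self.species_id}: {dupes}")
        self._by_id = {r.region_id: r for r in self.regions}

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    def __getitem__(self, region_id: str) -> GenomicRegion:
        return self._by_id[region_id]

    def region_to_gene(self) -> dict[str, str]:
        return {r.region_id: r.gene_id for r in self.regions}


@dataclass
class OrthologyMap:
    """reference region_id -> {species_id -> orthologous region_id}.

    Absent entries mean "no ortholog found"; the reference species always maps
    every region to itself.
    """

    reference_species: str
    mapping: dict[str, dict[str, str]]
    species_ids: list[str]

    def orthologs(self, region_id: str) -> dict[str, str]:
        return self.mapping.get(region_id, {})


@dataclass
class GeneSet:
    label: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"gene set {self.label!r} is empty")
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids


# ---------------------------------------------------------------------------
# interval helpers


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, merged when overlapping or touching."""
    if not intervals:
        return []
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# region construction from annotation


def build_regions(
    annotation: str,
    upstream_bp: int = 5000,
    include_introns: bool = True,
    species_id: str = "ref",
    chrom_sizes: dict[str, int] | None = None,
) -> RegionSet:
    """Build candidate regions from GFF3 annotation text or a file path.

    One strand-aware upstream region of exactly ``upstream_bp`` per gene
    (clipped at chromosome bounds when ``chrom_sizes`` is given), plus one
    region per merged intron (union across transcripts) when requested.
    Genes without any transcript are skipped with a warning.
    """
    if upstream_bp < 1:
        raise ValueError("upstream_bp must be positive")
    from_string = "\n" in annotation or "\t" in annotation
    db = gffutils.create_db(
        annotation,
        dbfn=":memory:",
        from_string=from_string,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    regions: list[GenomicRegion] = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = list(db.children(gene, level=1))
        transcripts = [t for t in transcripts if t.featuretype not in ("exon", "CDS")]
        if not transcripts:
            logger.warning("gene %s has no transcript; skipped", gene.id)
            continue
        g_start, g_end = gene.start - 1, gene.end  # to 0-based half-open
        if gene.strand == "-":
            up_start, up_end = g_end, g_end + upstream_bp
        else:
            up_start, up_end = g_start - upstream_bp, g_start
        up_start = max(up_start, 0)
        if chrom_sizes is not None and gene.seqid in chrom_sizes:
            up_end = min(up_end, chrom_sizes[gene.seqid])
        if up_start < up_end:
            regions.append(
                GenomicRegion(
                    region_id=f"{gene.id}:up",
                    gene_id=gene.id,
                    species_id=species_id,
                    chrom=gene.seqid,
                    start=up_start,
                    end=up_end,
                    kind="upstream",
                )
            )
        if include_introns:
            intron_intervals: list[tuple[int, int]] = []
            for tr in transcripts:
                exons = sorted(
                    (e.start - 1, e.end) for e in db.children(tr, featuretype="exon")
                )
                for (_s, prev_end), (nxt_start, _e) in zip(exons, exons[1:]):
                    if nxt_start > prev_end:
                        intron_intervals.append((prev_end, nxt_start))
            for i, (s, e) in enumerate(merge_intervals(intron_intervals)):
                regions.append(
                    GenomicRegion(
                        region_id=f"{gene.id}:int{i}",
                        gene_id=gene.id,
                        species_id=species_id,
                        chrom=gene.seqid,
                        start=s,
                        end=e,
                        kind="intron",
                    )
                )
    return RegionSet(species_id=species_id, regions=regions)


# ---------------------------------------------------------------------------
# orthology


def load_orthology(
    table: str,
    region_sets: dict[str, RegionSet],
    reference_species: str | None = None,
) -> OrthologyMap:
    """Load a TSV orthology table and validate region ids against the given
    per-species region sets.

    First column: reference region id; header names the species columns.
    Empty cells are recorded as missing.  Any orthologous id absent from its
    species' region set is an error (rows listed).
    """
    handle = io.StringIO(table)
    reader = csv.reader(handle, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise ValueError("empty orthology table") from None
    ref_col, species_cols = header[0], header[1:]
    if reference_species is None:
        reference_species = ref_col
    unknown = [s for s in species_cols if s not in region_sets]
    if unknown:
        raise ValueError(f"orthology table names unknown species: {unknown}")
    ref_set = region_sets.get(reference_species)
    mapping: dict[str, dict[str, str]] = {}
    bad_rows: list[str] = []
    for row in reader:
        if not row or not row[0].strip():
            continue
        ref_id = row[0].strip()
        if ref_set is not None and ref_id not in ref_set:
            bad_rows.append(f"{ref_id}: unknown reference region")
            continue
        entry: dict[str, str] = {reference_species: ref_id}
        for species, cell in zip(species_cols, row[1:]):
            cell = cell.strip()
            if not cell:
                continue
            if cell not in region_sets[species]:
                bad_rows.append(f"{ref_id}: {cell!r} not in species {species}")
                continue
            entry[species] = cell
        mapping[ref_id] = entry
    if bad_rows:
        raise ValueError("orthology table references unknown regions:\n" + "\n".join(bad_rows))
    all_species = [reference_species] + [s for s in species_cols if s != reference_species]
    return OrthologyMap(
        reference_species=reference_species, mapping=mapping, species_ids=all_species
    )


def write_orthology(orthology: OrthologyMap) -> str:
    out = io.StringIO()
    others = [s for s in orthology.species_ids if s != orthology.reference_species]
    out.write("\t".join([orthology.reference_species] + others) + "\n")
    for ref_id in sorted(orthology.mapping):
        entry = orthology.mapping[ref_id]
        out.write("\t".join([ref_id] + [entry.get(s, "") for s in others]) + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# gene sets


def read_gene_set(lines: str, label: str = "gene_set") -> GeneSet:
    """Read a plain-text gene list (one id per line, '#' comments allowed).

    Duplicates are collapsed with a logged count; an input with no usable id
    is an error.
    """
    ids: list[str] = []
    for line in lines.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ids.append(line.split()[0])
    if not ids:
        raise ValueError(f"gene set {label!r}: no gene ids found")
    unique = set(ids)
    n_dup = len(ids) - len(unique)
    if n_dup:
        logger.warning("gene set %s: collapsed %d duplicate ids", label, n_dup)
    return GeneSet(label=label, gene_ids=frozenset(unique))


# ---------------------------------------------------------------------------
# BED io (BED6 + optional gene_id column 7)


def write_bed(regions: RegionSet) -> str:
    out = io.StringIO()
    for r in regions:
        out.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t0\t+\t{r.gene_id}\t{r.kind}\n")
    return out.getvalue()


def read_bed(text: str, species_id: str) -> RegionSet:
    regions = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"BED line {lineno}: need at least 4 columns")
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        gene_id = fields[6] if len(fields) > 6 else name
        kind = fields[7] if len(fields) > 7 else "upstream"
        regions.append(
            GenomicRegion(
                region_id=name,
                gene_id=gene_id,
                species_id=species_id,
                chrom=chrom,
                start=start,
                end=end,
                kind=kind,
            )
        )
    return RegionSet(species_id=species_id, regions=regions)
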