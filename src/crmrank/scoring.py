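"""Homotypic / heterotypic motif-cluster scoring of candidate regions.

Site scores are log2-odds of the PWM against a 0-order background model.  A
region's cluster score is the best-scoring subsequence under an additive
model: the sum of a non-overlapping selection of positive-scoring sites (any
motif of the model, either strand) minus a linear gap penalty for every
non-site base inside the chosen window, floored at 0.  This rewards dense
homotypic site clusters while a single strong site is never penalized
(its window contains no gaps).

Two implementations are provided: a per-region dynamic program with full
traceback (:func:`cluster_score`, reporting the best window and the sites
used) and a numba batch kernel (:func:`cluster_scores_batch`) for scoring a
whole species' region set against a motif.  They compute the same quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .pwm import Pwm

DEFAULT_SITE_THRESHOLD_BITS = 6.0  # site-report threshold
DEFAULT_GAP_PENALTY = 0.1  # bits per non-site base inside a cluster window
BACKGROUND_FLOOR = 1e-4

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode_sequence(sequence: str) -> np.ndarray:
    """int8 codes: A=0 C=1 G=2 T=3; any other character (incl. N) = 4.

    Soft-masked (lowercase) bases are scored normally.
    """
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class BackgroundModel:
    """0-order, strand-symmetric base frequencies for A, C, G, T."""

    base_frequencies: np.ndarray
    scope: str = "global"

    def __post_init__(self) -> None:
        f = np.asarray(self.base_frequencies, dtype=float)
        if f.shape != (4,):
            raise ValueError("base_frequencies must have 4 entries")
        f = np.maximum(f, BACKGROUND_FLOOR)
        self.base_frequencies = f / f.sum()

    @classmethod
    def uniform(cls, scope: str = "global") -> "BackgroundModel":
        return cls(base_frequencies=np.full(4, 0.25), scope=scope)


def estimate_background(sequences, scope: str = "global") -> BackgroundModel:
    """Estimate strand-symmetrized 0-order frequencies from sequences.

    Both strands are counted (so freq(A) = freq(T) and freq(C) = freq(G)),
    frequencies are floored at 1e-4 and renormalized.  Sequences with no
    usable A/C/G/T base raise an error.
    """
    counts = np.zeros(4)
    for seq in sequences:
        codes = encode_sequence(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("no usable A/C/G/T bases in input sequences")
    sym = counts + counts[::-1]  # add reverse-complement counts (A<->T, C<->G)
    return BackgroundModel(base_frequencies=sym / sym.sum(), scope=scope)


@dataclass(frozen=True)
class SiteMatch:
    region_id: str
    offset: int
    strand: str  # '+' or '-'
    motif_id: str
    score_bits: float

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not math.isfinite(self.score_bits):
            raise ValueError("site score must be finite")


@dataclass
class ClusterModel:
    """Motif(s) plus cluster-scoring parameters.

    ``homotypic`` models carry exactly one PWM.  ``heterotypic_or`` lets all
    motifs compete within one cluster; ``heterotypic_and`` additionally
    requires every motif to contribute a site (enforced by
    :func:`heterotypic_filter`).
    """

    motifs: list[Pwm]
    gap_penalty_bits_per_base: float = DEFAULT_GAP_PENALTY
    site_threshold_bits: float = DEFAULT_SITE_THRESHOLD_BITS
    mode: str = "homotypic"

    def __post_init__(self) -> None:
        if self.mode not in ("homotypic", "heterotypic_and", "heterotypic_or"):
            raise ValueError(f"unknown cluster model mode {self.mode!r}")
        if self.mode == "homotypic" and len(self.motifs) != 1:
            raise ValueError("homotypic model requires exactly one motif")
        if self.mode != "homotypic" and len(self.motifs) < 2:
            raise ValueError("heterotypic model requires at least two motifs")
        if self.gap_penalty_bits_per_base < 0:
            raise ValueError("gap penalty must be nonnegative")

    @property
    def model_id(self) -> str:
        ids = "+".join(m.motif_id for m in self.motifs)
        return ids if self.mode == "homotypic" else f"{ids}[{self.mode}]"


@dataclass
class RegionScore:
    region_id: str
    species_id: str
    model_id: str
    score_bits: float
    best_window: tuple[int, int] | None = None  # half-open offsets, None if score 0
    sites_used: list[SiteMatch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.score_bits < 0:
            raise ValueError("cluster score is floored at 0")


# ---------------------------------------------------------------------------
# site-level scoring


def site_log_odds(pwm: Pwm, bg: BackgroundModel, window: str, strand: str = "+") -> float:
    """Log2-odds of one window; '-' scores the reverse complement.

    Returns -inf for windows containing non-ACGT characters ("no site").
    """
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != motif length {pwm.length}")
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    if strand == "-":
        window = reverse_complement(window)
    codes = encode_sequence(window)
    if (codes > 3).any():
        return float("-inf")
    lodds = pwm.log_odds(bg.base_frequencies)
    return float(lodds[np.arange(pwm.length), codes].sum())


def _strand_score_arrays(pwm: Pwm, bg: BackgroundModel, codes: np.ndarray):
    """(forward, reverse) per-offset site scores for a 1-D code array."""
    lodds = np.ascontiguousarray(pwm.log_odds(bg.base_frequencies))
    lodds_rc = np.ascontiguousarray(pwm.reverse_complement().log_odds(bg.base_frequencies))
    codes2 = codes[None, :]
    fwd = _kernels.site_scores_batch(codes2, lodds, pwm.length)[0]
    rev = _kernels.site_scores_batch(codes2, lodds_rc, pwm.length)[0]
    return fwd, rev


def scan_sites(
    pwm: Pwm,
    bg: BackgroundModel,
    sequence: str,
    threshold_bits: float = DEFAULT_SITE_THRESHOLD_BITS,
    region_id: str = "region",
) -> list[SiteMatch]:
    """All offsets/strands scoring strictly above ``threshold_bits``.

    A sequence shorter than the motif yields an empty list.  A site on the
    minus strand at offset o occupies the same coordinates [o, o+w) as its
    plus-strand counterpart; palindromic sites therefore appear once per
    strand at the same offset.
    """
    if len(sequence) < pwm.length:
        return []
    codes = encode_sequence(sequence)
    fwd, rev = _strand_score_arrays(pwm, bg, codes)
    matches: list[SiteMatch] = []
    for offset in range(len(fwd)):
        if fwd[offset] > threshold_bits:
            matches.append(SiteMatch(region_id, offset, "+", pwm.motif_id, float(fwd[offset])))
        if rev[offset] > threshold_bits:
            matches.append(SiteMatch(region_id, offset, "-", pwm.motif_id, float(rev[offset])))
    return matches


# ---------------------------------------------------------------------------
# cluster scoring


def cluster_score(
    model: ClusterModel,
    bg: BackgroundModel,
    sequence: str,
    region_id: str = "region",
    species_id: str = "ref",
) -> RegionScore:
    """Best additive cluster score with traceback (window + sites used).

    Dynamic program over positions: E[i], the best window ending at base i,
    either extends the previous window with a gap base (cost
    ``gap_penalty``) or appends a positive-scoring site ending at i (opening
    a new window at the site start if that is better).  O(L * n_motifs).
    """
    if not sequence:
        raise ValueError("cannot score an empty sequence")
    codes = encode_sequence(sequence)
    seq_len = len(sequence)
    gap = model.gap_penalty_bits_per_base

    # per-motif best-strand site scores and the strand achieving them
    per_motif: list[tuple[int, np.ndarray, np.ndarray]] = []
    for pwm in model.motifs:
        if seq_len < pwm.length:
            continue
        fwd, rev = _strand_score_arrays(pwm, bg, codes)
        best = np.maximum(fwd, rev)
        strands = np.where(fwd >= rev, 0, 1)
        per_motif.append((pwm.length, best, strands))

    NEG = float("-inf")
    E = np.full(seq_len + 1, NEG)
    # backpointer: (kind, arg); kind 0 = gap from i-1, kind 1 = site (motif_idx, fresh)
    back: list[tuple[int, int, bool] | None] = [None] * (seq_len + 1)
    best_score, best_end = 0.0, -1
    for i in range(1, seq_len + 1):
        e = E[i - 1] - gap
        choice: tuple[int, int, bool] | None = (0, 0, False) if e > NEG else None
        for m_idx, (width, scores, _strands) in enumerate(per_motif):
            if i < width:
                continue
            o = i - width
            s = scores[o]
            if s <= 0.0:
                continue
            fresh = not (E[o] > 0.0)
            cand = s + (0.0 if fresh else E[o])
            if cand > e:
                e, choice = cand, (1, m_idx, fresh)
        E[i] = e
        back[i] = choice
        if e > best_score:
            best_score, best_end = e, i

    if best_end < 0:  # no positive-scoring selection: floor at 0
        return RegionScore(region_id, species_id, model.model_id, 0.0)

    sites: list[SiteMatch] = []
    i = best_end
    window_start = best_end
    while i > 0:
        kind, arg, fresh = back[i]  # type: ignore[misc]
        if kind == 0:
            i -= 1
            continue
        width, scores, strands = per_motif[arg]
        o = i - width
        strand = "+" if strands[o] == 0 else "-"
        sites.append(
            SiteMatch(region_id, o, strand, model.motifs[arg].motif_id, float(scores[o]))
        )
        window_start = o
        if fresh:
            break
        i = o
    sites.reverse()
    return RegionScore(
        region_id=region_id,
        species_id=species_id,
        model_id=model.model_id,
        score_bits=float(best_score),
        best_window=(window_start, best_end),
        sites_used=sites,
    )


def cluster_scores_batch(
    model: ClusterModel,
    bg: BackgroundModel,
    sequences: np.ndarray | list[str],
) -> np.ndarray:
    """Cluster scores for a batch of equal-length sequences (numba kernel).

    ``sequences`` may be a pre-encoded int8 matrix or a list of strings
    (ragged lists are right-padded with the non-base code, which cannot
    change any score).
    """
    if isinstance(sequences, np.ndarray):
        codes = np.ascontiguousarray(sequences, dtype=np.int8)
    else:
        max_len = max(len(s) for s in sequences)
        codes = np.full((len(sequences), max_len), 4, dtype=np.int8)
        for i, s in enumerate(sequences):
            codes[i, : len(s)] = encode_sequence(s)
    widths = np.array([m.length for m in model.motifs], dtype=np.int64)
    w_max = int(widths.max())
    lodds_f = np.zeros((len(model.motifs), w_max, 4))
    lodds_r = np.zeros_like(lodds_f)
    for m_idx, pwm in enumerate(model.motifs):
        lodds_f[m_idx, : pwm.length] = pwm.log_odds(bg.base_frequencies)
        lodds_r[m_idx, : pwm.length] = pwm.reverse_complement().log_odds(bg.base_frequencies)
    return _kernels.cluster_scores_batch(
        codes, lodds_f, lodds_r, widths, float(model.gap_penalty_bits_per_base)
    )


def sites_to_gff3(
    sites: list[SiteMatch],
    motif_lengths: dict[str, int],
    source: str = "crmrank",
) -> str:
    """One GFF3 feature (1-based closed coordinates) per site match; the
    score column carries the bits."""
    lines = ["##gff-version 3"]
    for s in sites:
        end = s.offset + motif_lengths[s.motif_id]
        lines.append(
            "\t".join(
                [
                    s.region_id, source, "TF_binding_site",
                    str(s.offset + 1), str(end), f"{s.score_bits:.4f}",
                    s.strand, ".", f"Name={s.motif_id}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def region_scores_to_tsv(scores: list[RegionScore]) -> str:
    """Region score table: region, species, model, score, best window."""
    lines = ["region_id\tspecies_id\tmodel_id\tscore_bits\twindow_start\twindow_end"]
    for rs in scores:
        lo, hi = rs.best_window if rs.best_window is not None else ("", "")
        lines.append(
            f"{rs.region_id}\t{rs.species_id}\t{rs.model_id}\t{rs.score_bits:.4f}\t{lo}\t{hi}"
        )
    return "\n".join(lines) + "\n"


def heterotypic_filter(scores: list[RegionScore], model: ClusterModel) -> list[RegionScore]:
    """AND semantics: zero out regions whose cluster lacks any model motif.

    OR models pass through unchanged (all motifs already compete inside
    :func:`cluster_score`).
    """
    if model.mode == "homotypic":
        raise ValueError("heterotypic_filter requires a heterotypic model")
    if model.mode == "heterotypic_or":
        return list(scores)
    required = {m.motif_id for m in model.motifs}
    out = []
    for rs in scores:
        used = {s.motif_id for s in rs.sites_used}
        if required <= used:
            out.append(rs)
        else:
            out.append(
                RegionScore(rs.region_id, rs.species_id, rs.model_id, 0.0)
            )
    return out
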