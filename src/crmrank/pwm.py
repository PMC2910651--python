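"""Position weight matrices and motif libraries.

A PWM models a transcription-factor binding site as independent per-position
base probabilities over A, C, G, T.  Matrices are usually distributed as count
matrices; probabilities are derived with Laplace-style smoothing,

    p[j, b] = (count[j, b] + pseudocount) / (sum_b count[j, b] + 4 * pseudocount)

so that every probability is strictly positive and log-odds scores stay finite.

Three common text dialects are supported:

* ``jaspar``          -- ``>ID name`` header, one row per base: ``A [ 3 5 ... ]``
* ``transfac``        -- ``ID``/``P0`` header, numbered rows of A C G T counts
* ``clusterbuster``   -- ``>name`` header, one row of 4 counts per position
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_IDX = np.array([3, 2, 1, 0])

DEFAULT_PSEUDOCOUNT = 0.5


class PwmParseError(ValueError):
    """Raised when a motif text block cannot be parsed."""


@dataclass
class Pwm:
    """Per-position base-probability matrix with optional source counts.

    Parameters
    ----------
    motif_id : str
        Identifier taken from the source header.
    probs : ndarray, shape (length, 4)
        Base probabilities; each row sums to 1 and is strictly positive.
    counts : ndarray or None
        Source count matrix, if the motif came from counts.
    pseudocount : float
        Per-cell pseudocount used to derive ``probs`` from ``counts``.
    """

    motif_id: str
    probs: np.ndarray
    counts: np.ndarray | None = None
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must have shape (length, 4)")
        if self.probs.shape[0] < 1:
            raise ValueError("zero-length motif")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each probability row must sum to 1")
        if not (self.probs > 0).all():
            raise ValueError("all probabilities must be > 0 (use a pseudocount)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)
            if self.counts.shape != self.probs.shape:
                raise ValueError("counts shape must match probs shape")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must have shape (length, 4)")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        totals = counts.sum(axis=1, keepdims=True)
        probs = (counts + pseudocount) / (totals + 4.0 * pseudocount)
        return cls(motif_id=motif_id, probs=probs, counts=counts, pseudocount=pseudocount)

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        """Log2-odds matrix against per-base background frequencies."""
        bg = np.asarray(background, dtype=float)
        return np.log2(self.probs / bg[None, :])

    def information_content(self) -> np.ndarray:
        """Per-column Kullback-Leibler information (bits) vs uniform background."""
        return (self.probs * np.log2(self.probs * 4.0)).sum(axis=1)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        probs = self.probs[::-1, _COMPLEMENT_IDX]
        counts = None if self.counts is None else self.counts[::-1, _COMPLEMENT_IDX]
        return Pwm(
            motif_id=self.motif_id + "_rc",
            probs=probs.copy(),
            counts=None if counts is None else counts.copy(),
            pseudocount=self.pseudocount,
        )


@dataclass
class MotifLibrary:
    """Ordered, uniquely-identified collection of PWMs.

    When one library motif is the query, the remaining motifs serve as the
    control set for enrichment z-scores.
    """

    motifs: list[Pwm] = field(default_factory=list)
    library_id: str = "library"

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("motif library must be non-empty")
        ids = [m.motif_id for m in self.motifs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate motif ids in library: {dupes}")
        self._by_id = {m.motif_id: m for m in self.motifs}

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __getitem__(self, motif_id: str) -> Pwm:
        return self._by_id[motif_id]

    def __contains__(self, motif_id: str) -> bool:
        return motif_id in self._by_id

    @property
    def motif_ids(self) -> list[str]:
        return [m.motif_id for m in self.motifs]


# ---------------------------------------------------------------------------
# parsing


def _parse_float_fields(fields: list[str], lineno: int) -> list[float]:
    try:
        return [float(f) for f in fields]
    except ValueError as exc:
        raise PwmParseError(f"malformed matrix row at line {lineno}: {fields!r}") from exc


def _parse_clusterbuster(text: str, pseudocount: float) -> Pwm:
    lines = text.strip().splitlines()
    if not lines or not lines[0].startswith(">"):
        raise PwmParseError("cluster-buster block must start with '>'")
    motif_id = lines[0][1:].split()[0] if lines[0][1:].split() else ""
    if not motif_id:
        raise PwmParseError("empty motif id in header")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise PwmParseError(
                f"malformed matrix row at line {lineno}: expected 4 fields, got {len(fields)}"
            )
        rows.append(_parse_float_fields(fields, lineno))
    if not rows:
        raise PwmParseError(f"zero-length motif {motif_id!r}")
    return Pwm.from_counts(motif_id, np.array(rows), pseudocount)


_JASPAR_ROW = re.compile(r"^\s*([ACGTacgt])\s*\[?\s*([^\]]*?)\s*\]?\s*$")


def _parse_jaspar(text: str, pseudocount: float) -> Pwm:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise PwmParseError("jaspar block must start with '>'")
    header = lines[0][1:].split()
    if not header:
        raise PwmParseError("empty motif id in header")
    motif_id = header[0]
    per_base: dict[str, list[float]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        m = _JASPAR_ROW.match(line)
        if m is None:
            raise PwmParseError(f"malformed jaspar row at line {lineno}: {line!r}")
        base = m.group(1).upper()
        per_base[base] = _parse_float_fields(m.group(2).split(), lineno)
    if set(per_base) != set(BASES):
        raise PwmParseError(f"jaspar block must have one row per base, got {sorted(per_base)}")
    lengths = {len(v) for v in per_base.values()}
    if len(lengths) != 1:
        raise PwmParseError("jaspar base rows have unequal lengths")
    if lengths == {0}:
        raise PwmParseError(f"zero-length motif {motif_id!r}")
    counts = np.array([per_base[b] for b in BASES]).T  # -> (length, 4)
    return Pwm.from_counts(motif_id, counts, pseudocount)


def _parse_transfac(text: str, pseudocount: float) -> Pwm:
    lines = text.strip().splitlines()
    motif_id = None
    rows = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip()
        if not line or line.startswith(("XX", "//", "CC", "BF")):
            continue
        tag = line.split(None, 1)[0]
        if tag in ("ID", "AC", "NA") and motif_id is None:
            parts = line.split()
            if len(parts) > 1:
                motif_id = parts[1]
            continue
        if tag == "P0" or tag == "PO":
            continue  # column header row
        if re.fullmatch(r"\d+", tag):
            fields = line.split()[1:]
            if fields and not re.fullmatch(r"[\d.eE+-]+", fields[-1]):
                fields = fields[:-1]  # trailing consensus letter
            if len(fields) != 4:
                raise PwmParseError(
                    f"malformed matrix row at line {lineno}: expected 4 counts, got {len(fields)}"
                )
            rows.append(_parse_float_fields(fields, lineno))
    if motif_id is None:
        raise PwmParseError("transfac block lacks an ID/AC/NA line")
    if not rows:
        raise PwmParseError(f"zero-length motif {motif_id!r}")
    return Pwm.from_counts(motif_id, np.array(rows), pseudocount)


_DIALECTS = {
    "transfac": _parse_transfac,
    "jaspar": _parse_jaspar,
    "clusterbuster": _parse_clusterbuster,
}


def parse_pwm(
    text_block: str,
    dialect: str = "clusterbuster",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> Pwm:
    """Parse a single motif text block in the given dialect."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown PWM dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    return _DIALECTS[dialect](text_block, pseudocount)


def parse_library(
    text: str,
    dialect: str = "clusterbuster",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    library_id: str = "library",
) -> MotifLibrary:
    """Parse a multi-motif file into a :class:`MotifLibrary`.

    ``>``-header dialects are split on header lines; transfac on ``//``.
    """
    if dialect == "transfac":
        blocks = [b for b in text.split("//") if b.strip()]
    else:
        blocks = []
        current: list[str] = []
        for line in text.splitlines():
            if line.startswith(">"):
                if current:
                    blocks.append("\n".join(current))
                current = [line]
            elif current:
                current.append(line)
        if current:
            blocks.append("\n".join(current))
    motifs = [parse_pwm(b, dialect, pseudocount) for b in blocks]
    return MotifLibrary(motifs=motifs, library_id=library_id)


def write_pwm(pwm: Pwm, dialect: str = "jaspar") -> str:
    """Serialize a PWM.  Counts are written when available, else probabilities
    (which re-parse to the same probs for pseudocount 0)."""
    mat = pwm.counts if pwm.counts is not None else pwm.probs
    out = io.StringIO()
    if dialect == "jaspar":
        out.write(f">{pwm.motif_id}\n")
        for bi, base in enumerate(BASES):
            vals = " ".join(repr(float(v)) for v in mat[:, bi])
            out.write(f"{base} [ {vals} ]\n")
    elif dialect == "clusterbuster":
        out.write(f">{pwm.motif_id}\n")
        for row in mat:
            out.write(" ".join(repr(float(v)) for v in row) + "\n")
    elif dialect == "transfac":
        out.write(f"ID {pwm.motif_id}\nP0 A C G T\n")
        for j, row in enumerate(mat, start=1):
            out.write(f"{j:02d} " + " ".join(repr(float(v)) for v in row) + "\n")
        out.write("//\n")
    else:
        raise ValueError(f"unknown PWM dialect {dialect!r}")
    return out.getvalue()


def roundtrip_pseudocount(pwm: Pwm) -> float:
    """Pseudocount to use when re-parsing the output of :func:`write_pwm`."""
    return pwm.pseudocount if pwm.counts is not None else 0.0


def _is_palindromic(pwm: Pwm, tol: float = 1e-9) -> bool:
    return bool(np.allclose(pwm.probs, pwm.reverse_complement().probs, atol=tol))
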