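"""Degenerate-consensus motif scanning for the WRI1-binding AW-box.

The AW-box is the binding site of the WRINKLED1 (WRI1) AP2 transcription
factor upstream of fatty-acid synthesis genes; its consensus is the 14-nt
degenerate pattern [CnTnG](N)7[CG], written here in IUPAC codes as
``CNTNGNNNNNNNCG``.  Sequences are scanned on both strands by default; all
overlapping occurrences are reported.  Coordinates are 0-based half-open on
the forward strand (BED convention); minus-strand hits are reported in
forward coordinates with the matched text reverse-complemented so it reads
in motif orientation.

An ``N`` in a *sequence* is treated as an unknown base: it matches only
pattern positions that are themselves ``N`` (fully degenerate), never a
constrained position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ConfigError

DEFAULT_AW_BOX = "CNTNGNNNNNNNCG"

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """IUPAC-degenerate motif descriptor."""

    iupac: str = DEFAULT_AW_BOX
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ConfigError("motif pattern must be non-empty")
        bad = set(self.iupac.upper()) - set(IUPAC_CODES)
        if bad:
            raise ConfigError(
                f"invalid IUPAC code(s) {sorted(bad)} in pattern {self.iupac!r}"
            )
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)

    def regex(self) -> re.Pattern[str]:
        """Overlap-reporting regex; sequence N only matches pattern N."""
        parts = []
        for ch in self.iupac:
            allowed = IUPAC_CODES[ch] + ("N" if ch == "N" else "")
            parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
        return re.compile("(?=(" + "".join(parts) + "))")


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    start: int   # 0-based, forward-strand coordinates
    end: int     # half-open
    strand: str  # '+' or '-'
    matched_text: str  # motif-oriented (revcomp of the window for '-')


def scan_sequence(
    seq: str, pattern: MotifPattern | None = None, gene_id: str = ""
) -> list[MotifHit]:
    """All overlapping motif occurrences in ``seq``, sorted by start, '+' first."""
    pattern = pattern or MotifPattern()
    seq = seq.upper()
    m = len(pattern)
    rx = pattern.regex()
    hits = [
        MotifHit(gene_id, mo.start(), mo.start() + m, "+", mo.group(1))
        for mo in rx.finditer(seq)
    ]
    if pattern.both_strands:
        rc = reverse_complement(seq)
        L = len(seq)
        for mo in rx.finditer(rc):
            start = L - (mo.start() + m)
            hits.append(MotifHit(gene_id, start, start + m, "-", mo.group(1)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


@dataclass(frozen=True)
class MotifFractionSummary:
    n_with_motif: int
    n_total: int
    fraction: float          # full precision, in [0, 1]
    percent: int             # rounded for reporting


def percent_with_motif(n_with_motif: int, n_total: int) -> MotifFractionSummary:
    """Reporting arithmetic: fraction and nearest-integer percent."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_with_motif <= n_total:
        raise ValueError("n_with_motif outside [0, n_total]")
    frac = n_with_motif / n_total
    return MotifFractionSummary(n_with_motif, n_total, frac, round(100.0 * frac))


def motif_gene_fraction(
    promoters, pattern: MotifPattern | None = None
) -> MotifFractionSummary:
    """Fraction of promoters containing >= 1 motif hit (multiplicity ignored)."""
    pattern = pattern or MotifPattern()
    if len(promoters) == 0:
        raise ValueError("empty promoter set")
    n_with = sum(
        1
        for gene_id, seq in promoters.records.items()
        if scan_sequence(seq, pattern, gene_id)
    )
    return percent_with_motif(n_with, len(promoters))


def hits_to_bed(hits: list[MotifHit], pattern: MotifPattern) -> str:
    """6-column BED text: gene_id, start, end, pattern, score 0, strand."""
    lines = [
        f"{h.gene_id}\t{h.start}\t{h.end}\t{pattern.iupac}\t0\t{h.strand}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")
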