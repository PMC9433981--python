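"""CArG-box scanning in promoter sequences.

MADS-domain transcription factors bind CArG boxes with the consensus
CC(A/T)6-8GG, i.e. three widths (10, 11, 12 nt).  Because W = A/T is its
own complement and the flanks swap CC <-> GG, the reverse complement of a
CArG box is again a CArG box: minus-strand hits land on exactly the same
plus-strand coordinates as plus-strand hits.  The scanner exploits and
verifies that symmetry, and by default collapses the two strands to a
single '+' hit per site.

Every overlapping and nested match is reported: a run of 8 W's contains
anchored width-10/11/12 variants, and each (start, width) combination is
enumerated independently rather than by a single greedy regex pass.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import PromoterRecord

CARG_WIDTHS = (10, 11, 12)

# Lookahead so overlapping anchors are all found; one pattern per width so
# nested widths at the same anchor are all reported.  N never matches.
_CARG_RE = {
    w: re.compile(rf"(?=(CC[AT]{{{w - 4}}}GG))") for w in CARG_WIDTHS
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One CArG-box occurrence, 1-based inclusive coordinates."""

    gene_id: str
    start: int
    end: int
    width: int
    strand: str
    matched_sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.width:
            raise ValueError("inconsistent hit coordinates")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


def _scan_plus(gene_id: str, seq: str) -> list[MotifHit]:
    hits = []
    for w, pat in _CARG_RE.items():
        for m in pat.finditer(seq):
            start = m.start() + 1
            hits.append(
                MotifHit(gene_id, start, start + w - 1, w, "+", m.group(1))
            )
    hits.sort(key=lambda h: (h.start, h.width))
    return hits


def scan_carg(
    record: PromoterRecord,
    both_strands: bool = True,
    collapse: bool = True,
) -> list[MotifHit]:
    """All CArG-box matches in one promoter, sorted by (start, width).

    With ``both_strands`` the minus strand is scanned on the reverse
    complement and hits are mapped back to plus-strand coordinates.  The
    motif's strand symmetry makes the two hit sets coincide; this is
    checked, and with ``collapse`` (default) each site is reported once
    with strand '+'.  Set ``collapse=False`` to mirror a naive two-strand
    count (each site appears once per strand).
    """
    seq = record.sequence
    plus = _scan_plus(record.gene_id, seq)
    if not both_strands:
        return plus
    n = len(seq)
    minus: list[MotifHit] = []
    for h in _scan_plus(record.gene_id, reverse_complement(seq)):
        start = n - h.end + 1
        minus.append(
            MotifHit(record.gene_id, start, start + h.width - 1, h.width,
                     "-", h.matched_sequence)
        )
    minus.sort(key=lambda h: (h.start, h.width))
    plus_sites = [(h.start, h.width) for h in plus]
    minus_sites = [(h.start, h.width) for h in minus]
    if plus_sites != minus_sites:  # pragma: no cover - symmetry is structural
        raise AssertionError(
            f"{record.gene_id}: strand symmetry violated "
            f"({len(plus)} plus vs {len(minus)} minus hits)"
        )
    if collapse:
        return plus
    merged = plus + minus
    merged.sort(key=lambda h: (h.start, h.width, h.strand))
    return merged


def motif_summary(promoters: Sequence[PromoterRecord]) -> pd.DataFrame:
    """Per-gene hit counts and positions; zero-hit genes are included."""
    rows = []
    for p in promoters:
        hits = scan_carg(p)
        rows.append(
            {
                "gene_id": p.gene_id,
                "n_hits": len(hits),
                "positions": ";".join(
                    f"{h.start}-{h.end}" for h in hits
                ),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_hits", "positions"])


def write_hits(hits: Iterable[MotifHit], path: str | Path) -> None:
    """Write hits as a BED-like table with both coordinate conventions.

    Columns: gene_id, bed_start (0-based half-open), bed_end, start
    (1-based inclusive), end, motif, width, strand.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        w.writerow(
            ["gene_id", "bed_start", "bed_end", "start", "end",
             "motif", "width", "strand"]
        )
        for h in hits:
            w.writerow(
                [h.gene_id, h.start - 1, h.end, h.start, h.end,
                 h.matched_sequence, h.width, h.strand]
            )
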