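"""Degenerate-motif scanning of fixed-length upstream promoter sequences.

The motivating pattern is P1BS (``GNATATNC``), the imperfect palindrome bound
by the phosphate-starvation regulator PHR1.  Promoters are stored 5'->3' with
the last base immediately adjacent to the translation start, and hits are
reported as upstream distances: position 1 is the base just 5' of the start
codon, so a hit spanning distances (d_near, d_far) sits d_near bp upstream at
its closest edge.  Because P1BS equals its own reverse complement at the
degenerate level, a forward-strand scan is exhaustive for it.
"""

from __future__ import annotations

import importlib.resources
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "IUPAC",
    "P1BS",
    "MotifHit",
    "MotifSummary",
    "PromoterRecord",
    "compile_iupac",
    "matches",
    "scan_promoter",
    "scan_promoter_set",
    "summarize_hits",
    "load_published_p1bs_hits",
    "read_promoter_fasta",
]

#: IUPAC degenerate nucleotide codes.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: The PHR1 binding sequence.
P1BS = "GNATATNC"


@dataclass(frozen=True)
class PromoterRecord:
    """Upstream sequence of one gene; the last base abuts the translation start."""

    gene: str
    sequence: str
    upstream_length: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.upstream_length is None:
            object.__setattr__(self, "upstream_length", len(self.sequence))
        if self.upstream_length != len(self.sequence):
            raise ValueError(
                f"{self.gene}: sequence length {len(self.sequence)} != "
                f"declared upstream_length {self.upstream_length}")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"{self.gene}: sequence has non-ACGTN letters")


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in upstream-distance coordinates.

    ``d_near`` is the distance (bp) from the translation start of the match
    base closest to it; ``d_far = d_near + len(pattern) - 1``.
    """

    gene: str
    d_near: int
    d_far: int
    matched: str
    pattern: str


@dataclass(frozen=True)
class MotifSummary:
    total_hits: int
    unique_genes: int
    genes_within: int
    within_distance: int
    distinct_patterns: int
    per_pattern: tuple[tuple[str, int], ...] = field(default=())

    @property
    def top_pattern(self) -> tuple[str, int] | None:
        return self.per_pattern[0] if self.per_pattern else None


def compile_iupac(pattern: str) -> list[frozenset[str]]:
    """Translate an IUPAC pattern into position-wise allowed-base sets."""
    if not pattern:
        raise ValueError("empty pattern")
    sets = []
    for ch in pattern:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r} in pattern {pattern!r}")
        sets.append(IUPAC[ch])
    return sets


def matches(window: str, compiled: Sequence[frozenset[str]]) -> bool:
    """Exact degenerate match; an ``N`` in the *sequence* never matches."""
    return len(window) == len(compiled) and all(
        base in allowed for base, allowed in zip(window, compiled))


def scan_promoter(rec: PromoterRecord, pattern: str) -> list[MotifHit]:
    """All forward-strand occurrences of ``pattern``, nearest-first.

    A window starting at 1-based string position ``s`` lies at upstream
    distances ``d_near = L - s - m + 2`` .. ``d_far = L - s + 1`` where ``L``
    is the promoter length and ``m`` the pattern length.
    """
    compiled = compile_iupac(pattern)
    m, L = len(compiled), rec.upstream_length
    if m > L:
        warnings.warn(f"pattern {pattern!r} longer than promoter {rec.gene}")
        return []
    hits = []
    seq = rec.sequence
    for s in range(1, L - m + 2):
        window = seq[s - 1:s - 1 + m]
        if matches(window, compiled):
            hits.append(MotifHit(rec.gene, L - s - m + 2, L - s + 1,
                                 window, pattern))
    hits.sort(key=lambda h: h.d_near)
    return hits


def scan_promoter_set(
    promoters: Iterable[PromoterRecord], pattern: str
) -> list[MotifHit]:
    """Scan many promoters; output ordered by gene id, then distance."""
    recs = list(promoters)
    seen = Counter(r.gene for r in recs)
    dupes = [g for g, c in seen.items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate gene ids: {dupes}")
    hits: list[MotifHit] = []
    for rec in sorted(recs, key=lambda r: r.gene):
        hits.extend(scan_promoter(rec, pattern))
    return hits


def summarize_hits(hits: Sequence[MotifHit], within: int = 1000) -> MotifSummary:
    """Tally a hit list: totals, genes covered, proximal genes, pattern usage.

    Duplicate identical records are counted as distinct hit records (input
    fidelity); the per-pattern table is sorted by count descending, then
    pattern.
    """
    genes = {h.gene for h in hits}
    near_genes = {h.gene for h in hits if h.d_near <= within}
    counts = Counter(h.matched for h in hits)
    per_pattern = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return MotifSummary(
        total_hits=len(hits),
        unique_genes=len(genes),
        genes_within=len(near_genes),
        within_distance=within,
        distinct_patterns=len(counts),
        per_pattern=per_pattern,
    )


# ---------------------------------------------------------------------------
# IO

def load_published_p1bs_hits() -> list[MotifHit]:
    """The published table of P1BS occurrences in the -3000 bp promoters of
    Arabidopsis genes induced by Fe deficiency but repressed by Pi starvation
    (18 records over 12 genes, duplicates preserved as printed)."""
    src = importlib.resources.files("fepi.data") / "p1bs_promoter_hits.tsv"
    with importlib.resources.as_file(src) as path:
        df = pd.read_csv(path, sep="\t")
    return [
        MotifHit(r.gene, int(r.start), int(r.end), r.matched, P1BS)
        for r in df.itertuples()
    ]


def read_promoter_fasta(path) -> list[PromoterRecord]:
    """Read promoters from FASTA; record id = gene id."""
    from Bio import SeqIO

    return [
        PromoterRecord(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Hit list as a start/end table (start = d_near, end = d_far)."""
    return pd.DataFrame(
        [(h.gene, h.d_near, h.d_far, h.matched) for h in hits],
        columns=["gene", "start", "end", "matched"],
    )
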