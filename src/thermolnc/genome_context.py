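"""Strand-aware genomic-context classification of lncRNAs.

Every lncRNA is assigned exactly one of four categories against a
reference annotation, with fixed precedence:

1. ``sense``      — >= 1 bp exonic overlap with a reference exon, same strand
2. ``antisense``  — >= 1 bp exonic overlap with a reference exon, opposite strand
3. ``intronic``   — full genomic span inside a single intron of one transcript
4. ``intergenic`` — otherwise
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .formats_io import TranscriptModel

CATEGORIES = ("intergenic", "antisense", "sense", "intronic")


@dataclass
class LncRNARecord:
    """A classified lncRNA: the model, its category, and the gene evidence."""

    model: TranscriptModel
    category: str
    evidence: str = "none"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if (self.category == "intergenic") != (self.evidence == "none"):
            raise ValidationError("evidence must be 'none' iff intergenic")


class _IntervalSet:
    """Flat interval store supporting vectorised overlap queries."""

    def __init__(self):
        self._starts: list[int] = []
        self._ends: list[int] = []
        self._owners: list[str] = []
        self._a_starts: np.ndarray | None = None

    def add(self, start: int, end: int, owner: str) -> None:
        self._starts.append(start)
        self._ends.append(end)
        self._owners.append(owner)
        self._a_starts = None

    def _freeze(self):
        if self._a_starts is None:
            self._a_starts = np.asarray(self._starts, dtype=np.int64)
            self._a_ends = np.asarray(self._ends, dtype=np.int64)

    def overlapping(self, start: int, end: int) -> list[tuple[int, int, str]]:
        """All stored intervals intersecting [start, end)."""
        if not self._starts:
            return []
        self._freeze()
        hit = np.flatnonzero((self._a_starts < end) & (self._a_ends > start))
        return [(self._starts[i], self._ends[i], self._owners[i]) for i in hit]

    def containing(self, start: int, end: int) -> list[tuple[int, int, str]]:
        """All stored intervals that fully contain [start, end)."""
        if not self._starts:
            return []
        self._freeze()
        hit = np.flatnonzero((self._a_starts <= start) & (self._a_ends >= end))
        return [(self._starts[i], self._ends[i], self._owners[i]) for i in hit]


class GeneIndex:
    """Per-seq_name lookup structures over a reference annotation.

    Holds stranded exon intervals, per-transcript introns (multi-exon
    transcripts only), and strand-agnostic gene spans.
    """

    def __init__(self, reference: list[TranscriptModel]):
        if not reference:
            raise ValidationError("reference annotation is empty")
        self._exons: dict[tuple[str, str], _IntervalSet] = {}
        self._introns: dict[str, _IntervalSet] = {}
        self._spans: dict[str, _IntervalSet] = {}
        for m in reference:
            ex = self._exons.setdefault((m.seq_name, m.strand), _IntervalSet())
            for s, e in m.exons:
                ex.add(s, e, m.gene_id)
            intr = self._introns.setdefault(m.seq_name, _IntervalSet())
            for s, e in m.introns():
                intr.add(s, e, f"{m.gene_id}\t{m.strand}")
            self._spans.setdefault(m.seq_name, _IntervalSet()).add(
                m.start, m.end, m.gene_id)

    def exon_overlaps(self, seq_name: str, strand: str,
                      start: int, end: int) -> list[str]:
        """gene_ids with >= 1 bp exon overlap on the given strand."""
        iv = self._exons.get((seq_name, strand))
        return [] if iv is None else [g for _, _, g in iv.overlapping(start, end)]

    def introns_containing(self, seq_name: str, start: int,
                           end: int) -> list[tuple[str, str]]:
        """(gene_id, strand) pairs owning an intron fully containing [start, end)."""
        iv = self._introns.get(seq_name)
        if iv is None:
            return []
        return [tuple(g.split("\t")) for _, _, g in iv.containing(start, end)]

    def span_overlaps(self, seq_name: str, start: int, end: int) -> list[str]:
        iv = self._spans.get(seq_name)
        return [] if iv is None else [g for _, _, g in iv.overlapping(start, end)]


def build_gene_index(reference: list[TranscriptModel]) -> GeneIndex:
    return GeneIndex(reference)


def classify_lncrna(lnc: TranscriptModel, index: GeneIndex,
                    intronic_strand: str = "any") -> LncRNARecord:
    """Assign one genomic-context category (first matching rule wins)."""
    opposite = "-" if lnc.strand == "+" else "+"
    for s, e in lnc.exons:
        same = index.exon_overlaps(lnc.seq_name, lnc.strand, s, e)
        if same:
            return LncRNARecord(lnc, "sense", same[0])
    for s, e in lnc.exons:
        anti = index.exon_overlaps(lnc.seq_name, opposite, s, e)
        if anti:
            return LncRNARecord(lnc, "antisense", anti[0])
    hosts = index.introns_containing(lnc.seq_name, lnc.start, lnc.end)
    if intronic_strand == "sense":
        hosts = [(g, st) for g, st in hosts if st == lnc.strand]
    if hosts:
        return LncRNARecord(lnc, "intronic", hosts[0][0])
    return LncRNARecord(lnc, "intergenic", "none")


def classify_all(lncs: list[TranscriptModel], index: GeneIndex,
                 intronic_strand: str = "any") -> list[LncRNARecord]:
    return [classify_lncrna(m, index, intronic_strand) for m in lncs]


@dataclass
class CategorySummary:
    counts: dict[str, int]
    total: int
    percentages: dict[str, float]  # two decimals


def category_summary(records: list[LncRNARecord]) -> CategorySummary:
    """Counts and percentages per category (Fig 1C-style table)."""
    counts = {c: 0 for c in CATEGORIES}
    for r in records:
        counts[r.category] += 1
    total = sum(counts.values())
    if total == 0:
        warnings.warn("category_summary on empty input; percentages set to 0")
        pct = {c: 0.0 for c in CATEGORIES}
    else:
        pct = {c: round(100.0 * n / total, 2) for c, n in counts.items()}
    return CategorySummary(counts=counts, total=total, percentages=pct)
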