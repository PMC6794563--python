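"""Plain-text I/O for the formats every pipeline stage touches.

Dialects are fixed and validated strictly:

* FASTA — headers start with ``>``, sequences are case-folded to upper,
  wrapped at 60 columns on write.
* GTF 2.2 — 1-based inclusive coordinates on disk; internally every
  interval is 0-based half-open.  Only ``exon`` and ``CDS`` features are
  interpreted; unknown attributes are preserved verbatim for lossless
  round-trips.
* TSV — tab-separated with a header row, UTF-8, Unix newlines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (DNA by default)."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValidationError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


Interval = tuple[int, int]


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript on a named sequence.

    ``exons`` are 0-based half-open intervals, sorted ascending by genomic
    start regardless of strand; strand is applied when the spliced sequence
    is extracted.  ``cds`` intervals, when present, must each be contained
    in an exon.
    """

    transcript_id: str
    gene_id: str
    seq_name: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] | None = None
    biotype: str = "assembled"
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if self.cds is not None:
            self.cds = tuple((int(s), int(e)) for s, e in self.cds)
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id!r}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id!r}: no exons")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(
                    f"transcript {self.transcript_id!r}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id!r}: exons overlap or unsorted")
            prev_end = e
        if self.cds:
            for cs, ce in self.cds:
                if not any(cs >= s and ce <= e for s, e in self.exons):
                    raise ValidationError(
                        f"transcript {self.transcript_id!r}: CDS [{cs},{ce}) "
                        "not contained in any exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        """Genomic span [first exon start, last exon end)."""
        return (self.start, self.end)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> tuple[Interval, ...]:
        """Gaps between consecutive exons (empty for single-exon models)."""
        return tuple((self.exons[i][1], self.exons[i + 1][0])
                     for i in range(len(self.exons) - 1))


@dataclass
class ExpressionMatrix:
    """Per-transcript fragment counts over named samples in two conditions."""

    transcript_ids: list[str]
    sample_ids: list[str]
    condition_of: dict[str, str]
    counts: np.ndarray  # shape (n_transcripts, n_samples), non-negative ints
    library_size: np.ndarray  # per sample, >= column sums

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.library_size = np.asarray(self.library_size)
        n_t, n_s = self.counts.shape
        if n_t != len(self.transcript_ids) or n_s != len(self.sample_ids):
            raise ValidationError("counts table is not rectangular w.r.t. labels")
        if len(set(self.transcript_ids)) != n_t:
            raise ValidationError("duplicate transcript ids in expression matrix")
        if (self.counts < 0).any():
            raise ValidationError("negative count in expression matrix")
        if self.library_size.shape != (n_s,):
            raise ValidationError("library_size must have one entry per sample")
        colsum = self.counts.sum(axis=0)
        if (self.library_size < colsum).any():
            raise ValidationError("library_size smaller than column sum")
        if (self.library_size <= 0).any():
            raise ValidationError("library_size must be positive")
        conds = {self.condition_of.get(s) for s in self.sample_ids}
        if None in conds:
            raise ValidationError("every sample needs a condition")
        if len(conds) < 1:
            raise ValidationError("at least one condition required")
        self._row_of = {t: i for i, t in enumerate(self.transcript_ids)}

    def row(self, transcript_id: str) -> np.ndarray:
        return self.counts[self._row_of[transcript_id]]

    def samples_in(self, condition: str) -> list[int]:
        """Column indices belonging to one condition."""
        return [j for j, s in enumerate(self.sample_ids)
                if self.condition_of[s] == condition]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return seen


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    """DNA → RNA view (T→U)."""
    return seq.replace("T", "U")


def spliced_sequence(model: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Sense-strand spliced DNA sequence of a transcript (5'→3')."""
    chrom = genome[model.seq_name]
    seq = "".join(chrom[s:e] for s, e in model.exons)
    if model.strand == "-":
        seq = reverse_complement(seq)
    return seq


def spliced_rna(model: TranscriptModel, genome: Mapping[str, str]) -> str:
    return to_rna(spliced_sequence(model, genome))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, alphabet: frozenset = DNA_ALPHABET) -> list[SequenceRecord]:
    """Read a FASTA file with strict validation.

    Duplicate ids and out-of-alphabet characters are rejected with the
    offending line number.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_parts: list[str] = []
    header_line = 0

    def flush(line_no: int):
        if cur_id is None:
            return
        seq = "".join(cur_parts)
        if not seq:
            raise FormatError(f"record {cur_id!r} has no sequence",
                              str(path), header_line)
        records.append(SequenceRecord(cur_id, seq))

    with open(path, encoding="utf-8") as fh:
        any_line = False
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            any_line = True
            if line.startswith(">"):
                flush(line_no)
                cur_id = line[1:].split()[0] if line[1:].strip() else ""
                if not cur_id:
                    raise FormatError("empty FASTA header", str(path), line_no)
                if cur_id in seen:
                    raise FormatError(f"duplicate id {cur_id!r}", str(path), line_no)
                seen.add(cur_id)
                cur_parts = []
                header_line = line_no
            else:
                if cur_id is None:
                    raise FormatError("sequence before first header",
                                      str(path), line_no)
                chunk = line.upper()
                bad = set(chunk) - alphabet
                if bad:
                    raise FormatError(
                        f"illegal character(s) {sorted(bad)} in sequence",
                        str(path), line_no)
                cur_parts.append(chunk)
        if not any_line:
            raise FormatError("empty FASTA file", str(path), 1)
        flush(line_no)
    if not records:
        raise FormatError("no records in FASTA file", str(path), 1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;?')


def _parse_attributes(text: str, path: str, line_no: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(text))
    if not attrs:
        raise FormatError("unparseable attribute column", path, line_no)
    return attrs


def read_gtf(path, coding_only: bool = False) -> list[TranscriptModel]:
    """Read exon/CDS features from a GTF 2.2 file into transcript models.

    GTF [start, end] (1-based inclusive) becomes internal [start-1, end).
    Transcripts keep their file order of first appearance.
    """
    exons: dict[str, list[Interval]] = {}
    cdss: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str, dict]] = {}
    order: list[str] = []
    spath = str(path)

    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"expected 9 tab-separated columns, got "
                                  f"{len(fields)}", spath, line_no)
            seq_name, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError("non-integer coordinate", spath, line_no) from None
            if end < start:
                raise FormatError("zero-length or inverted feature", spath, line_no)
            if strand not in ("+", "-"):
                raise FormatError(f"bad strand {strand!r}", spath, line_no)
            attrs = _parse_attributes(attr_s, spath, line_no)
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id")
            if not tid:
                raise FormatError("missing transcript_id attribute", spath, line_no)
            if not gid:
                raise FormatError("missing gene_id attribute", spath, line_no)
            iv = (start - 1, end)  # 1-based inclusive -> 0-based half-open
            extra = {k: v for k, v in attrs.items()
                     if k not in ("gene_id", "transcript_id")}
            if tid not in meta:
                meta[tid] = (gid, seq_name, strand, extra)
                order.append(tid)
            else:
                pg, ps, pstr, pextra = meta[tid]
                if ps != seq_name:
                    raise FormatError(f"transcript {tid!r} on mixed seq_names",
                                      spath, line_no)
                if pstr != strand:
                    raise FormatError(f"transcript {tid!r} on mixed strands",
                                      spath, line_no)
                pextra.update(extra)
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:
                cdss.setdefault(tid, []).append(iv)

    models = []
    for tid in order:
        gid, seq_name, strand, extra = meta[tid]
        ex = sorted(exons.get(tid, []))
        if not ex:
            raise FormatError(f"transcript {tid!r} has CDS but no exon rows", spath)
        cds = tuple(sorted(cdss[tid])) if tid in cdss else None
        if coding_only and cds is None:
            continue
        models.append(TranscriptModel(
            transcript_id=tid, gene_id=gid, seq_name=seq_name, strand=strand,
            exons=tuple(ex), cds=cds,
            biotype="coding" if cds else "assembled",
            attributes=extra))
    return models


def write_gtf(models: Iterable[TranscriptModel], path, source: str = "thermolnc") -> None:
    """Write transcript models as exon (and CDS) rows, GTF 2.2 dialect."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in models:
            extra = "".join(f' {k} "{v}";' for k, v in sorted(m.attributes.items()))
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";' + extra
            for s, e in m.exons:
                fh.write("\t".join([m.seq_name, source, "exon", str(s + 1), str(e),
                                    ".", m.strand, ".", attrs]) + "\n")
            if m.cds:
                for s, e in m.cds:
                    fh.write("\t".join([m.seq_name, source, "CDS", str(s + 1), str(e),
                                        ".", m.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_table(path, required: Sequence[str], numeric: Sequence[str] = ()) -> pd.DataFrame:
    """Read a TSV with a header; validate required and numeric columns."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError("empty table", str(path), 1) from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing}", str(path), 1)
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            raise FormatError(f"non-numeric value in column {col!r}", str(path)) from None
    return df


def read_counts_table(path) -> tuple[list[str], list[str], np.ndarray]:
    """Counts TSV: first column ``transcript_id``, one column per sample."""
    df = read_table(path, required=["transcript_id"])
    sample_ids = [c for c in df.columns if c != "transcript_id"]
    if not sample_ids:
        raise FormatError("counts table has no sample columns", str(path), 1)
    for col in sample_ids:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            raise FormatError(f"non-numeric count in column {col!r}", str(path)) from None
        if (df[col] < 0).any():
            raise FormatError(f"negative count in column {col!r}", str(path))
        if not (df[col] == df[col].astype(np.int64)).all():
            raise FormatError(f"non-integer count in column {col!r}", str(path))
    tids = df["transcript_id"].tolist()
    if len(set(tids)) != len(tids):
        raise FormatError("duplicate transcript_id in counts table", str(path))
    counts = df[sample_ids].to_numpy(dtype=np.int64)
    return tids, sample_ids, counts


def read_design_table(path) -> pd.DataFrame:
    """Design TSV: sample_id, condition, and optional library_size."""
    df = read_table(path, required=["sample_id", "condition"])
    if "library_size" in df.columns:
        df["library_size"] = pd.to_numeric(df["library_size"]).astype(np.int64)
    return df


def build_expression_matrix(tids: list[str], sample_ids: list[str],
                            counts: np.ndarray, design: pd.DataFrame) -> ExpressionMatrix:
    cond = dict(zip(design["sample_id"], design["condition"]))
    missing = [s for s in sample_ids if s not in cond]
    if missing:
        raise FormatError(f"samples missing from design: {missing}")
    colsum = counts.sum(axis=0)
    if "library_size" in design.columns:
        lib = design.set_index("sample_id")["library_size"]
        library_size = np.array([lib[s] for s in sample_ids], dtype=np.int64)
    else:
        library_size = colsum.astype(np.int64)
    return ExpressionMatrix(tids, sample_ids, cond, counts, library_size)


def read_scores_table(path) -> dict[str, dict[str, float]]:
    """External coding-potential scores: transcript_id, cpc, txcds, cnci."""
    df = read_table(path, required=["transcript_id", "cpc", "txcds", "cnci"],
                    numeric=["cpc", "txcds", "cnci"])
    return {r.transcript_id: {"cpc": r.cpc, "txcds": r.txcds, "cnci": r.cnci}
            for r in df.itertuples()}


def read_domain_hits_table(path) -> set[str]:
    """Protein-domain hits: transcript ids with >= 1 hit row."""
    df = read_table(path, required=["transcript_id"])
    if "hit" in df.columns:
        df = df[pd.to_numeric(df["hit"]).astype(int) != 0]
    return set(df["transcript_id"])


def read_pathway_map(path) -> pd.DataFrame:
    """Gene→pathway membership: gene_id, pathway_id, pathway_name."""
    return read_table(path, required=["gene_id", "pathway_id", "pathway_name"])


def write_counts_table(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.counts, columns=expr.sample_ids)
    df.insert(0, "transcript_id", expr.transcript_ids)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_design_table(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame({
        "sample_id": expr.sample_ids,
        "condition": [expr.condition_of[s] for s in expr.sample_ids],
        "library_size": expr.library_size,
    })
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
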