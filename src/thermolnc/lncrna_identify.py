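"""Candidate-filter cascade for lncRNA identification.

Assembled transcripts pass through six ordered steps — novelty against the
reference annotation, minimum length, maximum ORF size, coding-potential
score, protein-domain hits, and minimum expression — with per-step
provenance recorded for every input transcript.

The coding-potential step either consumes an external score table
(CPC / txCdsPredict / CNCI conventions: pass iff cpc < 0 and txcds < 500
and cnci < 0) or falls back to a built-in hexamer log-ratio surrogate
scorer trained on the reference CDS set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PipelineError, ValidationError
from .expression_de import compute_fpkm
from .formats_io import ExpressionMatrix, TranscriptModel, spliced_rna
from .genome_context import GeneIndex, LncRNARecord, build_gene_index, classify_all

FILTER_STEPS = (
    "novel_locus",
    "length_ge_200",
    "orf_le_100aa",
    "coding_potential_pass",
    "no_domain_hit",
    "expressed_fpkm_gt_1",
)

_STOPS = ("UAA", "UAG", "UGA")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass
class Thresholds:
    """Cut-offs of the cascade; defaults mirror the published pipeline."""

    min_length_nt: int = 200      # keep length >= 200 (excluded if < 200)
    max_orf_aa: int = 100         # keep ORF <= 100 aa (excluded if > 100)
    cpc_max: float = 0.0          # external scores: strict <
    txcds_max: float = 500.0
    cnci_max: float = 0.0
    min_fpkm: float = 1.0         # strict >: FPKM > 1 in >= 1 library


@dataclass
class CodingScores:
    transcript_id: str
    cpc: float | None = None
    txcds: float | None = None
    cnci: float | None = None
    surrogate: float | None = None


@dataclass
class FilterTrace:
    """Per-transcript verdicts: pass / fail / skipped for each step, in order."""

    transcript_id: str
    step_results: dict[str, str] = field(default_factory=dict)
    final: str = "rejected"


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

def longest_orf_aa(seq: str) -> tuple[int, int, int]:
    """Longest AUG-initiated, stop-terminated ORF over the 3 forward frames.

    Returns ``(length_aa, start, end)`` on the spliced sequence, where the
    half-open [start, end) span includes the stop codon and ``length_aa``
    counts codons excluding the stop.  (0, 0, 0) when no complete ORF exists.
    """
    best = (0, 0, 0)
    n = len(seq)
    for frame in range(3):
        stops = [i for i in range(frame, n - 2, 3) if seq[i:i + 3] in _STOPS]
        starts = [i for i in range(frame, n - 2, 3) if seq[i:i + 3] == "AUG"]
        if not starts or not stops:
            continue
        stop_arr = stops
        si = 0
        for a in starts:
            while si < len(stop_arr) and stop_arr[si] < a:
                si += 1
            # first in-frame stop at or after the AUG
            j = si
            if j >= len(stop_arr):
                break
            stop = stop_arr[j]
            aa = (stop - a) // 3
            if aa > best[0]:
                best = (aa, a, stop + 3)
    return best


# ---------------------------------------------------------------------------
# hexamer surrogate scorer
# ---------------------------------------------------------------------------

class HexamerTable:
    """log2 ratio of in-frame coding vs background frequency per hexamer."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (4096,):
            raise ValidationError("hexamer table must have 4096 entries")
        if not np.isfinite(values).all():
            raise ValidationError("hexamer table contains non-finite values")
        self.values = values

    def __getitem__(self, hexamer: str) -> float:
        return float(self.values[_encode_hexamer(hexamer)])


def _encode_hexamer(h: str) -> int:
    code = 0
    for c in h:
        code = code * 4 + _BASE_CODE[c]
    return code


def _count_hexamers(seqs: Sequence[str], step: int) -> np.ndarray:
    counts = np.zeros(4096, dtype=np.int64)
    for seq in seqs:
        for i in range(0, len(seq) - 5, step):
            h = seq[i:i + 6]
            if all(c in _BASE_CODE for c in h):
                counts[_encode_hexamer(h)] += 1
    return counts


def train_hexamer_table(coding_seqs: Sequence[str],
                        background_seqs: Sequence[str] | None = None,
                        epsilon: float = 1.0 / 4096,
                        rng: np.random.Generator | None = None) -> HexamerTable:
    """Train the surrogate coding-potential table.

    Coding hexamers are counted in-frame (step 3, frame 0 of each CDS);
    background hexamers in all frames (step 1).  When no background is
    supplied, shuffled copies of the coding set are used.
    """
    if len(coding_seqs) < 10 or sum(map(len, coding_seqs)) < 20_000:
        raise ValidationError(
            "insufficient training mass for hexamer table: need >= 10 coding "
            "sequences totalling >= 20 kb; consider the synthetic defaults")
    if background_seqs is None:
        rng = rng or np.random.default_rng(0)
        background_seqs = ["".join(rng.permutation(list(s))) for s in coding_seqs]
    fc = _count_hexamers(coding_seqs, step=3)
    fb = _count_hexamers(background_seqs, step=1)
    pc = fc / max(fc.sum(), 1)
    pb = fb / max(fb.sum(), 1)
    return HexamerTable(np.log2((pc + epsilon) / (pb + epsilon)))


def surrogate_coding_score(seq: str, table: HexamerTable) -> float:
    """Mean in-frame hexamer log-ratio over the longest ORF (incl. its stop).

    Returns 0.0 when the sequence has no complete ORF; higher values are
    more coding-like.
    """
    aa, start, end = longest_orf_aa(seq)
    if aa == 0:
        return 0.0
    vals = [table.values[_encode_hexamer(seq[i:i + 6])]
            for i in range(start, end - 5, 3)
            if all(c in _BASE_CODE for c in seq[i:i + 6])]
    if not vals:
        return 0.0
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def novel_locus_filter(assembled: Sequence[TranscriptModel],
                       reference: Sequence[TranscriptModel]) -> dict[str, bool]:
    """Pass unless a transcript has same-strand exonic overlap with the
    reference.  Antisense or intron-contained overlap does not disqualify."""
    index = build_gene_index(list(reference)) if reference else None
    verdict: dict[str, bool] = {}
    for m in assembled:
        hit = False
        if index is not None:
            for s, e in m.exons:
                if index.exon_overlaps(m.seq_name, m.strand, s, e):
                    hit = True
                    break
        verdict[m.transcript_id] = not hit
    return verdict


def apply_filter_cascade(
    assembled: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    expr: ExpressionMatrix,
    genome: Mapping[str, str],
    scores: Mapping[str, Mapping[str, float]] | None = None,
    domain_hits: set[str] | None = None,
    thresholds: Thresholds | None = None,
    hexamer_table: HexamerTable | None = None,
    intronic_strand: str = "any",
) -> tuple[list[LncRNARecord], list[FilterTrace], pd.DataFrame]:
    """Run the six-step cascade and classify the survivors.

    Returns (classified lncRNA records, one trace per input transcript,
    per-step survivor counts).  Steps after the first failure are marked
    ``skipped``; the domain step is ``skipped`` when no hit table is given.
    """
    th = thresholds or Thresholds()
    missing = [m.transcript_id for m in assembled
               if m.transcript_id not in set(expr.transcript_ids)]
    if missing:
        raise PipelineError(
            f"transcripts absent from expression matrix: {missing[:5]}"
            + ("..." if len(missing) > 5 else ""))

    if scores is None and hexamer_table is None:
        coding_rna = [spliced_rna(m, genome) for m in reference if m.cds]
        # uniform-composition background: a shuffled-CDS background would
        # inherit the CDS base composition and inflate the scores of
        # composition-neutral transcripts
        rng = np.random.default_rng(0)
        background = ["".join(rng.choice(list("ACGU"), size=len(s)))
                      for s in coding_rna]
        hexamer_table = train_hexamer_table(coding_rna, background)

    novelty = novel_locus_filter(assembled, reference)
    lengths = {m.transcript_id: m.spliced_length for m in assembled}
    fpkm = compute_fpkm(expr, lengths | {
        t: 1 for t in expr.transcript_ids if t not in lengths})

    traces: list[FilterTrace] = []
    survivors: list[TranscriptModel] = []
    step_pass = {s: 0 for s in FILTER_STEPS}
    for m in assembled:
        tid = m.transcript_id
        trace = FilterTrace(tid)
        rna: str | None = None
        failed = False
        for step in FILTER_STEPS:
            if failed:
                trace.step_results[step] = "skipped"
                continue
            if step == "novel_locus":
                ok = novelty[tid]
            elif step == "length_ge_200":
                ok = m.spliced_length >= th.min_length_nt
            elif step == "orf_le_100aa":
                rna = spliced_rna(m, genome)
                ok = longest_orf_aa(rna)[0] <= th.max_orf_aa
            elif step == "coding_potential_pass":
                ext = scores.get(tid) if scores is not None else None
                if ext is not None:
                    ok = (ext["cpc"] < th.cpc_max
                          and ext["txcds"] < th.txcds_max
                          and ext["cnci"] < th.cnci_max)
                else:
                    rna = rna or spliced_rna(m, genome)
                    # tie at 0 passes: no-ORF transcripts score exactly 0
                    ok = surrogate_coding_score(rna, hexamer_table) <= 0.0
            elif step == "no_domain_hit":
                if domain_hits is None:
                    trace.step_results[step] = "skipped"
                    continue
                ok = tid not in domain_hits
            else:  # expressed_fpkm_gt_1
                ok = float(fpkm.loc[tid].max()) > th.min_fpkm
            trace.step_results[step] = "pass" if ok else "fail"
            if ok:
                step_pass[step] += 1
            else:
                failed = True
        trace.final = "rejected" if failed else "lncRNA"
        if not failed:
            survivors.append(m)
        traces.append(trace)

    # survivors-after-step table (Venn/flowchart analogue)
    remaining = len(assembled)
    rows = []
    for step in FILTER_STEPS:
        evaluated = sum(1 for t in traces if t.step_results[step] != "skipped")
        failed_n = sum(1 for t in traces if t.step_results[step] == "fail")
        remaining -= failed_n
        rows.append({"step": step, "evaluated": evaluated,
                     "failed": failed_n, "surviving": remaining})
    step_counts = pd.DataFrame(rows)

    index = build_gene_index(list(reference)) if reference else None
    if index is not None:
        records = classify_all(survivors, index, intronic_strand)
    else:
        records = [LncRNARecord(m, "intergenic", "none") for m in survivors]

    # cascade monotonicity: survivors of step k+1 are a subset of step k
    surv = step_counts["surviving"].to_numpy()
    if (np.diff(surv) > 0).any():
        raise PipelineError("filter cascade monotonicity violated")
    return records, traces, step_counts


def traces_to_frame(traces: list[FilterTrace]) -> pd.DataFrame:
    rows = []
    for t in traces:
        row = {"transcript_id": t.transcript_id}
        row.update(t.step_results)
        row["final"] = t.final
        rows.append(row)
    return pd.DataFrame(rows)
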