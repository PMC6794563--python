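"""Synthetic genome / annotation / expression generator with planted truth.

The generator emulates the statistical structure reported for fungal
heat-stress lncRNA surveys — lncRNAs shorter than mRNAs, mostly 1–2
exons, expressed lower than coding genes, a planted DE fraction with
large fold changes, and all four genomic-context categories — so every
downstream stage can be verified without external downloads.

Draw order is fixed per seed: genome background → gene placement →
lncRNA placement → expression truth; counts are drawn from a second
stream keyed ``(seed, 1)``.  All outputs are pure functions of the
configuration.

Coding sequences are sampled from a deliberately skewed codon-usage
table (one dominant synonymous codon per amino acid) so the hexamer
surrogate scorer has real signal; lncRNA sequences are uniform, with
stop codons injected until no open reading frame exceeds 100 aa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SimulationError, ValidationError
from .formats_io import (ExpressionMatrix, SequenceRecord, TranscriptModel,
                         reverse_complement, to_rna, write_counts_table,
                         write_design_table, write_fasta, write_gtf)
from .lncrna_identify import longest_orf_aa

CATEGORY_ORDER = ("intergenic", "antisense", "sense", "intronic")

# standard genetic code, codon order TTT, TTC, TTA, ... (bases TCAG)
_GC_BASES = "TCAG"
_GC_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_DOMINANT_WEIGHT = 0.94


def _codon_distribution() -> tuple[list[str], np.ndarray]:
    """Sense codons and their skewed sampling probabilities.

    Amino acids are drawn uniformly; within each amino acid the first
    codon in table order carries almost all the mass.
    """
    by_aa: dict[str, list[str]] = {}
    for i, aa in enumerate(_GC_AAS):
        codon = _GC_BASES[i // 16] + _GC_BASES[(i // 4) % 4] + _GC_BASES[i % 4]
        if aa != "*":
            by_aa.setdefault(aa, []).append(codon)
    codons: list[str] = []
    probs: list[float] = []
    n_aa = len(by_aa)
    for aa, cods in by_aa.items():
        if len(cods) == 1:
            codons.append(cods[0])
            probs.append(1.0 / n_aa)
        else:
            codons.append(cods[0])
            probs.append(_DOMINANT_WEIGHT / n_aa)
            rest = (1.0 - _DOMINANT_WEIGHT) / (len(cods) - 1) / n_aa
            for c in cods[1:]:
                codons.append(c)
                probs.append(rest)
    return codons, np.asarray(probs) / np.sum(probs)


_SENSE_CODONS, _CODON_P = _codon_distribution()
# codons rarely used by the simulated coding genes; planted lncRNA ORFs
# draw from these so their composition is genuinely unlike coding sequence
_NONPREF_CODONS = [c for c, p in zip(_SENSE_CODONS, _CODON_P)
                   if p < max(_CODON_P) / 2]
_STOP_DNA = ("TAA", "TAG", "TGA")


@dataclass
class SimConfig:
    """Everything the generator needs; all randomness flows from ``seed``."""

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 150_000
    n_coding: int = 50
    n_lnc: int = 60
    category_props: dict[str, float] = field(default_factory=lambda: {
        "intergenic": 0.8, "antisense": 0.1, "sense": 0.05, "intronic": 0.05})
    lnc_len_range: tuple[int, int] = (250, 1200)
    coding_len_range: tuple[int, int] = (600, 1500)  # spliced nt, incl. stop
    lnc_exon_max: int = 2
    coding_exon_range: tuple[int, int] = (2, 4)
    de_fraction: float = 0.3
    de_log2fc: float = 3.0
    nb_dispersion: float = 0.05
    libsize_range: tuple[int, int] = (2_000, 5_000)  # unassigned-fragment margin
    n_reps_per_condition: int = 3

    def validate(self) -> None:
        if abs(sum(self.category_props.values()) - 1.0) > 1e-9:
            raise ValidationError("category proportions must sum to 1")
        if set(self.category_props) != set(CATEGORY_ORDER):
            raise ValidationError(f"category_props must cover {CATEGORY_ORDER}")
        for name in ("n_chroms", "chrom_len", "n_coding", "n_lnc",
                     "lnc_exon_max", "n_reps_per_condition"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.de_log2fc <= 0:
            raise ValidationError("de_log2fc must be positive")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if not 0 <= self.de_fraction <= 1:
            raise ValidationError("de_fraction must lie in [0, 1]")


def category_counts(props: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment in fixed category order."""
    raw = {c: props[c] * n for c in CATEGORY_ORDER}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    rest = n - sum(counts.values())
    by_frac = sorted(CATEGORY_ORDER, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in by_frac[:rest]:
        counts[c] += 1
    return counts


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

def _overlaps_any(start: int, end: int, spans, margin: int = 0) -> bool:
    return any(start < e + margin and end > s - margin for s, e in spans)


def _random_partition(rng: np.random.Generator, total: int, parts: int,
                      min_size: int) -> list[int]:
    """Split ``total`` into ``parts`` pieces each >= min_size."""
    if parts * min_size > total:
        raise SimulationError("partition infeasible: pieces too large")
    slack = total - parts * min_size
    cuts = np.sort(rng.integers(0, slack + 1, size=parts - 1))
    sizes = np.diff(np.concatenate(([0], cuts, [slack])))
    return [int(s) + min_size for s in sizes]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _neutral_orf_dna(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + (n_aa - 1) non-preferred sense codons + TAA.

    Drawing uniformly from the codons the coding genes avoid gives the
    planted lncRNA ORF a composition clearly unlike coding sequence, as in
    real transcriptomes.
    """
    body = "".join(_NONPREF_CODONS[i]
                   for i in rng.integers(0, len(_NONPREF_CODONS), size=n_aa - 1))
    return "ATG" + body + "TAA"


def _lnc_free_content(rng: np.random.Generator, ext: int, strand: str,
                      fixed_g: str = "", fixed_side: str = "none",
                      max_aa: int = 100) -> str:
    """Genome-orientation content for the writable part of a lncRNA locus.

    A neutral ORF of 55-90 aa is planted inside the free region so the
    transcript's longest ORF is long (stable surrogate score) yet <= 100 aa.
    ``fixed_g`` is unwritable flanking genome content (e.g. a host exon
    overlap) sitting at ``fixed_side`` of the free region in genome order.
    The composed sense sequence is re-checked and regenerated until its
    longest ORF is within bounds.
    """
    hi = min(90, (ext - 12) // 3 - 1)
    lo = min(55, max(hi - 1, 20))
    for _ in range(50):
        aa = int(rng.integers(lo, hi + 1)) if hi > lo else hi
        orf_sense = _neutral_orf_dna(rng, aa)
        orf_g = orf_sense if strand == "+" else reverse_complement(orf_sense)
        pos = int(rng.integers(3, ext - len(orf_g) - 2))
        free_g = (_random_dna(rng, pos) + orf_g
                  + _random_dna(rng, ext - pos - len(orf_g)))
        if fixed_side == "left":
            full_g = fixed_g + free_g
        elif fixed_side == "right":
            full_g = free_g + fixed_g
        else:
            full_g = free_g
        sense = full_g if strand == "+" else reverse_complement(full_g)
        if longest_orf_aa(to_rna(sense))[0] <= max_aa:
            return free_g
    raise SimulationError("could not bound the longest ORF of a lncRNA locus")


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig
                    ) -> tuple[list[SequenceRecord], list[TranscriptModel], pd.DataFrame]:
    """Generate (chromosomes, transcript models, ground truth).

    Models comprise the coding reference (biotype ``coding``, CDS == exons)
    and the planted lncRNAs (biotype ``lncRNA_candidate``).  The truth
    table has one row per transcript: ``true_class``, ``true_de_status``,
    ``true_log2fc`` and ``true_mean_expression``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chroms = {name: np.array(list(_random_dna(rng, config.chrom_len)))
              for name in chrom_names}
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in chrom_names}

    cat_counts = category_counts(config.category_props, config.n_lnc)
    genes: list[TranscriptModel] = []

    def place(length: int, tries: int = 300) -> tuple[str, int]:
        for _ in range(tries):
            chrom = chrom_names[int(rng.integers(config.n_chroms))]
            if config.chrom_len <= length + 2:
                break
            start = int(rng.integers(1, config.chrom_len - length - 1))
            if not _overlaps_any(start, start + length, occupied[chrom], margin=2):
                return chrom, start
        raise SimulationError(
            "could not place a feature; try chrom_len >= "
            f"{config.chrom_len * 2}")

    # --- coding genes -----------------------------------------------------
    need_big_intron = cat_counts["intronic"]
    for g in range(config.n_coding):
        n_codons = int(rng.integers(config.coding_len_range[0] // 3,
                                    config.coding_len_range[1] // 3 + 1))
        spliced_len = 3 * n_codons
        n_exons = int(rng.integers(config.coding_exon_range[0],
                                   config.coding_exon_range[1] + 1))
        exon_sizes = _random_partition(rng, spliced_len, n_exons, 30)
        intron_sizes = [int(rng.integers(60, 400)) for _ in range(n_exons - 1)]
        if g < need_big_intron and intron_sizes:
            intron_sizes[int(rng.integers(len(intron_sizes)))] = int(
                rng.integers(1500, 2200))
        strand = "+" if rng.integers(2) == 0 else "-"
        body = "".join(_SENSE_CODONS[i] for i in
                       rng.choice(len(_SENSE_CODONS), size=n_codons - 2,
                                  p=_CODON_P))
        cds_seq = "ATG" + body + "TAA"
        # interleave exons and introns in transcript orientation
        blocks: list[tuple[str, str]] = []
        off = 0
        for i, es in enumerate(exon_sizes):
            blocks.append(("exon", cds_seq[off:off + es]))
            off += es
            if i < len(intron_sizes):
                blocks.append(("intron", _random_dna(rng, intron_sizes[i])))
        construct = "".join(s for _, s in blocks)
        chrom, start = place(len(construct))
        genomic = construct if strand == "+" else reverse_complement(construct)
        chroms[chrom][start:start + len(genomic)] = list(genomic)
        occupied[chrom].append((start, start + len(genomic)))
        exons: list[tuple[int, int]] = []
        off = 0
        for kind, s in blocks:
            if kind == "exon":
                if strand == "+":
                    exons.append((start + off, start + off + len(s)))
                else:
                    total = len(construct)
                    exons.append((start + total - off - len(s), start + total - off))
            off += len(s)
        exons.sort()
        genes.append(TranscriptModel(
            transcript_id=f"tx_c{g:04d}", gene_id=f"gene_c{g:04d}",
            seq_name=chrom, strand=strand, exons=tuple(exons),
            cds=tuple(exons), biotype="coding"))

    gene_exons_by_strand: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for m in genes:
        gene_exons_by_strand.setdefault((m.seq_name, m.strand), []).extend(m.exons)

    # --- lncRNAs ----------------------------------------------------------
    lncs: list[TranscriptModel] = []
    truth_class: dict[str, str] = {}
    idx = 0

    def next_ids() -> tuple[str, str]:
        nonlocal idx
        tid, gid = f"tx_l{idx:04d}", f"gene_l{idx:04d}"
        idx += 1
        return tid, gid

    def _write(chrom: str, start: int, content: str) -> None:
        chroms[chrom][start:start + len(content)] = list(content)

    def _slice_seq(chrom: str, start: int, end: int, strand: str) -> str:
        s = "".join(chroms[chrom][start:end])
        return s if strand == "+" else reverse_complement(s)

    def _emit(category: str, chrom: str, strand: str,
              exons: tuple[tuple[int, int], ...]) -> None:
        tid, gid = next_ids()
        truth_class[tid] = f"lnc:{category}"
        lncs.append(TranscriptModel(tid, gid, chrom, strand, exons,
                                    biotype="lncRNA_candidate"))

    # intergenic: written into free space, optionally spliced into 2 exons
    for _ in range(cat_counts["intergenic"]):
        length = int(rng.integers(max(config.lnc_len_range[0], 250),
                                  config.lnc_len_range[1] + 1))
        n_exons = int(rng.integers(1, config.lnc_exon_max + 1))
        strand = "+" if rng.integers(2) == 0 else "-"
        seq = _lnc_free_content(rng, length, "+")  # sense-orientation content
        if n_exons == 2 and length >= 400:
            # split outside the planted ORF so the spliced seq keeps it intact
            aa, os_, oe = longest_orf_aa(to_rna(seq))
            cut = oe + 3 if oe + 80 < length else max(os_ - 3, 80)
            intron = _random_dna(rng, int(rng.integers(60, 300)))
            construct = seq[:cut] + intron + seq[cut:]
            rel_exons = [(0, cut), (cut + len(intron), len(construct))]
        else:
            construct = seq
            rel_exons = [(0, length)]
        chrom, start = place(len(construct))
        _write(chrom, start, construct if strand == "+"
               else reverse_complement(construct))
        occupied[chrom].append((start, start + len(construct)))
        total = len(construct)
        exons = []
        for s, e in rel_exons:
            if strand == "+":
                exons.append((start + s, start + e))
            else:
                exons.append((start + total - e, start + total - s))
        _emit("intergenic", chrom, strand, tuple(sorted(exons)))

    # intronic: planted inside the reserved big intron of one host gene each
    for i in range(cat_counts["intronic"]):
        host = genes[i]
        iv = max(host.introns(), key=lambda x: x[1] - x[0])
        if iv[1] - iv[0] < 300:
            raise SimulationError("big intron missing; increase chrom_len")
        length = int(rng.integers(250, min(700, iv[1] - iv[0] - 4) + 1))
        start = int(rng.integers(iv[0] + 1, iv[1] - length))
        strand = "+" if rng.integers(2) == 0 else "-"
        content = _lnc_free_content(rng, length, strand)
        _write(host.seq_name, start, content)
        _emit("intronic", host.seq_name, strand, ((start, start + length),))

    # antisense: small exonic overlap at a host gene edge, extending outward
    # into free space that receives planted content on the opposite strand
    placed_as = 0
    for _ in range(600):
        if placed_as == cat_counts["antisense"]:
            break
        host = genes[int(rng.integers(len(genes)))]
        strand = "-" if host.strand == "+" else "+"
        side = "left" if rng.integers(2) == 0 else "right"
        ext = int(rng.integers(280, 601))
        if side == "left":
            first = host.exons[0]
            ovl = int(rng.integers(20, min(40, first[1] - first[0]) + 1))
            span = (host.start - ext, host.start + ovl)
            free = (span[0], host.start)
            fixed = (host.start, span[1])
            fixed_side = "right"  # fixed content right of the free region
        else:
            last = host.exons[-1]
            ovl = int(rng.integers(20, min(40, last[1] - last[0]) + 1))
            span = (host.end - ovl, host.end + ext)
            free = (host.end, span[1])
            fixed = (span[0], host.end)
            fixed_side = "left"
        if span[0] < 1 or span[1] > config.chrom_len - 1:
            continue
        others = [s for s in occupied[host.seq_name] if s != host.span]
        if _overlaps_any(free[0], free[1], others, margin=2):
            continue
        if _overlaps_any(span[0], span[1],
                         gene_exons_by_strand.get((host.seq_name, strand), [])):
            continue  # would be sense w.r.t. some gene
        fixed_g = "".join(chroms[host.seq_name][fixed[0]:fixed[1]])
        try:
            content = _lnc_free_content(rng, ext, strand, fixed_g, fixed_side)
        except SimulationError:
            continue
        _write(host.seq_name, free[0], content)
        occupied[host.seq_name].append(free)
        _emit("antisense", host.seq_name, strand, (span,))
        placed_as += 1
    if placed_as < cat_counts["antisense"]:
        raise SimulationError(
            f"could not place antisense lncRNAs; try chrom_len >= "
            f"{config.chrom_len * 2}")

    # sense: same-strand overlap with a host exon, read back from the genome
    placed_se = 0
    for _ in range(600):
        if placed_se == cat_counts["sense"]:
            break
        host = genes[int(rng.integers(len(genes)))]
        ex = host.exons[int(rng.integers(host.n_exons))]
        length = int(rng.integers(config.lnc_len_range[0],
                                  min(config.lnc_len_range[1], 600) + 1))
        lo = max(1, ex[0] - length + 20)
        hi = min(config.chrom_len - length - 1, ex[1] - 20)
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi + 1))
        end = start + length
        if (start, end) in [tuple(e) for e in host.exons]:
            continue  # must differ structurally from the host
        seq = _slice_seq(host.seq_name, start, end, host.strand)
        if longest_orf_aa(to_rna(seq))[0] > 100:
            continue
        _emit("sense", host.seq_name, host.strand, ((start, end),))
        placed_se += 1
    if placed_se < cat_counts["sense"]:
        raise SimulationError(
            f"could not place sense lncRNAs; try chrom_len >= "
            f"{config.chrom_len * 2}")

    models = genes + lncs
    for m in genes:
        truth_class[m.transcript_id] = "coding"

    # --- expression truth -------------------------------------------------
    tids = [m.transcript_id for m in models]
    is_lnc = np.array([t.startswith("tx_l") for t in tids])
    base = np.exp(rng.normal(np.log(80.0), 0.8, size=len(tids)))
    base = np.where(is_lnc, base * 0.2, base)
    base = np.maximum(base, 3.0)
    status = np.array(["null"] * len(tids), dtype=object)
    lfc = np.zeros(len(tids))
    n_de = int(round(config.de_fraction * len(tids)))
    if n_de:
        chosen = rng.choice(len(tids), size=n_de, replace=False)
        n_up = int(round(2 * n_de / 3))  # ~2:1 up:down, as in heat-stress data
        status[chosen[:n_up]] = "up"
        status[chosen[n_up:]] = "down"
        lfc[chosen[:n_up]] = config.de_log2fc
        lfc[chosen[n_up:]] = -config.de_log2fc

    truth = pd.DataFrame({
        "transcript_id": tids,
        "true_class": [truth_class[t] for t in tids],
        "true_de_status": status,
        "true_log2fc": lfc,
        "true_mean_expression": base,
    })

    seqs = [SequenceRecord(name, "".join(chroms[name])) for name in chrom_names]
    return seqs, models, truth


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def simulate_counts(models: list[TranscriptModel], truth: pd.DataFrame,
                    config: SimConfig,
                    n_reps: int | None = None) -> ExpressionMatrix:
    """Negative-binomial counts (variance m + phi * m^2) for two conditions."""
    config.validate()
    t = truth.set_index("transcript_id")
    missing = [m.transcript_id for m in models if m.transcript_id not in t.index]
    if missing:
        raise ValidationError(f"truth does not cover models: {missing[:5]}")
    rng = np.random.default_rng([config.seed, 1])
    reps = n_reps if n_reps is not None else config.n_reps_per_condition
    samples = [f"control_{i + 1}" for i in range(reps)] + \
              [f"heat_{i + 1}" for i in range(reps)]
    condition_of = {s: ("control" if s.startswith("control") else "heat")
                    for s in samples}
    tids = [m.transcript_id for m in models]
    mean_c = t.loc[tids, "true_mean_expression"].to_numpy(dtype=float)
    mean_h = mean_c * np.power(2.0, t.loc[tids, "true_log2fc"].to_numpy(dtype=float))
    means = np.concatenate([np.repeat(mean_c[:, None], reps, axis=1),
                            np.repeat(mean_h[:, None], reps, axis=1)], axis=1)
    phi = config.nb_dispersion
    if phi < 1e-9:
        counts = rng.poisson(means)
    else:
        r = 1.0 / phi
        p = r / (r + means)
        counts = rng.negative_binomial(r, p)
    margin = rng.integers(config.libsize_range[0], config.libsize_range[1] + 1,
                          size=len(samples))
    library_size = counts.sum(axis=0) + margin
    return ExpressionMatrix(tids, samples, condition_of,
                            counts.astype(np.int64), library_size)


def simulate_pathway_map(gene_ids: list[str], n_pathways: int = 15,
                         seed: int = 0) -> pd.DataFrame:
    """Random gene→pathway memberships (every gene annotated at least once)."""
    rng = np.random.default_rng([seed, 2])
    rows = []
    for g in gene_ids:
        k = 1 + int(rng.integers(0, 2))
        for p in rng.choice(n_pathways, size=k, replace=False):
            rows.append({"gene_id": g, "pathway_id": f"pw{p:03d}",
                         "pathway_name": f"pathway {p:03d}"})
    return pd.DataFrame(rows).drop_duplicates(ignore_index=True)


# ---------------------------------------------------------------------------
# dataset export
# ---------------------------------------------------------------------------

def write_dataset(outdir, seqs: list[SequenceRecord],
                  models: list[TranscriptModel], truth: pd.DataFrame,
                  expr: ExpressionMatrix,
                  pathways: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write genome.fa, annotation.gtf, assembled.gtf, counts/design/truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gtf",
        "assembled": outdir / "assembled.gtf",
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(seqs, paths["genome"])
    write_gtf([m for m in models if m.biotype == "coding"], paths["annotation"])
    assembled = [TranscriptModel(m.transcript_id, m.gene_id, m.seq_name,
                                 m.strand, m.exons, cds=None,
                                 biotype="assembled",
                                 attributes=dict(m.attributes))
                 for m in models]
    write_gtf(assembled, paths["assembled"])
    write_counts_table(expr, paths["counts"])
    write_design_table(expr, paths["design"])
    truth.to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
    if pathways is not None:
        paths["pathways"] = outdir / "pathways.tsv"
        pathways.to_csv(paths["pathways"], sep="\t", index=False,
                        lineterminator="\n")
    return paths
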