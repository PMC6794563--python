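"""End-to-end orchestration: simulate → identify → classify → de → targets
→ enrich, plus the summary report renderer.

The renderer re-derives every headline total (lncRNA isoform total, DE
total, cis total, percentage shares) from its components and refuses to
emit a report whose arithmetic does not check out.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import enrichment as enr
from . import expression_de as de
from . import formats_io as fio
from . import lncrna_identify as ident
from . import synthetic_data as synth
from . import target_prediction as tp
from .errors import PipelineError
from .genome_context import CATEGORIES, category_summary

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    outdir: str
    seed: int = 0
    simulate: bool = True
    sim: synth.SimConfig | None = None
    # external inputs, used when simulate=False
    genome_path: str | None = None
    reference_path: str | None = None
    assembled_path: str | None = None
    counts_path: str | None = None
    design_path: str | None = None
    pathways_path: str | None = None
    scores_path: str | None = None
    domains_path: str | None = None
    # thresholds (defaults mirror the published analysis)
    thresholds: ident.Thresholds = field(default_factory=ident.Thresholds)
    fdr_threshold: float = 0.001
    min_abs_log2fc: float = 1.0
    up_kb: float = 10.0
    down_kb: float = 20.0
    mfe_threshold: float = -30.0
    p_adj_threshold: float = 0.05
    min_pathway_genes: int = 4
    intronic_strand: str = "any"
    trans_prefilter: bool = True


@dataclass
class SummaryReport:
    """Per-stage counts; all headline totals are derived, never stored."""

    n_assembled: int
    category_counts: dict[str, int]
    n_lncrna: int | None = None  # cross-checked against category sum if given
    n_exons_le2: int | None = None
    n_len_lt_1500: int | None = None
    de_up: int = 0
    de_down: int = 0
    cis_overlap: int = 0
    cis_window: int = 0
    n_trans: int = 0
    n_significant_pathways: int = 0


def render_report(report: SummaryReport) -> tuple[str, dict]:
    """Render the summary; recomputes and re-checks every arithmetic identity.

    Returns (human-readable text, machine-readable dict of derived values).
    Percentages are given to two decimals for category shares and exon /
    length shares, with a one-decimal variant also provided.
    """
    counts = {c: int(report.category_counts.get(c, 0)) for c in CATEGORIES}
    total = sum(counts.values())
    if report.n_lncrna is not None and report.n_lncrna != total:
        raise PipelineError(
            f"report inconsistency: category counts sum to {total}, "
            f"not {report.n_lncrna}")
    de_total = report.de_up + report.de_down
    cis_total = report.cis_overlap + report.cis_window
    derived: dict = {
        "lnc_isoform_total": total,
        "category_counts": counts,
        "de_total": de_total,
        "cis_total": cis_total,
        "n_trans": report.n_trans,
        "n_significant_pathways": report.n_significant_pathways,
    }
    if total > 0:
        derived["category_pct"] = {c: round(100.0 * n / total, 2)
                                   for c, n in counts.items()}
        derived["category_pct_1dp"] = {c: round(100.0 * n / total, 1)
                                       for c, n in counts.items()}
    if report.n_exons_le2 is not None and total > 0:
        derived["pct_exons_le2"] = round(100.0 * report.n_exons_le2 / total, 2)
    if report.n_len_lt_1500 is not None and total > 0:
        derived["pct_len_lt_1500"] = round(100.0 * report.n_len_lt_1500 / total, 2)

    lines = [
        "thermolnc summary",
        "=================",
        f"assembled transcripts     {report.n_assembled}",
        f"lncRNA isoforms (total)   {total}",
    ]
    for c in CATEGORIES:
        pct = derived.get("category_pct", {}).get(c)
        lines.append(f"  {c:<11} {counts[c]:>6}"
                     + (f"  ({pct:.2f}%)" if pct is not None else ""))
    if "pct_exons_le2" in derived:
        lines.append(f"isoforms with <= 2 exons  {report.n_exons_le2} "
                     f"({derived['pct_exons_le2']:.2f}%)")
    if "pct_len_lt_1500" in derived:
        lines.append(f"isoforms shorter 1500 nt  {report.n_len_lt_1500} "
                     f"({derived['pct_len_lt_1500']:.2f}%)")
    lines += [
        f"DE lncRNAs (up + down)    {report.de_up} + {report.de_down} = {de_total}",
        f"cis pairs (overlap+window) {report.cis_overlap} + {report.cis_window}"
        f" = {cis_total}",
        f"trans pairs               {report.n_trans}",
        f"significant pathways      {report.n_significant_pathways}",
    ]
    # render-time re-check (never silently reconciled)
    assert de_total == report.de_up + report.de_down
    assert cis_total == report.cis_overlap + report.cis_window
    assert total == sum(counts.values())
    return "\n".join(lines) + "\n", derived


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> SummaryReport:
    """Run every stage in order, writing each stage's outputs before the next.

    Failures are re-raised with the stage name; a MANIFEST.tsv records the
    completion state and checksum of every output file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def done(stage: str, *paths: Path):
        for p in paths:
            manifest.append({"stage": stage, "file": p.name,
                             "sha256": _sha256(p), "status": "complete"})
        log.info("stage %s complete (%d files)", stage, len(paths))

    def write_manifest():
        pd.DataFrame(manifest).to_csv(outdir / "MANIFEST.tsv", sep="\t",
                                      index=False, lineterminator="\n")

    stage = "simulate"
    try:
        pathway_map = None
        if config.simulate:
            sim = config.sim or synth.SimConfig(seed=config.seed)
            seqs, models, truth = synth.simulate_genome(sim)
            expr = synth.simulate_counts(models, truth, sim)
            gene_ids = sorted({m.gene_id for m in models if m.biotype == "coding"})
            pathway_map = synth.simulate_pathway_map(gene_ids, seed=sim.seed)
            paths = synth.write_dataset(outdir / "data", seqs, models, truth,
                                        expr, pathway_map)
            done(stage, *paths.values())
            genome = {s.id: s.seq for s in seqs}
            reference = [m for m in models if m.biotype == "coding"]
            assembled = models
            scores = domain_hits = None
        else:
            genome = {r.id: r.seq for r in fio.read_fasta(config.genome_path)}
            reference = fio.read_gtf(config.reference_path, coding_only=True)
            assembled = fio.read_gtf(config.assembled_path)
            tids, sids, counts = fio.read_counts_table(config.counts_path)
            design = fio.read_design_table(config.design_path)
            expr = fio.build_expression_matrix(tids, sids, counts, design)
            pathway_map = (fio.read_pathway_map(config.pathways_path)
                           if config.pathways_path else None)
            scores = (fio.read_scores_table(config.scores_path)
                      if config.scores_path else None)
            domain_hits = (fio.read_domain_hits_table(config.domains_path)
                           if config.domains_path else None)

        stage = "identify"
        records, traces, step_counts = ident.apply_filter_cascade(
            assembled, reference, expr, genome, scores=scores,
            domain_hits=domain_hits, thresholds=config.thresholds,
            intronic_strand=config.intronic_strand)
        lnc_models = [r.model for r in records]
        fio.write_gtf(lnc_models, outdir / "lncrna.gtf")
        ident.traces_to_frame(traces).to_csv(
            outdir / "filter_trace.tsv", sep="\t", index=False,
            lineterminator="\n")
        step_counts.to_csv(outdir / "step_counts.tsv", sep="\t", index=False,
                           lineterminator="\n")
        done(stage, outdir / "lncrna.gtf", outdir / "filter_trace.tsv",
             outdir / "step_counts.tsv")

        stage = "classify"
        summary = category_summary(records)
        cat_df = pd.DataFrame(
            [{"transcript_id": r.model.transcript_id, "category": r.category,
              "evidence": r.evidence} for r in records])
        cat_df.to_csv(outdir / "categories.tsv", sep="\t", index=False,
                      lineterminator="\n")
        pd.DataFrame([
            {"category": c, "count": summary.counts[c],
             "percent": summary.percentages[c]} for c in CATEGORIES
        ]).to_csv(outdir / "category_counts.tsv", sep="\t", index=False,
                  lineterminator="\n")
        done(stage, outdir / "categories.tsv", outdir / "category_counts.tsv")

        stage = "de"
        model_of = {m.transcript_id: m for m in assembled}
        for m in reference:
            model_of.setdefault(m.transcript_id, m)
        lengths = {t: model_of[t].spliced_length for t in expr.transcript_ids
                   if t in model_of}
        missing = set(expr.transcript_ids) - set(lengths)
        if missing:
            raise PipelineError(f"no model for counted transcripts: "
                                f"{sorted(missing)[:5]}")
        results = de.call_de(expr, lengths,
                             fdr_threshold=config.fdr_threshold,
                             min_abs_log2fc=config.min_abs_log2fc)
        de.de_results_to_frame(results).to_csv(
            outdir / "de_results.tsv", sep="\t", index=False,
            lineterminator="\n")
        de_status = {r.transcript_id: r.status for r in results}
        lnc_ids = {m.transcript_id for m in lnc_models}
        de_lnc = [m for m in lnc_models
                  if de_status.get(m.transcript_id, "ns") != "ns"]
        coding = [m for m in reference if m.cds]
        de_mrna = [m for m in coding
                   if de_status.get(m.transcript_id, "ns") != "ns"]
        lnc_de_up = sum(1 for m in de_lnc
                        if de_status[m.transcript_id] == "up")
        lnc_de_down = len(de_lnc) - lnc_de_up
        pd.DataFrame([{"set": "lncRNA", "n_up": lnc_de_up,
                       "n_down": lnc_de_down, "n_de": len(de_lnc)},
                      {"set": "coding", "n_de": len(de_mrna)}]).to_csv(
            outdir / "de_summary.tsv", sep="\t", index=False,
            lineterminator="\n")
        done(stage, outdir / "de_results.tsv", outdir / "de_summary.tsv")

        stage = "targets"
        cis = tp.find_cis_pairs(de_lnc, de_mrna, config.up_kb, config.down_kb)
        lnc_seqs = {m.transcript_id: fio.spliced_rna(m, genome) for m in de_lnc}
        mrna_seqs = {m.transcript_id: fio.spliced_rna(m, genome) for m in de_mrna}
        trans = tp.find_trans_pairs(lnc_seqs, mrna_seqs, cis,
                                    energy_threshold=config.mfe_threshold,
                                    prefilter=config.trans_prefilter)
        assert not ({(p.lnc_id, p.mrna_id) for p in cis}
                    & {(p.lnc_id, p.mrna_id) for p in trans})
        pair_cols = ["lnc_id", "mrna_id", "mode", "signed_distance", "mfe"]
        pd.DataFrame([p.__dict__ for p in cis], columns=pair_cols).to_csv(
            outdir / "cis_pairs.tsv", sep="\t", index=False, lineterminator="\n")
        pd.DataFrame([p.__dict__ for p in trans], columns=pair_cols).to_csv(
            outdir / "trans_pairs.tsv", sep="\t", index=False,
            lineterminator="\n")
        done(stage, outdir / "cis_pairs.tsv", outdir / "trans_pairs.tsv")

        stage = "enrich"
        n_sig = 0
        if pathway_map is not None:
            gene_of = {m.transcript_id: m.gene_id for m in coding}
            target_genes = {gene_of[p.mrna_id] for p in cis} | \
                           {gene_of[p.mrna_id] for p in trans}
            rows = enr.enrich_pathways(target_genes, pathway_map,
                                       p_adj_threshold=config.p_adj_threshold,
                                       min_genes=config.min_pathway_genes)
            enr.enrichment_to_frame(rows).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False,
                lineterminator="\n")
            n_sig = sum(1 for r in rows if r.significant)
            done(stage, outdir / "enrichment.tsv")

        stage = "report"
        report = SummaryReport(
            n_assembled=len(assembled),
            category_counts=summary.counts,
            n_lncrna=len(records),
            n_exons_le2=sum(1 for m in lnc_models if m.n_exons <= 2),
            n_len_lt_1500=sum(1 for m in lnc_models if m.spliced_length < 1500),
            de_up=lnc_de_up, de_down=lnc_de_down,
            cis_overlap=sum(1 for p in cis if p.mode == "cis_overlap"),
            cis_window=sum(1 for p in cis if p.mode == "cis_window"),
            n_trans=len(trans),
            n_significant_pathways=n_sig,
        )
        text, derived = render_report(report)
        (outdir / "report.txt").write_text(text, encoding="utf-8")
        pd.DataFrame([
            {"metric": "lnc_isoform_total", "value": derived["lnc_isoform_total"]},
            {"metric": "de_total", "value": derived["de_total"]},
            {"metric": "cis_total", "value": derived["cis_total"]},
            {"metric": "n_trans", "value": derived["n_trans"]},
            {"metric": "n_significant_pathways",
             "value": derived["n_significant_pathways"]},
        ]).to_csv(outdir / "summary.tsv", sep="\t", index=False,
                  lineterminator="\n")
        done(stage, outdir / "report.txt", outdir / "summary.tsv")
        write_manifest()
        return report
    except Exception as exc:
        manifest.append({"stage": stage, "file": "", "sha256": "",
                         "status": f"failed: {type(exc).__name__}"})
        write_manifest()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
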