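# thermolnc

A tested, reusable pipeline for genome-wide lncRNA analysis in heat-stress
transcriptomes:

1. **Identification** — a six-step filter cascade over assembled transcripts
   (novelty against the reference annotation, length ≥ 200 nt, longest ORF
   ≤ 100 aa, coding potential, protein-domain hits, expression FPKM > 1),
   with per-transcript provenance for every step.  External
   CPC/txCdsPredict/CNCI score tables are honoured when available;
   otherwise a built-in hexamer log-ratio surrogate scorer is trained on
   the reference CDS set.
2. **Classification** — strand-aware assignment of each lncRNA to
   intergenic / antisense / sense / intronic by interval logic, with fixed
   precedence (sense > antisense > intronic > intergenic).
3. **Differential expression** — FPKM quantification and a pooled-replicate
   conditional exact binomial test with Benjamini–Hochberg FDR
   (defaults FDR < 0.001, |log2FC| > 1).
4. **Target prediction** — cis pairs by genomic overlap or 10 kb upstream /
   20 kb downstream windows; trans pairs by a nearest-neighbour RNA–RNA
   duplex minimum-free-energy dynamic program (intermolecular only) with a
   strict −30 kcal/mol rule and an optional seed-and-extend prefilter.
5. **Enrichment** — exact hypergeometric pathway enrichment of DE target
   genes, BH-adjusted, significant at p_adj < 0.05 with ≥ 4 DE target genes.
6. **Synthetic data** — a generator that plants a toy genome, annotation,
   four lncRNA context categories, codon-biased CDS, and
   negative-binomial counts with known DE labels, so every stage is
   verifiable offline against ground truth.

## CLI

```bash
# full synthetic run (simulate → identify → classify → de → targets → enrich)
thermolnc run --out out/ --seed 1

# individual stages
thermolnc simulate --seed 1 --out data/
thermolnc identify --genome data/genome.fa --reference data/annotation.gtf \
    --assembled data/assembled.gtf --counts data/counts.tsv \
    --design data/design.tsv --out ident/
thermolnc classify --reference data/annotation.gtf --lncrna ident/lncrna.gtf --out cls/
thermolnc de --counts data/counts.tsv --lengths lengths.tsv --design data/design.tsv --out de/
thermolnc targets --lncrna ident/lncrna.gtf --genes data/annotation.gtf \
    --genome data/genome.fa --de-lnc de_lnc.tsv --de-genes de_genes.tsv --out tgt/
thermolnc enrich --targets targets.tsv --pathways data/pathways.tsv --out enr/
```

`thermolnc run` accepts a YAML config overriding any `RunConfig` /
`SimConfig` field (thresholds, windows, the MFE cut-off, simulation sizes).
Every run writes a `MANIFEST.tsv` with per-file checksums; reruns with the
same config and seed are byte-identical.

## Conventions

* GTF is 1-based inclusive on disk; every internal interval is 0-based
  half-open.  Exons are stored ascending by genomic start for both strands;
  strand is applied at sequence extraction.
* Genomes are DNA (T); transcript sequences exposed to the duplex model are
  RNA (U).
* The embedded duplex stack table is Turner-2004-like; the package claims
  the published decision rule (MFE < −30 kcal/mol), not numeric identity
  with any external tool.
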