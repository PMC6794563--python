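"""Shared fixtures: a small simulated dataset and model-building helpers."""

from __future__ import annotations

import pytest

from thermolnc.formats_io import TranscriptModel
from thermolnc.synthetic_data import SimConfig, simulate_counts, simulate_genome


def make_tx(tid: str, exons, strand: str = "+", seq_name: str = "chr1",
            gene: str | None = None, cds=None, biotype: str = "assembled"):
    """Terse TranscriptModel builder for tests."""
    return TranscriptModel(transcript_id=tid, gene_id=gene or f"g_{tid}",
                           seq_name=seq_name, strand=strand,
                           exons=tuple(tuple(e) for e in exons),
                           cds=None if cds is None else tuple(tuple(c) for c in cds),
                           biotype=biotype)


@pytest.fixture
def tx_factory():
    return make_tx


@pytest.fixture(scope="session")
def sim_bundle():
    """One deterministic simulated dataset shared across the session."""
    cfg = SimConfig(seed=7, n_coding=40, n_lnc=40, chrom_len=120_000)
    seqs, models, truth = simulate_genome(cfg)
    expr = simulate_counts(models, truth, cfg)
    return {
        "config": cfg,
        "seqs": seqs,
        "models": models,
        "truth": truth,
        "expr": expr,
        "genome": {s.id: s.seq for s in seqs},
        "reference": [m for m in models if m.biotype == "coding"],
        "lncs": [m for m in models if m.biotype == "lncRNA_candidate"],
    }
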