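"""lncrna_identify: ORF scanning, hexamer surrogate, and the filter cascade."""

import numpy as np
import pytest

from thermolnc.errors import PipelineError, ValidationError
from thermolnc.formats_io import spliced_rna, to_rna
from thermolnc.lncrna_identify import (FILTER_STEPS, HexamerTable, Thresholds,
                                       apply_filter_cascade, longest_orf_aa,
                                       novel_locus_filter,
                                       surrogate_coding_score,
                                       train_hexamer_table, traces_to_frame)
from tests.conftest import make_tx

STOPS = {"UAA", "UAG", "UGA"}


def oracle_longest_orf(seq):
    """Enumerate every AUG and walk codon by codon to the next in-frame stop."""
    best = 0
    for a in range(len(seq) - 2):
        if seq[a:a + 3] != "AUG":
            continue
        j = a
        while j + 3 <= len(seq):
            if seq[j:j + 3] in STOPS:
                best = max(best, (j - a) // 3)
                break
            j += 3
    return best


class TestLongestOrf:
    def test_minimal_orf(self):
        assert longest_orf_aa("AUGAAAUAA") == (2, 0, 9)

    def test_no_start_codon(self):
        assert longest_orf_aa("CCCCCC")[0] == 0

    def test_start_without_stop_is_not_an_orf(self):
        assert longest_orf_aa("AUGAAAAAA")[0] == 0

    def test_orf_found_in_any_frame(self):
        assert longest_orf_aa("CAUGAAAUAA")[0] == 2

    def test_oracle_equivalence_500_random_1kb(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            seq = "".join(rng.choice(list("ACGU"), size=1000))
            assert longest_orf_aa(seq)[0] == oracle_longest_orf(seq)


class TestHexamerTable:
    def test_table_complete_4096(self):
        t = HexamerTable(np.zeros(4096))
        assert t.values.shape == (4096,)
        with pytest.raises(ValidationError):
            HexamerTable(np.zeros(100))

    def test_insufficient_training_mass_rejected(self):
        with pytest.raises(ValidationError, match="insufficient"):
            train_hexamer_table(["AUGGCU" * 10] * 5)

    def test_identical_composition_scores_near_zero(self):
        # random uniform sequences: in-frame and all-frame hexamer
        # frequencies coincide in expectation, so log-ratios concentrate at 0
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGU"), size=6000)) for _ in range(20)]
        t = train_hexamer_table(seqs, seqs)
        assert abs(float(np.mean(t.values))) < 0.05

    def test_biased_cds_separates_from_uniform(self):
        rng = np.random.default_rng(1)
        from thermolnc.synthetic_data import _CODON_P, _SENSE_CODONS
        coding = [to_rna("ATG" + "".join(
            _SENSE_CODONS[i] for i in rng.choice(len(_SENSE_CODONS), size=250,
                                                 p=_CODON_P)) + "TAA")
            for _ in range(40)]
        bg = ["".join(rng.choice(list("ACGU"), size=len(s))) for s in coding]
        table = train_hexamer_table(coding, bg)
        pos = sum(surrogate_coding_score(s, table) > 0 for s in coding)
        assert pos >= int(0.95 * len(coding))

    def test_hand_summed_12nt_orf(self):
        values = np.zeros(4096)
        table = HexamerTable(values)
        seq = "AUGAAACCCUAA"  # hexamers at 0, 3, 6
        hexes = [seq[i:i + 6] for i in (0, 3, 6)]
        for i, h in enumerate(hexes):
            code = 0
            for c in h:
                code = code * 4 + "ACGU".index(c)
            values[code] = float(i + 1)
        expected = np.mean([1.0, 2.0, 3.0])
        assert surrogate_coding_score(seq, HexamerTable(values)) == pytest.approx(expected)

    def test_no_orf_scores_zero(self):
        t = HexamerTable(np.ones(4096))
        assert surrogate_coding_score("CCCCCCCCC", t) == 0.0


class TestNovelLocusFilter:
    def test_same_strand_overlap_fails(self):
        asm = [make_tx("a", [(100, 200)], strand="+")]
        ref = [make_tx("r", [(150, 250)], strand="+")]
        assert novel_locus_filter(asm, ref) == {"a": False}

    def test_antisense_overlap_retained(self):
        asm = [make_tx("a", [(100, 200)], strand="+")]
        ref = [make_tx("r", [(150, 250)], strand="-")]
        assert novel_locus_filter(asm, ref) == {"a": True}

    def test_brute_force_oracle_50_placements(self):
        rng = np.random.default_rng(5)
        ref = [make_tx(f"r{i}", [(int(s), int(s) + int(rng.integers(20, 200)))],
                       strand="+" if rng.integers(2) else "-")
               for i, s in enumerate(rng.integers(0, 4000, size=30))]
        asm = [make_tx(f"a{i}", [(int(s), int(s) + int(rng.integers(20, 300)))],
                       strand="+" if rng.integers(2) else "-")
               for i, s in enumerate(rng.integers(0, 4000, size=50))]
        got = novel_locus_filter(asm, ref)
        for m in asm:
            overlap = any(
                r.strand == m.strand and ls < re_ and le > rs
                for r in ref for ls, le in m.exons for rs, re_ in r.exons)
            assert got[m.transcript_id] == (not overlap)


@pytest.fixture(scope="module")
def cascade_run(sim_bundle):
    records, traces, steps = apply_filter_cascade(
        sim_bundle["models"], sim_bundle["reference"], sim_bundle["expr"],
        sim_bundle["genome"])
    return records, traces, steps


class TestCascade:
    def test_short_transcript_fails_length_then_skips(self, sim_bundle):
        genome = dict(sim_bundle["genome"])
        genome["chrX"] = "ACGT" * 100
        short = make_tx("short", [(0, 150)], seq_name="chrX")
        expr = sim_bundle["expr"]
        from thermolnc.formats_io import ExpressionMatrix
        expr2 = ExpressionMatrix(
            expr.transcript_ids + ["short"], expr.sample_ids,
            expr.condition_of,
            np.vstack([expr.counts, np.full(len(expr.sample_ids), 5)]),
            expr.library_size + 5)
        _, traces, _ = apply_filter_cascade(
            sim_bundle["models"] + [short], sim_bundle["reference"], expr2,
            genome)
        t = {tr.transcript_id: tr for tr in traces}["short"]
        assert t.step_results["length_ge_200"] == "fail"
        assert t.step_results["orf_le_100aa"] == "skipped"
        assert t.final == "rejected"

    def test_external_scores_take_precedence(self, sim_bundle):
        lnc = sim_bundle["lncs"][0]
        scores = {m.transcript_id: {"cpc": -0.5, "txcds": 499.0, "cnci": -0.1}
                  for m in sim_bundle["models"]}
        _, traces, _ = apply_filter_cascade(
            sim_bundle["models"], sim_bundle["reference"], sim_bundle["expr"],
            sim_bundle["genome"], scores=scores)
        t = {tr.transcript_id: tr for tr in traces}[lnc.transcript_id]
        assert t.step_results["coding_potential_pass"] == "pass"
        # boundary: txcds == 500 must fail (strict <)
        scores2 = {k: dict(v, txcds=500.0) for k, v in scores.items()}
        _, traces2, _ = apply_filter_cascade(
            sim_bundle["models"], sim_bundle["reference"], sim_bundle["expr"],
            sim_bundle["genome"], scores=scores2)
        t2 = {tr.transcript_id: tr for tr in traces2}[lnc.transcript_id]
        assert t2.step_results["coding_potential_pass"] == "fail"

    def test_missing_expression_raises(self, sim_bundle):
        extra = make_tx("ghost", [(0, 300)])
        with pytest.raises(PipelineError, match="absent from expression"):
            apply_filter_cascade(sim_bundle["models"] + [extra],
                                 sim_bundle["reference"], sim_bundle["expr"],
                                 sim_bundle["genome"])

    def test_trace_completeness_and_partition(self, sim_bundle, cascade_run):
        records, traces, _ = cascade_run
        assert len(traces) == len(sim_bundle["models"])
        finals = {t.final for t in traces}
        assert finals <= {"lncRNA", "rejected"}
        assert sum(t.final == "lncRNA" for t in traces) == len(records)

    def test_monotone_survivors(self, cascade_run):
        _, _, steps = cascade_run
        surv = steps["surviving"].tolist()
        assert all(a >= b for a, b in zip(surv, surv[1:]))

    def test_steps_after_first_fail_are_skipped(self, cascade_run):
        _, traces, _ = cascade_run
        for t in traces:
            seen_fail = False
            for step in FILTER_STEPS:
                r = t.step_results[step]
                if seen_fail:
                    assert r == "skipped"
                if r == "fail":
                    seen_fail = True

    def test_planted_truth_agreement(self, sim_bundle, cascade_run):
        _, traces, _ = cascade_run
        truth = sim_bundle["truth"].set_index("transcript_id")["true_class"]
        agree = 0
        for t in traces:
            want_lnc = (truth[t.transcript_id].startswith("lnc")
                        and truth[t.transcript_id] != "lnc:sense")
            agree += (t.final == "lncRNA") == want_lnc
        assert agree / len(traces) >= 0.99

    def test_traces_frame_shape(self, sim_bundle, cascade_run):
        _, traces, _ = cascade_run
        df = traces_to_frame(traces)
        assert list(df.columns) == ["transcript_id", *FILTER_STEPS, "final"]
        assert len(df) == len(sim_bundle["models"])
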