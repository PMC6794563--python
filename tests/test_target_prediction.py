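"""target_prediction: cis windows, duplex MFE DP vs enumeration, trans scan."""

import itertools

import numpy as np
import pytest

from thermolnc.errors import ValidationError
from thermolnc.target_prediction import (DEFAULT_DUPLEX_PARAMS, DuplexParams,
                                         PAIR_NAMES, TargetPair, _WOBBLY,
                                         _flip, _rc_rna, cis_relation,
                                         duplex_mfe, find_cis_pairs,
                                         find_trans_pairs)
from tests.conftest import make_tx

P = DEFAULT_DUPLEX_PARAMS
COMP = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


# --- exhaustive pairing-enumeration oracle ---------------------------------

def oracle_mfe(x, y, params=P):
    """Enumerate every monotone pairing with per-side loops <= max_loop."""
    yr = y[::-1]
    cells = [(i, j) for i in range(len(x)) for j in range(len(yr))
             if (x[i], yr[j]) in COMP]
    best = [None]

    def energy(path):
        e = params.initiation
        for t in range(1, len(path)):
            (pi, pj), (i, j) = path[t - 1], path[t]
            if i - pi == 1 and j - pj == 1:
                e += params.stack[(x[pi] + yr[pj], x[i] + yr[j])]
            else:
                e += params.loop_base + params.loop_slope * (
                    (i - pi - 1) + (j - pj - 1))
        for t in (0, -1):
            i, j = path[t]
            if x[i] + yr[j] in _WOBBLY:
                e += params.terminal_penalty
        return e

    def extend(path):
        e = energy(path)
        if best[0] is None or e < best[0]:
            best[0] = e
        li, lj = path[-1]
        for i, j in cells:
            if (i > li and j > lj and i - li - 1 <= params.max_loop
                    and j - lj - 1 <= params.max_loop):
                extend(path + [(i, j)])

    for c in cells:
        extend([c])
    return best[0]


# --- quadratic cis oracle applying the rule sentence directly ---------------

def oracle_cis(lnc, mrna, up_kb=10.0, down_kb=20.0):
    if lnc.seq_name != mrna.seq_name:
        return None
    ls, le = lnc.span
    ms, me = mrna.span
    if ls < me and le > ms:
        return ("cis_overlap", 0)
    gap = ms - le if le <= ms else ls - me
    if gap == 0:
        return ("cis_overlap", 0)
    lnc_lower = le <= ms
    upstream = lnc_lower if mrna.strand == "+" else not lnc_lower
    if upstream and gap <= up_kb * 1000:
        return ("cis_window", -gap)
    if not upstream and gap <= down_kb * 1000:
        return ("cis_window", gap)
    return None


class TestCis:
    def test_upstream_window_pair(self):
        lnc = make_tx("l", [(5000, 6000)])
        mrna = make_tx("m", [(12000, 15000)], strand="+")
        assert cis_relation(lnc, mrna) == ("cis_window", -6000)

    def test_beyond_downstream_window(self):
        lnc = make_tx("l", [(40000, 41000)])
        mrna = make_tx("m", [(12000, 15000)], strand="+")
        assert cis_relation(lnc, mrna) is None

    def test_downstream_side_uses_20kb(self):
        lnc = make_tx("l", [(30000, 31000)])
        mrna = make_tx("m", [(12000, 15000)], strand="+")
        assert cis_relation(lnc, mrna) == ("cis_window", 15000)

    def test_minus_strand_flips_sides(self):
        lnc = make_tx("l", [(23000, 24000)])
        mrna = make_tx("m", [(12000, 15000)], strand="-")
        # lncRNA on the high-coordinate side is upstream of a minus gene,
        # so the 10-kb window applies and the distance is negative
        assert cis_relation(lnc, mrna) == ("cis_window", -8000)
        far = make_tx("f", [(30000, 31000)])
        assert cis_relation(far, mrna) is None  # 15 kb > 10 kb upstream

    def test_overlap_mode(self):
        lnc = make_tx("l", [(14000, 16000)])
        mrna = make_tx("m", [(12000, 15000)])
        assert cis_relation(lnc, mrna) == ("cis_overlap", 0)

    def test_different_seq_names_never_pair(self):
        lnc = make_tx("l", [(0, 100)], seq_name="chr2")
        mrna = make_tx("m", [(0, 100)], seq_name="chr1")
        assert cis_relation(lnc, mrna) is None

    def test_oracle_equivalence_1000_placements(self):
        rng = np.random.default_rng(21)
        lncs, mrnas = [], []
        for i in range(500):
            s = int(rng.integers(0, 200_000))
            chrom = f"chr{int(rng.integers(1, 3))}"
            strand = "+" if rng.integers(2) else "-"
            tx = make_tx(f"x{i}", [(s, s + int(rng.integers(200, 3000)))],
                         strand=strand, seq_name=chrom)
            (lncs if i % 2 else mrnas).append(tx)
        got = {(p.lnc_id, p.mrna_id): (p.mode, p.signed_distance)
               for p in find_cis_pairs(lncs, mrnas)}
        want = {}
        for l in lncs:
            for m in mrnas:
                rel = oracle_cis(l, m)
                if rel:
                    want[(l.transcript_id, m.transcript_id)] = rel
        assert got == want

    def test_invariant_overlap_iff_distance_zero(self):
        with pytest.raises(ValidationError):
            TargetPair("l", "m", "cis_overlap", signed_distance=5)


class TestDuplexParams:
    def test_stack_table_complete_and_symmetric(self):
        assert len(P.stack) == 36
        for p1 in PAIR_NAMES:
            for p2 in PAIR_NAMES:
                assert P.stack[(p1, p2)] == P.stack[(_flip(p2), _flip(p1))]
                assert P.stack[(p1, p2)] < 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            DuplexParams(initiation=-1.0)
        with pytest.raises(ValidationError):
            DuplexParams(loop_slope=0.0)


class TestDuplexMfe:
    def test_no_complementary_pair(self):
        assert duplex_mfe("AAAA", "AAAA") is None

    def test_perfect_gc_helix_hand_sum(self):
        r = duplex_mfe("GGGGG", "CCCCC")
        want = P.initiation + 4 * P.stack[("GC", "GC")]
        assert r.mfe == pytest.approx(want)
        assert r.pairing == [(0, 4), (1, 3), (2, 2), (3, 1), (4, 0)]

    def test_terminal_penalty_counted_both_ends(self):
        r = duplex_mfe("AAAAA", "UUUUU")
        want = P.initiation + 4 * P.stack[("AU", "AU")] + 2 * P.terminal_penalty
        assert r.mfe == pytest.approx(want)

    def test_alphabet_violation(self):
        with pytest.raises(ValidationError):
            duplex_mfe("ACGT", "ACGU")  # T is DNA

    def test_exhaustive_sweep_gc_alphabet(self):
        # full sweep of all {G,C} sequence pairs up to length 5
        seqs = ["".join(s) for n in range(2, 6)
                for s in itertools.product("GC", repeat=n)]
        for x in seqs:
            for y in seqs:
                o = oracle_mfe(x, y)
                r = duplex_mfe(x, y)
                got = None if r is None else r.mfe
                if o is None:
                    assert got is None
                else:
                    assert got == pytest.approx(o, abs=1e-9), (x, y)

    def test_random_pairs_vs_oracle_4letter(self):
        rng = np.random.default_rng(8)
        for _ in range(250):
            n, m = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            x = "".join(rng.choice(list("ACGU"), n))
            y = "".join(rng.choice(list("ACGU"), m))
            o = oracle_mfe(x, y)
            r = duplex_mfe(x, y)
            got = None if r is None else r.mfe
            assert (o is None) == (got is None)
            if o is not None:
                assert got == pytest.approx(o, abs=1e-9), (x, y)

    def test_role_swap_symmetry(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            x = "".join(rng.choice(list("ACGU"), int(rng.integers(4, 30))))
            y = "".join(rng.choice(list("ACGU"), int(rng.integers(4, 30))))
            a, b = duplex_mfe(x, y, traceback=False), \
                duplex_mfe(y, x, traceback=False)
            if a is None:
                assert b is None
            else:
                assert a.mfe == pytest.approx(b.mfe, abs=1e-9)

    def test_flank_extension_never_raises_mfe(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            x = "".join(rng.choice(list("ACGU"), 12))
            y = "".join(rng.choice(list("ACGU"), 12))
            base = duplex_mfe(x, y, traceback=False)
            ext = duplex_mfe("A" + x, "A" + y, traceback=False)
            if base is not None:
                assert ext is not None and ext.mfe <= base.mfe + 1e-9

    def test_traceback_pairs_are_monotone_and_complementary(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            x = "".join(rng.choice(list("ACGU"), 40))
            y = "".join(rng.choice(list("ACGU"), 40))
            r = duplex_mfe(x, y)
            if r is None:
                continue
            assert len(r.pairing) >= 1
            for (i1, j1), (i2, j2) in zip(r.pairing, r.pairing[1:]):
                assert i2 > i1 and j2 < j1  # j is 5'->3' on the mRNA
            for i, j in r.pairing:
                assert (x[i], y[j]) in COMP


class TestTrans:
    def test_cis_pairs_excluded(self):
        lnc = {"l1": "GGGG" * 30}
        mrna = {"m1": "CCCC" * 30}
        cis = [TargetPair("l1", "m1", "cis_overlap", signed_distance=0)]
        assert find_trans_pairs(lnc, mrna, cis) == []

    def test_planted_complement_crosses_threshold(self):
        rng = np.random.default_rng(3)
        mrna = "".join(rng.choice(list("ACGU"), 800))
        lnc = "".join(rng.choice(list("ACGU"), 600))
        lnc = lnc[:200] + _rc_rna(mrna[300:340]) + lnc[240:]
        pairs = find_trans_pairs({"l": lnc}, {"m": mrna}, [])
        assert len(pairs) == 1
        assert pairs[0].mode == "trans" and pairs[0].mfe < -30.0

    def test_prefilter_agrees_with_full_dp_on_planted(self):
        rng = np.random.default_rng(4)
        mrna = "".join(rng.choice(list("ACGU"), 300))
        lnc = "".join(rng.choice(list("ACGU"), 250))
        lnc = lnc[:100] + _rc_rna(mrna[100:140]) + lnc[140:]
        with_pf = find_trans_pairs({"l": lnc}, {"m": mrna}, [], prefilter=True)
        without = find_trans_pairs({"l": lnc}, {"m": mrna}, [], prefilter=False)
        assert [p.lnc_id for p in with_pf] == [p.lnc_id for p in without] == ["l"]
        # windowed MFE can only be an upper bound on the full-DP MFE
        assert with_pf[0].mfe >= without[0].mfe - 1e-9

    def test_random_pairs_rarely_cross_threshold(self):
        rng = np.random.default_rng(6)
        lncs = {f"l{i}": "".join(rng.choice(list("ACGU"), 500))
                for i in range(5)}
        mrnas = {f"m{i}": "".join(rng.choice(list("ACGU"), 500))
                 for i in range(5)}
        pairs = find_trans_pairs(lncs, mrnas, [])
        assert len(pairs) <= 3  # empirical FP characterisation, not exact
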