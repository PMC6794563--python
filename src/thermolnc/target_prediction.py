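"""Cis and trans target prediction for DE lncRNAs.

Cis pairing is purely positional: a lncRNA and an mRNA on the same
sequence are paired when their genomic spans overlap (or touch), or when
the gap between the nearest span edges is within 10 kb on the mRNA's
upstream side / 20 kb on its downstream side.

Trans pairing scores intermolecular RNA–RNA hybridisation with a
nearest-neighbour duplex minimum-free-energy dynamic program (no
intramolecular structure), keeping pairs whose MFE is strictly below
-30 kcal/mol.  The embedded stack table is Turner-2004-like; the package
claims the decision rule, not numeric identity with any external tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError
from .formats_io import TranscriptModel

PAIR_NAMES = ("AU", "UA", "CG", "GC", "GU", "UG")
_PAIR_INDEX = {p: i for i, p in enumerate(PAIR_NAMES)}
_WOBBLY = {"AU", "UA", "GU", "UG"}  # pairs carrying the terminal penalty
_BASES = "ACGU"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}


def _flip(pair: str) -> str:
    return pair[::-1]


# Stack free energies, kcal/mol, for 5'-p1 p2-3' on the lncRNA strand.
# Watson-Crick core follows Turner-style values; GU entries are
# approximate.  The full 36-entry table is generated under the symmetry
# stack(p1, p2) == stack(flip(p2), flip(p1)).
_STACK_SEED: dict[tuple[str, str], float] = {
    ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("AU", "CG"): -2.24,
    ("AU", "GC"): -2.08, ("AU", "GU"): -0.55, ("AU", "UG"): -1.36,
    ("UA", "AU"): -1.33, ("UA", "UA"): -0.93, ("UA", "CG"): -2.35,
    ("UA", "GC"): -2.11, ("UA", "GU"): -1.27, ("UA", "UG"): -1.00,
    ("CG", "CG"): -3.26, ("CG", "GC"): -2.36, ("CG", "GU"): -1.41,
    ("CG", "UG"): -2.11, ("GC", "CG"): -3.42, ("GC", "GU"): -2.51,
    ("GC", "UG"): -1.53, ("GU", "GU"): -0.50, ("GU", "UG"): -0.30,
    ("UG", "GU"): -0.60,
}


def _build_stack_table() -> dict[tuple[str, str], float]:
    table = dict(_STACK_SEED)
    for (p1, p2), v in _STACK_SEED.items():
        key = (_flip(p2), _flip(p1))
        if key in table and abs(table[key] - v) > 1e-9:
            raise ValidationError(f"stack table symmetry conflict at {key}")
        table[key] = v
    missing = [(p1, p2) for p1 in PAIR_NAMES for p2 in PAIR_NAMES
               if (p1, p2) not in table]
    if missing:
        raise ValidationError(f"stack table incomplete: {missing}")
    return table


@dataclass
class DuplexParams:
    """Nearest-neighbour duplex energy model parameters."""

    stack: dict[tuple[str, str], float] = field(default_factory=_build_stack_table)
    initiation: float = 4.09
    terminal_penalty: float = 0.45  # per AU/GU helix end
    loop_base: float = 5.0
    loop_slope: float = 0.8  # per unpaired base
    max_loop: int = 15  # unpaired bases allowed per side between pairs

    def __post_init__(self):
        if len(self.stack) != 36 or not all(np.isfinite(v) for v in self.stack.values()):
            raise ValidationError("stack table must have 36 finite entries")
        if self.initiation <= 0:
            raise ValidationError("duplex initiation must be positive")
        if self.loop_slope <= 0:
            raise ValidationError("loop slope must be positive")

    def stack_array(self) -> np.ndarray:
        arr = np.empty((6, 6))
        for (p1, p2), v in self.stack.items():
            arr[_PAIR_INDEX[p1], _PAIR_INDEX[p2]] = v
        return arr


DEFAULT_DUPLEX_PARAMS = DuplexParams()


@dataclass
class TargetPair:
    lnc_id: str
    mrna_id: str
    mode: str  # cis_overlap | cis_window | trans
    signed_distance: int | None = None  # bp; negative = lncRNA upstream
    mfe: float | None = None  # kcal/mol

    def __post_init__(self):
        if self.mode not in ("cis_overlap", "cis_window", "trans"):
            raise ValidationError(f"bad mode {self.mode!r}")
        if self.mode == "cis_overlap" and self.signed_distance != 0:
            raise ValidationError("cis_overlap requires distance 0")


# ---------------------------------------------------------------------------
# cis pairing
# ---------------------------------------------------------------------------

def cis_relation(lnc: TranscriptModel, mrna: TranscriptModel,
                 up_kb: float = 10.0, down_kb: float = 20.0
                 ) -> tuple[str, int] | None:
    """Classify one (lnc, mrna) pair; None when not cis.

    Touching spans (gap 0) count as overlap.  The upstream/downstream side
    is taken relative to the mRNA's strand; the signed distance is negative
    when the lncRNA sits upstream.
    """
    if lnc.seq_name != mrna.seq_name:
        return None
    ls, le = lnc.span
    ms, me = mrna.span
    if ls < me and le > ms:
        return ("cis_overlap", 0)
    if le <= ms:  # lncRNA on the lower-coordinate side
        gap = ms - le
        upstream = mrna.strand == "+"
    else:
        gap = ls - me
        upstream = mrna.strand == "-"
    if gap == 0:
        return ("cis_overlap", 0)
    limit = up_kb * 1000 if upstream else down_kb * 1000
    if gap <= limit:
        return ("cis_window", -gap if upstream else gap)
    return None


def find_cis_pairs(de_lnc: Sequence[TranscriptModel],
                   de_mrna: Sequence[TranscriptModel],
                   up_kb: float = 10.0, down_kb: float = 20.0) -> list[TargetPair]:
    """All cis pairs between DE lncRNAs and DE mRNAs.

    Candidate mRNAs are pre-selected per sequence with a vectorised window
    query before the per-pair rule is applied.
    """
    by_seq: dict[str, list[TranscriptModel]] = {}
    for m in de_mrna:
        by_seq.setdefault(m.seq_name, []).append(m)
    starts = {s: np.array([m.start for m in ms]) for s, ms in by_seq.items()}
    ends = {s: np.array([m.end for m in ms]) for s, ms in by_seq.items()}
    reach = max(up_kb, down_kb) * 1000
    pairs: list[TargetPair] = []
    for lnc in de_lnc:
        ms = by_seq.get(lnc.seq_name)
        if not ms:
            continue
        ls, le = lnc.span
        cand = np.flatnonzero((starts[lnc.seq_name] <= le + reach)
                              & (ends[lnc.seq_name] >= ls - reach))
        for j in cand:
            rel = cis_relation(lnc, ms[j], up_kb, down_kb)
            if rel is not None:
                pairs.append(TargetPair(lnc.transcript_id, ms[j].transcript_id,
                                        rel[0], signed_distance=rel[1]))
    return pairs


# ---------------------------------------------------------------------------
# duplex MFE dynamic program
# ---------------------------------------------------------------------------

def _pair_codes(x: str, yr: str) -> np.ndarray:
    """6-valued pair code (or -1) for every (i, j); yr is the mRNA reversed."""
    lut = np.full((4, 4), -1, dtype=np.int8)
    for p, idx in _PAIR_INDEX.items():
        lut[_BASE_CODE[p[0]], _BASE_CODE[p[1]]] = idx
    xc = np.array([_BASE_CODE[c] for c in x], dtype=np.int8)
    yc = np.array([_BASE_CODE[c] for c in yr], dtype=np.int8)
    return lut[xc[:, None], yc[None, :]]


def _check_rna(seq: str, name: str) -> None:
    bad = set(seq) - set(_BASES)
    if bad:
        raise ValidationError(f"{name}: illegal RNA character(s) {sorted(bad)}")
    if len(seq) < 2:
        raise ValidationError(f"{name}: sequence must be >= 2 nt")


@dataclass
class DuplexResult:
    mfe: float
    pairing: list[tuple[int, int]]  # (lnc index, mRNA index), both 5'->3'


def duplex_mfe(lnc_seq: str, mrna_seq: str,
               params: DuplexParams | None = None,
               traceback: bool = True) -> DuplexResult | None:
    """Minimum free energy of an intermolecular duplex, or None.

    ``H(i, j)`` is the best energy of a duplex whose rightmost base pair is
    lnc position i with mRNA position j (j indexed 3'→5').  A duplex is
    opened for the initiation cost plus a terminal AU/GU penalty, extended
    by a stack when both strands advance by one, or by an affine loop of up
    to ``max_loop`` unpaired bases per side.  Closing adds the right-end
    terminal penalty.
    """
    params = params or DEFAULT_DUPLEX_PARAMS
    _check_rna(lnc_seq, "lnc_seq")
    _check_rna(mrna_seq, "mrna_seq")
    x = lnc_seq
    yr = mrna_seq[::-1]
    n, m = len(x), len(yr)
    pc = _pair_codes(x, yr)
    if (pc < 0).all():
        return None

    L = params.max_loop + 1
    INF = np.inf
    stackE = params.stack_array()
    term_vec = np.array([params.terminal_penalty if p in _WOBBLY else 0.0
                         for p in PAIR_NAMES])

    # gap-cost matrix indexed so that C[L-k, L-l] is the cost of advancing
    # k on the lnc and l on the mRNA; (1, 1) is the stack case, set to inf
    kk = L - np.arange(L)
    C = params.loop_base + params.loop_slope * ((kk[:, None] - 1) + (kk[None, :] - 1))
    C[L - 1, L - 1] = INF

    Hp = np.full((n + L, m + L), INF)
    for i in range(n):
        row_pc = pc[i]
        prev = Hp[i:i + L, :]
        sw = sliding_window_view(prev, L, axis=1)  # (L, m+1, L)
        gap_opt = np.min(sw + C[:, None, :], axis=(0, 2))[:m]
        if i > 0:
            prev_diag = Hp[i + L - 1, L - 1:L - 1 + m]
            prev_pc = np.concatenate(([np.int8(-1)], pc[i - 1, :m - 1]))
            valid = (prev_pc >= 0) & (row_pc >= 0)
            stack_opt = np.where(
                valid,
                prev_diag + stackE[np.maximum(prev_pc, 0), np.maximum(row_pc, 0)],
                INF)
        else:
            stack_opt = np.full(m, INF)
        open_opt = np.where(row_pc >= 0,
                            params.initiation + term_vec[np.maximum(row_pc, 0)],
                            INF)
        row = np.minimum(np.minimum(open_opt, stack_opt), gap_opt)
        row[row_pc < 0] = INF
        Hp[i + L, L:] = row

    H = Hp[L:, L:]
    close = np.where(pc >= 0, term_vec[np.maximum(pc, 0)], INF)
    total = H + close
    best = float(total.min())
    if not np.isfinite(best):
        return None

    pairing: list[tuple[int, int]] = []
    if traceback:
        i, j = np.unravel_index(int(np.argmin(total)), total.shape)
        tol = 1e-9
        while True:
            pairing.append((int(i), m - 1 - int(j)))
            here = H[i, j]
            p_here = int(pc[i, j])
            if abs(here - (params.initiation + term_vec[p_here])) <= tol:
                break
            moved = False
            if i >= 1 and j >= 1 and pc[i - 1, j - 1] >= 0:
                cand = H[i - 1, j - 1] + stackE[pc[i - 1, j - 1], p_here]
                if abs(here - cand) <= tol:
                    i, j = i - 1, j - 1
                    moved = True
            if not moved:
                for k in range(1, L + 1):
                    for l in range(1, L + 1):
                        if k == 1 and l == 1:
                            continue
                        if i - k < 0 or j - l < 0:
                            continue
                        cost = params.loop_base + params.loop_slope * (k - 1 + l - 1)
                        if abs(here - (H[i - k, j - l] + cost)) <= tol:
                            i, j = i - k, j - l
                            moved = True
                            break
                    if moved:
                        break
            if not moved:  # pragma: no cover - defensive
                raise ValidationError("duplex traceback failed")
        pairing.reverse()
    return DuplexResult(mfe=best, pairing=pairing)


# ---------------------------------------------------------------------------
# trans pairing
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGU", "UGCA")


def _rc_rna(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def find_trans_pairs(lnc_seqs: Mapping[str, str],
                     mrna_seqs: Mapping[str, str],
                     cis_pairs: Sequence[TargetPair],
                     params: DuplexParams | None = None,
                     energy_threshold: float = -30.0,
                     prefilter: bool = True,
                     seed_len: int = 10,
                     window: int = 100,
                     max_seeds: int = 4) -> list[TargetPair]:
    """Duplex-screen every non-cis DE lnc × DE mRNA pair.

    With the default seed-and-extend prefilter, an exact ``seed_len``-mer
    reverse-complement match is required before the DP runs on windows of
    ``window`` nt around each seed (capped at ``max_seeds`` seeds); the
    windowed MFE is an upper bound on duplex stability, so the prefilter
    can only lose borderline pairs, never invent them.
    """
    params = params or DEFAULT_DUPLEX_PARAMS
    cis_set = {(p.lnc_id, p.mrna_id) for p in cis_pairs}
    lnc_kmers: dict[str, dict[str, list[int]]] = {}
    if prefilter:
        for lid, seq in lnc_seqs.items():
            d: dict[str, list[int]] = {}
            for i in range(len(seq) - seed_len + 1):
                d.setdefault(seq[i:i + seed_len], []).append(i)
            lnc_kmers[lid] = d

    out: list[TargetPair] = []
    for lid, lseq in lnc_seqs.items():
        for mid, mseq in mrna_seqs.items():
            if (lid, mid) in cis_set:
                continue
            best: float | None = None
            if prefilter:
                kmers = lnc_kmers[lid]
                seeds: list[tuple[int, int]] = []
                for j in range(len(mseq) - seed_len + 1):
                    rc = _rc_rna(mseq[j:j + seed_len])
                    for i in kmers.get(rc, ()):
                        seeds.append((i, j))
                        break
                    if len(seeds) >= max_seeds:
                        break
                for i, j in seeds:
                    lw = lseq[max(0, i - window): i + seed_len + window]
                    mw = mseq[max(0, j - window): j + seed_len + window]
                    res = duplex_mfe(lw, mw, params, traceback=False)
                    if res is not None and (best is None or res.mfe < best):
                        best = res.mfe
                    if best is not None and best < energy_threshold:
                        break
            else:
                res = duplex_mfe(lseq, mseq, params, traceback=False)
                best = None if res is None else res.mfe
            if best is not None and best < energy_threshold:
                out.append(TargetPair(lid, mid, "trans", mfe=best))
    assert not {(p.lnc_id, p.mrna_id) for p in out} & cis_set
    return out
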