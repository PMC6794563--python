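"""FPKM quantification and differential-expression calling.

The test is a pooled-replicate conditional exact binomial: given the total
pooled count n = a + b of a transcript across the two conditions, under the
null a ~ Binomial(n, La / (La + Lb)) where La and Lb are the summed library
sizes.  The two-sided p-value sums the probabilities of all outcomes no
more likely than the observed one.  FDR control is Benjamini–Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .formats_io import ExpressionMatrix

# relative tolerance for "no more likely than observed" so that exact
# pmf ties survive floating-point noise
_TIE_RTOL = 1e-12


@dataclass
class DEResult:
    transcript_id: str
    mean_fpkm_control: float
    mean_fpkm_heat: float
    log2fc: float  # heat vs control
    p_value: float
    fdr: float
    status: str  # up | down | ns


def compute_fpkm(expr: ExpressionMatrix, lengths: Mapping[str, int]) -> pd.DataFrame:
    """FPKM(t, s) = 1e9 * counts(t, s) / (library_size(s) * length_nt(t))."""
    L = np.array([lengths[t] for t in expr.transcript_ids], dtype=float)
    if (L <= 0).any():
        raise ValidationError("zero or negative spliced length")
    lib = expr.library_size.astype(float)
    if (lib <= 0).any():
        raise ValidationError("zero library size")
    fpkm = 1e9 * expr.counts / (lib[None, :] * L[:, None])
    return pd.DataFrame(fpkm, index=expr.transcript_ids, columns=expr.sample_ids)


def de_exact_test(a: int, b: int, La: int, Lb: int) -> float:
    """Two-sided conditional exact binomial p-value for pooled counts."""
    if a < 0 or b < 0:
        raise ValidationError("counts must be non-negative")
    if La <= 0 or Lb <= 0:
        raise ValidationError("library sizes must be positive")
    n = a + b
    if n == 0:
        return 1.0
    pi = La / (La + Lb)
    pmf = stats.binom.pmf(np.arange(n + 1), n, pi)
    p = float(pmf[pmf <= pmf[a] * (1.0 + _TIE_RTOL)].sum())
    return min(max(p, 0.0), 1.0)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, mapped back to input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_de(expr: ExpressionMatrix, lengths: Mapping[str, int],
            condition_a: str = "control", condition_b: str = "heat",
            fdr_threshold: float = 0.001, min_abs_log2fc: float = 1.0,
            pseudocount: float = 0.01) -> list[DEResult]:
    """Call DE per transcript (condition_b vs condition_a).

    Thresholds are applied strictly: ``fdr < fdr_threshold`` and
    ``|log2fc| > min_abs_log2fc``.
    """
    cols_a = expr.samples_in(condition_a)
    cols_b = expr.samples_in(condition_b)
    if not cols_a or not cols_b:
        raise ValidationError("both conditions need >= 1 sample")
    fpkm = compute_fpkm(expr, lengths)
    La = int(expr.library_size[cols_a].sum())
    Lb = int(expr.library_size[cols_b].sum())
    a = expr.counts[:, cols_a].sum(axis=1)
    b = expr.counts[:, cols_b].sum(axis=1)
    mean_a = fpkm.iloc[:, cols_a].mean(axis=1).to_numpy()
    mean_b = fpkm.iloc[:, cols_b].mean(axis=1).to_numpy()
    lfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    pvals = np.array([de_exact_test(int(ai), int(bi), La, Lb)
                      for ai, bi in zip(a, b)])
    fdr = bh_adjust(pvals)
    results = []
    for i, tid in enumerate(expr.transcript_ids):
        if fdr[i] < fdr_threshold and lfc[i] > min_abs_log2fc:
            status = "up"
        elif fdr[i] < fdr_threshold and lfc[i] < -min_abs_log2fc:
            status = "down"
        else:
            status = "ns"
        results.append(DEResult(tid, float(mean_a[i]), float(mean_b[i]),
                                float(lfc[i]), float(pvals[i]), float(fdr[i]),
                                status))
    return results


def de_summary(results: Sequence[DEResult]) -> dict[str, int]:
    n_up = sum(1 for r in results if r.status == "up")
    n_down = sum(1 for r in results if r.status == "down")
    summary = {"n_tested": len(results), "n_up": n_up, "n_down": n_down,
               "n_de": n_up + n_down}
    if n_up + n_down + sum(1 for r in results if r.status == "ns") != len(results):
        raise ValidationError("DE status does not partition the tested set")
    return summary


def de_results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
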