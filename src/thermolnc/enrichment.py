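"""Hypergeometric pathway enrichment of DE target genes.

For each pathway with at least one DE target, the upper-tail
hypergeometric probability of drawing >= k annotated genes in a size-n DE
set from a background of N annotated genes (K in the pathway) is computed
exactly with integer arithmetic, then Benjamini–Hochberg adjusted across
pathways.  A pathway is significant when p_adj < 0.05 and it has at least
four DE target genes (both thresholds configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable

import pandas as pd

from .errors import ValidationError
from .expression_de import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    pathway_id: str
    pathway_name: str
    k: int  # DE target genes in pathway
    K: int  # annotated genes in pathway
    n: int  # DE target genes with any annotation
    N: int  # annotated background genes
    p_raw: float
    p_adj: float
    significant: bool


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed exactly."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValidationError(
            f"hypergeometric bounds violated: N={N}, K={K}, n={n}, k={k}")
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    p = float(Fraction(num, comb(N, n)))
    return min(max(p, 0.0), 1.0)


def enrich_pathways(de_targets: Iterable[str], pathway_map: pd.DataFrame,
                    p_adj_threshold: float = 0.05, min_genes: int = 4,
                    background: str = "annotated",
                    total_genes: int | None = None) -> list[EnrichmentRow]:
    """One EnrichmentRow per pathway containing >= 1 DE target gene.

    ``background='annotated'`` (default) restricts the universe to genes
    with >= 1 pathway annotation; ``background='all'`` uses ``total_genes``.
    DE targets absent from the map are excluded from n and logged.
    """
    if pathway_map.empty:
        raise ValidationError("pathway map is empty")
    targets = set(de_targets)
    annotated = set(pathway_map["gene_id"])
    if background == "annotated":
        N = len(annotated)
        n_set = targets & annotated
    elif background == "all":
        if total_genes is None or total_genes < len(annotated):
            raise ValidationError("background='all' needs total_genes >= annotated")
        N = total_genes
        n_set = targets
    else:
        raise ValidationError(f"unknown background {background!r}")
    dropped = targets - annotated
    if dropped and background == "annotated":
        log.info("enrich_pathways: %d DE target(s) without annotation dropped",
                 len(dropped))
    n = len(n_set)

    rows: list[EnrichmentRow] = []
    for (pid, pname), grp in pathway_map.groupby(["pathway_id", "pathway_name"],
                                                 sort=True):
        genes = set(grp["gene_id"])
        K = len(genes)
        k = len(genes & n_set)
        if k == 0:
            continue
        p = hypergeom_tail(N, K, n, k)
        rows.append(EnrichmentRow(pid, pname, k, K, n, N, p, 1.0, False))
    if not rows:
        return []
    adj = bh_adjust([r.p_raw for r in rows])
    for r, a in zip(rows, adj):
        r.p_adj = float(a)
        r.significant = bool(a < p_adj_threshold and r.k >= min_genes)
    rows.sort(key=lambda r: (r.p_adj, r.pathway_id))
    return rows


def enrichment_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
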