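"""Wilcoxon rank-sum DE, BH adjustment, hypergeometric enrichment, and the
two-caller consensus malignancy rule.

The rank-sum test uses the exact null distribution whenever the number of
group-label arrangements C(na+nb, na) is at most 10,000 and the combined
values are tie-free; otherwise it falls back to the tie-corrected,
continuity-corrected normal approximation. Log fold change is the natural
log ratio of group means of normalized expression with a small pseudocount.

Enrichment is the upper-tail hypergeometric P(X >= k) of drawing k term
genes in a query of size n from a universe of size N containing K term
genes, BH-adjusted across terms.

A cell's consensus malignancy label is ``malignant`` only when both
copy-number callers say malignant, ``nonmalignant`` only when both say
nonmalignant, and ``ambiguous`` otherwise (disagreement or an uncallable
verdict from either side).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

EXACT_MAX_ARRANGEMENTS = 10_000


class DiffExprError(ValueError):
    pass


@dataclass
class DEGResult:
    gene_id: str
    statistic: float
    log_fold_change: float
    p_value: float
    fdr: float
    direction: str  # "up" (higher in group A) or "down"


@dataclass
class EnrichmentResult:
    term_id: str
    overlap_count: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    fdr: float
    significant: bool


@dataclass
class ConsensusLabel:
    cell_id: str
    caller_a: str
    caller_b: str
    consensus: str


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DiffExprError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(U statistic of group A, two-sided p)."""
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        u = len(a) * len(b) / 2.0
        return u, 1.0
    no_ties = len(np.unique(combined)) == len(combined)
    exact_ok = no_ties and comb(len(a) + len(b), len(a)) <= EXACT_MAX_ARRANGEMENTS
    method = "exact" if exact_ok else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_deg(m: ExpressionMatrix, group_a, group_b,
                 pseudocount: float = 1e-9) -> list[DEGResult]:
    """Per-gene rank-sum DE between two disjoint cell groups."""
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise DiffExprError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(group_a) < 3 or len(group_b) < 3:
        raise DiffExprError("both groups need at least 3 cells")
    idx = {c: i for i, c in enumerate(m.cell_ids)}
    missing = [c for c in group_a + group_b if c not in idx]
    if missing:
        raise DiffExprError(f"unknown cell IDs: {missing[:5]}")
    ia = [idx[c] for c in group_a]
    ib = [idx[c] for c in group_b]
    X = m.dense()
    A, B = X[:, ia], X[:, ib]
    pvals, stats, lfcs = [], [], []
    for g in range(m.n_genes):
        u, p = _rank_sum_p(A[g], B[g])
        stats.append(u)
        pvals.append(p)
        lfcs.append(float(np.log((A[g].mean() + pseudocount) / (B[g].mean() + pseudocount))))
    fdrs = bh_adjust(pvals)
    return [
        DEGResult(
            gene_id=m.gene_ids[g],
            statistic=stats[g],
            log_fold_change=lfcs[g],
            p_value=pvals[g],
            fdr=float(fdrs[g]),
            direction="up" if lfcs[g] >= 0 else "down",
        )
        for g in range(m.n_genes)
    ]


def hypergeom_enrich(query, terms: dict[str, set], universe,
                     alpha: float = 0.05) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a query set against GMT terms."""
    universe = set(universe)
    if not universe:
        raise DiffExprError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside universe dropped: "
            f"{sorted(outside)[:10]}",
            stacklevel=2,
        )
        query &= universe
    N, n = len(universe), len(query)
    rows = []
    for term_id, genes in terms.items():
        term = set(genes) & universe
        K = len(term)
        k = len(term & query)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((term_id, k, K, p))
    fdrs = bh_adjust([r[3] for r in rows]) if rows else []
    return [
        EnrichmentResult(
            term_id=term_id,
            overlap_count=k,
            set_size=K,
            query_size=n,
            universe_size=N,
            p_value=p,
            fdr=float(fdr),
            significant=bool(fdr < alpha),
        )
        for (term_id, k, K, p), fdr in zip(rows, fdrs)
    ]


VALID_CALLS = ("malignant", "nonmalignant", "uncallable")


def consensus_malignancy(calls_a: pd.Series, calls_b: pd.Series) -> list[ConsensusLabel]:
    """Intersection rule over two caller outputs on the same cell universe."""
    ids_a, ids_b = set(calls_a.index), set(calls_b.index)
    if ids_a != ids_b:
        diff = sorted(ids_a ^ ids_b)
        raise DiffExprError(f"mismatched cell IDs between callers: {diff[:10]}")
    labels = []
    for cell_id in calls_a.index:
        a, b = str(calls_a[cell_id]), str(calls_b[cell_id])
        for v in (a, b):
            if v not in VALID_CALLS:
                raise DiffExprError(f"invalid call {v!r} for cell {cell_id}")
        if a == b == "malignant":
            consensus = "malignant"
        elif a == b == "nonmalignant":
            consensus = "nonmalignant"
        else:
            consensus = "ambiguous"
        labels.append(ConsensusLabel(cell_id=cell_id, caller_a=a, caller_b=b,
                                     consensus=consensus))
    return labels


def consensus_counts(labels: list[ConsensusLabel]) -> dict[str, int]:
    out = {"malignant": 0, "nonmalignant": 0, "ambiguous": 0}
    for lab in labels:
        out[lab.consensus] += 1
    return out
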