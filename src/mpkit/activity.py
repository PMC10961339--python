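"""Per-cell gene-set activity (AUCell-style) and Ro/e tissue preference.

AUCell is rank-based: for each cell, genes are ranked by expression
(highest first) and the score is the area under the recovery curve of the
gene set within the top ``top_fraction`` of ranks, normalized by the
maximal achievable area (all set genes at the very top). Because only
ranks enter, the score is invariant to any monotone transformation of a
cell's expression values. Expression ties — abundant in sparse count data,
where most genes are zero — are resolved by average ranks by default
(deterministic) or by a seeded random permutation.

Ro/e is the observed/expected ratio of a group×condition contingency
table: expected counts come from the table margins (row_total × col_total
/ grand_total), so a ratio above 1 marks preference of that group for that
condition. Per-cell chi-square contributions and Fisher exact tests on
2×2 collapses (group vs rest × condition vs rest) are reported alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import fisher_exact, rankdata

from .matrix import ExpressionMatrix


class ActivityError(ValueError):
    pass


@dataclass
class AUCellConfig:
    top_fraction: float = 0.05
    tie_rule: str = "average_rank"  # or "seeded_random"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ActivityError("top_fraction must be in (0, 1]")
        if self.tie_rule not in ("average_rank", "seeded_random"):
            raise ActivityError(f"unknown tie_rule {self.tie_rule!r}")


@dataclass
class ActivityScores:
    gene_set_name: str
    scores: pd.Series          # per-cell AUC in [0, 1], indexed by cell ID
    threshold_rank: int        # number of top ranks actually integrated


@dataclass
class RoETable:
    observed: pd.DataFrame
    expected: pd.DataFrame
    roe: pd.DataFrame
    chi2_contrib: pd.DataFrame
    fisher_p: pd.DataFrame     # per-cell 2x2 (group vs rest) Fisher exact p


def _ranks(X: np.ndarray, cfg: AUCellConfig) -> np.ndarray:
    """Per-cell descending ranks (1 = highest expression), genes×cells in."""
    if cfg.tie_rule == "average_rank":
        return rankdata(-X, method="average", axis=0)
    rng = np.random.default_rng(cfg.seed)
    jitter = rng.random(X.shape)
    # ordinal rank of (-value, jitter): random tie order, value order intact
    order = np.lexsort((jitter, -X), axis=0)
    ranks = np.empty_like(order, dtype=float)
    cols = np.arange(X.shape[1])[None, :]
    ranks[order, cols] = np.arange(1, X.shape[0] + 1)[:, None]
    return ranks


def aucell(m: ExpressionMatrix, gene_set, cfg: AUCellConfig | None = None,
           name: str = "gene_set") -> ActivityScores:
    """Score one gene set in every cell by recovery-curve AUC.

    The recovery curve counts, at each rank position x = 1..threshold, how
    many set genes have rank <= x; its area is the sum of those counts, and
    the score divides by the best possible area for a set of that size.
    """
    cfg = cfg or AUCellConfig()
    cfg.validate()
    genes = set(gene_set)
    present = [g for g in m.gene_ids if g in genes]
    missing = genes - set(present)
    if not present:
        raise ActivityError("gene set has no genes in the matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} gene-set genes absent from matrix: {sorted(missing)[:10]}...",
            stacklevel=2,
        )
    X = m.dense()
    ranks = _ranks(X, cfg)
    thr = math.ceil(cfg.top_fraction * m.n_genes)
    gidx = m.gene_index()
    hit_ranks = ranks[[gidx[g] for g in present], :]  # n_hits x n_cells
    # sum over x=1..thr of [rank <= x]  ==  max(0, thr - ceil(rank) + 1)
    contrib = np.clip(thr - np.ceil(hit_ranks) + 1, 0, None)
    auc = contrib.sum(axis=0)
    n_set = len(present)
    xs = np.arange(1, thr + 1)
    max_area = np.minimum(xs, n_set).sum()
    scores = pd.Series(auc / max_area, index=pd.Index(m.cell_ids, name="cell_id"),
                       name=name)
    return ActivityScores(gene_set_name=name, scores=scores, threshold_rank=thr)


def score_groups(scores: ActivityScores, annotations: pd.DataFrame,
                 group_keys, levels: dict[str, list] | None = None) -> pd.DataFrame:
    """Mean/median AUC and size per annotation group (e.g. cell type × stage)."""
    if isinstance(group_keys, str):
        group_keys = [group_keys]
    for key in group_keys:
        if key not in annotations.columns:
            raise ActivityError(f"unknown annotation key {key!r}")
    df = annotations.loc[scores.scores.index, list(group_keys)].copy()
    df["auc"] = scores.scores
    out = df.groupby(list(group_keys), observed=True)["auc"].agg(
        n="size", mean_auc="mean", median_auc="median"
    )
    if levels:
        idx = pd.MultiIndex.from_product(
            [levels.get(k, out.index.get_level_values(k).unique()) for k in group_keys],
            names=group_keys,
        ) if len(group_keys) > 1 else pd.Index(levels[group_keys[0]], name=group_keys[0])
        out = out.reindex(idx)
        out["n"] = out["n"].fillna(0).astype(int)
    return out.reset_index()


def roe(annotations: pd.DataFrame, row_key: str, col_key: str) -> RoETable:
    """Observed/expected cell-count ratios over two categorical labels."""
    for key in (row_key, col_key):
        if key not in annotations.columns:
            raise ActivityError(f"unknown annotation key {key!r}")
        if annotations[key].nunique() < 2:
            raise ActivityError(f"{key!r} needs at least 2 levels")
    observed = pd.crosstab(annotations[row_key], annotations[col_key])
    if (observed.sum(axis=1) == 0).any() or (observed.sum(axis=0) == 0).any():
        raise ActivityError("contingency table has a zero margin")
    total = observed.to_numpy().sum()
    row_tot = observed.sum(axis=1).to_numpy()[:, None]
    col_tot = observed.sum(axis=0).to_numpy()[None, :]
    expected = pd.DataFrame(
        row_tot * col_tot / total, index=observed.index, columns=observed.columns
    )
    roe_mat = observed / expected
    chi2 = (observed - expected) ** 2 / expected
    fisher = pd.DataFrame(index=observed.index, columns=observed.columns, dtype=float)
    obs = observed.to_numpy()
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            a = obs[i, j]
            b = row_tot[i, 0] - a
            c = col_tot[0, j] - a
            d = total - a - b - c
            fisher.iloc[i, j] = fisher_exact([[a, b], [c, d]])[1]
    return RoETable(observed=observed, expected=expected, roe=roe_mat,
                    chi2_contrib=chi2, fisher_p=fisher)
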