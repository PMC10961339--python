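"""Per-study NMF gene programs over a rank grid, and robustness selection.

Each study's log-normalized matrix is factorized at every rank in the grid
(default k = 4..9, which yields 4+5+6+7+8+9 = 39 programs per study). A
program is the top-``n_top_genes`` genes of one factor, ranked by NMF
coefficient. A program is *robust* when (a) a program from the same study
at a different rank shares at least ``intra_study_min_overlap_genes`` of
its top genes (default 35 of 50, i.e. 70%), and (b) some program from a
different study is more than ``cross_study_min_similarity`` similar
(default 0.2, measured as shared-top-gene fraction).

Matrix preparation before factorization: restrict to the most variable
genes, center each gene and clip negatives to zero — a non-negative
relative-expression representation in which factors capture co-varying
gene modules rather than mean expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .matrix import LOGNORM, ExpressionMatrix


class NMFError(ValueError):
    pass


@dataclass
class NMFConfig:
    ranks: list[int] = field(default_factory=lambda: [4, 5, 6, 7, 8, 9])
    n_top_genes: int = 50
    intra_study_min_overlap_genes: int = 35
    cross_study_min_similarity: float = 0.2
    cross_study_metric: str = "shared_fraction"  # or "jaccard"
    require_cross_study: bool = True
    n_variable_genes: int = 3000
    max_iter: int = 500
    tol: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if not self.ranks or any(k < 2 for k in self.ranks):
            raise NMFError("all ranks must be >= 2")
        if self.intra_study_min_overlap_genes > self.n_top_genes:
            raise NMFError("intra_study_min_overlap_genes must be <= n_top_genes")
        if not (0 < self.cross_study_min_similarity < 1):
            raise NMFError("cross_study_min_similarity must be in (0, 1)")
        if self.cross_study_metric not in ("shared_fraction", "jaccard"):
            raise NMFError(f"unknown cross_study_metric {self.cross_study_metric!r}")


@dataclass(frozen=True)
class GeneProgram:
    study_id: str
    rank_k: int
    factor_index: int
    top_genes: tuple[str, ...]
    coefficients: tuple[float, ...]

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.study_id, self.rank_k, self.factor_index)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.top_genes)


@dataclass
class RobustProgramSet:
    programs: list[GeneProgram]
    #: program key -> {"intra": [witness keys], "cross": [witness keys]}
    provenance: dict[tuple[str, int, int], dict[str, list[tuple[str, int, int]]]]


def top_genes(coefficients: np.ndarray, gene_ids: list[str], n: int) -> tuple[list[str], list[float]]:
    """The n genes with largest coefficients, descending; ties broken by gene ID."""
    if n > len(gene_ids):
        raise NMFError(f"requested {n} top genes from {len(gene_ids)} genes")
    order = sorted(range(len(gene_ids)), key=lambda i: (-coefficients[i], gene_ids[i]))
    sel = order[:n]
    return [gene_ids[i] for i in sel], [float(coefficients[i]) for i in sel]


def prepare_matrix(m: ExpressionMatrix, n_variable_genes: int = 3000):
    """Variable-gene, gene-centered, non-negative matrix for factorization.

    Returns (X of shape cells×genes, kept gene IDs).
    """
    if m.layer_state != LOGNORM:
        raise NMFError("NMF input must be log-normalized")
    X = m.dense()  # genes x cells
    if n_variable_genes and n_variable_genes < X.shape[0]:
        var = X.var(axis=1)
        keep = np.sort(np.argsort(-var, kind="stable")[:n_variable_genes])
    else:
        keep = np.arange(X.shape[0])
    Xv = X[keep]
    Xv = Xv - Xv.mean(axis=1, keepdims=True)
    np.clip(Xv, 0, None, out=Xv)
    genes = [m.gene_ids[i] for i in keep]
    return Xv.T, genes


def run_nmf_grid(m: ExpressionMatrix, cfg: NMFConfig | None = None) -> list[GeneProgram]:
    """Factorize one study at every rank in the grid; emit k programs per rank."""
    cfg = cfg or NMFConfig()
    cfg.validate()
    studies = set(m.annotations.get("study", ["?"]))
    if len(studies) > 1:
        raise NMFError(f"run_nmf_grid expects a single study, got {sorted(studies)}")
    study_id = next(iter(studies)) if "study" in m.annotations else "study"
    X, genes = prepare_matrix(m, cfg.n_variable_genes)
    n_cells, n_genes = X.shape
    programs: list[GeneProgram] = []
    for k in cfg.ranks:
        if k >= min(n_cells, n_genes):
            raise NMFError(f"rank {k} >= min(matrix dims) = {min(n_cells, n_genes)}")
        model = NMF(
            n_components=k,
            init="nndsvd",
            solver="cd",
            max_iter=cfg.max_iter,
            tol=cfg.tol,
            random_state=cfg.seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(X)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            warnings.warn(
                f"NMF at k={k} did not converge in {cfg.max_iter} iterations "
                f"(reconstruction error {model.reconstruction_err_:.4g}); "
                "programs emitted anyway",
                stacklevel=2,
            )
        H = model.components_  # k x genes
        for f in range(k):
            tg, coefs = top_genes(H[f], genes, min(cfg.n_top_genes, len(genes)))
            programs.append(
                GeneProgram(
                    study_id=study_id, rank_k=k, factor_index=f,
                    top_genes=tuple(tg), coefficients=tuple(coefs),
                )
            )
    return programs


def _similarity(a: GeneProgram, b: GeneProgram, cfg: NMFConfig) -> float:
    inter = len(a.gene_set & b.gene_set)
    if cfg.cross_study_metric == "jaccard":
        union = len(a.gene_set | b.gene_set)
        return inter / union if union else 0.0
    return inter / cfg.n_top_genes


def select_robust(programs: list[GeneProgram], cfg: NMFConfig | None = None) -> RobustProgramSet:
    """Keep programs reproduced at another rank in-study and echoed in another study."""
    cfg = cfg or NMFConfig()
    cfg.validate()
    studies = {p.study_id for p in programs}
    if cfg.require_cross_study and len(studies) < 2:
        raise NMFError(
            "cross-study robustness requires >= 2 studies; "
            "set require_cross_study=False for a single study"
        )
    kept: list[GeneProgram] = []
    provenance: dict[tuple, dict[str, list[tuple]]] = {}
    for p in programs:
        intra = [
            q.key
            for q in programs
            if q.study_id == p.study_id
            and q.rank_k != p.rank_k
            and len(p.gene_set & q.gene_set) >= cfg.intra_study_min_overlap_genes
        ]
        if not intra:
            continue
        cross: list[tuple] = []
        if cfg.require_cross_study:
            cross = [
                q.key
                for q in programs
                if q.study_id != p.study_id
                and _similarity(p, q, cfg) > cfg.cross_study_min_similarity
            ]
            if not cross:
                continue
        kept.append(p)
        provenance[p.key] = {"intra": intra, "cross": cross}
    return RobustProgramSet(programs=kept, provenance=provenance)
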