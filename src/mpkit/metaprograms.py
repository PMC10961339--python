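"""Founder-based clustering of robust NMF programs into Meta Programs.

Clustering is greedy agglomeration on top-gene overlap. The founder of a
new cluster is the unclustered program with the greatest total top-gene
intersection with all other unclustered programs. The cluster then grows
by repeatedly admitting the unclustered program with maximal overlap to the
cluster's current consensus gene set, as long as that overlap exceeds
``min_cluster_overlap_genes`` (strictly more than 10 genes by default).
When no program can join, the cluster closes, its consensus is frozen as
the Meta Program's gene set — the ``mp_gene_count`` genes most commonly
shared among member programs — and the process repeats on the remainder.

Clusters smaller than ``min_programs_per_mp`` are not meta-programs; their
members land on an ``unassigned`` list, so every robust program is in
exactly one MP or unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nmf import GeneProgram, RobustProgramSet


class MPError(ValueError):
    pass


@dataclass
class MPConfig:
    #: a candidate joins a cluster only with strictly more than this many shared genes
    min_cluster_overlap_genes: int = 10
    mp_gene_count: int = 50
    min_programs_per_mp: int = 2

    def validate(self) -> None:
        if self.min_cluster_overlap_genes >= self.mp_gene_count:
            raise MPError("min_cluster_overlap_genes must be < mp_gene_count")
        if self.min_programs_per_mp < 1:
            raise MPError("min_programs_per_mp must be >= 1")


@dataclass
class MetaProgram:
    mp_id: str
    founder: GeneProgram
    members: list[GeneProgram]
    mp_genes: list[str]
    sharing_counts: list[int]
    truncated: bool = False  # True when fewer than mp_gene_count genes existed


@dataclass
class MPOverlap:
    mp_a: str
    mp_b: str
    shared_genes: frozenset[str]
    overlap_count: int
    overlap_fraction: float


def jaccard(a, b) -> float:
    """|A∩B| / |A∪B|; 0 for two empty sets by convention."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def mp_genes(members: list[GeneProgram], mp_gene_count: int = 50) -> tuple[list[str], list[int], bool]:
    """Consensus gene list: ranked by how many members share each gene.

    Ties are broken by the gene's mean rank within the member programs that
    contain it (better average placement first), then lexicographically by
    gene ID, so the list is deterministic.
    """
    if not members:
        raise MPError("mp_genes requires at least one member program")
    counts: dict[str, int] = {}
    rank_sums: dict[str, float] = {}
    for prog in members:
        for r, g in enumerate(prog.top_genes):
            counts[g] = counts.get(g, 0) + 1
            rank_sums[g] = rank_sums.get(g, 0.0) + r
    ordered = sorted(
        counts,
        key=lambda g: (-counts[g], rank_sums[g] / counts[g], g),
    )
    truncated = len(ordered) < mp_gene_count
    sel = ordered[:mp_gene_count]
    return sel, [counts[g] for g in sel], truncated


def _overlap(genes_a, genes_b) -> int:
    return len(set(genes_a) & set(genes_b))


def cluster_programs(rps: RobustProgramSet, cfg: MPConfig | None = None) -> tuple[list[MetaProgram], list[GeneProgram]]:
    """Greedy founder-based agglomeration; returns (meta-programs, unassigned)."""
    cfg = cfg or MPConfig()
    cfg.validate()
    unclustered = list(rps.programs)
    mps: list[MetaProgram] = []
    unassigned: list[GeneProgram] = []
    counter = 0
    while unclustered:
        # founder: greatest total overlap with all other unclustered programs;
        # ties go to the lexicographically smallest (study, rank, factor) key
        totals = [
            sum(_overlap(p.top_genes, q.top_genes) for j, q in enumerate(unclustered) if j != i)
            for i, p in enumerate(unclustered)
        ]
        founder_i = min(range(len(unclustered)), key=lambda i: (-totals[i], unclustered[i].key))
        founder = unclustered.pop(founder_i)
        members = [founder]
        consensus, _, _ = mp_genes(members, cfg.mp_gene_count)
        while unclustered:
            best_i = min(
                range(len(unclustered)),
                key=lambda i: (-_overlap(unclustered[i].top_genes, consensus), unclustered[i].key),
            )
            if _overlap(unclustered[best_i].top_genes, consensus) <= cfg.min_cluster_overlap_genes:
                break
            members.append(unclustered.pop(best_i))
            consensus, _, _ = mp_genes(members, cfg.mp_gene_count)
        if len(members) >= cfg.min_programs_per_mp:
            counter += 1
            genes, counts, truncated = mp_genes(members, cfg.mp_gene_count)
            mps.append(
                MetaProgram(
                    mp_id=f"MP{counter}",
                    founder=founder,
                    members=members,
                    mp_genes=genes,
                    sharing_counts=counts,
                    truncated=truncated,
                )
            )
        else:
            unassigned.extend(members)
    return mps, unassigned


def compare_mps(a: MetaProgram, b: MetaProgram) -> MPOverlap:
    """Shared-gene count and fraction (of the MP gene-set size) of two MPs."""
    if len(a.mp_genes) != len(b.mp_genes):
        raise MPError(
            f"meta-programs use different gene counts: {len(a.mp_genes)} vs {len(b.mp_genes)}"
        )
    shared = frozenset(a.mp_genes) & frozenset(b.mp_genes)
    n = len(a.mp_genes)
    return MPOverlap(
        mp_a=a.mp_id,
        mp_b=b.mp_id,
        shared_genes=shared,
        overlap_count=len(shared),
        overlap_fraction=len(shared) / n if n else 0.0,
    )
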