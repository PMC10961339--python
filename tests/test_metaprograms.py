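"""Founder-based meta-program clustering and cross-entity comparison."""

import pytest

from mpkit.metaprograms import (
    MPConfig,
    MPError,
    cluster_programs,
    compare_mps,
    jaccard,
    mp_genes,
)
from mpkit.nmf import GeneProgram, RobustProgramSet


def program(study, k, f, genes):
    genes = list(genes)
    return GeneProgram(
        study_id=study, rank_k=k, factor_index=f,
        top_genes=tuple(genes),
        coefficients=tuple(float(len(genes) - i) for i in range(len(genes))),
    )


def genes(prefix, n, start=0):
    return [f"{prefix}{i:03d}" for i in range(start, start + n)]


class TestJaccard:
    def test_identity(self):
        s = genes("a", 50)
        assert jaccard(s, s) == 1.0

    def test_disjoint(self):
        assert jaccard(genes("a", 10), genes("b", 10)) == 0.0

    def test_34_of_50_shared(self):
        a = genes("s", 34) + genes("a", 16)
        b = genes("s", 34) + genes("b", 16)
        assert jaccard(a, b) == pytest.approx(34 / 66)

    def test_both_empty_is_zero_by_convention(self):
        assert jaccard([], []) == 0.0


class TestMpGenes:
    def test_frequency_ranks_above_rarity(self):
        g_shared = genes("s", 5)
        members = [
            program("s1", 4, 0, g_shared + genes("a", 5)),
            program("s1", 5, 0, g_shared + genes("b", 5)),
            program("s2", 4, 0, g_shared + genes("c", 5)),
        ]
        ranked, counts, _ = mp_genes(members, mp_gene_count=5)
        assert set(ranked) == set(g_shared)
        assert counts == [3, 3, 3, 3, 3]

    def test_single_member_returns_its_top_list(self):
        p = program("s1", 4, 0, genes("a", 10))
        ranked, counts, truncated = mp_genes([p], mp_gene_count=10)
        assert ranked == list(p.top_genes)
        assert counts == [1] * 10
        assert not truncated

    def test_tie_at_cutoff_is_deterministic(self):
        members = [
            program("s1", 4, 0, genes("a", 6)),
            program("s1", 5, 0, genes("a", 3) + genes("b", 3)),
        ]
        first, _, _ = mp_genes(members, mp_gene_count=4)
        second, _, _ = mp_genes(members, mp_gene_count=4)
        assert first == second

    def test_short_supply_flags_truncation(self):
        p = program("s1", 4, 0, genes("a", 5))
        ranked, _, truncated = mp_genes([p], mp_gene_count=50)
        assert truncated and len(ranked) == 5


def rps(programs):
    return RobustProgramSet(programs=programs, provenance={})


class TestClusterPrograms:
    def test_two_disjoint_pairs_give_two_mps(self):
        """Block structure: within-pair overlap 40, across-pair overlap 0."""
        pair1 = [
            program("s1", 4, 0, genes("a", 40) + genes("p", 10)),
            program("s2", 5, 0, genes("a", 40) + genes("q", 10)),
        ]
        pair2 = [
            program("s1", 5, 1, genes("b", 40) + genes("r", 10)),
            program("s2", 4, 1, genes("b", 40) + genes("t", 10)),
        ]
        mps, unassigned = cluster_programs(rps(pair1 + pair2),
                                           MPConfig(mp_gene_count=50))
        assert len(mps) == 2 and not unassigned
        member_sets = {frozenset(p.key for p in mp.members) for mp in mps}
        assert member_sets == {
            frozenset(p.key for p in pair1),
            frozenset(p.key for p in pair2),
        }

    def test_overlap_threshold_is_strictly_greater_than_10(self):
        """Pairwise overlaps of exactly 10 genes never cluster."""
        a = program("s1", 4, 0, genes("s", 10) + genes("a", 40))
        b = program("s2", 5, 0, genes("s", 10) + genes("b", 40))
        mps, unassigned = cluster_programs(rps([a, b]), MPConfig(mp_gene_count=50))
        assert mps == []
        assert {p.key for p in unassigned} == {a.key, b.key}

    def test_partition_property(self):
        """Every program lands in exactly one MP or in the unassigned list."""
        programs = [
            program("s1", 4, 0, genes("a", 40) + genes("p", 10)),
            program("s2", 5, 0, genes("a", 40) + genes("q", 10)),
            program("s3", 6, 0, genes("a", 35) + genes("r", 15)),
            program("s1", 5, 1, genes("z", 50)),
        ]
        mps, unassigned = cluster_programs(rps(programs), MPConfig(mp_gene_count=50))
        seen = [p.key for mp in mps for p in mp.members] + [p.key for p in unassigned]
        assert sorted(seen) == sorted(p.key for p in programs)

    def test_founder_had_maximal_total_overlap(self):
        """Recompute the founder criterion on the first cluster."""
        programs = [
            program("s1", 4, 0, genes("a", 40) + genes("p", 10)),
            program("s2", 5, 0, genes("a", 40) + genes("q", 10)),
            program("s3", 6, 0, genes("a", 30) + genes("b", 20)),
            program("s4", 7, 0, genes("c", 50)),
        ]
        mps, _ = cluster_programs(rps(programs), MPConfig(mp_gene_count=50))
        totals = {
            p.key: sum(len(set(p.top_genes) & set(q.top_genes))
                       for q in programs if q.key != p.key)
            for p in programs
        }
        assert totals[mps[0].founder.key] == max(totals.values())

    def test_matches_exhaustive_greedy_oracle_on_blocks(self):
        """On block-diagonal overlap structure every greedy founder ordering
        yields the same partition, so the output must equal the blocks."""
        blocks = {
            "A": [program("s1", 4, 0, genes("a", 30) + genes("p", 20)),
                  program("s2", 5, 0, genes("a", 30) + genes("q", 20)),
                  program("s3", 6, 0, genes("a", 30) + genes("r", 20))],
            "B": [program("s1", 5, 1, genes("b", 30) + genes("u", 20)),
                  program("s2", 6, 1, genes("b", 30) + genes("v", 20))],
        }
        all_programs = blocks["A"] + blocks["B"]
        mps, unassigned = cluster_programs(rps(all_programs),
                                           MPConfig(mp_gene_count=50))
        assert not unassigned and len(mps) == 2
        found = {frozenset(p.key for p in mp.members) for mp in mps}
        expected = {frozenset(p.key for p in progs) for progs in blocks.values()}
        assert found == expected

    def test_empty_input_gives_empty_output(self):
        mps, unassigned = cluster_programs(rps([]), MPConfig())
        assert mps == [] and unassigned == []

    def test_singleton_clusters_respect_min_members(self):
        lone = program("s1", 4, 0, genes("z", 50))
        mps, unassigned = cluster_programs(
            rps([lone]), MPConfig(min_programs_per_mp=1, mp_gene_count=50))
        assert len(mps) == 1 and unassigned == []


class TestCompareMps:
    def make_mp(self, mp_id, gene_list):
        p = program("s1", 4, 0, gene_list)
        return cluster_programs(
            rps([p]), MPConfig(min_programs_per_mp=1, mp_gene_count=len(gene_list))
        )[0][0]

    def test_identical_mps_fraction_one(self):
        a = self.make_mp("MP1", genes("a", 50))
        b = self.make_mp("MP1", genes("a", 50))
        assert compare_mps(a, b).overlap_fraction == 1.0

    def test_disjoint_mps_share_nothing(self):
        a = self.make_mp("MP1", genes("a", 50))
        b = self.make_mp("MP1", genes("b", 50))
        ov = compare_mps(a, b)
        assert ov.overlap_count == 0 and ov.overlap_fraction == 0.0

    def test_34_of_50_is_68_percent(self):
        shared = genes("s", 34)
        a = self.make_mp("MP1", shared + genes("a", 16))
        b = self.make_mp("MP2", shared + genes("b", 16))
        ov = compare_mps(a, b)
        assert ov.overlap_count == 34
        assert ov.overlap_fraction == pytest.approx(0.68)

    def test_symmetry(self):
        a = self.make_mp("MP1", genes("s", 20) + genes("a", 30))
        b = self.make_mp("MP2", genes("s", 20) + genes("b", 30))
        assert compare_mps(a, b).overlap_count == compare_mps(b, a).overlap_count

    def test_mismatched_gene_counts_error(self):
        a = self.make_mp("MP1", genes("a", 50))
        b = self.make_mp("MP2", genes("b", 40))
        with pytest.raises(MPError, match="different gene counts"):
            compare_mps(a, b)
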