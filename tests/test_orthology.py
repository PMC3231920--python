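import itertools

import numpy as np
import pytest

import cladecore as cc
from cladecore.errors import EmptyInputError, IncompleteGraphError
from cladecore.orthology import (
    OrthologEdge,
    OrthologGraph,
    OrthologyThresholds,
    call_orthologs,
    core_proteins,
)
from cladecore.pairwise_align import AlignmentResult, BestHitTable, best_hits
from conftest import random_protein


def _proteome(seqs, gid):
    p = cc.Proteome(genome_id=gid)
    for i, s in enumerate(seqs):
        tag = f"{gid}{i:03d}"
        p.proteins[tag] = cc.SequenceRecord(id=tag, residues=s, alphabet="protein")
    return p


def _hit(q, s, identity, cov=1.0, score=100):
    return AlignmentResult(
        query=q, subject=s, score=score, identity=identity, aln_len=100,
        q_cov=cov, s_cov=cov, q_range=(1, 100), s_range=(1, 100),
    )


class TestCallOrthologs:
    def test_identical_proteomes_give_one_edge_each(self, scheme):
        rng = np.random.default_rng(0)
        seqs = [random_protein(rng, 80) for _ in range(10)]
        pa, pb = _proteome(seqs, "A"), _proteome(seqs, "B")
        edges = call_orthologs(best_hits(pa, pb, scheme), best_hits(pb, pa, scheme))
        assert len(edges) == 10
        for e in edges:
            assert e.tag_a[1:] == e.tag_b[1:]

    def test_threshold_boundary_rejection(self):
        ab = BestHitTable("A", "B", {"A000": [_hit("A000", "B000", 0.29, 0.95)]})
        ba = BestHitTable("B", "A", {"B000": [_hit("B000", "A000", 0.29, 0.95)]})
        assert call_orthologs(ab, ba) == []
        ab2 = BestHitTable("A", "B", {"A000": [_hit("A000", "B000", 0.30, 0.80)]})
        ba2 = BestHitTable("B", "A", {"B000": [_hit("B000", "A000", 0.30, 0.80)]})
        assert len(call_orthologs(ab2, ba2)) == 1

    def test_both_coverages_must_pass(self):
        hit = _hit("A000", "B000", 0.9)
        hit.s_cov = 0.5
        ab = BestHitTable("A", "B", {"A000": [hit]})
        ba = BestHitTable("B", "A", {"B000": [_hit("B000", "A000", 0.9)]})
        assert call_orthologs(ab, ba) == []

    def test_mismatched_pair_errors(self):
        ab = BestHitTable("A", "B")
        cb = BestHitTable("C", "B")
        with pytest.raises(ValueError):
            call_orthologs(ab, cb)

    def test_any_hit_mode_relaxes_reciprocity(self):
        # B000 is A000's 2nd-best hit; best-hit mode drops it, any-hit keeps it
        ab = BestHitTable(
            "A", "B",
            {"A000": [_hit("A000", "B001", 0.9, score=200), _hit("A000", "B000", 0.8)]},
        )
        ba = BestHitTable("B", "A", {"B000": [_hit("B000", "A000", 0.8)]})
        assert call_orthologs(ab, ba) == []
        th = OrthologyThresholds(reciprocity="any_hit")
        edges = call_orthologs(ab, ba, th)
        assert [(e.tag_a, e.tag_b) for e in edges] == [("A000", "B000")]


def _random_graph(rng, n_genomes, n_prot, edge_p):
    """A random multipartite threshold-passing graph built directly."""
    genomes = [f"g{i}" for i in range(n_genomes)]
    graph = OrthologGraph(
        genomes=genomes,
        proteins={g: {f"{g}p{j}" for j in range(n_prot)} for g in genomes},
    )
    for ga, gb in itertools.combinations(genomes, 2):
        edges = []
        for ta in sorted(graph.proteins[ga]):
            for tb in sorted(graph.proteins[gb]):
                if rng.random() < edge_p:
                    ident = float(rng.uniform(0.3, 1.0))
                    edges.append(
                        OrthologEdge(ga, ta, gb, tb, ident, 1.0, 1.0)
                    )
        graph.add_pair(ga, gb, edges)
    return graph


def _oracle_core(graph):
    """Exhaustive one-per-genome clique enumeration straight from the edge
    list, with the same conflict rule (keep highest mean identity)."""
    genomes = graph.genomes
    edge_ident = {}
    for e in graph.edges:
        (ga, ta), (gb, tb) = e.endpoints()
        edge_ident[((ga, ta), (gb, tb))] = e.identity
        edge_ident[((gb, tb), (ga, ta))] = e.identity
    members = [sorted((g, t) for t in graph.proteins[g]) for g in genomes]
    cliques = []
    for combo in itertools.product(*members):
        idents = []
        ok = True
        for x, y in itertools.combinations(combo, 2):
            if (x, y) not in edge_ident:
                ok = False
                break
            idents.append(edge_ident[(x, y)])
        if ok:
            cliques.append((dict(combo), sum(idents) / len(idents)))
    cliques.sort(key=lambda c: (-c[1], tuple(sorted(c[0].items()))))
    used, families = set(), []
    for fam, _ in cliques:
        m = set(fam.items())
        if m & used:
            continue
        used |= m
        families.append(fam)
    return sorted(families, key=lambda f: tuple(sorted(f.items())))


class TestCoreProteins:
    def test_three_identical_proteomes_all_core(self, scheme):
        rng = np.random.default_rng(1)
        seqs = [random_protein(rng, 80) for _ in range(8)]
        prots = {g: _proteome(seqs, g) for g in "ABC"}
        graph = OrthologGraph.build(prots, scheme=scheme)
        core = core_proteins(graph, prots)
        assert len(core) == 8

    def test_broken_pair_breaks_clique(self):
        graph = OrthologGraph(genomes=["A", "B", "C"],
                              proteins={g: {f"{g}0"} for g in "ABC"})
        graph.add_pair("A", "B", [OrthologEdge("A", "A0", "B", "B0", 0.9, 1, 1)])
        graph.add_pair("B", "C", [OrthologEdge("B", "B0", "C", "C0", 0.9, 1, 1)])
        graph.add_pair("A", "C", [])  # A-C comparison computed but empty
        assert len(core_proteins(graph)) == 0

    def test_missing_pairwise_comparison_errors(self):
        graph = OrthologGraph(genomes=["A", "B", "C"],
                              proteins={g: {f"{g}0"} for g in "ABC"})
        graph.add_pair("A", "B", [])
        with pytest.raises(IncompleteGraphError):
            core_proteins(graph)

    @pytest.mark.parametrize("n_genomes", [3, 4])
    def test_matches_exhaustive_oracle(self, n_genomes):
        rng = np.random.default_rng(42 + n_genomes)
        for _ in range(25):
            graph = _random_graph(rng, n_genomes, n_prot=8, edge_p=0.15)
            got = sorted(
                core_proteins(graph).families,
                key=lambda f: tuple(sorted(f.items())),
            )
            assert got == _oracle_core(graph)

    def test_adding_a_genome_never_grows_the_core(self, clade_sim, clade_graph):
        prots = {g: s.proteome for g, s in clade_sim.genomes.items()}
        sub = dict(list(prots.items())[:2])
        graph2 = OrthologGraph(
            genomes=list(sub),
            proteins={g: set(p.proteins) for g, p in sub.items()},
        )
        ga, gb = list(sub)
        pair_edges = [
            e for e in clade_graph.edges
            if {e.genome_a, e.genome_b} == {ga, gb}
        ]
        graph2.add_pair(ga, gb, pair_edges)
        assert len(core_proteins(clade_graph)) <= len(core_proteins(graph2))


class TestUniqueAndFraction:
    def test_identical_proteomes_nothing_unique(self, scheme):
        rng = np.random.default_rng(2)
        seqs = [random_protein(rng, 80) for _ in range(6)]
        prots = {g: _proteome(seqs, g) for g in "AB"}
        graph = OrthologGraph.build(prots, scheme=scheme)
        assert len(cc.unique_proteins("A", graph)) == 0
        assert cc.ortholog_fraction("A", graph) == 100.0

    def test_disjoint_proteomes_everything_unique(self, scheme):
        rng = np.random.default_rng(3)
        prots = {
            "A": _proteome([random_protein(rng, 60) for _ in range(6)], "A"),
            "B": _proteome([random_protein(rng, 60) for _ in range(6)], "B"),
        }
        graph = OrthologGraph.build(prots, scheme=scheme)
        assert len(cc.unique_proteins("A", graph)) == 6
        assert cc.ortholog_fraction("A", graph) == 0.0

    def test_unique_plus_connected_partitions_proteome(self, clade_graph):
        for g in clade_graph.genomes:
            uniq = cc.unique_proteins(g, clade_graph)
            with_edge = sum(
                1 for t in clade_graph.proteins[g] if clade_graph.degree(g, t) > 0
            )
            assert len(uniq) + with_edge == len(clade_graph.proteins[g])

    def test_planted_fraction_recovered(self, scheme):
        """With 60% of genes kept as orthologs and the rest replaced by
        novel genes, the measured ortholog fraction lands within 2 points."""
        rng = np.random.default_rng(4)
        shared = [random_protein(rng, 100) for _ in range(30)]
        novel_a = [random_protein(rng, 100) for _ in range(20)]
        novel_b = [random_protein(rng, 100) for _ in range(20)]
        prots = {
            "A": _proteome(shared + novel_a, "A"),
            "B": _proteome(shared + novel_b, "B"),
        }
        graph = OrthologGraph.build(prots, scheme=scheme)
        assert cc.ortholog_fraction("A", graph) == pytest.approx(60.0, abs=2.0)


class TestThresholdMonotonicity:
    def test_edge_and_core_counts_non_increasing(self, clade_sim):
        """Raising min_identity can only remove edges and core families."""
        prots = {g: s.proteome for g, s in clade_sim.genomes.items()}
        ga, gb = list(prots)[:2]
        ab = best_hits(prots[ga], prots[gb])
        ba = best_hits(prots[gb], prots[ga])
        prev_edges = None
        for min_id in [0.2, 0.3, 0.4, 0.5, 0.6]:
            th = OrthologyThresholds(min_identity=min_id)
            n = len(call_orthologs(ab, ba, th))
            if prev_edges is not None:
                assert n <= prev_edges
            prev_edges = n
        prev = None
        for min_cov in [0.5, 0.7, 0.9]:
            th = OrthologyThresholds(min_coverage=min_cov)
            n = len(call_orthologs(ab, ba, th))
            if prev is not None:
                assert n <= prev
            prev = n


class TestGroupAlgebra:
    def _core_from(self, seqs_by_genome, scheme):
        prots = {g: _proteome(seqs, g) for g, seqs in seqs_by_genome.items()}
        return cc.group_core(prots, scheme=scheme)

    def test_single_genome_group_every_protein_a_family(self):
        rng = np.random.default_rng(5)
        prots = {"solo": _proteome([random_protein(rng, 60) for _ in range(7)], "solo")}
        core = cc.group_core(prots)
        assert len(core) == 7

    def test_two_identical_genomes_core_equals_proteome(self, scheme):
        rng = np.random.default_rng(6)
        seqs = [random_protein(rng, 70) for _ in range(6)]
        core = self._core_from({"A": seqs, "B": seqs}, scheme)
        assert len(core) == 6

    def test_compare_identical_cores_all_shared(self, scheme):
        rng = np.random.default_rng(7)
        seqs = [random_protein(rng, 70) for _ in range(6)]
        coreA = self._core_from({"A1": seqs, "A2": seqs}, scheme)
        coreB = self._core_from({"B1": seqs, "B2": seqs}, scheme)
        shared, unique = cc.compare_group_cores(coreA, coreB, scheme=scheme)
        assert (shared, unique) == (6, 0)

    def test_compare_disjoint_cores_none_shared(self, scheme):
        rng = np.random.default_rng(8)
        coreA = self._core_from(
            {"A1": [random_protein(rng, 70) for _ in range(5)]}, scheme
        )
        coreB = self._core_from(
            {"B1": [random_protein(rng, 70) for _ in range(5)]}, scheme
        )
        shared, unique = cc.compare_group_cores(coreA, coreB, scheme=scheme)
        assert (shared, unique) == (0, 5)

    def test_planted_overlap_counted_exactly(self, scheme):
        rng = np.random.default_rng(9)
        shared_fams = [random_protein(rng, 80) for _ in range(10)]
        only_a = [random_protein(rng, 80) for _ in range(4)]
        only_b = [random_protein(rng, 80) for _ in range(6)]
        coreA = self._core_from({"A1": shared_fams + only_a}, scheme)
        coreB = self._core_from({"B1": shared_fams + only_b}, scheme)
        shared, unique = cc.compare_group_cores(coreA, coreB, scheme=scheme)
        assert (shared, unique) == (10, 4)
        # symmetry of the shared count in best-hit mode
        shared_ba, _ = cc.compare_group_cores(coreB, coreA, scheme=scheme)
        assert shared_ba == shared

    def test_multi_group_shared_universal_families(self, scheme):
        rng = np.random.default_rng(10)
        universal = [random_protein(rng, 80) for _ in range(5)]
        cores = [
            self._core_from(
                {f"{g}1": universal + [random_protein(rng, 80) for _ in range(3)]},
                scheme,
            )
            for g in "ABC"
        ]
        count, fams = cc.multi_group_shared(cores, scheme=scheme)
        assert count == 5

    def test_multi_group_shared_empty_core_gives_zero(self, scheme):
        rng = np.random.default_rng(11)
        coreA = self._core_from({"A1": [random_protein(rng, 60)]}, scheme)
        empty = cc.CoreSet(genomes=["E"], families=[], mean_identities=[], proteomes={})
        assert cc.multi_group_shared([coreA, empty], scheme=scheme) == (0, [])

    def test_group_unique_core(self, scheme):
        rng = np.random.default_rng(12)
        shared_fams = [random_protein(rng, 80) for _ in range(5)]
        novel = [random_protein(rng, 80) for _ in range(10)]
        coreA = self._core_from({"A1": shared_fams + novel}, scheme)
        coreB = self._core_from({"B1": shared_fams}, scheme)
        count, fams = cc.group_unique_core(coreA, [coreB], scheme=scheme)
        assert count == 10
        # pooled others empty -> everything unique
        count2, _ = cc.group_unique_core(coreA, [], scheme=scheme)
        assert count2 == len(coreA)

    def test_empty_core_errors(self, scheme):
        empty = cc.CoreSet(genomes=["E"], families=[], mean_identities=[], proteomes={})
        with pytest.raises(EmptyInputError):
            cc.compare_group_cores(empty, empty, scheme=scheme)
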