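from itertools import combinations

import numpy as np
import pytest

import cladecore as cc
from cladecore.orthology import OrthologGraph, call_orthologs
from cladecore.pairwise_align import ScoringScheme, best_hits


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def small_ancestor():
    """A 60-gene genome: fast, used by most structural tests."""
    return cc.simulate_ancestor(n_genes=60, seed=1)


@pytest.fixture(scope="session")
def clade_sim():
    """The study-condition clade: 3 genomes diverged to ~50% mean protein
    identity with 20 gene gains and ~20 expected losses per branch."""
    prm = cc.EvolutionParams(
        sub_rate=cc.sub_rate_for_mean_identity(0.5),
        gene_loss_p=0.04,
        n_gene_gain=20,
    )
    return cc.simulate_clade(
        n_genomes=3, branch_params=prm, seed=17, ancestor_kwargs={"n_genes": 500}
    )


@pytest.fixture(scope="session")
def clade_tables(clade_sim, scheme):
    """Best-hit tables for every genome pair, both directions (the
    threshold-independent, expensive part of the pipeline)."""
    prots = {g: s.proteome for g, s in clade_sim.genomes.items()}
    tables = {}
    for ga, gb in combinations(prots, 2):
        tables[(ga, gb)] = (
            best_hits(prots[ga], prots[gb], scheme),
            best_hits(prots[gb], prots[ga], scheme),
        )
    return tables


def graph_at_thresholds(clade_sim, clade_tables, th=None):
    prots = {g: s.proteome for g, s in clade_sim.genomes.items()}
    graph = OrthologGraph(
        genomes=list(prots),
        proteins={g: set(p.proteins) for g, p in prots.items()},
    )
    for (ga, gb), (ab, ba) in clade_tables.items():
        graph.add_pair(ga, gb, call_orthologs(ab, ba, th))
    return graph


@pytest.fixture(scope="session")
def clade_graph(clade_sim, clade_tables):
    return graph_at_thresholds(clade_sim, clade_tables)


@pytest.fixture(scope="session")
def inversion_case():
    """A descendant carrying only a terminus-centred inversion, plus the
    synteny blocks and replication axis the detectors produce."""
    anc = cc.simulate_ancestor(n_genes=300, seed=7)
    ter = anc.meta["ter_bp"]
    child, truth = cc.evolve(
        anc, cc.EvolutionParams(inversion=(ter, 120000), seed=7), genome_id="inv"
    )
    graph = cc.OrthologGraph.build({"anc": anc.proteome, "inv": child.proteome})
    anchors = cc.anchor_from_orthologs(graph.edges, anc.annotation, child.annotation)
    blocks = cc.chain_blocks(anchors)
    axis = cc.infer_replication_axis(cc.gc_skew_series(anc.genome))
    return anc, child, truth, blocks, axis


def random_protein(rng: np.random.Generator, length: int) -> str:
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aas[i] for i in rng.integers(0, 20, length))


def truth_edge_set(sim):
    pairs = set()
    for (ga, gb), lst in sim.truth.ortholog_map.items():
        for ta, tb in lst:
            pairs.add(tuple(sorted([(ga, ta), (gb, tb)])))
    return pairs


def predicted_edge_set(graph):
    return {
        tuple(sorted([(e.genome_a, e.tag_a), (e.genome_b, e.tag_b)]))
        for e in graph.edges
    }
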