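"""Reciprocal orthology at identity/coverage thresholds, n-genome core
proteomes via the all-pairwise-combinations rule, unique protein sets, and
the group-core set algebra.

Two proteins are orthologs when they are reciprocal hits (best-hit mode by
default) AND the alignment reaches the identity threshold with coverage of
*both* sequences at the coverage threshold.  A core family is a clique over
the ortholog graph containing exactly one protein per genome, i.e. the
ortholog is present in all possible pairwise genome combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .errors import EmptyInputError, IncompleteGraphError
from .genome_io import GenomeAnnotation, Proteome, SequenceRecord
from .pairwise_align import (
    AlignmentResult,
    BestHitTable,
    ScoringScheme,
    best_hits,
)


@dataclass
class OrthologyThresholds:
    """Acceptance rule for an ortholog pair."""

    min_identity: float = 0.30
    min_coverage: float = 0.80
    reciprocity: str = "best_hit"  # or "any_hit"

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_coverage):
            if not (0.0 < v <= 1.0):
                raise ValueError("thresholds must lie in (0, 1]")
        if self.reciprocity not in ("best_hit", "any_hit"):
            raise ValueError("reciprocity must be 'best_hit' or 'any_hit'")

    def passes(self, r: AlignmentResult) -> bool:
        return (
            r.identity >= self.min_identity
            and r.q_cov >= self.min_coverage
            and r.s_cov >= self.min_coverage
        )


@dataclass(frozen=True)
class OrthologEdge:
    genome_a: str
    tag_a: str
    genome_b: str
    tag_b: str
    identity: float
    q_cov: float
    s_cov: float

    def endpoints(self):
        return (self.genome_a, self.tag_a), (self.genome_b, self.tag_b)


def call_orthologs(
    ab: BestHitTable, ba: BestHitTable, th: OrthologyThresholds | None = None
) -> list[OrthologEdge]:
    """Accepted ortholog pairs between one genome pair.

    ``best_hit`` mode: an edge (a, b) requires b to be a's best hit, a to
    be b's best hit, and the forward alignment to pass the thresholds.
    ``any_hit`` mode relaxes reciprocity to mutual presence in the hit
    lists, with the thresholds applied in both directions.
    """
    if th is None:
        th = OrthologyThresholds()
    if ab.query_genome != ba.subject_genome or ab.subject_genome != ba.query_genome:
        raise ValueError(
            f"tables are not the two directions of one genome pair: "
            f"{ab.query_genome}->{ab.subject_genome} vs "
            f"{ba.query_genome}->{ba.subject_genome}"
        )
    edges: list[OrthologEdge] = []
    if th.reciprocity == "best_hit":
        for query in ab.all_queries():
            fwd = ab.best(query)
            if fwd is None or not th.passes(fwd):
                continue
            rev = ba.best(fwd.subject)
            if rev is None or rev.subject != query:
                continue
            edges.append(
                OrthologEdge(
                    ab.query_genome,
                    query,
                    ab.subject_genome,
                    fwd.subject,
                    fwd.identity,
                    fwd.q_cov,
                    fwd.s_cov,
                )
            )
    else:
        rev_pairs = {
            (r.subject, q)
            for q, lst in ba.hits.items()
            for r in lst
            if th.passes(r)
        }
        for query, lst in ab.hits.items():
            for r in lst:
                if th.passes(r) and (query, r.subject) in rev_pairs:
                    edges.append(
                        OrthologEdge(
                            ab.query_genome,
                            query,
                            ab.subject_genome,
                            r.subject,
                            r.identity,
                            r.q_cov,
                            r.s_cov,
                        )
                    )
    return edges


@dataclass
class OrthologGraph:
    """Multipartite graph of accepted ortholog pairs across >= 2 genomes."""

    genomes: list[str]
    proteins: dict[str, set[str]] = field(default_factory=dict)
    edges: list[OrthologEdge] = field(default_factory=list)
    pairs_computed: set[frozenset] = field(default_factory=set)
    _adj: dict = field(default_factory=dict, repr=False)

    def add_pair(self, genome_a: str, genome_b: str, edges: list[OrthologEdge]):
        self.pairs_computed.add(frozenset((genome_a, genome_b)))
        for e in edges:
            self.edges.append(e)
            (ga, ta), (gb, tb) = e.endpoints()
            self._adj.setdefault((ga, ta), {}).setdefault(gb, []).append((tb, e))
            self._adj.setdefault((gb, tb), {}).setdefault(ga, []).append((ta, e))

    def neighbors(self, genome: str, tag: str, other_genome: str):
        return self._adj.get((genome, tag), {}).get(other_genome, [])

    def degree(self, genome: str, tag: str) -> int:
        return sum(len(v) for v in self._adj.get((genome, tag), {}).values())

    def edge_between(self, ga, ta, gb, tb) -> OrthologEdge | None:
        for tag, e in self.neighbors(ga, ta, gb):
            if tag == tb:
                return e
        return None

    @classmethod
    def build(
        cls,
        proteomes: dict[str, Proteome],
        th: OrthologyThresholds | None = None,
        scheme: ScoringScheme | None = None,
        exhaustive: bool = False,
    ) -> "OrthologGraph":
        """All-pairs comparison of a set of proteomes."""
        if th is None:
            th = OrthologyThresholds()
        if scheme is None:
            scheme = ScoringScheme.blosum62()
        graph = cls(
            genomes=list(proteomes),
            proteins={g: set(p.proteins) for g, p in proteomes.items()},
        )
        for ga, gb in combinations(proteomes, 2):
            ab = best_hits(proteomes[ga], proteomes[gb], scheme, exhaustive=exhaustive)
            ba = best_hits(proteomes[gb], proteomes[ga], scheme, exhaustive=exhaustive)
            graph.add_pair(ga, gb, call_orthologs(ab, ba, th))
        return graph


# ---------------------------------------------------------------------------
# Core proteome


@dataclass
class CoreSet:
    """One-protein-per-genome ortholog families (the core proteome)."""

    genomes: list[str]
    families: list[dict[str, str]]
    mean_identities: list[float]
    proteomes: dict[str, Proteome] | None = None
    dropped: list[dict[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.families)

    def member_index(self, genome: str) -> set[str]:
        return {fam[genome] for fam in self.families}

    def representative(self, idx: int) -> tuple[str, str, SequenceRecord]:
        """Longest member of a family (ties broken lexicographically)."""
        if self.proteomes is None:
            raise ValueError("core set has no attached proteomes")
        fam = self.families[idx]
        best = None
        for genome in sorted(fam):
            tag = fam[genome]
            rec = self.proteomes[genome].proteins[tag]
            key = (-len(rec), genome, tag)
            if best is None or key < best[0]:
                best = (key, genome, tag, rec)
        return best[1], best[2], best[3]

    def representative_proteome(self, group_id: str = "core") -> tuple[Proteome, dict]:
        """Representatives as a Proteome keyed F<idx>; returns (proteome, map)."""
        prot = Proteome(genome_id=group_id)
        fam_of_key: dict[str, int] = {}
        for i in range(len(self.families)):
            _, _, rec = self.representative(i)
            key = f"F{i:05d}"
            prot.proteins[key] = SequenceRecord(
                id=key, residues=rec.residues, alphabet="protein"
            )
            fam_of_key[key] = i
        return prot, fam_of_key


def _enumerate_cliques(graph: OrthologGraph) -> list[tuple[dict[str, str], float]]:
    genomes = graph.genomes
    cliques: list[tuple[dict[str, str], float]] = []

    def extend(partial: list[tuple[str, str]], gi: int):
        if gi == len(genomes):
            idents = []
            for (ga, ta), (gb, tb) in combinations(partial, 2):
                e = graph.edge_between(ga, ta, gb, tb)
                idents.append(e.identity)
            cliques.append(
                ({g: t for g, t in partial}, sum(idents) / len(idents))
            )
            return
        g_next = genomes[gi]
        # candidates: neighbors of every already-chosen member in g_next
        cand: set[str] | None = None
        for g, t in partial:
            nbrs = {tag for tag, _ in graph.neighbors(g, t, g_next)}
            cand = nbrs if cand is None else (cand & nbrs)
            if not cand:
                return
        for tag in sorted(cand):
            extend(partial + [(g_next, tag)], gi + 1)

    for tag in sorted(graph.proteins[genomes[0]]):
        extend([(genomes[0], tag)], 1)
    return cliques


def core_proteins(
    graph: OrthologGraph, proteomes: dict[str, Proteome] | None = None
) -> CoreSet:
    """Maximal one-per-genome cliques over the ortholog graph.

    A protein belonging to more than one qualifying clique is assigned to
    the clique with the highest mean pairwise identity; the losing cliques
    are dropped and recorded.
    """
    genomes = graph.genomes
    if len(genomes) < 2:
        raise IncompleteGraphError("core requires at least 2 genomes")
    for ga, gb in combinations(genomes, 2):
        if frozenset((ga, gb)) not in graph.pairs_computed:
            raise IncompleteGraphError(f"missing pairwise comparison {ga} vs {gb}")
    cliques = _enumerate_cliques(graph)
    cliques.sort(key=lambda c: (-c[1], tuple(sorted(c[0].items()))))
    used: set[tuple[str, str]] = set()
    families: list[dict[str, str]] = []
    idents: list[float] = []
    dropped: list[dict[str, str]] = []
    for fam, mean_id in cliques:
        members = {(g, t) for g, t in fam.items()}
        if members & used:
            dropped.append(fam)
            continue
        used |= members
        families.append(fam)
        idents.append(mean_id)
    families_sorted = sorted(
        zip(families, idents), key=lambda fi: tuple(sorted(fi[0].items()))
    )
    return CoreSet(
        genomes=list(genomes),
        families=[f for f, _ in families_sorted],
        mean_identities=[i for _, i in families_sorted],
        proteomes=proteomes,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Unique proteins and ortholog fraction


@dataclass
class UniqueSet:
    genome: str
    proteins: set[str]

    def __len__(self) -> int:
        return len(self.proteins)


def _is_loci(ann: GenomeAnnotation | None) -> set[str]:
    if ann is None:
        return set()
    return {f.locus_tag for f in ann.features if f.is_IS_related}


def unique_proteins(
    genome: str,
    graph: OrthologGraph,
    ann: GenomeAnnotation | None = None,
    exclude_is_and_pseudo: bool = False,
) -> UniqueSet:
    """Proteins of one genome with no qualifying ortholog anywhere.

    With ``exclude_is_and_pseudo`` IS-related loci are removed from the
    set (pseudogenes are never in a proteome to begin with).
    """
    if genome not in graph.proteins:
        raise KeyError(f"genome {genome} not in graph")
    tags = set(graph.proteins[genome])
    if exclude_is_and_pseudo:
        tags -= _is_loci(ann)
    unique = {t for t in tags if graph.degree(genome, t) == 0}
    return UniqueSet(genome=genome, proteins=unique)


def ortholog_fraction(
    genome: str, graph: OrthologGraph, ann: GenomeAnnotation | None = None
) -> float:
    """Percent of (non-IS, non-pseudogene) proteins with >= 1 ortholog."""
    tags = set(graph.proteins[genome]) - _is_loci(ann)
    if not tags:
        raise EmptyInputError("no proteins left after exclusions")
    with_edge = sum(1 for t in tags if graph.degree(genome, t) > 0)
    return 100.0 * with_edge / len(tags)


# ---------------------------------------------------------------------------
# Group algebra


def group_core(
    proteomes: dict[str, Proteome],
    th: OrthologyThresholds | None = None,
    scheme: ScoringScheme | None = None,
    exhaustive: bool = False,
) -> CoreSet:
    """Core proteome of a genome group.

    A single-genome group degenerates to one family per protein.
    """
    if not proteomes:
        raise EmptyInputError("empty group")
    if len(proteomes) == 1:
        (gid, prot), = proteomes.items()
        fams = [{gid: tag} for tag in sorted(prot.proteins)]
        return CoreSet(
            genomes=[gid],
            families=fams,
            mean_identities=[1.0] * len(fams),
            proteomes=proteomes,
        )
    graph = OrthologGraph.build(proteomes, th=th, scheme=scheme, exhaustive=exhaustive)
    return core_proteins(graph, proteomes)


def _rep_tables(coreA: CoreSet, coreB: CoreSet, scheme, exhaustive):
    protA, mapA = coreA.representative_proteome("A")
    protB, mapB = coreB.representative_proteome("B")
    ab = best_hits(protA, protB, scheme, exhaustive=exhaustive)
    ba = best_hits(protB, protA, scheme, exhaustive=exhaustive)
    return protA, mapA, protB, mapB, ab, ba


def compare_group_cores(
    coreA: CoreSet,
    coreB: CoreSet,
    th: OrthologyThresholds | None = None,
    scheme: ScoringScheme | None = None,
    exhaustive: bool = False,
) -> tuple[int, int]:
    """(shared, unique_in_A) between two group cores.

    Each family is represented by its longest member; shared counts A
    families whose representative has a qualifying reciprocal ortholog
    among B's representatives.
    """
    if len(coreA) == 0 or len(coreB) == 0:
        raise EmptyInputError("empty core set")
    if th is None:
        th = OrthologyThresholds()
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    _, mapA, _, _, ab, ba = _rep_tables(coreA, coreB, scheme, exhaustive)
    edges = call_orthologs(ab, ba, th)
    shared_keys = {e.tag_a for e in edges}
    shared = len(shared_keys)
    return shared, len(coreA) - shared


def multi_group_shared(
    cores: list[CoreSet],
    th: OrthologyThresholds | None = None,
    scheme: ScoringScheme | None = None,
    exhaustive: bool = False,
) -> tuple[int, list[int]]:
    """Families of the first core with qualifying orthologs in every other
    core; returns (count, family indices of the first core)."""
    if not cores:
        raise EmptyInputError("no cores given")
    if any(len(c) == 0 for c in cores):
        return 0, []
    if th is None:
        th = OrthologyThresholds()
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    first = cores[0]
    surviving: set[int] | None = None
    for other in cores[1:]:
        _, mapA, _, _, ab, ba = _rep_tables(first, other, scheme, exhaustive)
        edges = call_orthologs(ab, ba, th)
        idx = {mapA[e.tag_a] for e in edges}
        surviving = idx if surviving is None else (surviving & idx)
        if not surviving:
            return 0, []
    if surviving is None:  # single core in the list
        surviving = set(range(len(first)))
    return len(surviving), sorted(surviving)


def group_unique_core(
    core: CoreSet,
    other_cores: list[CoreSet],
    th: OrthologyThresholds | None = None,
    scheme: ScoringScheme | None = None,
    exhaustive: bool = False,
) -> tuple[int, list[int]]:
    """Families of ``core`` absent from the pooled representatives of all
    other cores (no threshold-qualifying hit in either direction)."""
    if len(core) == 0:
        raise EmptyInputError("empty core set")
    if th is None:
        th = OrthologyThresholds()
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    pooled = Proteome(genome_id="pooled")
    for gi, other in enumerate(other_cores):
        prot, _ = other.representative_proteome(f"G{gi}")
        for key, rec in prot:
            pooled.proteins[f"G{gi}_{key}"] = SequenceRecord(
                id=f"G{gi}_{key}", residues=rec.residues, alphabet="protein"
            )
    protA, mapA = core.representative_proteome("A")
    if len(pooled) == 0:
        return len(core), list(range(len(core)))
    ab = best_hits(protA, pooled, scheme, exhaustive=exhaustive)
    hit_keys = {
        q for q, lst in ab.hits.items() if any(th.passes(r) for r in lst)
    }
    unique_idx = sorted(mapA[k] for k in mapA if k not in hit_keys)
    return len(unique_idx), unique_idx
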