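"""Synthetic bacterial genomes, proteomes and microarray data with known
planted structure, so every pipeline stage can be tested against truth.

The generator emulates a small single-chromosome bacterial genome:
non-overlapping protein-coding genes on both strands separated by short
intergenic spacers, a target GC content, and a replication-axis GC skew
(the leading strand is G-rich, flipping at the terminus).  Evolution is a
star phylogeny: each descendant accumulates amino-acid substitutions,
gene losses, novel gene gains, intergenic IS-element insertions,
pseudogenizations (premature stops), an optional low-GC island, and an
optional large inversion; every event is recorded in a
:class:`SimulationTruth`.

Amino-acid substitutions are proposed with probability proportional to
exp(BLOSUM62/2), so simulated divergence stays alignable in the way real
protein divergence does.  Gained genes are novel random sequences rather
than duplications, which keeps "unique" unambiguous.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_io import (
    GeneFeature,
    GenomeAnnotation,
    Proteome,
    SequenceRecord,
    write_fasta,
    write_gff3,
    write_proteome_fasta,
)
from .pairwise_align import ScoringScheme

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Approximate bacterial amino-acid composition (fraction per residue).
_AA_FREQ = {
    "A": 0.089, "C": 0.012, "D": 0.054, "E": 0.061, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.060, "K": 0.063, "L": 0.100,
    "M": 0.024, "N": 0.040, "P": 0.044, "Q": 0.039, "R": 0.055,
    "S": 0.058, "T": 0.054, "V": 0.069, "W": 0.013, "Y": 0.032,
}
_AA_P = np.array([_AA_FREQ[a] for a in AA20])
_AA_P = _AA_P / _AA_P.sum()

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_OF: dict[str, list[str]] = {}
for _codon, _aa in _TABLE11.forward_table.items():
    _CODONS_OF.setdefault(_aa, []).append(_codon)
_STOPS = sorted(_TABLE11.stop_codons)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _substitution_proposal() -> np.ndarray:
    """Row-normalized proposal P[old, new] ~ exp(BLOSUM62/2), zero diagonal."""
    scheme = ScoringScheme.blosum62()
    from .pairwise_align import ALPHABET

    idx = [ALPHABET.index(a) for a in AA20]
    sub = scheme.matrix[np.ix_(idx, idx)].astype(float)
    w = np.exp(sub / 2.0)
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


_SUB_PROPOSAL = _substitution_proposal()
_AA_INDEX = {a: i for i, a in enumerate(AA20)}


def _base_probs(gc: float, skew: float = 0.0) -> np.ndarray:
    """Probabilities over ACGT with G/C imbalance ``skew`` (leading-strand
    G enrichment): pG = gc/2*(1+skew), pC = gc/2*(1-skew)."""
    pg = gc / 2.0 * (1.0 + skew)
    pc = gc / 2.0 * (1.0 - skew)
    pa = pt = (1.0 - gc) / 2.0
    return np.array([pa, pc, pg, pt])  # A C G T


_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int, gc: float, skew: float = 0.0) -> str:
    return "".join(_BASES[rng.choice(4, size=length, p=_base_probs(gc, skew))])


def _expected_coding_gc(gc_param: float) -> float:
    """Expected GC fraction of coding sequence when synonymous codons are
    weighted by base probabilities at ``gc_param``, averaged over the
    amino-acid composition (stop codons ignored: three per gene)."""
    probs = _base_probs(gc_param)
    total = 0.0
    for aa, freq in zip(AA20, _AA_P):
        codons = _CODONS_OF[aa]
        w = np.array([_codon_weight(c, probs, False) for c in codons])
        w = w / w.sum()
        gc_frac = np.array([(c.count("G") + c.count("C")) / 3.0 for c in codons])
        total += freq * float(w @ gc_frac)
    return total


_GC_CALIBRATION: dict[float, float] = {}


def _calibrated_gc_param(target_gc: float) -> float:
    """Codon-weighting GC parameter whose expected coding GC equals the
    target (bisection; cached)."""
    if target_gc in _GC_CALIBRATION:
        return _GC_CALIBRATION[target_gc]
    lo, hi = 0.02, 0.98
    for _ in range(50):
        mid = (lo + hi) / 2.0
        if _expected_coding_gc(mid) < target_gc:
            lo = mid
        else:
            hi = mid
    _GC_CALIBRATION[target_gc] = (lo + hi) / 2.0
    return _GC_CALIBRATION[target_gc]


def _codon_weight(codon: str, probs: np.ndarray, on_minus: bool) -> float:
    w = 1.0
    for b in codon:
        if on_minus:
            b = b.translate(_COMPLEMENT)
        w *= probs["ACGT".index(b)]
    return w


def _encode_protein_dna(
    rng: np.random.Generator,
    protein: str,
    gc: float,
    skew: float = 0.0,
    strand: str = "+",
) -> str:
    """Coding-strand DNA for a protein plus a stop codon.  Synonymous
    codons are weighted by genome-strand base probabilities so codon
    usage carries the target GC and replication skew; the GC weight is
    calibrated so realized coding GC matches the target despite the
    amino-acid composition."""
    probs = _base_probs(_calibrated_gc_param(gc), skew)
    on_minus = strand == "-"
    parts = []
    for aa in protein:
        codons = _CODONS_OF[aa]
        w = np.array([_codon_weight(c, probs, on_minus) for c in codons])
        parts.append(codons[rng.choice(len(codons), p=w / w.sum())])
    w = np.array([_codon_weight(c, probs, on_minus) for c in _STOPS])
    parts.append(_STOPS[rng.choice(len(_STOPS), p=w / w.sum())])
    return "".join(parts)


def _revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Data containers


@dataclass
class SimulatedGenome:
    """A genome plus its annotation, proteome and generator metadata."""

    genome: SequenceRecord
    annotation: GenomeAnnotation
    proteome: Proteome
    meta: dict = field(default_factory=dict)

    @property
    def genome_id(self) -> str:
        return self.annotation.genome_id


@dataclass
class EvolutionParams:
    """Per-branch event rates for :func:`evolve`."""

    sub_rate: float = 0.0  # expected substitutions per protein site
    gene_loss_p: float = 0.0
    n_gene_gain: int = 0
    n_is_insertions: int = 0
    pseudogenize_p: float = 0.0
    island: tuple[int, float] | None = None  # (length bp, gc fraction)
    inversion: tuple[int, int] | None = None  # (center bp, length bp)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.gene_loss_p, self.pseudogenize_p):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.sub_rate < 0:
            raise ValueError("sub_rate must be >= 0")


@dataclass
class SimulationTruth:
    """Planted structure: what the pipeline should recover."""

    ortholog_map: dict = field(default_factory=dict)  # (gidA,gidB) -> [(tagA,tagB)]
    unique_genes: dict = field(default_factory=dict)  # gid -> set of tags
    pseudogenes: dict = field(default_factory=dict)  # gid -> list of tags
    is_elements: dict = field(default_factory=dict)  # gid -> list of tags
    island: dict = field(default_factory=dict)  # gid -> (start, end, gc) | None
    inversion: dict = field(default_factory=dict)  # gid -> (start, end) | None
    de_genes: dict = field(default_factory=dict)  # gene -> linear fold
    identity_trace: dict = field(default_factory=dict)  # (tagA,tagB) -> expected id


@dataclass
class CladeSimulation:
    ancestor: SimulatedGenome
    genomes: dict[str, SimulatedGenome]
    truth: SimulationTruth


def sub_rate_for_mean_identity(pairwise_identity: float, n_branches: int = 2) -> float:
    """Per-branch substitution rate giving the requested expected pairwise
    identity between two descendants (sites diverge independently on each
    branch; convergent substitutions are ignored)."""
    if not (0.0 < pairwise_identity <= 1.0):
        raise ValueError("identity must lie in (0, 1]")
    return -math.log(pairwise_identity) / n_branches


# ---------------------------------------------------------------------------
# Ancestor


def simulate_ancestor(
    n_genes: int = 500,
    mean_len_bp: int = 900,
    gc: float = 0.44,
    seed: int = 0,
    genome_id: str = "anc",
    skew: float = 0.12,
    sd_len_bp: int = 250,
    min_len_bp: int = 300,
    max_len_bp: int = 2400,
    intergenic_mean_bp: int = 150,
    leading_strand_bias: float = 0.75,
) -> SimulatedGenome:
    """A circular single-chromosome genome of non-overlapping genes.

    The leading strand is G-enriched by ``skew`` up to the terminus at
    half the genome length, giving a detectable cumulative GC-skew axis
    with the origin at position 1.  Codon constraints attenuate the
    realized per-window skew to roughly 0.4x the parameter, so the
    default 0.12 produces the ~0.05 window skew typical of real
    bacterial chromosomes.

    Coding strands are intrinsically G-rich, so each gene lies on the
    leading strand with probability ``leading_strand_bias`` (the real
    bacterial pattern); without this bias the coding-strand skew of
    randomly stranded genes would swamp the replichore signal.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    lengths = np.clip(
        (rng.normal(mean_len_bp, sd_len_bp, n_genes) / 3).round().astype(int) * 3,
        min_len_bp,
        max_len_bp,
    )
    gaps = rng.integers(
        max(20, intergenic_mean_bp // 3), 2 * intergenic_mean_bp, n_genes + 1
    )
    total = int(lengths.sum() + gaps.sum())
    ter = total // 2

    pieces: list[str] = []
    features: list[GeneFeature] = []
    proteome = Proteome(genome_id=genome_id)
    pos = 0  # 0-based running position

    def _s(p):  # replichore sign at position p
        return 1 if p < ter else -1

    for i in range(n_genes):
        g = int(gaps[i])
        pieces.append(_random_dna(rng, g, gc, skew * _s(pos)))
        pos += g
        plen = lengths[i] // 3 - 1
        protein = "M" + "".join(
            np.array(list(AA20))[rng.choice(20, size=plen - 1, p=_AA_P)]
        )
        s_sign = _s(pos + lengths[i] // 2)
        on_leading = rng.random() < leading_strand_bias
        # leading strand is '+' on the ori->ter arc, '-' on the other arc
        strand = ("+" if s_sign > 0 else "-") if on_leading else (
            "-" if s_sign > 0 else "+"
        )
        local_skew = skew * s_sign
        dna = _encode_protein_dna(rng, protein, gc, local_skew, strand)
        seg = dna if strand == "+" else _revcomp(dna)
        tag = f"{genome_id}_{(i + 1) * 10:05d}"
        features.append(
            GeneFeature(
                locus_tag=tag,
                ftype="CDS",
                start=pos + 1,
                end=pos + len(seg),
                strand=strand,
                product="hypothetical protein",
            )
        )
        proteome.proteins[tag] = SequenceRecord(
            id=tag, residues=protein, alphabet="protein"
        )
        pieces.append(seg)
        pos += len(seg)
    pieces.append(_random_dna(rng, int(gaps[n_genes]), gc, skew * _s(pos)))
    pos += int(gaps[n_genes])

    genome = SequenceRecord(id=genome_id, residues="".join(pieces), alphabet="dna")
    ann = GenomeAnnotation(
        genome_id=genome_id, length=len(genome), topology="circular", features=features
    )
    return SimulatedGenome(
        genome=genome,
        annotation=ann,
        proteome=proteome,
        meta={"ori_bp": 1, "ter_bp": ter, "gc": gc, "skew": skew, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Branch evolution


def _mutate_protein(
    rng: np.random.Generator, protein: str, dna: str, sub_rate: float, gc: float
) -> tuple[str, str, int]:
    """Substitute amino-acid sites at rate ``sub_rate``; re-encode only the
    affected codons.  Returns (protein, dna, n_substituted)."""
    if sub_rate <= 0:
        return protein, dna, 0
    p_sub = 1.0 - math.exp(-sub_rate)
    sites = np.flatnonzero(rng.random(len(protein)) < p_sub)
    if sites.size == 0:
        return protein, dna, 0
    prot = list(protein)
    codons = [dna[i : i + 3] for i in range(0, len(dna), 3)]
    probs = _base_probs(_calibrated_gc_param(gc))
    for s in sites:
        old = prot[s]
        new = AA20[rng.choice(20, p=_SUB_PROPOSAL[_AA_INDEX[old]])]
        prot[s] = new
        opts = _CODONS_OF[new]
        w = np.array([_codon_weight(c, probs, False) for c in opts])
        codons[s] = opts[rng.choice(len(opts), p=w / w.sum())]
    return "".join(prot), "".join(codons), int(sites.size)


def evolve(
    parent: SimulatedGenome,
    prm: EvolutionParams,
    genome_id: str = "child",
) -> tuple[SimulatedGenome, SimulationTruth]:
    """Derive one descendant genome and the truth record of every event."""
    rng = np.random.default_rng(prm.seed)
    pid = parent.genome_id
    genome_seq = parent.genome.residues
    cds = [f for f in parent.annotation.features if f.ftype == "CDS"]
    cds.sort(key=lambda f: f.start)

    # parent intergenic segments (n_genes + 1 of them)
    inters: list[str] = []
    prev_end = 0
    for f in cds:
        inters.append(genome_seq[prev_end : f.start - 1])
        prev_end = f.end
    inters.append(genome_seq[prev_end:])

    gc = parent.meta.get("gc", 0.44)

    # --- per-gene events -------------------------------------------------
    @dataclass
    class _Gene:
        tag: str
        parent_tag: str | None
        strand: str
        dna: str  # coding strand, includes stop
        protein: str
        ftype: str = "CDS"
        product: str = "hypothetical protein"
        is_IS: bool = False
        n_sub: int = 0
        parent_len: int = 0

    genes: list[_Gene | None] = []
    lost_parent_tags: list[str] = []
    for f in cds:
        suffix = f.locus_tag.split("_", 1)[1]
        if rng.random() < prm.gene_loss_p:
            genes.append(None)
            lost_parent_tags.append(f.locus_tag)
            continue
        dna = genome_seq[f.start - 1 : f.end]
        if f.strand == "-":
            dna = _revcomp(dna)
        protein = parent.proteome.proteins[f.locus_tag].residues
        new_prot, new_dna, n_sub = _mutate_protein(rng, protein, dna, prm.sub_rate, gc)
        genes.append(
            _Gene(
                tag=f"{genome_id}_{suffix}",
                parent_tag=f.locus_tag,
                strand=f.strand,
                dna=new_dna,
                protein=new_prot,
                n_sub=n_sub,
                parent_len=len(protein),
            )
        )

    # pseudogenization: premature stop at the middle codon
    pseudo_tags: list[str] = []
    for g in genes:
        if g is not None and g.ftype == "CDS" and rng.random() < prm.pseudogenize_p:
            mid = len(g.protein) // 2
            codons = [g.dna[i : i + 3] for i in range(0, len(g.dna), 3)]
            codons[mid] = "TAA"
            g.dna = "".join(codons)
            g.ftype = "pseudogene"
            g.product = g.product + " (pseudogene)"
            pseudo_tags.append(g.tag)

    # --- novel elements ---------------------------------------------------
    n_slots = len(inters)
    insertions: dict[int, list] = {}

    def _insert(slot: int, item) -> None:
        insertions.setdefault(slot, []).append(item)

    gain_tags: list[str] = []
    for i in range(prm.n_gene_gain):
        plen = max(100, int(round(rng.normal(300, 80))))
        protein = "M" + "".join(
            np.array(list(AA20))[rng.choice(20, size=plen - 1, p=_AA_P)]
        )
        strand = "+" if rng.random() < 0.5 else "-"
        tag = f"{genome_id}_G{i + 1:04d}"
        gain_tags.append(tag)
        _insert(
            int(rng.integers(0, n_slots)),
            _Gene(tag=tag, parent_tag=None, strand=strand,
                  dna=_encode_protein_dna(rng, protein, gc, 0.0, strand),
                  protein=protein, product="hypothetical protein (novel)"),
        )

    is_tags: list[str] = []
    if prm.n_is_insertions:
        n_fam = min(2, prm.n_is_insertions)
        fams = []
        for fi in range(n_fam):
            plen = 300
            protein = "M" + "".join(
                np.array(list(AA20))[rng.choice(20, size=plen - 1, p=_AA_P)]
            )
            fams.append(
                (f"IS{101 + fi}", protein,
                 _encode_protein_dna(rng, protein, gc, 0.0, "+"))
            )
        for i in range(prm.n_is_insertions):
            fam_name, protein, dna = fams[i % n_fam]
            strand = "+" if rng.random() < 0.5 else "-"
            tag = f"{genome_id}_IS{i + 1:03d}"
            is_tags.append(tag)
            _insert(
                int(rng.integers(0, n_slots)),
                _Gene(tag=tag, parent_tag=None, strand=strand,
                      dna=dna if strand == "+" else dna,
                      protein=protein,
                      product=f"{fam_name} family transposase", is_IS=True),
            )

    island_seq = None
    if prm.island is not None:
        island_len, island_gc = prm.island
        island_seq = _random_dna(rng, int(island_len), island_gc)

    # --- layout (with island/inversion overlap retry) --------------------
    for attempt in range(20):
        island_slot = int(rng.integers(0, n_slots)) if island_seq else -1
        pieces = []
        features: list[GeneFeature] = []
        proteome = Proteome(genome_id=genome_id)
        island_coords = None
        pos = 0
        gi = 0
        for slot in range(n_slots):
            pieces.append(inters[slot])
            pos += len(inters[slot])
            if slot == island_slot:
                island_coords = (pos + 1, pos + len(island_seq))
                pieces.append(island_seq)
                pos += len(island_seq)
            for item in insertions.get(slot, ()):
                spacer = _random_dna(rng, 120, gc)
                seg = item.dna if item.strand == "+" else _revcomp(item.dna)
                features.append(
                    GeneFeature(
                        locus_tag=item.tag, ftype=item.ftype,
                        start=pos + 1, end=pos + len(seg),
                        strand=item.strand, product=item.product,
                        is_IS_related=item.is_IS,
                    )
                )
                if item.ftype == "CDS":
                    proteome.proteins[item.tag] = SequenceRecord(
                        id=item.tag, residues=item.protein, alphabet="protein"
                    )
                pieces.append(seg)
                pos += len(seg)
                pieces.append(spacer)
                pos += len(spacer)
            if slot < len(genes):
                g = genes[slot]
                if g is None:
                    continue
                seg = g.dna if g.strand == "+" else _revcomp(g.dna)
                features.append(
                    GeneFeature(
                        locus_tag=g.tag, ftype=g.ftype,
                        start=pos + 1, end=pos + len(seg),
                        strand=g.strand, product=g.product,
                        is_IS_related=g.is_IS,
                    )
                )
                if g.ftype == "CDS":
                    proteome.proteins[g.tag] = SequenceRecord(
                        id=g.tag, residues=g.protein, alphabet="protein"
                    )
                pieces.append(seg)
                pos += len(seg)
        child_seq = "".join(pieces)

        inv_coords = None
        if prm.inversion is not None:
            center, length = prm.inversion
            lo = center - length // 2
            hi = center + length // 2
            contained = [f for f in features if f.start >= lo and f.end <= hi]
            if not contained:
                raise ValueError("inversion segment contains no features")
            inv_start = min(f.start for f in contained)
            inv_end = max(f.end for f in contained)
            if island_coords is not None and not (
                island_coords[1] < inv_start or island_coords[0] > inv_end
            ):
                if attempt == 19:
                    raise ValueError("island placement kept colliding with inversion")
                continue  # retry island placement
            seg = child_seq[inv_start - 1 : inv_end]
            child_seq = (
                child_seq[: inv_start - 1] + _revcomp(seg) + child_seq[inv_end:]
            )
            for f in features:
                if f.start >= inv_start and f.end <= inv_end:
                    s, e = f.start, f.end
                    f.start = inv_start + inv_end - e
                    f.end = inv_start + inv_end - s
                    f.strand = "+" if f.strand == "-" else "-"
            inv_coords = (inv_start, inv_end)
        break

    ann = GenomeAnnotation(
        genome_id=genome_id,
        length=len(child_seq),
        topology="circular",
        features=features,
    )
    child = SimulatedGenome(
        genome=SequenceRecord(id=genome_id, residues=child_seq, alphabet="dna"),
        annotation=ann,
        proteome=proteome,
        meta={**parent.meta, "parent": pid, "seed": prm.seed},
    )

    truth = SimulationTruth()
    pairs = [
        (g.parent_tag, g.tag)
        for g in genes
        if g is not None and g.ftype == "CDS" and g.parent_tag is not None
    ]
    truth.ortholog_map[(pid, genome_id)] = pairs
    for g in genes:
        if g is not None and g.parent_tag is not None and g.ftype == "CDS":
            truth.identity_trace[(g.parent_tag, g.tag)] = (
                (g.parent_len - g.n_sub) / g.parent_len
            )
    truth.unique_genes[genome_id] = set(gain_tags) | set(is_tags)
    truth.unique_genes[pid] = set(lost_parent_tags) | {
        g.parent_tag for g in genes if g is not None and g.ftype == "pseudogene"
        and g.parent_tag is not None
    }
    truth.pseudogenes[genome_id] = pseudo_tags
    truth.is_elements[genome_id] = is_tags
    truth.island[genome_id] = (
        (*island_coords, prm.island[1]) if island_coords else None
    )
    truth.inversion[genome_id] = inv_coords
    return child, truth


# ---------------------------------------------------------------------------
# Clade


def simulate_clade(
    n_genomes: int = 3,
    branch_params: EvolutionParams | list[EvolutionParams] | None = None,
    seed: int = 0,
    ancestor_kwargs: dict | None = None,
) -> CladeSimulation:
    """Star phylogeny: one ancestor, ``n_genomes`` independent branches.

    Pairwise ortholog truth between descendants is composed through the
    shared ancestral gene: two child copies of one ancestral gene are
    orthologs when both are retained and protein-coding.
    """
    kwargs = dict(ancestor_kwargs or {})
    kwargs.setdefault("seed", seed % (2**31))
    ancestor = simulate_ancestor(**kwargs)
    if branch_params is None:
        branch_params = EvolutionParams()
    if isinstance(branch_params, EvolutionParams):
        branch_params = [
            dataclasses.replace(branch_params, seed=(seed + 7919 * (i + 1)) % (2**31))
            for i in range(n_genomes)
        ]
    if len(branch_params) != n_genomes:
        raise ValueError("need one EvolutionParams per genome")

    genomes: dict[str, SimulatedGenome] = {}
    branch_truths: dict[str, SimulationTruth] = {}
    for i, prm in enumerate(branch_params):
        gid = f"g{i + 1}"
        child, truth = evolve(ancestor, prm, genome_id=gid)
        genomes[gid] = child
        branch_truths[gid] = truth

    pooled = SimulationTruth()
    aid = ancestor.genome_id
    # map ancestral tag -> child tag for each branch (coding copies only)
    child_of: dict[str, dict[str, str]] = {}
    for gid, truth in branch_truths.items():
        child_of[gid] = {pa: ch for pa, ch in truth.ortholog_map[(aid, gid)]}
        pooled.pseudogenes[gid] = branch_truths[gid].pseudogenes[gid]
        pooled.is_elements[gid] = branch_truths[gid].is_elements[gid]
        pooled.island[gid] = branch_truths[gid].island[gid]
        pooled.inversion[gid] = branch_truths[gid].inversion[gid]
    gids = list(genomes)
    for i, ga in enumerate(gids):
        for gb in gids[i + 1 :]:
            pairs = [
                (child_of[ga][anc_tag], child_of[gb][anc_tag])
                for anc_tag in child_of[ga]
                if anc_tag in child_of[gb]
            ]
            pooled.ortholog_map[(ga, gb)] = pairs
    for gid in gids:
        novel = branch_truths[gid].unique_genes[gid]
        retained_elsewhere = set()
        for other in gids:
            if other == gid:
                continue
            retained_elsewhere |= set(child_of[other])
        ancestral_only_here = {
            child_of[gid][anc_tag]
            for anc_tag in child_of[gid]
            if anc_tag not in retained_elsewhere
        }
        pooled.unique_genes[gid] = novel | ancestral_only_here
    return CladeSimulation(ancestor=ancestor, genomes=genomes, truth=pooled)


# ---------------------------------------------------------------------------
# Summary-statistic fixtures
#
# These rebuild a genome *annotation* from published summary counts so the
# census arithmetic (shares, densities, strand balances) can be recomputed
# from integers rather than asserted.  No sequence is attached.


def annotation_from_counts(
    n_cds: int = 1901,
    n_pseudogenes: int = 85,
    n_is_cds: int = 58,
    n_is_pseudogenes: int = 25,
    mean_gene_len_bp: int = 875,
    genome_length: int = 2_066_657,
    genome_id: str = "summary",
) -> GenomeAnnotation:
    """An annotation realizing the headline counts of a finished genome
    table: CDS and pseudogene totals, IS-related subsets, and the mean
    gene length, laid out end to end on a chromosome of the given size."""
    features = []
    pos = 1
    for i in range(n_cds):
        end = pos + mean_gene_len_bp - 1
        features.append(
            GeneFeature(
                f"c{i:05d}", "CDS", pos, end,
                product="IS3 family transposase" if i < n_is_cds else "protein",
            )
        )
        pos = end + 2
    for i in range(n_pseudogenes):
        end = pos + 400
        features.append(
            GeneFeature(
                f"p{i:05d}", "pseudogene", pos, end,
                product=(
                    "IS3 family transposase" if i < n_is_pseudogenes
                    else "degraded protein"
                ),
            )
        )
        pos = end + 2
    return GenomeAnnotation(
        genome_id=genome_id, length=genome_length, features=features
    )


def trna_strand_annotation(
    n_leading: int = 41,
    n_lagging: int = 26,
    genome_length: int = 2_000_000,
    genome_id: str = "trnas",
):
    """tRNA genes laid out so that exactly ``n_leading`` fall on the
    leading strand of a genome with the origin at 1 and the terminus at
    half the genome length; returns (annotation, axis)."""
    from .genome_stats import ReplicationAxis

    half = genome_length // 2
    features = []
    step = (half - 2000) // max(1, n_leading + n_lagging)
    pos = 1000
    for i in range(n_leading):
        features.append(
            GeneFeature(f"tl{i:03d}", "tRNA", pos, pos + 75, strand="+",
                        product="tRNA-Ala")
        )
        pos += step
    for i in range(n_lagging):
        features.append(
            GeneFeature(f"tg{i:03d}", "tRNA", pos, pos + 75, strand="-",
                        product="tRNA-Gly")
        )
        pos += step
    ann = GenomeAnnotation(
        genome_id=genome_id, length=genome_length, features=features
    )
    axis = ReplicationAxis(
        origin_bp=1, terminus_bp=half, genome_length=genome_length
    )
    return ann, axis


# ---------------------------------------------------------------------------
# Truth self-check


def truth_problems(sim: CladeSimulation) -> list[str]:
    """Independent consistency check of a clade's truth record against the
    emitted annotations and proteomes; returns a list of discrepancies."""
    problems = []
    for gid, g in sim.genomes.items():
        tags = {f.locus_tag: f for f in g.annotation.features}
        for tag in sim.truth.pseudogenes.get(gid, ()):
            if tags.get(tag) is None or tags[tag].ftype != "pseudogene":
                problems.append(f"{gid}:{tag} not annotated as pseudogene")
            if tag in g.proteome.proteins:
                problems.append(f"{gid}:{tag} pseudogene present in proteome")
        for tag in sim.truth.is_elements.get(gid, ()):
            if tags.get(tag) is None or not tags[tag].is_IS_related:
                problems.append(f"{gid}:{tag} not flagged IS-related")
        isl = sim.truth.island.get(gid)
        if isl:
            s, e, target_gc = isl
            from .genome_stats import gc_content

            realized = gc_content(g.genome, s, e)
            if abs(realized - 100 * target_gc) > 2.0:
                problems.append(f"{gid}: island GC {realized:.1f} != {100*target_gc}")
        inv = sim.truth.inversion.get(gid)
        if inv:
            s, e = inv
            if not (1 <= s < e <= g.annotation.length):
                problems.append(f"{gid}: inversion coords {inv} out of range")
    for (ga, gb), pairs in sim.truth.ortholog_map.items():
        pa = sim.genomes[ga].proteome.proteins
        pb = sim.genomes[gb].proteome.proteins
        for ta, tb in pairs:
            if ta not in pa or tb not in pb:
                problems.append(f"ortholog pair ({ta},{tb}) missing from proteomes")
    return problems


# ---------------------------------------------------------------------------
# Microarray


def simulate_microarray(
    genes: list[str],
    de_genes: dict[str, float] | None = None,
    sigma_log2: float = 0.25,
    replicate_sigma_log2: float = 0.1,
    n_replicates: int = 3,
    probes_per_gene: int = 6,
    outlier_p: float = 0.01,
    seed: int = 0,
    baseline_mean: float = 9.0,
    baseline_sd: float = 1.5,
    conditions: tuple[str, str] = ("A", "B"),
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Two-condition probe-level microarray with planted fold changes.

    Probe value = gene baseline + condition effect (log2 fold in condition
    B) + biological replicate offset (sd ``replicate_sigma_log2``) + probe
    noise (sd ``sigma_log2``).  Outliers are injected with probability
    ``outlier_p`` as +-5 sigma shifts.
    """
    de_genes = dict(de_genes or {})
    for g, fold in de_genes.items():
        if fold < 1:
            raise ValueError("planted folds must be >= 1")
    rng = np.random.default_rng(seed)
    baselines = rng.normal(baseline_mean, baseline_sd, len(genes))
    rows = []
    for gi, gene in enumerate(genes):
        effect = math.log2(de_genes.get(gene, 1.0))
        for cond in conditions:
            shift = effect if cond == conditions[1] else 0.0
            for rep in range(1, n_replicates + 1):
                rep_off = rng.normal(0.0, replicate_sigma_log2)
                for probe in range(1, probes_per_gene + 1):
                    val = baselines[gi] + shift + rep_off + rng.normal(0, sigma_log2)
                    if rng.random() < outlier_p:
                        val += (5.0 if rng.random() < 0.5 else -5.0) * max(
                            sigma_log2, 1e-12
                        )
                    rows.append(
                        (gene, f"{gene}_p{probe}", cond, f"r{rep}", val)
                    )
    table = pd.DataFrame(
        rows, columns=["gene", "probe_id", "condition", "replicate", "log2_intensity"]
    )
    truth = SimulationTruth(de_genes=de_genes)
    return table, truth


# ---------------------------------------------------------------------------
# File emission


def write_simulation(sim: CladeSimulation, outdir: str | Path) -> Path:
    """Emit FASTA/GFF3/protein FASTA per genome plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    everything = {"anc": sim.ancestor, **sim.genomes}
    for gid, g in everything.items():
        write_fasta([g.genome], outdir / f"{gid}.fa")
        write_gff3(g.annotation, outdir / f"{gid}.gff3")
        write_proteome_fasta(g.proteome, outdir / f"{gid}.faa")
    truth = sim.truth
    payload = {
        "ortholog_map": {f"{a}|{b}": pairs for (a, b), pairs in truth.ortholog_map.items()},
        "unique_genes": {g: sorted(v) for g, v in truth.unique_genes.items()},
        "pseudogenes": truth.pseudogenes,
        "is_elements": truth.is_elements,
        "island": truth.island,
        "inversion": truth.inversion,
        "de_genes": truth.de_genes,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return outdir
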