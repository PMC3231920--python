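import numpy as np
import pytest

import cladecore as cc
from cladecore.errors import DegenerateAxisError, UndefinedValueError
from cladecore.genome_stats import MotifPattern, ReplicationAxis


@pytest.mark.parametrize(
    "seq,expected",
    [("GGCC", 100.0), ("ATAT", 0.0), ("ATGCN", 50.0)],  # N excluded from both sides
)
def test_gc_content_basics(seq, expected):
    assert cc.gc_content(seq) == pytest.approx(expected)


def test_gc_content_empty_range_errors():
    with pytest.raises(UndefinedValueError):
        cc.gc_content("ACGT", 3, 2)


def test_gc_content_equals_weighted_window_mean(small_ancestor):
    """Whole-genome GC equals the length-weighted mean of non-overlapping
    window GC values."""
    genome = small_ancestor.genome
    w = 1000
    L = (len(genome) // w) * w
    vals = [cc.gc_content(genome, i + 1, i + w) for i in range(0, L, w)]
    tail = cc.gc_content(genome, L + 1, len(genome)) if L < len(genome) else None
    weights = [w] * len(vals)
    if tail is not None:
        vals.append(tail)
        weights.append(len(genome) - L)
    assert cc.gc_content(genome) == pytest.approx(
        np.average(vals, weights=weights), abs=1e-9
    )


@pytest.mark.parametrize(
    "seq,expected",
    [("G" * 16, [1.0] * 4), ("C" * 16, [-1.0] * 4)],
)
def test_gc_skew_constant_sequences(seq, expected):
    s = cc.gc_skew_series(seq, window_bp=4, step_bp=4, circular=False)
    assert list(s.values) == expected


def test_gc_skew_two_windows():
    s = cc.gc_skew_series("GGGGCCCC", window_bp=4, step_bp=4, circular=False)
    assert list(s.values) == [1.0, -1.0]


def test_gc_skew_degenerate_window_flagged():
    s = cc.gc_skew_series("AAAATTTT", window_bp=4, step_bp=4, circular=False)
    assert list(s.values) == [0.0, 0.0]
    assert s.degenerate.all()


def test_replication_axis_on_constructed_genome():
    """G-rich first half / C-rich second half puts the origin at the
    junction near position 1 and the terminus near the midpoint."""
    rng = np.random.default_rng(0)
    L = 40000
    half = L // 2
    bases = np.array(list("ACGT"))
    first = bases[rng.choice(4, half, p=[0.28, 0.16, 0.28, 0.28])]
    second = bases[rng.choice(4, half, p=[0.28, 0.28, 0.16, 0.28])]
    seq = "".join(first) + "".join(second)
    axis = cc.infer_replication_axis(cc.gc_skew_series(seq, 2000, 200))
    def circ(a, b):
        d = abs(a - b) % L
        return min(d, L - d)
    assert circ(axis.origin_bp, 1) <= 2000
    assert circ(axis.terminus_bp, half) <= 2000


def test_replication_axis_rotation_equivariance():
    rng = np.random.default_rng(3)
    L = 40000
    bases = np.array(list("ACGT"))
    first = bases[rng.choice(4, L // 2, p=[0.28, 0.16, 0.28, 0.28])]
    second = bases[rng.choice(4, L // 2, p=[0.28, 0.28, 0.16, 0.28])]
    seq = "".join(first) + "".join(second)
    offset = 10000
    rotated = seq[offset:] + seq[:offset]
    ax1 = cc.infer_replication_axis(cc.gc_skew_series(seq, 2000, 200))
    ax2 = cc.infer_replication_axis(cc.gc_skew_series(rotated, 2000, 200))
    def circ(a, b):
        d = abs(a - b) % L
        return min(d, L - d)
    assert circ((ax1.terminus_bp - offset) % L, ax2.terminus_bp) <= 2000
    assert circ((ax1.origin_bp - offset) % L, ax2.origin_bp) <= 2000


def test_flat_skew_degenerate_axis():
    with pytest.raises(DegenerateAxisError):
        cc.infer_replication_axis(cc.gc_skew_series("G" * 1000, 100, 100))


def test_classify_strand_by_arc_and_midpoint():
    axis = ReplicationAxis(origin_bp=1, terminus_bp=500, genome_length=1000)
    fwd = cc.GeneFeature("a", "CDS", 10, 100, strand="+")
    assert cc.classify_strand(fwd, axis) == "leading"
    rev = cc.GeneFeature("b", "CDS", 10, 100, strand="-")
    assert cc.classify_strand(rev, axis) == "lagging"
    # beyond the terminus the assignment flips
    fwd2 = cc.GeneFeature("c", "CDS", 600, 700, strand="+")
    assert cc.classify_strand(fwd2, axis) == "lagging"
    # feature straddling the terminus is assigned by its midpoint
    strad = cc.GeneFeature("d", "CDS", 450, 560, strand="+")  # midpoint 505
    assert cc.classify_strand(strad, axis) == "lagging"


class TestDeviantGC:
    def test_no_island_no_regions(self):
        anc = cc.simulate_ancestor(n_genes=300, seed=5)
        assert cc.find_deviant_gc_regions(anc.genome) == []

    def test_planted_island_recovered(self):
        anc = cc.simulate_ancestor(n_genes=300, seed=5)
        child, truth = cc.evolve(
            anc, cc.EvolutionParams(island=(60000, 0.35), seed=5), genome_id="isl"
        )
        s, e, _ = truth.island["isl"]
        regions = cc.find_deviant_gc_regions(child.genome)
        low = [r for r in regions if r.direction == "low"]
        assert len(low) == 1
        r = low[0]
        ov = max(0, min(e, r.end) - max(s, r.start) + 1)
        recip = min(ov / (e - s + 1), ov / (r.end - r.start + 1))
        assert recip >= 0.9

    def test_two_islands_two_regions(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        def block(n, gc):
            p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            return "".join(bases[rng.choice(4, n, p=p)])
        seq = (
            block(100000, 0.44)
            + block(20000, 0.30)
            + block(200000, 0.44)
            + block(20000, 0.30)
            + block(100000, 0.44)
        )
        regions = cc.find_deviant_gc_regions(seq, circular=False)
        assert len([r for r in regions if r.direction == "low"]) == 2


def _census_fixture():
    """Annotation with the headline feature counts of a finished
    single-chromosome lactic-acid-bacterium genome: 1901 CDS (58 of them
    transposases), 85 pseudogenes (25 IS-related), mean gene 875 bp on a
    2,066,657 bp chromosome."""
    L = 2066657
    features = []
    pos = 1
    for i in range(1901):
        end = pos + 874
        features.append(
            cc.GeneFeature(
                f"c{i:05d}", "CDS", pos, end,
                product="IS3 family transposase" if i < 58 else "protein",
            )
        )
        pos = end + 2
    for i in range(85):
        end = pos + 400
        features.append(
            cc.GeneFeature(
                f"p{i:05d}", "pseudogene", pos, end,
                product="IS3 family transposase" if i < 25 else "degraded protein",
            )
        )
        pos = end + 2
    return cc.GenomeAnnotation(genome_id="fx", length=L, features=features)


class TestCensus:
    def test_table_scale_arithmetic(self):
        c = cc.census(_census_fixture())
        assert c.n_cds == 1901 and c.n_pseudogenes == 85
        assert c.n_is_elements == 83 and c.n_is_pseudogenes == 25
        assert round(c.pseudogene_share_pct, 1) == 4.3
        assert round(c.is_share_pct, 1) == 4.2
        assert round(c.is_pseudogene_share_pct, 1) == 29.4
        assert round(c.summary_coding_density_pct, 1) == 80.5
        assert c.mean_gene_len_bp == pytest.approx(875.0)

    def test_percentages_recompute_from_integers(self):
        c = cc.census(_census_fixture())
        assert c.pseudogene_share_pct == pytest.approx(
            100 * c.n_pseudogenes / (c.n_cds + c.n_pseudogenes)
        )
        assert c.is_pseudogene_share_pct == pytest.approx(
            100 * c.n_is_pseudogenes / c.n_pseudogenes
        )

    def test_empty_annotation_all_zero(self):
        c = cc.census(cc.GenomeAnnotation(genome_id="e", length=1000, features=[]))
        assert (c.n_cds, c.n_pseudogenes, c.n_is_elements, c.n_trna) == (0, 0, 0, 0)
        assert c.coding_density_pct == 0.0


def _rrna_operon(prefix, start, strand="+"):
    return [
        cc.GeneFeature(f"{prefix}_16s", "rRNA", start, start + 1500, strand, "16S ribosomal RNA"),
        cc.GeneFeature(f"{prefix}_23s", "rRNA", start + 1600, start + 4500, strand, "23S ribosomal RNA"),
        cc.GeneFeature(f"{prefix}_5s", "rRNA", start + 4600, start + 4710, strand, "5S ribosomal RNA"),
    ]


class TestRrnaOperons:
    def test_six_planted_triplets(self):
        features = []
        for i in range(6):
            features += _rrna_operon(f"op{i}", 10000 + i * 50000)
        ann = cc.GenomeAnnotation(genome_id="r", length=400000, features=features)
        assert cc.count_rrna_operons(ann) == 6

    def test_lone_5s_not_an_operon(self):
        features = _rrna_operon("op0", 10000)
        features.append(
            cc.GeneFeature("lone_5s", "rRNA", 90000, 90110, "+", "5S ribosomal RNA")
        )
        ann = cc.GenomeAnnotation(genome_id="r", length=200000, features=features)
        assert cc.count_rrna_operons(ann) == 1

    def test_adjacent_triplets_split_when_gap_exceeded(self):
        features = _rrna_operon("op0", 10000) + _rrna_operon("op1", 16000)
        ann = cc.GenomeAnnotation(genome_id="r", length=100000, features=features)
        # gap between op0 end (14710) and op1 start (16000) is 1290 > 1000
        assert cc.count_rrna_operons(ann, max_gap_bp=1000) == 2
        assert cc.count_rrna_operons(ann, max_gap_bp=2000) == 1


@pytest.mark.parametrize("gap,unit,expected", [(887, 65, 13), (64, 65, 0), (130, 65, 2)])
def test_spacer_capacity(gap, unit, expected):
    assert cc.spacer_capacity(gap, unit) == expected


def test_spacer_capacity_negative_gap_errors():
    with pytest.raises(UndefinedValueError):
        cc.spacer_capacity(-1, 65)


class TestMotifScan:
    def _proteome(self, seqs):
        p = cc.Proteome(genome_id="m")
        for tag, s in seqs.items():
            p.proteins[tag] = cc.SequenceRecord(id=tag, residues=s, alphabet="protein")
        return p

    def test_sortase_motif_lowercase_reports_but_never_vetoes(self):
        prot = self._proteome({"p1": "MSTDNKLPKTGEESSN"})
        hits = cc.motif_scan(prot, MotifPattern("LPxTGc", c_terminal_window=50))
        assert len(hits) == 1
        assert hits[0].matched == "LPKTGE"
        assert hits[0].lowercase_agreement == 0.0  # E != c at the preferred site

    def test_pediocin_box_wildcards(self):
        prot = self._proteome({"bac": "MKYGNGVHCGKKGCSVDWGKA"})
        hits = cc.motif_scan(prot, "YGNGVXCXXXXCXV")
        assert len(hits) == 1 and hits[0].position == 3

    def test_no_hit_without_required_residues(self):
        prot = self._proteome({"p1": "MSTDNKLPKAEEESSN"})  # no TG
        assert cc.motif_scan(prot, "LPxTGc") == []

    def test_c_terminal_window_excludes_internal_hits(self):
        seq = "MKLPNTGA" + "A" * 100
        prot = self._proteome({"p1": seq})
        assert cc.motif_scan(prot, MotifPattern("LPxTG")) != []
        assert cc.motif_scan(prot, MotifPattern("LPxTG", c_terminal_window=50)) == []


class TestGeneSetGC:
    def test_mean_min_max(self):
        genome = cc.SequenceRecord(id="g", residues="ATGCATGCAT" + "GGGCCGGCCG")
        g1 = cc.GeneFeature("a", "CDS", 1, 10)
        g2 = cc.GeneFeature("b", "CDS", 11, 20)
        mean, lo, hi = cc.gene_set_gc_summary([g1, g2], genome)
        assert (lo, hi) == (40.0, 100.0)
        assert mean == pytest.approx(70.0)

    def test_single_gene_degenerate(self):
        genome = cc.SequenceRecord(id="g", residues="ATGC" * 10)
        g = cc.GeneFeature("a", "CDS", 1, 40)
        mean, lo, hi = cc.gene_set_gc_summary([g], genome)
        assert mean == lo == hi

    def test_empty_set_errors(self):
        genome = cc.SequenceRecord(id="g", residues="ATGC")
        with pytest.raises(UndefinedValueError):
            cc.gene_set_gc_summary([], genome)
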