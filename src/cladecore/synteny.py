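"""Dotplot-style genome comparison: maximal exact DNA matches on both
strands, ortholog anchors, greedy colinear chaining into synteny blocks,
and a symmetry score for terminus-centred inversions.

Forward matches appear as ascending diagonals in a dotplot (conventionally
red), reverse matches as descending diagonals (blue); a single inversion
centred on the replication terminus produces the familiar X pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq

from .genome_io import GenomeAnnotation, SequenceRecord
from .genome_stats import ReplicationAxis
from .orthology import OrthologEdge


@dataclass(frozen=True)
class ExactMatch:
    """A maximal exact match; coordinates are 1-based on the forward
    strands of both genomes (b_start is the leftmost matched base)."""

    a_start: int
    b_start: int
    length: int
    orientation: str  # "forward" or "reverse"

    @property
    def a_end(self) -> int:
        return self.a_start + self.length - 1

    @property
    def b_end(self) -> int:
        return self.b_start + self.length - 1


def _seq_str(seq: SequenceRecord | str) -> str:
    return seq.residues if isinstance(seq, SequenceRecord) else seq.upper()


def _forward_matches(a: bytes, b: bytes, min_len: int) -> list[tuple[int, int, int]]:
    """All left-maximal, right-maximal exact matches >= min_len (0-based)."""
    index: dict[bytes, list[int]] = {}
    for j in range(len(b) - min_len + 1):
        index.setdefault(b[j : j + min_len], []).append(j)
    out = []
    n, m = len(a), len(b)
    for i in range(n - min_len + 1):
        for j in index.get(a[i : i + min_len], ()):
            if i > 0 and j > 0 and a[i - 1] == b[j - 1]:
                continue  # not left-maximal; counted at its leftmost seed
            k = min_len
            while i + k < n and j + k < m and a[i + k] == b[j + k]:
                k += 1
            out.append((i, j, k))
    return out


def find_exact_matches(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    min_len: int = 20,
    both_strands: bool = True,
    unique: bool = False,
    allow_short: bool = False,
) -> list[ExactMatch]:
    """All maximal exact matches >= min_len between two DNA sequences.

    ``min_len < 8`` is refused unless ``allow_short`` is set (short seeds
    explode quadratically on real genomes).  With ``unique`` only matches
    whose matched substring occurs exactly once in each genome are kept
    (MUM-style filtering).
    """
    if min_len < 8 and not allow_short:
        raise ValueError("min_len < 8 refused; pass allow_short=True to override")
    sa = _seq_str(a).encode()
    sb = _seq_str(b).encode()
    if not sa or not sb:
        raise ValueError("empty sequence")
    matches: list[ExactMatch] = []
    for i, j, k in _forward_matches(sa, sb, min_len):
        matches.append(ExactMatch(i + 1, j + 1, k, "forward"))
    if both_strands:
        rb = str(Seq(sb.decode()).reverse_complement()).encode()
        m = len(sb)
        for i, jr, k in _forward_matches(sa, rb, min_len):
            # position jr in revcomp(b) maps to forward-strand start m-jr-k
            matches.append(ExactMatch(i + 1, m - jr - k + 1, k, "reverse"))
    if unique:
        rb_full = str(Seq(sb.decode()).reverse_complement()).encode()
        kept = []
        for mt in matches:
            sub = sa[mt.a_start - 1 : mt.a_start - 1 + mt.length]
            rsub = str(Seq(sub.decode()).reverse_complement()).encode()
            in_a = sa.count(sub) + (sa.count(rsub) if sub != rsub else 0)
            in_b = sb.count(sub) + (rb_full.count(sub) if sub != rsub else 0)
            if in_a == 1 and in_b == 1:
                kept.append(mt)
        matches = kept
    matches.sort(key=lambda mt: (mt.a_start, mt.b_start, mt.orientation))
    return matches


# ---------------------------------------------------------------------------
# Anchors


@dataclass(frozen=True)
class Anchor:
    """A synteny anchor: paired positions with relative orientation."""

    a_pos: float
    b_pos: float
    orientation: str  # "forward" (same strand) or "reverse"
    a_tag: str = ""
    b_tag: str = ""


def anchor_from_orthologs(
    edges: list[OrthologEdge], annA: GenomeAnnotation, annB: GenomeAnnotation
) -> list[Anchor]:
    """One anchor per ortholog edge at the midpoints of the two loci."""
    featA = {f.locus_tag: f for f in annA.features}
    featB = {f.locus_tag: f for f in annB.features}
    anchors = []
    for e in edges:
        fa = featA[e.tag_a]
        fb = featB[e.tag_b]
        anchors.append(
            Anchor(
                a_pos=fa.midpoint(annA.length),
                b_pos=fb.midpoint(annB.length),
                orientation="forward" if fa.strand == fb.strand else "reverse",
                a_tag=e.tag_a,
                b_tag=e.tag_b,
            )
        )
    anchors.sort(key=lambda x: x.a_pos)
    return anchors


def anchors_from_matches(matches: list[ExactMatch]) -> list[Anchor]:
    return sorted(
        (
            Anchor(
                a_pos=(m.a_start + m.a_end) / 2.0,
                b_pos=(m.b_start + m.b_end) / 2.0,
                orientation=m.orientation,
            )
            for m in matches
        ),
        key=lambda x: x.a_pos,
    )


# ---------------------------------------------------------------------------
# Chaining


@dataclass
class SyntenyBlock:
    anchors: list[Anchor]
    orientation: str

    @property
    def score(self) -> int:
        return len(self.anchors)

    @property
    def a_range(self) -> tuple[float, float]:
        return (
            min(x.a_pos for x in self.anchors),
            max(x.a_pos for x in self.anchors),
        )

    @property
    def b_range(self) -> tuple[float, float]:
        return (
            min(x.b_pos for x in self.anchors),
            max(x.b_pos for x in self.anchors),
        )


def chain_blocks(
    anchors: list[Anchor],
    max_gap_bp: float = 20000,
    min_anchors: int = 3,
) -> list[SyntenyBlock]:
    """Greedy colinear chaining of anchors into synteny blocks.

    Anchors are scanned in a-order; an anchor joins the most recently
    extended chain of matching orientation whose last anchor is within
    ``max_gap_bp`` on both genomes and colinear (b ascending for forward
    chains, descending for reverse).  Chains shorter than ``min_anchors``
    are discarded.  Each anchor belongs to at most one chain, so chaining
    conserves total anchor count.
    """
    anchors = sorted(anchors, key=lambda x: (x.a_pos, x.b_pos))
    chains: list[list[Anchor]] = []
    for anc in anchors:
        placed = False
        for chain in reversed(chains):
            last = chain[-1]
            if last.orientation != anc.orientation:
                continue
            if anc.a_pos - last.a_pos > max_gap_bp:
                continue
            db = anc.b_pos - last.b_pos
            if anc.orientation == "forward" and (db < 0 or db > max_gap_bp):
                continue
            if anc.orientation == "reverse" and (db > 0 or -db > max_gap_bp):
                continue
            chain.append(anc)
            placed = True
            break
        if not placed:
            chains.append([anc])
    return [
        SyntenyBlock(anchors=c, orientation=c[0].orientation)
        for c in chains
        if len(c) >= min_anchors
    ]


# ---------------------------------------------------------------------------
# Inversion symmetry


def _circ_dist(x: float, y: float, length: float) -> float:
    d = abs(x - y) % length
    return min(d, length - d)


def inversion_symmetry_score(
    blocks: list[SyntenyBlock],
    axis: ReplicationAxis,
    tol_frac: float = 0.05,
) -> float | None:
    """Fraction of reverse-block anchors mirror-symmetric about the
    origin-terminus axis.

    An inversion centred at the terminus maps position x to 2*ter - x, so
    symmetric anchor pairs have circular midpoint (x+y)/2 at the terminus
    (or, for the antipodal branch, at the origin).  Returns None when no
    reverse block exists.
    """
    L = axis.genome_length
    rev_anchors = [a for b in blocks if b.orientation == "reverse" for a in b.anchors]
    if not rev_anchors:
        return None
    tol = tol_frac * L
    n_sym = 0
    for anc in rev_anchors:
        m1 = ((anc.a_pos + anc.b_pos) / 2.0) % L
        m2 = (m1 + L / 2.0) % L
        d = min(
            _circ_dist(m1, axis.terminus_bp, L),
            _circ_dist(m2, axis.terminus_bp, L),
        )
        if d <= tol:
            n_sym += 1
    return n_sym / len(rev_anchors)


# ---------------------------------------------------------------------------
# Plotting


def plot_dotplot(
    anchors: list[Anchor],
    path: str | Path,
    title: str = "",
    a_label: str = "genome A (bp)",
    b_label: str = "genome B (bp)",
) -> Path:
    """Render anchors as a dotplot PNG/SVG (forward red, reverse blue)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for orientation, color in (("forward", "red"), ("reverse", "blue")):
        xs = [a.a_pos for a in anchors if a.orientation == orientation]
        ys = [a.b_pos for a in anchors if a.orientation == orientation]
        ax.scatter(xs, ys, s=4, c=color, label=orientation)
    ax.set_xlabel(a_label)
    ax.set_ylabel(b_label)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
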