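"""Protein-protein comparison engine: Smith-Waterman local alignment with
affine gaps, k-mer candidate seeding, and per-genome best-hit tables.

Scoring follows common protein-search defaults: BLOSUM62 with a gap of
length L costing 11 + (L-1) (``gap_open`` is the score of the first gap
column, ``gap_extend`` of each further column).  Identity is the number
of identical aligned residues divided by the number of alignment columns
(gap columns included in the denominator); ``X`` never counts as an
identity.  Coverage is the aligned span divided by the full sequence
length, computed for query and subject separately.

The dynamic-programming kernel is deterministic: on ties it prefers a
diagonal move over a gap in the subject over a gap in the query, prefers
opening a gap over extending one, and starts the traceback at the
first maximal cell in row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .errors import EmptyInputError
from .genome_io import Proteome, SequenceRecord

ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX"
_X_CODE = ALPHABET.index("X")

_ENCODE = np.full(128, _X_CODE, dtype=np.int64)
for _i, _ch in enumerate(ALPHABET):
    _ENCODE[ord(_ch)] = _i


def encode_protein(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    return _ENCODE[arr]


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap scores (both negative)."""

    matrix: np.ndarray
    gap_open: int = -11
    gap_extend: int = -1
    name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError("matrix must cover the 23-letter protein alphabet")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")

    @classmethod
    def blosum62(cls, gap_open: int = -11, gap_extend: int = -1) -> "ScoringScheme":
        blosum = substitution_matrices.load("BLOSUM62")
        idx = [blosum.alphabet.index(ch) for ch in ALPHABET]
        mat = np.asarray(blosum)[np.ix_(idx, idx)].astype(np.int64)
        return cls(matrix=mat, gap_open=gap_open, gap_extend=gap_extend)


@njit(cache=False)
def _sw_affine(a, b, mat, gap_open, gap_extend, x_code):  # pragma: no cover
    n = a.size
    m = b.size
    NEG = np.int64(-(10**9))
    # rolling score rows; full matrices only for the uint8 traceback pointers
    H_prev = np.zeros(m + 1, np.int64)
    H_cur = np.zeros(m + 1, np.int64)
    E_row = np.full(m + 1, NEG, np.int64)
    ptrH = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 gap-in-b, 3 gap-in-a
    ptrE = np.zeros((n + 1, m + 1), np.uint8)  # 1 open, 0 extend
    ptrF = np.zeros((n + 1, m + 1), np.uint8)
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        H_cur[0] = 0
        f = NEG
        ai = a[i - 1]
        mrow = mat[ai]
        for j in range(1, m + 1):
            eo = H_prev[j] + gap_open
            ee = E_row[j] + gap_extend
            if eo >= ee:
                E_row[j] = eo
                ptrE[i, j] = 1
            else:
                E_row[j] = ee
                ptrE[i, j] = 0
            fo = H_cur[j - 1] + gap_open
            fe = f + gap_extend
            if fo >= fe:
                f = fo
                ptrF[i, j] = 1
            else:
                f = fe
                ptrF[i, j] = 0
            h = H_prev[j - 1] + mrow[b[j - 1]]
            p = np.uint8(1)
            if E_row[j] > h:
                h = E_row[j]
                p = np.uint8(2)
            if f > h:
                h = f
                p = np.uint8(3)
            if h <= 0:
                h = np.int64(0)
                p = np.uint8(0)
            H_cur[j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = H_prev
        H_prev = H_cur
        H_cur = tmp
    if best == 0:
        return best, 0, 0, 0, 0, 0, 0, 0, 0
    i = bi
    j = bj
    state = 0
    n_id = 0
    n_cols = 0
    n_mismatch = 0
    n_gapopen = 0
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                n_cols += 1
                if a[i - 1] == b[j - 1] and a[i - 1] != x_code:
                    n_id += 1
                else:
                    n_mismatch += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            n_cols += 1
            pe = ptrE[i, j]
            i -= 1
            if pe == 1:
                n_gapopen += 1
                state = 0
        else:
            n_cols += 1
            pf = ptrF[i, j]
            j -= 1
            if pf == 1:
                n_gapopen += 1
                state = 0
    return best, i + 1, bi, j + 1, bj, n_id, n_cols, n_mismatch, n_gapopen


@dataclass
class AlignmentResult:
    """Identity/coverage summary of one local alignment."""

    query: str
    subject: str
    score: int
    identity: float
    aln_len: int
    q_cov: float
    s_cov: float
    q_range: tuple[int, int] | None
    s_range: tuple[int, int] | None
    n_identical: int = 0
    n_mismatch: int = 0
    n_gap_opens: int = 0

    @property
    def is_hit(self) -> bool:
        return self.score > 0


def local_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scheme: ScoringScheme | None = None,
    query_id: str | None = None,
    subject_id: str | None = None,
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two proteins."""
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    a_seq = a.residues if isinstance(a, SequenceRecord) else a
    b_seq = b.residues if isinstance(b, SequenceRecord) else b
    if not a_seq or not b_seq:
        raise EmptyInputError("cannot align empty sequences")
    qid = query_id or (a.id if isinstance(a, SequenceRecord) else "query")
    sid = subject_id or (b.id if isinstance(b, SequenceRecord) else "subject")
    return _align_encoded(
        encode_protein(a_seq), encode_protein(b_seq), scheme, qid, sid
    )


def _align_encoded(
    enc_a: np.ndarray,
    enc_b: np.ndarray,
    scheme: ScoringScheme,
    qid: str,
    sid: str,
) -> AlignmentResult:
    (score, qs, qe, ss, se, n_id, n_cols, n_mm, n_go) = _sw_affine(
        enc_a,
        enc_b,
        scheme.matrix,
        np.int64(scheme.gap_open),
        np.int64(scheme.gap_extend),
        np.int64(_X_CODE),
    )
    if score == 0:
        return AlignmentResult(qid, sid, 0, 0.0, 0, 0.0, 0.0, None, None)
    return AlignmentResult(
        query=qid,
        subject=sid,
        score=int(score),
        identity=n_id / n_cols,
        aln_len=int(n_cols),
        q_cov=(qe - qs + 1) / enc_a.size,
        s_cov=(se - ss + 1) / enc_b.size,
        q_range=(int(qs), int(qe)),
        s_range=(int(ss), int(se)),
        n_identical=int(n_id),
        n_mismatch=int(n_mm),
        n_gap_opens=int(n_go),
    )


# ---------------------------------------------------------------------------
# Candidate seeding


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def seed_candidates(
    pA: Proteome, pB: Proteome, k: int = 4, min_shared: int = 2
) -> list[tuple[str, str]]:
    """Pairs sharing >= min_shared distinct k-mers, plus every pair that
    involves a protein shorter than k (which cannot be seeded)."""
    if k < 3:
        raise ValueError("k must be >= 3")
    index: dict[str, list[str]] = {}
    short_b = []
    for tag_b, rec_b in pB:
        if len(rec_b) < k:
            short_b.append(tag_b)
            continue
        for kmer in _kmer_set(rec_b.residues, k):
            index.setdefault(kmer, []).append(tag_b)
    pairs: list[tuple[str, str]] = []
    for tag_a, rec_a in pA:
        if len(rec_a) < k:
            for tag_b, _ in pB:
                pairs.append((tag_a, tag_b))
            continue
        counts: dict[str, int] = {}
        for kmer in _kmer_set(rec_a.residues, k):
            for tag_b in index.get(kmer, ()):
                counts[tag_b] = counts.get(tag_b, 0) + 1
        for tag_b, c in counts.items():
            if c >= min_shared:
                pairs.append((tag_a, tag_b))
        for tag_b in short_b:
            pairs.append((tag_a, tag_b))
    return pairs


# ---------------------------------------------------------------------------
# Best-hit tables


@dataclass
class BestHitTable:
    """Per-query alignment hits against one subject genome, best first.

    Hits are ordered by descending score, then descending identity, then
    subject locus tag, so ``best()`` is deterministic.
    """

    query_genome: str
    subject_genome: str
    hits: dict[str, list[AlignmentResult]] = field(default_factory=dict)

    def best(self, query: str) -> AlignmentResult | None:
        lst = self.hits.get(query)
        return lst[0] if lst else None

    def all_queries(self) -> list[str]:
        return list(self.hits)


def best_hits(
    pA: Proteome,
    pB: Proteome,
    scheme: ScoringScheme | None = None,
    exhaustive: bool = False,
    k: int = 4,
    min_shared: int = 3,
) -> BestHitTable:
    """Align candidate pairs A->B and keep each query's hits, best first."""
    if len(pA) == 0:
        raise EmptyInputError("empty query proteome")
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    if exhaustive or len(pB) == 0:
        pairs = [(qa, qb) for qa in pA.proteins for qb in pB.proteins]
    else:
        pairs = seed_candidates(pA, pB, k=k, min_shared=min_shared)
    enc_a = {tag: encode_protein(rec.residues) for tag, rec in pA}
    enc_b = {tag: encode_protein(rec.residues) for tag, rec in pB}
    table = BestHitTable(pA.genome_id, pB.genome_id)
    for tag_a, tag_b in pairs:
        res = _align_encoded(enc_a[tag_a], enc_b[tag_b], scheme, tag_a, tag_b)
        if res.is_hit:
            table.hits.setdefault(tag_a, []).append(res)
    for lst in table.hits.values():
        lst.sort(key=lambda r: (-r.score, -r.identity, r.subject))
    return table


# ---------------------------------------------------------------------------
# Tab-separated interchange (BLAST outfmt-6 field order)


def write_hits_tsv(table: BestHitTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for query in table.hits:
            for r in table.hits[query]:
                n_gaps = r.aln_len - r.n_identical - r.n_mismatch
                fh.write(
                    "\t".join(
                        [
                            r.query,
                            r.subject,
                            f"{100.0 * r.identity:.2f}",
                            str(r.aln_len),
                            str(r.n_mismatch),
                            str(r.n_gap_opens),
                            str(r.q_range[0]),
                            str(r.q_range[1]),
                            str(r.s_range[0]),
                            str(r.s_range[1]),
                            ".",
                            str(r.score),
                        ]
                    )
                    + "\n"
                )
    return path


def read_hits_tsv(
    path: str | Path,
    query_lengths: dict[str, int],
    subject_lengths: dict[str, int],
    query_genome: str = "A",
    subject_genome: str = "B",
) -> BestHitTable:
    """Read a 12-column hit table (accepts genuine BLAST outfmt-6 output).

    Sequence lengths are required to reconstruct coverage fractions.
    """
    table = BestHitTable(query_genome, subject_genome)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qid, sid = f[0], f[1]
            aln_len = int(f[3])
            qs, qe, ss, se = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            score = int(float(f[11]))
            res = AlignmentResult(
                query=qid,
                subject=sid,
                score=score,
                identity=float(f[2]) / 100.0,
                aln_len=aln_len,
                q_cov=(qe - qs + 1) / query_lengths[qid],
                s_cov=(abs(se - ss) + 1) / subject_lengths[sid],
                q_range=(qs, qe),
                s_range=(ss, se),
                n_mismatch=int(f[4]),
                n_gap_opens=int(f[5]),
            )
            table.hits.setdefault(qid, []).append(res)
    for lst in table.hits.values():
        lst.sort(key=lambda r: (-r.score, -r.identity, r.subject))
    return table
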