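"""Independent naive Smith-Waterman/Gotoh oracle in plain Python.

Full DP matrices, no shared code with the package kernel.  The tie-break
convention is the documented one: diagonal move preferred over a gap in
the subject over a gap in the query, gap opening preferred over
extension, traceback starting at the first maximal cell in row-major
order.  Identity counts identical non-X residues over all alignment
columns; coverage is the aligned span over the full length.
"""

NEG = -(10**9)


def naive_local_align(a: str, b: str, matrix, alphabet: str, gap_open: int, gap_extend: int):
    """Return (score, identity, aln_len, q_cov, s_cov, q_range, s_range)."""
    idx = {ch: i for i, ch in enumerate(alphabet)}
    x = idx["X"]
    ea = [idx.get(ch, x) for ch in a.upper()]
    eb = [idx.get(ch, x) for ch in b.upper()]
    n, m = len(ea), len(eb)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    PH = [[0] * (m + 1) for _ in range(n + 1)]
    PE = [[0] * (m + 1) for _ in range(n + 1)]
    PF = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo = H[i - 1][j] + gap_open
            ee = E[i - 1][j] + gap_extend
            if eo >= ee:
                E[i][j], PE[i][j] = eo, 1
            else:
                E[i][j], PE[i][j] = ee, 0
            fo = H[i][j - 1] + gap_open
            fe = F[i][j - 1] + gap_extend
            if fo >= fe:
                F[i][j], PF[i][j] = fo, 1
            else:
                F[i][j], PF[i][j] = fe, 0
            h = H[i - 1][j - 1] + matrix[ea[i - 1]][eb[j - 1]]
            p = 1
            if E[i][j] > h:
                h, p = E[i][j], 2
            if F[i][j] > h:
                h, p = F[i][j], 3
            if h <= 0:
                h, p = 0, 0
            H[i][j], PH[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j
    if best == 0:
        return 0, 0.0, 0, 0.0, 0.0, None, None
    i, j, state = bi, bj, 0
    n_id = n_cols = 0
    while True:
        if state == 0:
            p = PH[i][j]
            if p == 0:
                break
            if p == 1:
                n_cols += 1
                if ea[i - 1] == eb[j - 1] and ea[i - 1] != x:
                    n_id += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            n_cols += 1
            pe = PE[i][j]
            i -= 1
            if pe == 1:
                state = 0
        else:
            n_cols += 1
            pf = PF[i][j]
            j -= 1
            if pf == 1:
                state = 0
    return (
        best,
        n_id / n_cols,
        n_cols,
        (bi - i) / n,
        (bj - j) / m,
        (i + 1, bi),
        (j + 1, bj),
    )
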