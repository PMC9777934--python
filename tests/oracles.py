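"""Independent reference implementations used only to check the package.

These deliberately avoid the production code paths: the TIR oracles
enumerate every candidate explicitly (one as pure-Python loops, one as a
one-hot matrix product), the translated-search oracle runs full local
dynamic programming on every frame, and the NJ oracle is scikit-bio's
implementation.
"""

from __future__ import annotations

import numpy as np

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def revcomp_py(seq: str) -> str:
    return "".join(COMP.get(c, "N") for c in reversed(seq.upper()))


def tir_bruteforce(seq, min_len, max_len, max_frac, window):
    """Triple-loop enumeration of every (5' offset, 3' offset, length).

    Returns (score, length, tir5_start, tir3_start, mismatches) of the
    best pair under the documented tie-break, or None.  Only usable on
    short loci.
    """
    n = len(seq)
    best = None
    for L in range(min_len, min(max_len, window) + 1):
        for i in range(0, window - L + 1):
            a = seq[i:i + L]
            for t3 in range(n - window, n - L + 1):
                if t3 < i + L:
                    continue
                b = revcomp_py(seq[t3:t3 + L])
                mism = sum(1 for x, y in zip(a, b) if x != y or x not in COMP)
                if mism > max_frac * L + 1e-9:
                    continue
                score = L - 2 * mism
                key = (score, L, -i, t3)
                if best is None or key > best[:4]:
                    best = (score, L, -i, t3, mism)
    if best is None:
        return None
    score, L, neg_i, t3, mism = best
    return (score, L, -neg_i, t3, mism)


def tir_matrix_oracle(seq, min_len, max_len, max_frac, window):
    """Exhaustive all-pairs scan via a one-hot match-matrix product.

    Evaluates every length over every diagonal of the 5'-window x
    reverse-complemented-3'-window match matrix; no pruning.  Tie-break
    identical to the brute-force enumeration: (score, length, smaller 5'
    offset, larger 3' start).
    """
    n = len(seq)
    A = seq[:window].upper()
    B = revcomp_py(seq[n - window:])
    onehot = {b: i for i, b in enumerate("ACGT")}

    def enc(s):
        out = np.zeros((len(s), 4))
        for i, c in enumerate(s):
            if c in onehot:
                out[i, onehot[c]] = 1.0
        return out

    M = enc(A) @ enc(B).T          # match matrix, floats 0/1
    W = window
    best = None
    for L in range(min_len, min(max_len, W) + 1):
        for off in range(-(W - 1), W):
            diag = np.diagonal(M, offset=off)
            if len(diag) < L:
                continue
            c = np.concatenate([[0.0], np.cumsum(diag)])
            matches = c[L:] - c[:-L]
            for a_ in range(len(matches)):
                i = a_ if off >= 0 else a_ - off
                j = a_ + off if off >= 0 else a_
                t3 = n - j - L
                if i + L > t3:
                    continue
                m = int(round(L - matches[a_]))
                if m > max_frac * L + 1e-9:
                    continue
                score = L - 2 * m
                key = (score, L, -i, t3)
                if best is None or key > best[:4]:
                    best = (score, L, -i, t3, m)
    if best is None:
        return None
    score, L, neg_i, t3, m = best
    return (score, L, -neg_i, t3, m)


def tir_matrix_oracle_fast(seq, min_len, max_len, max_frac, window):
    """Vectorised variant of the matrix oracle (same enumeration order and
    tie-break, no early termination or candidate pruning)."""
    n = len(seq)
    A = seq[:window].upper()
    B = revcomp_py(seq[n - window:])
    code = np.full(256, 4, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    a = code[np.frombuffer(A.encode(), dtype=np.uint8)]
    b = code[np.frombuffer(B.encode(), dtype=np.uint8)]
    M = (a[:, None] == b[None, :]) & (a[:, None] < 4)
    W = window
    offsets = np.arange(-(W - 1), W)
    D = np.zeros((len(offsets), W), dtype=bool)
    dlen = np.zeros(len(offsets), dtype=np.int64)
    i0 = np.where(offsets < 0, -offsets, 0)
    j0 = np.where(offsets > 0, offsets, 0)
    for k, off in enumerate(offsets):
        d = np.diagonal(M, offset=off)
        dlen[k] = len(d)
        D[k, :len(d)] = d
    C = np.zeros((len(offsets), W + 1), dtype=np.int32)
    np.cumsum(D, axis=1, out=C[:, 1:])
    # L-independent index fields over the full (diagonal, start) grid
    aidx_full = np.arange(W, dtype=np.int32)[None, :]
    i_full = (i0[:, None] + aidx_full).astype(np.int32)
    j_full = (j0[:, None] + aidx_full).astype(np.int32)
    nj_full = (n - j_full).astype(np.int32)            # t3 = nj - L
    room_full = (dlen[:, None] - aidx_full).astype(np.int32)   # >= L needed
    sep_full = (nj_full - i_full)                      # >= 2L for no overlap
    NEG = np.iinfo(np.int32).min
    best = None
    for L in range(min_len, min(max_len, W) + 1):
        ncol = W + 1 - L
        matches = C[:, L:] - C[:, :-L]
        mism = L - matches
        ok = (room_full[:, :ncol] >= L) & (sep_full[:, :ncol] >= 2 * L) \
            & (mism <= max_frac * L + 1e-9)
        if not ok.any():
            continue
        score = np.where(ok, 2 * matches - L, NEG)
        mx = int(score.max())
        cand = np.argwhere(score == mx)
        keys = [(mx, L, -int(i_full[r, c]), int(nj_full[r, c]) - L, int(mism[r, c]))
                for r, c in cand]
        top = max(keys)
        if best is None or top[:4] > best[:4]:
            best = top
    if best is None:
        return None
    score, L, neg_i, t3, m = best
    return (score, L, -neg_i, t3, m)


def sw_sixframe_oracle(genome_contig: str, query_protein: str):
    """Best local protein alignment over all six frames by full DP.

    Returns (score, nt_start, nt_end, strand) of the top-scoring locus.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices
    from Bio.Seq import Seq

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    best = None
    n = len(genome_contig)
    for strand in "+-":
        seq = genome_contig if strand == "+" else revcomp_py(genome_contig)
        for f in range(3):
            prot = str(Seq(seq[f:f + 3 * ((n - f) // 3)]).translate())
            if not prot:
                continue
            aln = aligner.align(query_protein, prot)
            if len(aln) == 0:
                continue
            a = aln[0]
            ss, se = int(a.aligned[1][0][0]), int(a.aligned[1][-1][1])
            nt_s, nt_e = f + 3 * ss, f + 3 * se
            if strand == "-":
                nt_s, nt_e = n - nt_e, n - nt_s
            if best is None or a.score > best[0]:
                best = (float(a.score), nt_s, nt_e, strand)
    return best


def skbio_nj_tip_distances(D: np.ndarray, labels: list[str]) -> dict:
    """Leaf-to-leaf path lengths of scikit-bio's NJ tree."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(D, ids=labels))
    out = {}
    for i, a in enumerate(labels):
        for b_ in labels[i + 1:]:
            key = (a, b_) if a < b_ else (b_, a)
            out[key] = tree.find(a).distance(tree.find(b_))
    return out
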