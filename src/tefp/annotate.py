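"""Element boundary annotation: TIRs, TA TSDs, the transposase ORF, and
full/intact classification, plus per-genome consensus or representative
construction.

A copy is *full* when both terminal inverted repeats are detectable and
the two flanking target-site duplications are identical; it is *intact*
when, in addition, its longest ORF encodes a transposase of at least
300 aa.  Element coordinates run TIR-start to TIR-end (both TIRs
included, TSDs excluded), 0-based half-open.

TIR detection is a gapless inverted-repeat scan (+1 match / -1 mismatch)
with a mismatch-fraction tolerance.  For search windows up to 800 nt the
scan is exhaustive over every (5' offset, 3' offset, length) triple; for
wider windows (loci extracted with long flanks) candidate repeat pairs
are first localized with exact 10-mer inverted seeds and then refined
with the same exhaustive scan inside the candidate subwindows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from tefp.msa import align
from tefp.simulate import revcomp

_NT_IDX = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _NT_IDX[ord(_b)] = _i
    _NT_IDX[ord(_b.lower())] = _i

_STOPS = {"TAA", "TAG", "TGA"}

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass
class TirPair:
    """A detected terminal-inverted-repeat pair on a locus."""

    tir5_start: int
    tir3_start: int
    length: int
    mismatches: int
    score: int

    @property
    def tir3_end(self) -> int:
        return self.tir3_start + self.length

    def seqs(self, locus: str) -> tuple[str, str]:
        return (locus[self.tir5_start:self.tir5_start + self.length],
                locus[self.tir3_start:self.tir3_start + self.length])


def _best_gapless_ir(
    locus: str,
    aspan: tuple[int, int],
    bspan: tuple[int, int],
    min_len: int,
    max_len: int,
    max_mismatch_frac: float,
) -> Optional[TirPair]:
    """Best gapless inverted-repeat pair with the 5' copy in ``aspan`` and
    the 3' copy in ``bspan``, by exhaustive scan over every offset pair
    and length.

    Score is matches - mismatches.  Ties break toward longer length, then
    smaller 5' offset, then outermost (larger) 3' start.
    """
    n = len(locus)
    a0, a1 = aspan
    b0, b1 = bspan
    A = _NT_IDX[np.frombuffer(locus[a0:a1].encode(), dtype=np.uint8)]
    B = _NT_IDX[np.frombuffer(revcomp(locus[b0:b1]).encode(), dtype=np.uint8)]
    la, lb = len(A), len(B)
    if la < min_len or lb < min_len:
        return None
    # match matrix and its diagonals; N never matches
    M = (A[:, None] == B[None, :]) & (A[:, None] < 4)
    offsets = np.arange(-(la - 1), lb)
    ndiag = len(offsets)
    maxd = min(la, lb)
    D = np.zeros((ndiag, maxd), dtype=bool)
    diag_len = np.zeros(ndiag, dtype=np.int64)
    i0 = np.zeros(ndiag, dtype=np.int64)
    j0 = np.zeros(ndiag, dtype=np.int64)
    for k, o in enumerate(offsets):
        d = np.diagonal(M, offset=o)
        diag_len[k] = len(d)
        D[k, :len(d)] = d
        i0[k] = -o if o < 0 else 0
        j0[k] = o if o > 0 else 0
    C = np.zeros((ndiag, maxd + 1), dtype=np.int32)
    np.cumsum(D, axis=1, out=C[:, 1:])
    total_matches = C[np.arange(ndiag), diag_len]  # upper bound per diagonal

    best: Optional[tuple] = None  # (score, L, -i_locus, t3_start, mism)
    upper = min(max_len, maxd)
    for L in range(upper, min_len - 1, -1):
        if best is not None and best[0] >= L:
            break
        ncol = maxd + 1 - L
        if ncol <= 0:
            continue
        # a window of length L needs >= (1-f)L matches, and must beat the
        # current best; the diagonal's total match count bounds both
        need = (1.0 - max_mismatch_frac) * L
        if best is not None:
            need = max(need, (best[0] + 1 + L) / 2.0)
        rows = np.flatnonzero(total_matches >= need)
        if len(rows) == 0:
            continue
        matches = C[rows, L:] - C[rows, :-L]
        a_idx = np.arange(ncol)[None, :]
        mism = L - matches
        i_loc = a0 + i0[rows, None] + a_idx
        j_arr = j0[rows, None] + a_idx
        t3 = b1 - j_arr - L
        ok = (a_idx <= (diag_len[rows, None] - L)) \
            & (mism <= max_mismatch_frac * L + 1e-9) \
            & (i_loc + L <= t3)
        if not ok.any():
            continue
        score = np.where(ok, 2 * matches - L, np.iinfo(np.int32).min)
        mx = int(score.max())
        if best is not None and mx < best[0]:
            continue
        cand = np.argwhere(score == mx)
        keys = [
            (mx, L, -int(i_loc[r, c]), int(t3[r, c]), int(mism[r, c]))
            for r, c in cand
        ]
        top = max(keys)
        if best is None or (top[0], top[1], top[2], top[3]) > (best[0], best[1], best[2], best[3]):
            best = top
    if best is None:
        return None
    score, L, neg_i, t3_start, mism = best
    return TirPair(tir5_start=-neg_i, tir3_start=t3_start, length=L,
                   mismatches=mism, score=score)


def _seed_ir_clusters(locus: str, window: int, k: int = 10) -> list[tuple[int, int, int, int]]:
    """Localize candidate inverted-repeat pairs via exact inverted k-mer seeds.

    Returns subwindow pairs (a0, a1, b0, b1) ordered by seed support.
    """
    n = len(locus)
    w5 = locus[:min(window, n)]
    w3 = locus[max(0, n - window):]
    b_off = max(0, n - window)
    codes5 = _NT_IDX[np.frombuffer(w5.encode(), dtype=np.uint8)].astype(np.int64)
    codes3 = _NT_IDX[np.frombuffer(w3.encode(), dtype=np.uint8)].astype(np.int64)

    def hashes(codes):
        m = len(codes) - k + 1
        if m <= 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
        h = np.zeros(m, dtype=np.int64)
        v = np.ones(m, dtype=bool)
        for j in range(k):
            h = h * 4 + codes[j:j + m]
            v &= codes[j:j + m] < 4
        return h, v

    h5, v5 = hashes(codes5)
    # hash of the reverse complement of each k-mer in the 3' window
    rc3 = _NT_IDX[np.frombuffer(revcomp(w3).encode(), dtype=np.uint8)].astype(np.int64)
    hr, vr = hashes(rc3)
    # k-mer starting at w3 position q corresponds to rc position len(w3)-q-k
    m3 = len(w3) - k + 1
    if m3 <= 0 or len(h5) == 0:
        return []
    rcmap: dict[int, list[int]] = {}
    for pos in np.flatnonzero(vr):
        q = len(w3) - int(pos) - k
        rcmap.setdefault(int(hr[pos]), []).append(b_off + q)
    pairs = []
    for p in np.flatnonzero(v5):
        lst = rcmap.get(int(h5[p]))
        if lst:
            for q in lst:
                if q > p + k:
                    pairs.append((int(p), q))
    if not pairs:
        return []
    # bucket on the anti-diagonal p + q (fixed-width bins: an inverted-repeat
    # pair keeps p + q constant, so its seeds share a bin or two)
    buckets: dict[int, list[tuple[int, int]]] = {}
    for p, q in pairs:
        buckets.setdefault((p + q) // 40, []).append((p, q))
    merged: dict[int, list[tuple[int, int]]] = {}
    for key in sorted(buckets):
        if key - 1 in merged and len(merged[key - 1]) < 4000:
            merged[key - 1].extend(buckets[key])
            merged[key] = merged[key - 1]
        else:
            merged[key] = buckets[key]
    clusters = []
    seen_ids = set()
    for cl in merged.values():
        if id(cl) not in seen_ids:
            seen_ids.add(id(cl))
            clusters.append(cl)
    clusters.sort(key=len, reverse=True)
    out = []
    for cl in clusters[:8]:
        ps = sorted(p for p, _ in cl)
        qs = sorted(q for _, q in cl)
        # cap the subwindow at 650 nt around the densest seed region
        p_med = ps[len(ps) // 2]
        q_med = qs[len(qs) // 2]
        a0 = max(0, max(min(ps), p_med - 325) - 60)
        a1 = min(n, min(max(ps), p_med + 325) + k + 60)
        b0 = max(0, max(min(qs), q_med - 325) - 60)
        b1 = min(n, min(max(qs), q_med + 325) + k + 60)
        out.append((a0, a1, b0, b1))
    return out


def find_tirs(
    locus_seq: str,
    min_len: int = 20,
    max_len: int = 450,
    max_mismatch_frac: float = 0.15,
    search_window: int = 600,
) -> Optional[TirPair]:
    """Best-scoring TIR pair within the terminal search windows, or None.

    The 5' TIR is sought in the first ``search_window`` nt and the 3' TIR
    (reverse-complemented) in the last ``search_window`` nt.  Windows up
    to 800 nt use the exhaustive all-pairs scan directly; wider windows
    are first narrowed with inverted-seed localization.
    """
    n = len(locus_seq)
    if search_window > n:
        raise ValueError("search window larger than the sequence")
    if n <= 2 * min_len:
        raise ValueError("locus shorter than two minimal TIRs")
    W = search_window
    if W <= 800:
        return _best_gapless_ir(locus_seq, (0, W), (n - W, n),
                                min_len, max_len, max_mismatch_frac)
    best: Optional[TirPair] = None
    for a0, a1, b0, b1 in _seed_ir_clusters(locus_seq, W):
        hit = _best_gapless_ir(locus_seq, (a0, a1), (b0, b1),
                               min_len, max_len, max_mismatch_frac)
        if hit is None:
            continue
        key = (hit.score, hit.length, -hit.tir5_start, hit.tir3_start)
        if best is None or key > (best.score, best.length, -best.tir5_start, best.tir3_start):
            best = hit
    return best


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def refine_element_boundaries(
    locus_seq: str,
    tir: TirPair,
    tsd_len: int = 2,
    tsd_motif: str = "TA",
    max_extend: int = 8,
    min_len: int = 20,
) -> TirPair:
    """Snap the element boundaries onto the duplicated target site.

    The raw gapless scan can over- or under-run the true termini by a few
    neutral columns (a match plus a mismatch scores zero).  Because the
    outermost TIR column pairs the element's first and last base, the
    boundary error is a symmetric outer trim/extension ``x``; this picks
    the ``x`` maximizing the TIR score of the retained columns plus a
    bonus per flank equal to the family TSD motif — the automated
    counterpart of curating boundaries manually against the flanks.
    """
    i, e, L = tir.tir5_start, tir.tir3_end, tir.length
    n = len(locus_seq)
    lo = -min(max_extend, i - tsd_len, n - e - tsd_len)
    hi = L - min_len
    if lo > 0 or hi < 0:
        return tir
    # match indicator for outer columns c in [lo, L)
    cols = np.arange(lo, L)
    m = np.array([
        locus_seq[i + c].upper() == _COMP.get(locus_seq[e - 1 - c].upper(), "?")
        for c in cols
    ])
    suffix = np.concatenate([np.cumsum(m[::-1])[::-1], [0]])  # matches in [c, L)
    col_score = {}
    tsd_ok = {}
    for x in range(lo, hi + 1):
        col_score[x] = 2 * int(suffix[x - lo]) - (L - x)
        left = locus_seq[i + x - tsd_len:i + x].upper()
        right = locus_seq[e - x:e - x + tsd_len].upper()
        tsd_ok[x] = (left == tsd_motif and right == tsd_motif)
    with_tsd = sorted((x for x in col_score if tsd_ok[x]), reverse=True)
    if with_tsd:
        # A TA-flanked boundary's own duplicated-target columns pair with
        # each other for free (TA is self-complementary), biasing the raw
        # score toward spuriously outer TA boundaries.  Walk from the
        # innermost TA candidate outward; before comparing, discount the
        # current candidate's two self-pairing TSD columns (always +2 in
        # the outer score) and then require the remaining columns to show
        # repeat-like gain (midpoint between the expected drift of genuine
        # repeat columns and of background columns, ~0.2/column).
        x = with_tsd[0]
        for cand in with_tsd[1:]:
            dx = x - cand
            gain = col_score[cand] - col_score[x] - 2.0
            if gain > 0.2 * (dx - 2):
                x = cand
    else:
        x = max(col_score, key=lambda x_: (col_score[x_], -abs(x_)))
    length = L - x
    matches = int(suffix[x - lo])
    return TirPair(tir5_start=i + x, tir3_start=tir.tir3_start,
                   length=length, mismatches=length - matches,
                   score=2 * matches - length)


def detect_tsd(
    contig_seq: str, start: int, end: int, tsd_len: int = 2
) -> tuple[str, str, str]:
    """Immediate flanking k-mers of an element and their match status.

    Returns (left, right, flag) with flag in {"match", "mismatch",
    "indeterminate"}; indeterminate when a flank is shorter than
    ``tsd_len`` (element abutting a contig edge).
    """
    left = contig_seq[max(0, start - tsd_len):start]
    right = contig_seq[end:end + tsd_len]
    if len(left) < tsd_len or len(right) < tsd_len:
        return left, right, "indeterminate"
    return left, right, ("match" if left.upper() == right.upper() else "mismatch")


@dataclass
class Orf:
    start: int       # nt on the element, 0-based half-open, stop codon included
    end: int
    strand: str
    protein: str     # excludes the stop


def recover_orf(element_seq: str, min_codons: int = 100) -> Optional[Orf]:
    """Longest ATG-to-stop ORF on either strand of the element.

    Ties break toward the earlier start on the forward element
    coordinates.  Returns None when no ORF reaches ``min_codons``.
    """
    if len(element_seq) < 300:
        raise ValueError("element shorter than 300 nt")
    candidates: list[tuple[int, int, int, str, str, int, int]] = []
    for strand in "+-":
        seq = element_seq if strand == "+" else revcomp(element_seq)
        L = len(seq)
        for f in range(3):
            ncod = (L - f) // 3
            m_codon = None  # first ATG since the last stop
            for ci in range(ncod):
                codon = seq[f + 3 * ci: f + 3 * ci + 3].upper()
                if codon in _STOPS:
                    if m_codon is not None:
                        aa_len = ci - m_codon
                        if aa_len >= min_codons:
                            s_nt = f + 3 * m_codon
                            e_nt = f + 3 * (ci + 1)
                            if strand == "-":
                                s_nt, e_nt = L - e_nt, L - s_nt
                            prot = _translate_simple(seq[f + 3 * m_codon: f + 3 * ci])
                            candidates.append((aa_len, -s_nt, 0 if strand == "+" else -1,
                                               strand, prot, s_nt, e_nt))
                    m_codon = None
                elif codon == "ATG" and m_codon is None:
                    m_codon = ci
    if not candidates:
        return None
    aa_len, _, _, strand, prot, s_nt, e_nt = max(
        candidates, key=lambda c: (c[0], c[1], c[2]))
    return Orf(start=s_nt, end=e_nt, strand=strand, protein=prot)


_CODON_TABLE: dict[str, str] = {}


def _translate_simple(seq: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq
        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    _CODON_TABLE[a + b + c] = str(Seq(a + b + c).translate())
    return "".join(
        _CODON_TABLE.get(seq[i:i + 3].upper(), "X")
        for i in range(0, len(seq) - len(seq) % 3, 3)
    )


@dataclass
class ElementAnnotation:
    """One annotated genomic transposon copy."""

    element_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    tir: Optional[TirPair] = None            # on the oriented locus
    tsd_left: str = ""
    tsd_right: str = ""
    tsd_flag: str = "indeterminate"
    orf: Optional[Orf] = None
    classification: str = "hit_only"
    family: str = "unassigned"
    locus_start: int = 0                     # element offset inside the locus
    meta: dict = field(default_factory=dict)

    @property
    def tsd_is_ta(self) -> bool:
        return self.tsd_left.upper() == "TA" and self.tsd_right.upper() == "TA"

    @property
    def orf_aa(self) -> int:
        return len(self.orf.protein) if self.orf else 0


def classify_copy(ann: ElementAnnotation, min_intact_aa: int = 300) -> str:
    """Deterministic class from the annotation fields.

    full: both TIRs present and identical flanking TSDs;
    intact: full and ORF protein >= ``min_intact_aa`` aa; else hit_only.
    """
    if ann.tir is None or ann.tsd_flag != "match":
        return "hit_only"
    if ann.orf is not None and len(ann.orf.protein) >= min_intact_aa:
        return "intact"
    return "full"


def annotate_locus(
    locus: dict,
    element_id: str,
    genome_id: str = "",
    min_tir_len: int = 20,
    max_tir_len: int = 450,
    max_mismatch_frac: float = 0.15,
    search_window: Optional[int] = None,
    min_intact_aa: int = 300,
) -> ElementAnnotation:
    """Annotate one extracted locus (output of ``extract_with_flanks``).

    Finds the TIR pair, reads the flanking TSDs inside the locus, recovers
    the longest ORF between the TIRs and classifies the copy.  Genome
    coordinates account for reverse-complemented loci.
    """
    seq = locus["sequence"]
    n = len(seq)
    window = search_window or min(n, max(600, max(locus.get("left_flank", 0),
                                                  locus.get("right_flank", 0)) + 600))
    window = min(window, n)
    tir = None
    if n > 2 * min_tir_len:
        tir = find_tirs(seq, min_tir_len, max_tir_len, max_mismatch_frac, window)
    ann = ElementAnnotation(
        element_id=element_id, genome_id=genome_id,
        contig=locus.get("contig", ""), start=locus.get("slice_start", 0),
        end=locus.get("slice_end", n), strand=locus.get("strand", "+"),
    )
    if tir is None:
        return ann
    tir = refine_element_boundaries(seq, tir, min_len=min_tir_len)
    e_start, e_end = tir.tir5_start, tir.tir3_end
    ann.tir = tir
    ann.locus_start = e_start
    left, right, flag = detect_tsd(seq, e_start, e_end)
    ann.tsd_left, ann.tsd_right, ann.tsd_flag = left, right, flag
    if e_end - e_start >= 300:
        ann.orf = recover_orf(seq[e_start:e_end])
    # genome coordinates of the element (forward strand)
    s0 = locus.get("slice_start", 0)
    if locus.get("oriented"):
        ann.start = s0 + (n - e_end)
        ann.end = s0 + (n - e_start)
    else:
        ann.start = s0 + e_start
        ann.end = s0 + e_end
    ann.classification = classify_copy(ann, min_intact_aa)
    return ann


def build_family_reference(
    copies: list[tuple[str, str, str]],
    consensus_cutoff: int = 10,
) -> tuple[str, str]:
    """Per-genome family reference: consensus (>10 copies) or representative.

    ``copies`` is a list of (id, sequence, classification).  With more
    than ``consensus_cutoff`` copies a column-majority consensus over a
    MAFFT alignment is built (ties resolved with IUPAC ambiguity codes,
    majority-gap columns dropped); otherwise the longest copy is chosen,
    preferring intact, then full copies.  Returns (sequence, method).
    """
    if not copies:
        raise ValueError("no copies supplied")
    if len(copies) > consensus_cutoff:
        aligned = align({cid: seq for cid, seq, _ in copies})
        cols = len(next(iter(aligned.values())))
        rows = list(aligned.values())
        out = []
        for c in range(cols):
            counts: dict[str, int] = {}
            for r in rows:
                counts[r[c].upper()] = counts.get(r[c].upper(), 0) + 1
            gap = counts.pop("-", 0)
            if not counts or gap > sum(counts.values()):
                continue
            mx = max(counts.values())
            winners = frozenset(b for b, k in counts.items() if k == mx and b in "ACGT")
            if not winners:
                out.append("N")
            else:
                out.append(IUPAC.get(winners, "N"))
        return "".join(out), "consensus"
    rank = {"intact": 0, "full": 1, "hit_only": 2}
    best = min(copies, key=lambda c: (rank.get(c[2], 3), -len(c[1]), c[0]))
    return best[1], "representative"


def annotations_to_tsv(annotations: list[ElementAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("element_id\tgenome_id\tcontig\tstart\tend\tstrand\tclass\t"
                 "tir_length\ttir_mismatches\ttsd_left\ttsd_right\torf_aa\tfamily\n")
        for a in annotations:
            fh.write(
                f"{a.element_id}\t{a.genome_id}\t{a.contig}\t{a.start}\t{a.end}\t"
                f"{a.strand}\t{a.classification}\t"
                f"{a.tir.length if a.tir else 0}\t{a.tir.mismatches if a.tir else ''}\t"
                f"{a.tsd_left}\t{a.tsd_right}\t{a.orf_aa}\t{a.family}\n"
            )


def annotations_to_gff3(annotations: list[ElementAnnotation], path) -> None:
    """Annotations as GFF3 with TIR/TSD/ORF child features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            fh.write("\t".join([
                a.contig, "tefp", "transposable_element",
                str(a.start + 1), str(a.end), ".", a.strand, ".",
                f"ID={a.element_id};class={a.classification};family={a.family}"]) + "\n")
            if a.tir is not None:
                for tag, s in (("tir5", a.start), ("tir3", a.end - a.tir.length)):
                    fh.write("\t".join([
                        a.contig, "tefp", "terminal_inverted_repeat",
                        str(s + 1), str(s + a.tir.length), ".", a.strand, ".",
                        f"ID={a.element_id}.{tag};Parent={a.element_id}"]) + "\n")
            if a.orf is not None:
                fh.write("\t".join([
                    a.contig, "tefp", "ORF",
                    str(a.start + a.orf.start + 1), str(a.start + a.orf.end),
                    ".", a.orf.strand, ".",
                    f"ID={a.element_id}.orf;Parent={a.element_id}"]) + "\n")
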