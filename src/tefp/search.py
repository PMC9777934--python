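"""Translated homology search: find transposase-coding loci in assemblies.

A desk-scale stand-in for a TBLASTN screen: genomes are translated in all
six frames, exact amino-acid word seeds are clustered by diagonal, and
candidate regions are re-scored by local protein alignment (BLOSUM62,
gap open/extend 11/1).  Significance uses a Karlin-Altschul E-value
``E = K * m * n * exp(-lambda * S)`` with the standard gapped BLOSUM62
parameters, and only hits at or below the E-value cutoff (default 1e-4)
are reported.

Nucleotide-level copy counting against a family consensus follows the
same seed-and-align scheme with a 40% query-coverage and 90% identity
cutoff; overlapping qualifying hits on one strand merge into one copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from tefp.simulate import revcomp

logger = logging.getLogger(__name__)

# gapped BLOSUM62 (open 11 / extend 1) Karlin-Altschul parameters
GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_NT_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i
    _NT_CODE[ord(_b.lower())] = _i

# codon -> amino acid lookup over base-5 codes (4 = N/other -> X)
_CODON_AA = np.full(125, ord("X"), dtype=np.uint8)
for _a in range(4):
    for _b in range(4):
        for _c in range(4):
            codon = "ACGT"[_a] + "ACGT"[_b] + "ACGT"[_c]
            aa = str(Seq(codon).translate())
            _CODON_AA[_a * 25 + _b * 5 + _c] = ord(aa)


@dataclass
class ProteinQuery:
    id: str
    family_label: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq or set(seq) - set(AA_ALPHABET + "X"):
            raise ValueError(f"invalid protein query sequence for {self.id}")
        self.sequence = seq


@dataclass
class SearchHit:
    genome_id: str
    contig: str
    start: int            # nt, 0-based half-open, forward strand
    end: int
    strand: str
    frame: int            # 1-3
    raw_score: float
    evalue: float
    query_coverage: float
    pct_identity: float
    query_id: str = ""
    aligned_query: str = ""
    aligned_subject: str = ""
    meta: dict = field(default_factory=dict)

    def overlaps(self, other: "SearchHit", min_frac: float = 0.5) -> bool:
        if self.contig != other.contig:
            return False
        inter = min(self.end, other.end) - max(self.start, other.start)
        if inter <= 0:
            return False
        return inter >= min_frac * min(self.end - self.start, other.end - other.start)


def _encode_nt(dna: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(dna.encode(), dtype=np.uint8)]


def _translate_codes(codes: np.ndarray) -> str:
    n = len(codes) // 3
    if n == 0:
        return ""
    c = codes[: n * 3].reshape(n, 3)
    idx = c[:, 0] * 25 + c[:, 1] * 5 + c[:, 2]
    return _CODON_AA[idx].tobytes().decode()


def six_frame_translate(dna: str) -> list[tuple[str, int, str]]:
    """All six conceptual translations of ``dna``.

    Returns (strand, frame, protein) triples; frames 1-3 start at offsets
    0-2 of the forward strand or of the reverse complement.  Codons
    containing N (or any non-ACGT symbol) translate to X; trailing bases
    short of a codon are dropped.
    """
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    fwd = _encode_nt(dna)
    rev = _encode_nt(revcomp(dna))
    out = []
    for frame in range(3):
        out.append(("+", frame + 1, _translate_codes(fwd[frame:])))
    for frame in range(3):
        out.append(("-", frame + 1, _translate_codes(rev[frame:])))
    return out


def _kmer_hashes(codes: np.ndarray, k: int, radix: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling base-``radix`` hashes; positions containing invalid symbols masked."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    h = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        h = h * radix + codes[j: j + n]
        valid &= codes[j: j + n] < radix
    return h, valid


_AA_CODE = np.full(256, 25, dtype=np.int64)
for _i, _a in enumerate(AA_ALPHABET):
    _AA_CODE[ord(_a)] = _i


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, int, int, int]:
    """(matches, columns, q_start, q_end, s_start) over the aligned core."""
    q, s = alignment[0], alignment[1]  # target=first passed, query=second
    matches = columns = 0
    for a, b in zip(q, s):
        if a == "-" and b == "-":
            continue
        columns += 1
        if a == b and a != "X":
            matches += 1
    (qs, qe) = alignment.aligned[0][0][0], alignment.aligned[0][-1][1]
    ss = alignment.aligned[1][0][0]
    return matches, columns, int(qs), int(qe), int(ss)


def _cluster_seeds(seeds: np.ndarray, band: int, gap: int) -> list[tuple[int, int]]:
    """Group (qpos, spos) seeds into candidate subject spans.

    Seeds are clustered on (diagonal within ``band``, subject gap within
    ``gap``); returns (spos_min, spos_max) per cluster.
    """
    if len(seeds) == 0:
        return []
    diag = seeds[:, 1] - seeds[:, 0]
    order = np.lexsort((seeds[:, 1], diag // band))
    clusters = []
    cur_band = None
    cur_min = cur_max = 0
    last_s = 0
    n_seeds = 0
    for i in order:
        b = diag[i] // band
        s = seeds[i, 1]
        if cur_band is None or b != cur_band or s - last_s > gap:
            if cur_band is not None:
                clusters.append((cur_min, cur_max, n_seeds))
            cur_band, cur_min, cur_max, n_seeds = b, s, s, 0
        cur_max = max(cur_max, s)
        last_s = s
        n_seeds += 1
    clusters.append((cur_min, cur_max, n_seeds))
    return [(a, b) for a, b, n in clusters if n >= 2]


def search_translated(
    genome: dict[str, str],
    query: ProteinQuery,
    evalue_max: float = 1e-4,
    word_size: int = 4,
    genome_id: str = "",
) -> list[SearchHit]:
    """Seeded six-frame search of one genome with a protein query.

    Hits are sorted by raw alignment score, descending; every reported
    hit has ``evalue <= evalue_max`` and nt coordinates that re-translate
    to the aligned protein segment in the reported frame/strand.
    """
    if len(query.sequence) < 10:
        raise ValueError("query shorter than 10 aa")
    if not genome:
        return []
    qcodes = _AA_CODE[np.frombuffer(query.sequence.encode(), dtype=np.uint8)]
    qhash, qvalid = _kmer_hashes(qcodes, word_size, 25)
    qmap: dict[int, list[int]] = {}
    for pos in np.flatnonzero(qvalid):
        qmap.setdefault(int(qhash[pos]), []).append(int(pos))
    qkeys = np.array(sorted(qmap), dtype=np.int64)
    qlen = len(query.sequence)
    aligner = _protein_aligner()

    total_aa = sum(2 * len(s) for s in genome.values())  # both strands
    hits: list[SearchHit] = []
    for contig, dna in genome.items():
        if len(dna) < 3:
            continue
        clen = len(dna)
        for strand, frame, prot in six_frame_translate(dna):
            pcodes = _AA_CODE[np.frombuffer(prot.encode(), dtype=np.uint8)]
            phash, pvalid = _kmer_hashes(pcodes, word_size, 25)
            if len(phash) == 0:
                continue
            cand = np.flatnonzero(pvalid & np.isin(phash, qkeys))
            seeds = []
            for spos in cand:
                for qpos in qmap[int(phash[spos])]:
                    seeds.append((qpos, int(spos)))
            spans = _cluster_seeds(np.array(seeds, dtype=np.int64).reshape(-1, 2),
                                   band=16, gap=qlen)
            merged: list[list[int]] = []
            for smin, smax in sorted(spans):
                w0, w1 = max(0, smin - qlen), min(len(prot), smax + word_size + qlen)
                if merged and w0 <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], w1)
                else:
                    merged.append([w0, w1])
            for w0, w1 in merged:
                window = prot[w0:w1]
                alns = aligner.align(query.sequence, window)
                if len(alns) == 0:
                    continue
                aln = alns[0]
                score = float(aln.score)
                evalue = GAPPED_K * qlen * total_aa * np.exp(-GAPPED_LAMBDA * score)
                if evalue > evalue_max:
                    continue
                matches, columns, qs, qe, ss = _alignment_stats(aln)
                s_cols = sum(1 for c in aln[1] if c != "-")
                aa_start = w0 + ss
                aa_end = aa_start + s_cols
                off = frame - 1
                if strand == "+":
                    nt_start, nt_end = off + 3 * aa_start, off + 3 * aa_end
                else:
                    nt_start = clen - (off + 3 * aa_end)
                    nt_end = clen - (off + 3 * aa_start)
                hits.append(SearchHit(
                    genome_id=genome_id, contig=contig,
                    start=nt_start, end=nt_end, strand=strand, frame=frame,
                    raw_score=score, evalue=float(evalue),
                    query_coverage=(qe - qs) / qlen,
                    pct_identity=100.0 * matches / columns if columns else 0.0,
                    query_id=query.id,
                    aligned_query=str(aln[0]), aligned_subject=str(aln[1]),
                ))
    # deduplicate overlapping hits (same locus reached from several windows/frames)
    hits.sort(key=lambda h: -h.raw_score)
    kept: list[SearchHit] = []
    for h in hits:
        if not any(h.overlaps(k) and h.strand == k.strand for k in kept):
            kept.append(h)
    return kept


def extract_with_flanks(genome: dict[str, str], hit: SearchHit, flank_nt: int = 2000) -> dict:
    """Slice the hit with up to ``flank_nt`` of genomic flank on each side.

    Reverse-strand hits are returned reverse-complemented so the element
    reads 5'->3'; genome coordinates of the (forward-strand) slice are
    recorded along with the flank actually obtained and clipping flags.
    """
    contig_seq = genome[hit.contig]
    clen = len(contig_seq)
    s = max(0, hit.start - flank_nt)
    e = min(clen, hit.end + flank_nt)
    seq = contig_seq[s:e]
    left = hit.start - s
    right = e - hit.end
    oriented = hit.strand == "-"
    if oriented:
        seq = revcomp(seq)
    return {
        "sequence": seq,
        "contig": hit.contig,
        "slice_start": s,
        "slice_end": e,
        "left_flank": left if not oriented else right,
        "right_flank": right if not oriented else left,
        "left_clipped": (s == 0 and hit.start - flank_nt < 0),
        "right_clipped": (e == clen and hit.end + flank_nt > clen),
        "oriented": oriented,
        "strand": hit.strand,
    }


def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -0.5
    aligner.mode = "local"
    return aligner


def search_nucleotide(
    genome: dict[str, str],
    query_nt: str,
    word_size: int = 12,
    min_score: float = 30.0,
) -> list[SearchHit]:
    """Seeded nucleotide search (BLASTN-like) of a consensus against a genome."""
    query_nt = query_nt.upper()
    qlen = len(query_nt)
    aligner = _nt_aligner()
    hits: list[SearchHit] = []
    for contig, dna in genome.items():
        ccodes = _encode_nt(dna)
        chash, cvalid = _kmer_hashes(ccodes, word_size, 4)
        for strand in "+-":
            q = query_nt if strand == "+" else revcomp(query_nt)
            qcodes = _encode_nt(q)
            qhash, qvalid = _kmer_hashes(qcodes, word_size, 4)
            qmap: dict[int, list[int]] = {}
            for pos in np.flatnonzero(qvalid):
                qmap.setdefault(int(qhash[pos]), []).append(int(pos))
            if not qmap:
                continue
            qkeys = np.array(sorted(qmap), dtype=np.int64)
            cand = np.flatnonzero(cvalid & np.isin(chash, qkeys))
            seeds = []
            for spos in cand:
                for qpos in qmap[int(chash[spos])]:
                    seeds.append((qpos, int(spos)))
            spans = _cluster_seeds(np.array(seeds, dtype=np.int64).reshape(-1, 2),
                                   band=32, gap=qlen)
            merged: list[list[int]] = []
            for smin, smax in sorted(spans):
                w0, w1 = max(0, smin - qlen), min(len(dna), smax + word_size + qlen)
                if merged and w0 <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], w1)
                else:
                    merged.append([w0, w1])
            for w0, w1 in merged:
                alns = aligner.align(q, dna[w0:w1])
                if len(alns) == 0:
                    continue
                aln = alns[0]
                if aln.score < min_score:
                    continue
                matches, columns, qs, qe, ss = _alignment_stats(aln)
                s_cols = sum(1 for c in aln[1] if c != "-")
                start = w0 + ss
                end = start + s_cols
                hits.append(SearchHit(
                    genome_id="", contig=contig, start=start, end=end,
                    strand=strand, frame=0, raw_score=float(aln.score),
                    evalue=0.0, query_coverage=(qe - qs) / qlen,
                    pct_identity=100.0 * matches / columns if columns else 0.0,
                ))
    hits.sort(key=lambda h: -h.raw_score)
    kept: list[SearchHit] = []
    for h in hits:
        if not any(h.overlaps(k, 0.5) and h.strand == k.strand for k in kept):
            kept.append(h)
    return kept


def count_copies(
    genome: dict[str, str],
    query_element: str,
    min_coverage: float = 0.40,
    min_identity: float = 90.0,
) -> tuple[int, list[tuple[str, int, int, str]]]:
    """Copy number of an element consensus in one genome.

    Hits passing the coverage and identity cutoffs are merged when they
    overlap by >= 1 nt on the same strand; each merged interval counts as
    one copy.
    """
    hits = [
        h for h in search_nucleotide(genome, query_element)
        if h.query_coverage > min_coverage and h.pct_identity >= min_identity
    ]
    by_key: dict[tuple[str, str], list[SearchHit]] = {}
    for h in hits:
        by_key.setdefault((h.contig, h.strand), []).append(h)
    intervals: list[tuple[str, int, int, str]] = []
    for (contig, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: h.start)
        cur_s, cur_e = group[0].start, group[0].end
        for h in group[1:]:
            if h.start < cur_e:  # >=1 nt overlap
                cur_e = max(cur_e, h.end)
            else:
                intervals.append((contig, cur_s, cur_e, strand))
                cur_s, cur_e = h.start, h.end
        intervals.append((contig, cur_s, cur_e, strand))
    return len(intervals), sorted(intervals)


def iterative_search(
    genome: dict[str, str],
    queries: list[ProteinQuery],
    rounds: int = 2,
    evalue_max: float = 1e-4,
    genome_id: str = "",
    min_new_query_aa: int = 100,
    max_new_queries: int = 3,
) -> list[SearchHit]:
    """Bounded re-query loop: found transposases become queries in turn.

    Seeding with a single diverged reference can miss family members a
    genome's own (mutually similar) copies would find, so up to
    ``max_new_queries`` of the longest recovered protein segments are
    used as fresh queries in later rounds.  Hits are deduplicated across
    rounds by coordinate overlap.
    """
    all_hits: list[SearchHit] = []
    current = list(queries)
    for rnd in range(rounds):
        novel: list[SearchHit] = []
        for q in current:
            for h in search_translated(genome, q, evalue_max, genome_id=genome_id):
                if not any(h.overlaps(k) and h.strand == k.strand for k in all_hits + novel):
                    novel.append(h)
        all_hits.extend(novel)
        if rnd + 1 >= rounds or not novel:
            break
        candidates = []
        for i, h in enumerate(novel):
            prot = h.aligned_subject.replace("-", "")
            if len(prot) >= min_new_query_aa:
                candidates.append((len(prot), i, prot))
        candidates.sort(reverse=True)
        current = [
            ProteinQuery(id=f"round{rnd + 1}_{i}", family_label="reference-other",
                         sequence=prot.replace("*", "X"))
            for _, i, prot in candidates[:max_new_queries]
        ]
        if not current:
            break
    all_hits.sort(key=lambda h: -h.raw_score)
    return all_hits


def hits_to_tsv(hits: list[SearchHit], path) -> None:
    """BLAST outfmt-6-like TSV."""
    cols = ("query_id\tcontig\tpct_identity\tlength\tstart\tend\tstrand\t"
            "frame\tevalue\traw_score\tquery_coverage\n")
    with open(path, "w") as fh:
        fh.write(cols)
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.contig}\t{h.pct_identity:.2f}\t{h.end - h.start}\t"
                f"{h.start}\t{h.end}\t{h.strand}\t{h.frame}\t{h.evalue:.3g}\t"
                f"{h.raw_score:.1f}\t{h.query_coverage:.3f}\n"
            )
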