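"""Integration-site and TIR-end sequence preferences as numeric profiles.

Insertion windows are stacked so the target TA dinucleotide occupies the
two central positions (positions 20 and 21, 1-based, of the default
40-mer); minus-strand elements are reverse-complemented before stacking.
Per-position information content against a uniform background is
``2 + sum_b f_b log2 f_b`` bits, so an invariant position carries 2 bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from tefp.simulate import revcomp

logger = logging.getLogger(__name__)

_BASE_ORDER = "ACGT"


@dataclass
class PositionProfile:
    """Per-position base counts and information content of a window stack."""

    window_length: int
    counts: np.ndarray          # shape (window, 4), A/C/G/T
    n_sequences: int
    ic: np.ndarray              # bits per position
    background: np.ndarray      # base frequencies used for ic

    @property
    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tA\tC\tG\tT\tic_bits\n")
            for i in range(self.window_length):
                row = "\t".join(str(int(c)) for c in self.counts[i])
                fh.write(f"{i + 1}\t{row}\t{self.ic[i]:.4f}\n")

    def to_meme(self, path, motif_name: str = "profile") -> None:
        """MEME minimal motif format for logo renderers."""
        freqs = self.frequencies
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            bg = " ".join(f"{b} {f:.4f}" for b, f in zip(_BASE_ORDER, self.background))
            fh.write(f"Background letter frequencies\n{bg}\n\n")
            fh.write(f"MOTIF {motif_name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {self.window_length} "
                     f"nsites= {self.n_sequences} E= 0\n")
            for i in range(self.window_length):
                fh.write(" ".join(f"{f:.6f}" for f in freqs[i]) + "\n")


def extract_insertion_windows(
    genome: dict[str, str],
    elements,
    window: int = 40,
) -> list[str]:
    """Genomic windows centred on each element's target TA.

    ``elements`` yields objects (or dicts) with contig, start, end, strand
    and a located TSD; the left TSD occupies [start-2, start).  The
    window is placed so the TA sits at the two central positions; windows
    running past a contig edge are dropped (and counted in the log), and
    minus-strand elements are reverse-complemented.
    """
    if window % 2 != 0:
        raise ValueError("window must be even")
    half = window // 2
    out: list[str] = []
    dropped = skipped = 0
    for el in elements:
        get = el.get if isinstance(el, dict) else lambda k, d=None: getattr(el, k, d)
        contig = get("contig")
        start = get("start")
        strand = get("strand", "+")
        tsd_flag = get("tsd_flag", "match")
        if tsd_flag == "indeterminate":
            skipped += 1
            logger.debug("element without located TSD skipped")
            continue
        seq = genome[contig]
        ta = start - 2  # left TSD position
        w0, w1 = ta - (half - 1), ta + (half + 1)
        if w0 < 0 or w1 > len(seq):
            dropped += 1
            continue
        win = seq[w0:w1]
        out.append(revcomp(win) if strand == "-" else win)
    if dropped or skipped:
        logger.info("insertion windows: %d clipped at contig edges, %d without TSD",
                    dropped, skipped)
    return out


def build_profile(window_set: list[str], background=None) -> PositionProfile:
    """Counts and information content of an equal-length window stack.

    Non-ACGT symbols are masked (excluded from that position's counts).
    ``ic`` uses the plug-in entropy with no small-sample correction.
    """
    if not window_set:
        raise ValueError("empty window set")
    L = len(window_set[0])
    if any(len(w) != L for w in window_set):
        raise ValueError("windows must have equal lengths")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    mat = np.frombuffer("".join(w.upper() for w in window_set).encode(), dtype="S1")
    mat = mat.reshape(len(window_set), L)
    counts = np.zeros((L, 4), dtype=np.int64)
    for bi, b in enumerate(_BASE_ORDER):
        counts[:, bi] = (mat == b.encode()).sum(axis=0)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(totals[:, None] > 0, counts / totals[:, None], 0.0)
        logf = np.where(f > 0, np.log2(np.where(f > 0, f, 1.0)), 0.0)
    ic = 2.0 + (f * logf).sum(axis=1)
    ic[totals == 0] = 0.0
    return PositionProfile(window_length=L, counts=counts,
                           n_sequences=len(window_set), ic=ic,
                           background=background)


def tir_end_windows(annotations, locus_seqs: dict[str, str], k: int = 20) -> list[str]:
    """Pooled element end motifs: first ``k`` nt of the 5' TIR plus the
    reverse complement of the last ``k`` nt of the 3' TIR."""
    out = []
    for a in annotations:
        if a.tir is None or a.tir.length < k:
            continue
        seq = locus_seqs.get(a.element_id)
        if seq is None:
            continue
        out.append(seq[a.tir.tir5_start:a.tir.tir5_start + k])
        out.append(revcomp(seq[a.tir.tir3_end - k:a.tir.tir3_end]))
    return out


def reverse_complement_profile(profile: PositionProfile) -> PositionProfile:
    """The profile of the reverse-complemented window stack."""
    counts = profile.counts[::-1, ::-1].copy()
    return PositionProfile(window_length=profile.window_length, counts=counts,
                           n_sequences=profile.n_sequences, ic=profile.ic[::-1].copy(),
                           background=profile.background[::-1].copy())
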