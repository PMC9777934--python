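"""Pairwise and group-averaged sequence identities (CDS/DBD/DDE/TIR panels).

Identity is measured on a global, end-gap-free pairwise alignment: the
denominator counts alignment columns between the first and the last
position where both sequences are present (terminal overhangs of the
shorter sequence are not penalised), including internal gap columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

DNA_CHARS = set("ACGTUN-")

PARTITIONS = ("CDS", "DBD", "DDE", "TIR")


def _is_dna(seq: str) -> bool:
    return set(seq.upper()) <= DNA_CHARS


_dna_aligner = None
_prot_aligner = None


def _get_aligner(dna: bool) -> Align.PairwiseAligner:
    global _dna_aligner, _prot_aligner
    if dna:
        if _dna_aligner is None:
            a = Align.PairwiseAligner()
            a.match_score = 2.0
            a.mismatch_score = -1.0
            a.open_gap_score = -5.0
            a.extend_gap_score = -1.0
            a.end_gap_score = 0.0
            a.mode = "global"
            _dna_aligner = a
        return _dna_aligner
    if _prot_aligner is None:
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        a.end_gap_score = 0.0
        a.mode = "global"
        _prot_aligner = a
    return _prot_aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of two sequences after end-gap-free global alignment.

    Both sequences must be of the same type (both nucleotide or both
    protein); mixed input raises ``ValueError``.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    a, b = seq_a.upper(), seq_b.upper()
    if _is_dna(a) != _is_dna(b):
        raise ValueError("mixed alphabets: one sequence looks like DNA, the other protein")
    if a == b:
        return 100.0
    if b < a:   # canonical order: co-optimal alignments could otherwise
        a, b = b, a   # make the measure asymmetric in its arguments
    aligner = _get_aligner(_is_dna(a))
    aln = aligner.align(a.replace("-", ""), b.replace("-", ""))[0]
    sa, sb = str(aln[0]), str(aln[1])
    both = [i for i, (x, y) in enumerate(zip(sa, sb)) if x != "-" and y != "-"]
    if not both:
        return 0.0
    lo, hi = both[0], both[-1] + 1
    matches = columns = 0
    for x, y in zip(sa[lo:hi], sb[lo:hi]):
        if x == "-" and y == "-":
            continue
        columns += 1
        if x == y:
            matches += 1
    return 100.0 * matches / columns


@dataclass
class IdentityMatrix:
    """Group-averaged percent-identity matrix for one sequence partition."""

    partition: str
    values: pd.DataFrame          # symmetric, percent; NaN where undefined
    n_per_group: dict[str, int]

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.2f")

    def to_long_tsv(self, path) -> None:
        long = self.values.stack(dropna=False).reset_index()
        long.columns = ["group_a", "group_b", "mean_identity"]
        long.to_csv(path, sep="\t", index=False, float_format="%.2f")


def group_identity_summary(
    sequence_groups: dict[str, list[str]],
    partition: str = "CDS",
) -> IdentityMatrix:
    """Mean pairwise identity within and between labelled sequence groups.

    Cell (i, j) with i != j averages over every cross pair; the diagonal
    averages within-group pairs excluding self-comparisons and is NaN for
    single-sequence groups.
    """
    if partition not in PARTITIONS:
        raise ValueError(f"unknown partition {partition!r}")
    labels = list(sequence_groups)
    for g, seqs in sequence_groups.items():
        if not seqs:
            raise ValueError(f"group {g!r} is empty")
    vals = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, gi in enumerate(labels):
        si = sequence_groups[gi]
        for gj in labels[i:]:
            sj = sequence_groups[gj]
            if gi == gj:
                pairs = [(si[a], si[b]) for a in range(len(si)) for b in range(a + 1, len(si))]
            else:
                pairs = [(x, y) for x in si for y in sj]
            if pairs:
                mean = float(np.mean([pairwise_identity(x, y) for x, y in pairs]))
                vals.loc[gi, gj] = vals.loc[gj, gi] = mean
    return IdentityMatrix(partition=partition, values=vals,
                          n_per_group={g: len(s) for g, s in sequence_groups.items()})


def partition_protein(protein: str, partition: str, dbd_end: int = 120) -> str:
    """Domain slice of a transposase: DBD = N-terminal region through the
    linker (first ``dbd_end`` residues), DDE = catalytic region to the end."""
    if partition == "DBD":
        return protein[:dbd_end]
    if partition == "DDE":
        return protein[dbd_end:]
    raise ValueError("partition must be DBD or DDE")
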