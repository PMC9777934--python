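"""TIR detection, TSD checks, ORF recovery, classification, consensus."""

import numpy as np
import pytest

from oracles import tir_bruteforce, tir_matrix_oracle_fast
from tefp.annotate import (
    ElementAnnotation,
    Orf,
    TirPair,
    build_family_reference,
    classify_copy,
    detect_tsd,
    find_tirs,
    recover_orf,
    refine_element_boundaries,
)
from tefp.simulate import SENSE_CODONS, random_sequence, revcomp


def _planted_ir_locus(rng, tir_len, spacer=1500, mismatches=0, off5=0, off3=0):
    tir = random_sequence(tir_len, 0.5, rng)
    tir3 = revcomp(tir)
    if mismatches:
        pos = rng.choice(tir_len, size=mismatches, replace=False)
        t = list(tir3)
        for p in pos:
            alt = [b for b in "ACGT" if b != t[p]]
            t[p] = alt[rng.integers(0, 3)]
        tir3 = "".join(t)
    return (random_sequence(off5, 0.5, rng) + tir
            + random_sequence(spacer, 0.5, rng) + tir3
            + random_sequence(off3, 0.5, rng))


class TestFindTirs:
    def test_perfect_planted_ir_recovered(self, rng):
        locus = _planted_ir_locus(rng, 25, off5=40, off3=60)
        hit = find_tirs(locus, max_mismatch_frac=0.0, search_window=300)
        assert hit is not None and hit.mismatches == 0
        # the maximal exact run contains the planted repeat
        assert hit.tir5_start <= 40 and hit.tir5_start + hit.length >= 65
        assert hit.tir3_start + hit.length >= len(locus) - 60

    def test_mismatched_planted_ir_reports_mismatch_count(self, rng):
        locus = _planted_ir_locus(rng, 200, mismatches=10, off5=30, off3=30)
        hit = find_tirs(locus, search_window=280)
        assert hit is not None
        assert hit.length >= 195 and hit.mismatches <= 10

    def test_random_sequence_has_no_exact_long_ir(self, rng):
        locus = random_sequence(2000, 0.5, rng)
        hit = find_tirs(locus, min_len=20, max_mismatch_frac=0.0, search_window=600)
        oracle = tir_matrix_oracle_fast(locus, 20, 450, 0.0, 600)
        assert (hit is None) == (oracle is None)

    @pytest.mark.parametrize("tir_len,mism", [(20, 0), (25, 3), (40, 6)])
    def test_agrees_with_pure_python_bruteforce(self, tir_len, mism):
        # triple-loop enumeration is only tractable on tiny windows
        rng = np.random.default_rng(1000 + tir_len + mism)
        locus = _planted_ir_locus(rng, tir_len, spacer=150, mismatches=mism,
                                  off5=int(rng.integers(0, 15)),
                                  off3=int(rng.integers(0, 15)))
        window = 60
        hit = find_tirs(locus, max_len=60, search_window=window)
        oracle = tir_bruteforce(locus, 20, 60, 0.15, window)
        assert hit is not None and oracle is not None
        assert (hit.score, hit.length, hit.tir5_start, hit.tir3_start,
                hit.mismatches) == oracle

    @pytest.mark.parametrize("tir_len,mism", [(20, 0), (35, 3), (60, 8), (120, 15),
                                              (250, 30), (415, 50)])
    def test_agrees_with_matrix_oracle(self, tir_len, mism):
        rng = np.random.default_rng(2000 + tir_len + mism)
        locus = _planted_ir_locus(rng, tir_len, spacer=800, mismatches=mism,
                                  off5=int(rng.integers(0, 100)),
                                  off3=int(rng.integers(0, 100)))
        window = 600
        hit = find_tirs(locus, search_window=window)
        oracle = tir_matrix_oracle_fast(locus, 20, 450, 0.15, window)
        assert hit is not None and oracle is not None
        assert (hit.score, hit.length, hit.tir5_start, hit.tir3_start,
                hit.mismatches) == oracle

    def test_window_larger_than_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            find_tirs(random_sequence(100, 0.5, rng), search_window=200)

    def test_wide_window_seeded_path_matches_direct_scan(self, rng):
        # seeded localization reproduces the exhaustive result
        locus = _planted_ir_locus(rng, 150, spacer=2500, mismatches=6,
                                  off5=700, off3=700)
        hit = find_tirs(locus, search_window=900)
        oracle = tir_matrix_oracle_fast(locus, 20, 450, 0.15, 900)
        assert hit is not None
        assert (hit.score, hit.length, hit.tir5_start, hit.tir3_start,
                hit.mismatches) == oracle

    def test_raising_min_len_never_adds_detections(self, rng):
        found = []
        loci = [_planted_ir_locus(rng, 30, spacer=600, off5=20, off3=20)
                for _ in range(5)]
        loci += [random_sequence(700, 0.5, rng) for _ in range(5)]
        for min_len in (20, 28, 40):
            found.append(sum(
                1 for l in loci
                if find_tirs(l, min_len=min_len, search_window=200) is not None))
        assert found[0] >= found[1] >= found[2]


class TestBoundaryRefinement:
    def test_overrun_boundary_snaps_back_to_tsd(self, rng):
        tir = random_sequence(100, 0.5, rng)
        element = tir + random_sequence(800, 0.5, rng) + revcomp(tir)
        # poly-C flanks are self-mismatching, so only the TSD columns pair
        locus = "C" * 300 + "TA" + element + "TA" + "C" * 300
        start = 302
        # symmetric 2-nt overrun on the true anti-diagonal
        raw = TirPair(tir5_start=start - 2, tir3_start=start + len(element) - 100 - 2,
                      length=104, mismatches=2, score=100)
        refined = refine_element_boundaries(locus, raw)
        assert refined.tir5_start == start
        assert refined.tir3_end == start + len(element)


class TestDetectTsd:
    def test_ta_duplication_matches(self):
        seq = "GGGG" + "TA" + "C" * 50 + "TA" + "GGGG"
        left, right, flag = detect_tsd(seq, 6, 56)
        assert (left, right, flag) == ("TA", "TA", "match")

    def test_element_at_contig_start_is_indeterminate(self):
        seq = "C" * 50 + "TAGG"
        assert detect_tsd(seq, 0, 50)[2] == "indeterminate"

    def test_different_flanks_mismatch(self):
        seq = "GGTA" + "C" * 50 + "TGGG"
        assert detect_tsd(seq, 4, 54)[2] == "mismatch"


def _orf_element(rng, n_codons, stop_at=None):
    body = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=n_codons - 1)]
    if stop_at is not None:
        body[stop_at] = "TAA"
    cds = "ATG" + "".join(body) + "TAA"
    return random_sequence(150, 0.5, rng) + cds + random_sequence(150, 0.5, rng)


class TestRecoverOrf:
    def test_planted_340_codon_orf_recovered(self, rng):
        el = _orf_element(rng, 340)
        orf = recover_orf(el)
        assert orf is not None and len(orf.protein) == 340
        assert orf.protein.startswith("M")

    def test_premature_stop_shortens_orf(self, rng):
        el = _orf_element(rng, 340, stop_at=149)
        orf = recover_orf(el)
        assert orf is not None and len(orf.protein) < 300

    def test_all_n_element_has_no_orf(self):
        assert recover_orf("N" * 1200) is None

    def test_minus_strand_orf_found_with_element_coordinates(self, rng):
        el = _orf_element(rng, 200)
        orf_f = recover_orf(el)
        orf_r = recover_orf(revcomp(el))
        assert orf_r is not None and orf_r.strand == "-"
        assert orf_r.protein == orf_f.protein
        assert orf_r.start == len(el) - orf_f.end
        assert orf_r.end == len(el) - orf_f.start

    def test_short_element_rejected(self):
        with pytest.raises(ValueError):
            recover_orf("ATG" * 50)


class TestClassification:
    def _ann(self, tir=True, tsd="match", orf_aa=340):
        a = ElementAnnotation("e", "g", "c", 0, 1600, "+")
        if tir:
            a.tir = TirPair(0, 1400, 200, 0, 200)
        a.tsd_left = a.tsd_right = "TA"
        a.tsd_flag = tsd
        if orf_aa:
            a.orf = Orf(300, 300 + orf_aa * 3 + 3, "+", "M" * orf_aa)
        return a

    def test_full_structure_with_long_orf_is_intact(self):
        assert classify_copy(self._ann()) == "intact"

    def test_299_aa_orf_is_only_full(self):
        assert classify_copy(self._ann(orf_aa=299)) == "full"

    def test_300_aa_orf_boundary_is_intact(self):
        assert classify_copy(self._ann(orf_aa=300)) == "intact"

    def test_missing_tir_is_hit_only(self):
        assert classify_copy(self._ann(tir=False)) == "hit_only"

    def test_tsd_mismatch_is_hit_only(self):
        assert classify_copy(self._ann(tsd="mismatch")) == "hit_only"


class TestFamilyReference:
    def test_unanimous_copies_give_identical_consensus(self, rng):
        seq = random_sequence(400, 0.5, rng)
        copies = [(f"c{i}", seq, "intact") for i in range(15)]
        ref, method = build_family_reference(copies)
        assert method == "consensus" and ref == seq

    def test_few_copies_pick_longest_intact_representative(self, rng):
        copies = [
            ("a", random_sequence(900, 0.5, rng), "full"),
            ("b", random_sequence(800, 0.5, rng), "intact"),
            ("c", random_sequence(1000, 0.5, rng), "hit_only"),
        ]
        ref, method = build_family_reference(copies)
        assert method == "representative" and ref == copies[1][1]

    def test_exactly_ten_copies_use_representative(self, rng):
        copies = [(f"c{i}", random_sequence(300, 0.5, rng), "full") for i in range(10)]
        _, method = build_family_reference(copies)
        assert method == "representative"

    def test_private_mutations_average_out_to_ancestor(self, rng):
        anc = random_sequence(600, 0.5, rng)
        copies = []
        for i in range(12):
            pos = int(rng.integers(0, 600))
            alt = [b for b in "ACGT" if b != anc[pos]][int(rng.integers(0, 3))]
            copies.append((f"c{i}", anc[:pos] + alt + anc[pos + 1:], "intact"))
        ref, method = build_family_reference(copies)
        assert method == "consensus" and ref == anc

    def test_no_copies_rejected(self):
        with pytest.raises(ValueError):
            build_family_reference([])
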