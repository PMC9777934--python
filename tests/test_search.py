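"""Translated homology search, flank extraction, and copy counting."""

import numpy as np
import pytest

from oracles import sw_sixframe_oracle
from tefp.annotate import recover_orf
from tefp.search import (
    ProteinQuery,
    SearchHit,
    count_copies,
    extract_with_flanks,
    search_translated,
    six_frame_translate,
)
from tefp.simulate import SimulationConfig, jc_mutate, random_sequence, revcomp, simulate_dataset


class TestSixFrameTranslate:
    def test_single_codon(self):
        frames = dict(((s, f), p) for s, f, p in six_frame_translate("ATG"))
        assert frames[("+", 1)] == "M"
        assert frames[("+", 2)] == "" and frames[("+", 3)] == ""

    def test_reverse_strand_codon(self):
        frames = dict(((s, f), p) for s, f, p in six_frame_translate("CAT"))
        assert frames[("-", 1)] == "M"

    def test_frame_lengths_of_999nt_sequence(self, rng):
        seq = random_sequence(999, 0.5, rng)
        lengths = [len(p) for s, f, p in six_frame_translate(seq) if s == "+"]
        assert lengths == [333, 332, 332]

    def test_n_codons_become_x(self):
        frames = dict(((s, f), p) for s, f, p in six_frame_translate("ATGNNNAAA"))
        assert frames[("+", 1)] == "MXK"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            six_frame_translate("AT")


def _planted_genome(rng, protein_aa=120, identity=1.0):
    """A random contig with one in-frame CDS encoding a known protein."""
    from tefp.simulate import SENSE_CODONS

    codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=protein_aa)]
    cds = "".join(codons)
    if identity < 1.0:
        # amino-acid-level decay: mutate whole codons
        n_mut = int(round((1 - identity) * protein_aa))
        for p in rng.choice(protein_aa, size=n_mut, replace=False):
            cds = cds[:3 * p] + SENSE_CODONS[rng.integers(0, 61)] + cds[3 * p + 3:]
    left = random_sequence(5000, 0.5, rng)
    right = random_sequence(5000, 0.5, rng)
    genome = {"c1": left + cds + right}
    from Bio.Seq import Seq

    prot = str(Seq("".join(codons)).translate())
    return genome, prot, (5000, 5000 + 3 * protein_aa)


class TestSearchTranslated:
    def test_exact_planted_cds_recovered(self, rng):
        genome, prot, (s, e) = _planted_genome(rng)
        hits = search_translated(genome, ProteinQuery("q", "ZB", prot))
        assert hits and hits[0].pct_identity == 100.0
        assert hits[0].query_coverage == pytest.approx(1.0)
        assert (hits[0].start, hits[0].end) == (s, e)

    def test_all_n_genome_yields_nothing(self):
        hits = search_translated({"c1": "N" * 3000},
                                 ProteinQuery("q", "ZB", "MKLVRTGEAWQ" * 10))
        assert hits == []

    def test_empty_genome_yields_nothing(self):
        assert search_translated({}, ProteinQuery("q", "ZB", "MKLVRTGEAWQ" * 3)) == []

    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            search_translated({"c1": "ACGT" * 100}, ProteinQuery("q", "ZB", "MKLVRTGE"))

    def test_decayed_cds_found_where_full_dp_oracle_finds_it(self, rng):
        genome, prot, (s, e) = _planted_genome(rng, protein_aa=150, identity=0.85)
        hits = search_translated(genome, ProteinQuery("q", "ZB", prot))
        oracle = sw_sixframe_oracle(genome["c1"], prot)
        assert hits, "seeded search missed a locus the DP oracle scores highly"
        top = hits[0]
        o_score, o_s, o_e, o_strand = oracle
        inter = min(top.end, o_e) - max(top.start, o_s)
        recip = inter / max(top.end - top.start, o_e - o_s)
        assert recip >= 0.9
        assert top.raw_score == pytest.approx(o_score)

    def test_minus_strand_hit_coordinates_translate_back(self, rng):
        genome, prot, (s, e) = _planted_genome(rng, protein_aa=100)
        flipped = {"c1": revcomp(genome["c1"])}
        hits = search_translated(flipped, ProteinQuery("q", "ZB", prot))
        assert hits and hits[0].strand == "-"
        n = len(flipped["c1"])
        assert (hits[0].start, hits[0].end) == (n - e, n - s)
        # re-translating the reported interval reproduces the aligned protein
        sub = revcomp(flipped["c1"][hits[0].start:hits[0].end])
        from Bio.Seq import Seq

        assert str(Seq(sub).translate()) == prot


class TestExtractWithFlanks:
    def test_interior_hit_gets_full_flanks(self):
        genome = {"c1": "A" * 20000}
        hit = SearchHit("", "c1", 5000, 6600, "+", 1, 100, 1e-9, 1.0, 100.0)
        loc = extract_with_flanks(genome, hit, 2000)
        assert (loc["slice_start"], loc["slice_end"]) == (3000, 8600)
        assert loc["left_flank"] == loc["right_flank"] == 2000
        assert not loc["left_clipped"] and not loc["right_clipped"]

    def test_boundary_hit_clipped_and_recorded(self):
        genome = {"c1": "A" * 20000}
        hit = SearchHit("", "c1", 500, 2100, "+", 1, 100, 1e-9, 1.0, 100.0)
        loc = extract_with_flanks(genome, hit, 2000)
        assert loc["slice_start"] == 0 and loc["left_flank"] == 500
        assert loc["left_clipped"] and not loc["right_clipped"]

    def test_slice_relocates_in_contig(self, rng):
        contig = random_sequence(30000, 0.5, rng)
        genome = {"c1": contig}
        hit = SearchHit("", "c1", 9000, 10000, "+", 1, 100, 1e-9, 1.0, 100.0)
        loc = extract_with_flanks(genome, hit, 2000)
        assert contig.find(loc["sequence"]) == loc["slice_start"]

    def test_minus_hit_returned_reverse_complemented(self, rng):
        contig = random_sequence(30000, 0.5, rng)
        hit = SearchHit("", "c1", 9000, 10000, "-", 1, 100, 1e-9, 1.0, 100.0)
        loc = extract_with_flanks({"c1": contig}, hit, 1000)
        assert loc["oriented"]
        assert loc["sequence"] == revcomp(contig[8000:11000])


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(n_species=2, contig_length=300_000,
                           copies_per_genome=10, decay_rate=0.02,
                           truncation_prob=0.0, seed=23)
    b = simulate_dataset(cfg)
    sp = next(iter(b.genomes))
    return b.genomes[sp], b.te_master[sp], b.truth[b.truth.species == sp]


class TestCountCopies:

    def test_planted_copy_number_recovered(self, planted):
        genome, master, truth = planted
        n, intervals = count_copies(genome, master)
        assert n == len(truth) == 10

    def test_short_fragment_fails_coverage_rule(self, rng):
        master = random_sequence(2000, 0.5, rng)
        fragment = master[:700]  # 35% of the query length
        genome = {"c1": random_sequence(5000, 0.5, rng) + fragment
                  + random_sequence(5000, 0.5, rng)}
        n, _ = count_copies(genome, master)
        assert n == 0

    def test_raising_thresholds_never_increases_count(self, planted):
        genome, master, _ = planted
        n_base, _ = count_copies(genome, master, 0.40, 90.0)
        n_cov, _ = count_copies(genome, master, 0.80, 90.0)
        n_id, _ = count_copies(genome, master, 0.40, 99.0)
        assert n_cov <= n_base and n_id <= n_base
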