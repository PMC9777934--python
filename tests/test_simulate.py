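"""The synthetic-data generator: trees, sequence evolution, planting, HT."""

import numpy as np
import pandas as pd
import pytest

from tefp.simulate import (
    SimulationConfig,
    choose_ht_edges,
    evolve_sequences,
    expected_te_divergence,
    inject_ht,
    jc_expected_p,
    jc_mutate,
    make_te_consensus,
    plant_transposons,
    random_sequence,
    revcomp,
    simulate_dataset,
    simulate_species_tree,
)
from tefp.treeutil import tip_distances


class TestSpeciesTree:
    def test_two_species_cherry_has_forced_divergence(self):
        root, div = simulate_species_tree(2, 0.1, np.random.default_rng(0))
        assert len(list(root.leaves())) == 2
        assert div.values[0, 1] == pytest.approx(0.2)

    def test_pairwise_divergence_bounded_by_twice_height(self):
        _, div = simulate_species_tree(3, 0.07, np.random.default_rng(1))
        off = div.values[~np.eye(3, dtype=bool)]
        assert (off <= 2 * 0.07 + 1e-12).all() and (off > 0).all()

    def test_divergence_table_matches_tree_path_lengths(self):
        root, div = simulate_species_tree(8, 0.15, np.random.default_rng(2))
        paths = tip_distances(root)
        for (a, b), d in paths.items():
            assert div.loc[a, b] == pytest.approx(d, abs=1e-9)

    def test_same_seed_reproduces_newick(self):
        t1, _ = simulate_species_tree(8, 0.1, np.random.default_rng(7))
        t2, _ = simulate_species_tree(8, 0.1, np.random.default_rng(7))
        assert t1.newick() == t2.newick()

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, 0.1, np.random.default_rng(0))


class TestEvolution:
    def test_zero_branch_lengths_reproduce_ancestor(self):
        root, _ = simulate_species_tree(4, 0.1, np.random.default_rng(3))
        for node in root.preorder():
            node.length = 0.0
        anc = random_sequence(500, 0.5, np.random.default_rng(4))
        leaves = evolve_sequences(root, anc, np.random.default_rng(5))
        assert all(s == anc for s in leaves.values())

    def test_p_distance_matches_jc_expectation(self, rng):
        # closed-form oracle: E[p] = (3/4)(1 - exp(-4d/3)) at divergence 0.2
        anc = random_sequence(30_000, 0.5, rng)
        a = jc_mutate(anc, 0.1, rng)
        b = jc_mutate(anc, 0.1, rng)
        p = sum(x != y for x, y in zip(a, b)) / len(a)
        exp = jc_expected_p(0.2)
        se = np.sqrt(exp * (1 - exp) / len(a))
        assert abs(p - exp) < 3 * se

    def test_non_acgt_ancestor_rejected(self, rng):
        with pytest.raises(ValueError):
            jc_mutate("ACGTN", 0.1, rng)

    def test_same_seed_gives_identical_leaves(self):
        root, _ = simulate_species_tree(5, 0.1, np.random.default_rng(6))
        anc = random_sequence(300, 0.5, np.random.default_rng(8))
        l1 = evolve_sequences(root, anc, np.random.default_rng(9))
        l2 = evolve_sequences(root, anc, np.random.default_rng(9))
        assert l1 == l2

    def test_orf_preserving_decay_never_creates_stops(self, rng):
        cfg = SimulationConfig()
        te, meta = make_te_consensus(cfg, rng)
        os_, oe_ = meta["orf_start"], meta["orf_end"]
        for _ in range(10):
            mut = jc_mutate(te, 0.1, rng, orf_span=(os_, oe_))
            orf = mut[os_:oe_]
            assert orf.startswith("ATG")
            codons = [orf[i:i + 3] for i in range(0, len(orf) - 3, 3)]
            assert not any(c in ("TAA", "TAG", "TGA") for c in codons)


class TestPlanting:
    def test_no_decay_copies_match_consensus_with_ta_flanks(self, clean_bundle):
        b = clean_bundle
        assert len(b.truth) == 2 * 3
        for _, r in b.truth.iterrows():
            g = b.genomes[r.species][r.contig]
            copy = g[r.start:r.end]
            if r.strand == "-":
                copy = revcomp(copy)
            assert copy == b.te_master[r.species]
            assert g[r.start - 2:r.start] == "TA"
            assert g[r.end:r.end + 2] == "TA"

    def test_forced_truncation_leaves_no_full_copies(self):
        cfg = SimulationConfig(n_species=2, contig_length=60_000,
                               copies_per_genome=3, truncation_prob=1.0, seed=13)
        b = simulate_dataset(cfg)
        assert b.truth.truncated.all()
        assert not (b.truth.tir_left_present & b.truth.tir_right_present).any()

    def test_copy_decay_matches_jc_expectation(self, rng):
        cfg = SimulationConfig(n_species=2, contig_length=400_000,
                               copies_per_genome=10, decay_rate=0.05,
                               truncation_prob=0.0, preserve_orf=False, seed=17)
        b = simulate_dataset(cfg)
        ps = []
        for _, r in b.truth.iterrows():
            g = b.genomes[r.species][r.contig]
            copy = g[r.start:r.end]
            if r.strand == "-":
                copy = revcomp(copy)
            master = b.te_master[r.species]
            ps.append(sum(x != y for x, y in zip(copy, master)) / len(master))
        exp = jc_expected_p(0.05)
        se = np.sqrt(exp * (1 - exp) / (len(ps) * cfg.te_length))
        assert abs(np.mean(ps) - exp) < 3 * se

    def test_truth_count_matches_genome_insertions(self, small_bundle):
        b = small_bundle
        total_len = sum(len(c) for g in b.genomes.values() for c in g.values())
        planted_len = int((b.truth.end - b.truth.start).sum())
        n_background = b.config.n_species * b.config.contig_length
        # every insertion adds its element plus one duplicated TA
        assert total_len == n_background + planted_len + 2 * len(b.truth)

    def test_planted_coordinates_inside_contigs(self, small_bundle):
        for _, r in small_bundle.truth.iterrows():
            clen = len(small_bundle.genomes[r.species][r.contig])
            assert 0 <= r.start < r.end <= clen


class TestHorizontalTransfer:
    def test_empty_edge_list_is_identity(self, rng):
        seqs = {"a": "ACGT" * 50, "b": "TTGG" * 50}
        assert inject_ht(seqs, [], rng) == seqs

    def test_unknown_species_rejected(self, rng):
        with pytest.raises(ValueError):
            inject_ht({"a": "ACGT" * 50}, [("a", "zz", 0.01)], rng)

    def test_transfer_not_below_host_divergence_rejected(self, rng):
        div = pd.DataFrame([[0, 0.1], [0.1, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            inject_ht({"a": "ACGT" * 50, "b": "ACGT" * 50}, [("a", "b", 0.2)],
                      rng, divergence=div)

    def test_same_seed_reproduces_output(self):
        seqs = {"a": "ACGT" * 200, "b": "TTGGCATG" * 100}
        o1 = inject_ht(seqs, [("a", "b", 0.05)], np.random.default_rng(3))
        o2 = inject_ht(seqs, [("a", "b", 0.05)], np.random.default_rng(3))
        assert o1 == o2

    def test_expected_te_divergence_reflects_edges(self):
        sps = ["a", "b", "c"]
        div = pd.DataFrame([[0, .3, .3], [.3, 0, .2], [.3, .2, 0]],
                           index=sps, columns=sps)
        d = expected_te_divergence(div, [("a", "b", 0.01)], te_rate_scale=2.0)
        assert d.loc["a", "b"] == pytest.approx(0.01)
        # recipient now carries the donor's lineage against third species
        assert d.loc["b", "c"] == pytest.approx(2.0 * 0.3 + 0.01)

    def test_rule_oracle_flags_chosen_edges_only(self):
        _, div = simulate_species_tree(12, 0.15, np.random.default_rng(21))
        edges = choose_ht_edges(div, 4, np.random.default_rng(22))
        d_te = expected_te_divergence(div, edges, te_rate_scale=2.0)
        edge_pairs = {frozenset((a, b)) for a, b, _ in edges}
        called = set()
        for i, a in enumerate(div.index):
            for b in div.index[i + 1:]:
                ident = 100 * (1 - jc_expected_p(d_te.loc[a, b]))
                if ident >= 70 and 1.2 * d_te.loc[a, b] < div.loc[a, b]:
                    called.add(frozenset((a, b)))
        assert called == edge_pairs


class TestConfig:
    def test_orf_tir_budget_enforced(self):
        cfg = SimulationConfig(te_length=1000, tir_length=300, orf_length_aa=340)
        with pytest.raises(ValueError):
            cfg.validate()

    @pytest.mark.parametrize("field,value", [
        ("truncation_prob", 1.5), ("background_gc", -0.1),
        ("n_species", 1), ("host_gene_length", 1001),
    ])
    def test_invalid_fields_rejected(self, field, value):
        cfg = SimulationConfig(**{field: value})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_identical_seed_bit_identical_dataset(self):
        cfg = SimulationConfig(n_species=2, contig_length=50_000,
                               copies_per_genome=2, seed=31)
        b1 = simulate_dataset(cfg)
        b2 = simulate_dataset(SimulationConfig(n_species=2, contig_length=50_000,
                                               copies_per_genome=2, seed=31))
        assert b1.genomes == b2.genomes
        assert b1.newick == b2.newick
        pd.testing.assert_frame_equal(b1.truth, b2.truth)


def test_host_gene_divergence_tracks_tree_expectation():
    """Regression of observed host-gene p-distances on tree expectations
    across replicates has slope near 1 (divergence calibration)."""
    xs, ys = [], []
    for rep in range(20):
        cfg = SimulationConfig(n_species=4, contig_length=1000,
                               copies_per_genome=1, host_gene_length=3000,
                               seed=100 + rep)
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        tree, div = simulate_species_tree(cfg.n_species, cfg.tree_height, rng)
        anc = random_sequence(cfg.host_gene_length, 0.5, rng)
        leaves = evolve_sequences(tree, anc, rng)
        names = sorted(leaves)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                p = sum(x != y for x, y in zip(leaves[a], leaves[b])) / cfg.host_gene_length
                xs.append(jc_expected_p(div.loc[a, b]))
                ys.append(p)
    slope = np.polyfit(xs, ys, 1)[0]
    assert 0.9 <= slope <= 1.1
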