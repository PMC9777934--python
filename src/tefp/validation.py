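"""Ground-truth validation runs: the study conditions for the package's
property checks, shared by the test suite and the reproduction script.

Each function simulates data at fixed, documented conditions, runs the
relevant pipeline stages from scratch and returns measured quantities
(recovery rates, estimator means, call counts).  Nothing here reads
external data; everything flows from one integer seed.
"""

from __future__ import annotations

import numpy as np

from tefp import annotate as ann_mod
from tefp.annotate import recover_orf
from tefp.distances import call_ht, distance_table, estimate_composite_params, pairwise_distance
from tefp.identity import pairwise_identity
from tefp.msa import align
from tefp.phylo import nj_tree
from tefp.search import ProteinQuery, extract_with_flanks, iterative_search
from tefp.simulate import (
    SimulationConfig,
    choose_ht_edges,
    jc_mutate,
    random_sequence,
    revcomp,
    simulate_dataset,
    simulate_species_tree,
)
from tefp.sitepref import build_profile, extract_insertion_windows
from tefp.treeutil import Node, tip_distances


def te_cds(master: str) -> str:
    """Transposase CDS of a master element (oriented forward)."""
    orf = recover_orf(master)
    if orf.strand == "+":
        return master[orf.start:orf.end]
    rc = revcomp(master)
    return rc[len(master) - orf.end:len(master) - orf.start]


def planted_recovery(
    seed: int = 0,
    n_species: int = 12,
    contig_length: int = 1_000_000,
    copies_per_genome: int = 20,
    decay_rate: float = 0.03,
    truncation_prob: float = 0.2,
) -> dict:
    """Mine and annotate simulated genomes; score against planted truth.

    One family query (the transposase of the first species' element
    lineage) searches every genome; annotations are matched to planted
    copies by coordinate overlap.  Reports the fraction of non-truncated
    copies classified intact, the fraction with both element boundaries
    within +/-2 nt of truth, and whether the intact/full/detected nesting
    held on every annotation.
    """
    cfg = SimulationConfig(
        n_species=n_species, contig_length=contig_length,
        copies_per_genome=copies_per_genome, decay_rate=decay_rate,
        truncation_prob=truncation_prob, seed=seed,
    )
    bundle = simulate_dataset(cfg)
    query_sp = sorted(bundle.te_master)[0]
    query = ProteinQuery("family_query", "reference-other",
                         recover_orf(bundle.te_master[query_sp]).protein)
    n_target = n_intact = n_within2 = 0
    nesting_ok = True
    for sp, genome in bundle.genomes.items():
        hits = iterative_search(genome, [query], rounds=2, genome_id=sp)
        annotations = []
        for k, hit in enumerate(hits):
            locus = extract_with_flanks(genome, hit, 2000)
            a = ann_mod.annotate_locus(locus, f"{sp}.e{k}", sp)
            if a.tir is None:
                a.start, a.end = hit.start, hit.end
            annotations.append(a)
        for a in annotations:
            if a.classification == "intact":
                good = (a.tir is not None and a.tsd_flag == "match"
                        and a.orf is not None and len(a.orf.protein) >= 300)
                nesting_ok &= good
            elif a.classification == "full":
                nesting_ok &= (a.tir is not None and a.tsd_flag == "match")
        truth = bundle.truth[bundle.truth.species == sp]
        for _, row in truth.iterrows():
            if row.truncated:
                continue
            n_target += 1
            matched = [a for a in annotations
                       if min(a.end, row.end) - max(a.start, row.start) > 0]
            if not matched:
                continue
            a = max(matched, key=lambda x: min(x.end, row.end) - max(x.start, row.start))
            if a.classification == "intact":
                n_intact += 1
                if abs(a.start - row.start) <= 2 and abs(a.end - row.end) <= 2:
                    n_within2 += 1
    return {
        "n_non_truncated": n_target,
        "intact_recovery_pct": 100.0 * n_intact / n_target if n_target else 0.0,
        "boundary_within_2nt_pct": 100.0 * n_within2 / n_target if n_target else 0.0,
        "nesting_ok": bool(nesting_ok),
    }


def make_planted_ir_locus(rng, locus_len: int = 3000, window: int = 600):
    """One random locus with a planted inverted repeat (length 20-415,
    0-15% one-sided mismatches) inside the terminal search windows."""
    L = int(rng.integers(20, 416))
    frac = float(rng.uniform(0.0, 0.15))
    mism = int(frac * L)
    tir = random_sequence(L, 0.5, rng)
    t3 = revcomp(tir)
    if mism:
        pos = rng.choice(L, size=mism, replace=False)
        t = list(t3)
        for p in pos:
            alts = [b for b in "ACGT" if b != t[p]]
            t[p] = alts[rng.integers(0, 3)]
        t3 = "".join(t)
    off5 = int(rng.integers(0, window - L))
    off3 = int(rng.integers(0, window - L))
    mid = locus_len - off5 - off3 - 2 * L
    return (random_sequence(off5, 0.5, rng) + tir + random_sequence(mid, 0.5, rng)
            + t3 + random_sequence(off3, 0.5, rng))


def tir_oracle_agreement(oracle_fn, n_loci: int = 200, seed: int = 0) -> dict:
    """Fraction of random planted-IR loci where the production TIR finder
    returns exactly the oracle's best pair."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_loci):
        locus = make_planted_ir_locus(rng)
        hit = ann_mod.find_tirs(locus, search_window=600)
        got = None if hit is None else (hit.score, hit.length, hit.tir5_start,
                                        hit.tir3_start, hit.mismatches)
        if got == oracle_fn(locus, 20, 450, 0.15, 600):
            agree += 1
    return {"n_loci": n_loci, "agreement_pct": 100.0 * agree / n_loci}


def distance_calibration(
    seed: int = 0,
    true_d=(0.05, 0.2, 0.5),
    length: int = 10_000,
    reps: int = 200,
) -> dict:
    """Mean distance estimates on simulated pairs, by model and divergence,
    with the standard error of each replicate mean; plus the largest
    TN93-CL vs JC discrepancy on 50-kb uniform-composition pairs."""
    rng = np.random.default_rng(seed)
    out: dict = {}
    for d in true_d:
        est = {"JC": [], "K2P": [], "TN93-CL": []}
        for _ in range(reps):
            a = random_sequence(length, 0.5, rng)
            b = jc_mutate(a, d, rng)
            shared = estimate_composite_params({"a": a, "b": b})
            est["JC"].append(pairwise_distance(a, b, "JC").distance)
            est["K2P"].append(pairwise_distance(a, b, "K2P").distance)
            est["TN93-CL"].append(
                pairwise_distance(a, b, "TN93-CL", shared=shared).distance)
        for model, vals in est.items():
            v = np.asarray(vals)
            out[(model, d)] = {"mean": float(v.mean()),
                               "sem": float(v.std(ddof=1) / np.sqrt(len(v)))}
    collapse = []
    for _ in range(3):
        a = random_sequence(50_000, 0.5, rng)
        b = jc_mutate(a, 0.2, rng)
        shared = estimate_composite_params({"a": a, "b": b})
        jc = pairwise_distance(a, b, "JC").distance
        tn = pairwise_distance(a, b, "TN93-CL", shared=shared).distance
        collapse.append(abs(tn - jc))
    out["tn93cl_jc_max_abs_diff"] = float(max(collapse))
    return out


def ht_recovery(seed: int = 0, n_species: int = 12, n_edges: int = 4) -> dict:
    """Inject HT edges with clean expected-distance margins, then rerun the
    whole distance/identity/ratio machinery on the simulated sequences."""
    tree_rng = np.random.default_rng(seed)
    _, div = simulate_species_tree(n_species, 0.15, tree_rng)
    edges = choose_ht_edges(div, n_edges, np.random.default_rng(seed + 1))
    cfg = SimulationConfig(n_species=n_species, contig_length=60_000,
                           copies_per_genome=2, seed=seed, ht_edges=edges)
    bundle = simulate_dataset(cfg)
    cds = {sp: te_cds(m) for sp, m in bundle.te_master.items()}
    te_aligned = align(cds)
    te_recs = {frozenset((r.species_a, r.species_b)): r
               for r in distance_table(te_aligned, "TE")}
    host = {}
    for marker in ("RPL3", "RPL4"):
        host[marker] = {frozenset((r.species_a, r.species_b)): r
                        for r in distance_table(align(bundle.host_genes[marker]), marker)}
    species = sorted(bundle.genomes)
    calls = []
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            pair = frozenset((a, b))
            ident = pairwise_identity(cds[a], cds[b])
            calls.append(call_ht(
                te_recs[pair].distance, host["RPL3"][pair].distance,
                host["RPL4"][pair].distance, ident, species=(a, b), family="TE"))
    called = {frozenset((c.species_a, c.species_b)) for c in calls
              if c.decision == "HT"}
    true_pairs = {frozenset((a, b)) for a, b, _ in edges}
    counts_by_factor = {}
    for f in (1.0, 1.2, 1.5, 2.0):
        counts_by_factor[f] = sum(
            1 for c in calls
            if c.decision != "excluded" and c.d_te * f < min(c.d_rpl3, c.d_rpl4))
    fs = sorted(counts_by_factor)
    monotone = all(counts_by_factor[fs[k]] >= counts_by_factor[fs[k + 1]]
                   for k in range(len(fs) - 1))
    return {
        "n_edges": n_edges,
        "edges_recovered": len(called & true_pairs),
        "false_positives": len(called - true_pairs),
        "counts_by_factor": counts_by_factor,
        "factor_monotonic": monotone,
    }


def random_additive_matrix(rng, n: int = 5):
    """Random binary tree with positive branch lengths and its path metric."""
    nodes = [Node(name=f"t{i}", length=float(rng.uniform(0.05, 1.0)))
             for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        p = Node(length=float(rng.uniform(0.05, 1.0)))
        p.add(nodes[i])
        p.add(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [p]
    root = Node()
    root.add(nodes[0])
    root.add(nodes[1])
    td = tip_distances(root)
    labels = sorted({x for pair in td for x in pair})
    import pandas as pd

    D = pd.DataFrame(0.0, index=labels, columns=labels)
    for (a, b), v in td.items():
        D.loc[a, b] = D.loc[b, a] = v
    return D


def nj_exactness(n_matrices: int = 100, n_taxa: int = 5, seed: int = 0) -> dict:
    """Fraction of random additive matrices whose path metric the NJ tree
    reproduces exactly (to 1e-9)."""
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_matrices):
        D = random_additive_matrix(rng, n_taxa)
        td = tip_distances(nj_tree(D))
        if all(abs(td[k] - D.loc[k[0], k[1]]) < 1e-9 for k in td):
            exact += 1
    return {"n_matrices": n_matrices, "exact_pct": 100.0 * exact / n_matrices}


def insertion_profile_center_ic(seed: int = 0) -> dict:
    """Information content at the two central positions of the 40-bp
    insertion-window profile of a strict-TA simulation."""
    cfg = SimulationConfig(n_species=3, contig_length=150_000,
                           copies_per_genome=8, seed=seed)
    bundle = simulate_dataset(cfg)
    windows = []
    for sp, contigs in bundle.genomes.items():
        truth = bundle.truth[bundle.truth.species == sp]
        els = [{"contig": r.contig, "start": int(r.start), "strand": r.strand,
                "tsd_flag": "match"} for _, r in truth.iterrows()]
        windows.extend(extract_insertion_windows(contigs, els))
    prof = build_profile(windows)
    return {"n_windows": prof.n_sequences,
            "center_ic_bits": (float(prof.ic[19]), float(prof.ic[20]))}
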