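"""Synthetic genomes with planted DNA transposons and known ground truth.

The generator emulates the statistical structure a Tc1-type transposon
survey relies on: a set of species related by an ultrametric tree, two
conserved host genes (RPL3/RPL4 stand-ins) whose divergence tracks the
tree, and a transposon family whose copies carry terminal inverted repeats
(TIRs), a TA target-site duplication (TSD) and a single transposase ORF.
Copies decay neutrally after insertion and may be truncated at one end.
Horizontal-transfer (HT) events replace a recipient species' element
lineage with a recent derivative of a donor lineage, which makes the
element divergence of that species pair anomalously low relative to the
host genes — exactly the signal the distance-ratio HT test looks for.

Vertically transmitted element lineages evolve at ``te_rate_scale`` times
the species rate (default 2x): transposon sequence drifts neutrally while
ribosomal-protein coding sequence is under strong purifying selection, so
element divergence between species normally exceeds host-gene divergence.

All coordinates are 0-based, half-open; strands are "+"/"-".  All
randomness flows from the single integer seed in ``SimulationConfig``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from tefp.treeutil import Node

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_TO_IDX = {b: i for i, b in enumerate(BASES)}
_STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# the 61 sense codons, fixed order
SENSE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in _STOP_CODONS
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random DNA with the requested GC fraction (A/T and G/C split evenly)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Units: tree_height and decay_rate are expected substitutions per site;
    lengths are nucleotides (host_gene_length a multiple of 3);
    orf_length_aa counts residues including the initial Met.
    """

    n_species: int = 12
    tree_height: float = 0.15
    host_gene_length: int = 1200
    te_length: int = 1600
    tir_length: int = 220
    orf_length_aa: int = 340
    copies_per_genome: int = 20
    decay_rate: float = 0.03
    truncation_prob: float = 0.2
    ht_edges: list[tuple[str, str, float]] = field(default_factory=list)
    background_gc: float = 0.41
    seed: int = 0
    # generator extensions
    contig_length: int = 1_000_000
    te_rate_scale: float = 2.0
    preserve_orf: bool = True
    ta_only: bool = True

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.host_gene_length % 3 != 0:
            raise ValueError("host_gene_length must be a multiple of 3")
        for name in ("host_gene_length", "te_length", "tir_length",
                     "orf_length_aa", "copies_per_genome", "contig_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("truncation_prob", "background_gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.decay_rate < 0 or self.tree_height < 0:
            raise ValueError("rates must be non-negative")
        if self.orf_length_aa * 3 + 2 * self.tir_length > self.te_length:
            raise ValueError("ORF plus TIRs exceed te_length")


@dataclass
class SimulationBundle:
    """Everything one simulated study produces, truth included."""

    config: SimulationConfig
    tree: Node
    newick: str
    divergence: pd.DataFrame          # expected pairwise divergence (2 * MRCA height)
    host_genes: dict[str, dict[str, str]]   # marker -> species -> CDS
    te_master: dict[str, str]               # species -> element lineage sequence
    te_meta: dict
    genomes: dict[str, dict[str, str]]      # species -> contig -> sequence
    truth: pd.DataFrame
    ht_edges: list[tuple[str, str, float]]


# ---------------------------------------------------------------------------
# tree simulation and sequence evolution
# ---------------------------------------------------------------------------


def simulate_species_tree(
    n_species: int, tree_height: float, rng: np.random.Generator
) -> tuple[Node, pd.DataFrame]:
    """Random ultrametric species tree plus its expected-divergence table.

    ``n_species - 1`` merge heights are drawn uniformly below the root
    height (the last merge sits exactly at ``tree_height``), and random
    lineage pairs are joined bottom-up, giving a rooted ultrametric tree.
    Expected pairwise divergence is twice the height of the MRCA.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    names = [f"sp{i + 1:02d}" for i in range(n_species)]
    lineages: list[tuple[Node, float]] = [(Node(name=n), 0.0) for n in names]
    if n_species == 2:
        heights = np.array([tree_height])
    else:
        heights = np.sort(rng.uniform(0.0, tree_height, size=n_species - 2))
        heights = np.append(heights, tree_height)
    for h in heights:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (a, ha), (b, hb) = lineages[i], lineages[j]
        parent = Node()
        a.length = h - ha
        b.length = h - hb
        parent.add(a)
        parent.add(b)
        # replace the two lineages with their parent
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append((parent, h))
    root = lineages[0][0]

    # divergence = 2 * MRCA height, computed from node heights
    div = pd.DataFrame(0.0, index=names, columns=names)

    def heights_below(node: Node, h: float) -> list[str]:
        if node.is_leaf:
            return [node.name]
        groups = [heights_below(c, h - c.length) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a_ in groups[gi]:
                    for b_ in groups[gj]:
                        div.loc[a_, b_] = div.loc[b_, a_] = 2.0 * h
        return [x for g in groups for x in g]

    heights_below(root, tree_height)
    return root, div


def jc_mutate(
    seq: str,
    t: float,
    rng: np.random.Generator,
    orf_span: Optional[tuple[int, int]] = None,
) -> str:
    """Evolve ``seq`` for ``t`` expected substitutions/site under Jukes-Cantor.

    A site differs from its ancestor with probability
    ``3/4 * (1 - exp(-4t/3))`` and, conditional on change, takes each of
    the three alternative bases with equal probability.

    When ``orf_span`` is given, substitutions inside it are constrained to
    keep the reading frame translatable: the start codon and terminal stop
    are immutable and proposed changes that create a premature stop are
    resampled among the remaining alternatives (kept ancestral when no
    alternative is sense).  This emulates copies that are still intact.
    """
    if t <= 0:
        return seq
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT symbols in ancestral sequence: {sorted(bad)}")
    n = len(seq)
    p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    idx = np.fromiter((_BASE_TO_IDX[c] for c in seq), dtype=np.int8, count=n)
    hit = rng.random(n) < p
    shift = rng.integers(1, 4, size=n, dtype=np.int8)
    new = (idx + shift) % 4
    out = list(seq)
    sites = np.flatnonzero(hit)
    if orf_span is None:
        for i in sites:
            out[i] = BASES[new[i]]
        return "".join(out)

    os_, oe_ = orf_span
    immutable = set(range(os_, os_ + 3)) | set(range(oe_ - 3, oe_))
    for i in sites:
        i = int(i)
        if i < os_ or i >= oe_:
            out[i] = BASES[new[i]]
            continue
        if i in immutable:
            continue
        cs = os_ + ((i - os_) // 3) * 3
        placed = False
        for k in range(3):  # try the drawn shift first, then rotate
            cand = BASES[(idx[i] + ((shift[i] - 1 + k) % 3) + 1) % 4]
            codon = "".join(out[cs:cs + 3])
            pos_in_codon = i - cs
            trial = codon[:pos_in_codon] + cand + codon[pos_in_codon + 1:]
            if trial not in _STOP_CODONS:
                out[i] = cand
                placed = True
                break
        if not placed:
            pass  # keep ancestral base
    return "".join(out)


def mirror_tirs(seq: str, tir_len: int) -> str:
    """Restore exact TIR complementarity: 3' TIR := revcomp of the 5' TIR.

    Active element lineages are kept transposition-competent by selection,
    so their termini stay near-perfect inverted repeats even as the
    element drifts; this constraint models that by mirroring the 5' TIR
    onto the 3' end after each branch of master-lineage evolution.
    """
    if tir_len <= 0 or 2 * tir_len > len(seq):
        return seq
    return seq[:-tir_len] + revcomp(seq[:tir_len])


def evolve_sequences(
    tree: Node,
    ancestral_seq: str,
    rng: np.random.Generator,
    rate_scale: float = 1.0,
    orf_span: Optional[tuple[int, int]] = None,
    tir_mirror: Optional[int] = None,
) -> dict[str, str]:
    """One descendant sequence per leaf, evolved under JC along the tree.

    ``tir_mirror`` keeps the terminal ``tir_mirror`` nt an exact inverted
    repeat after every branch (master element lineages only).
    """
    if not ancestral_seq:
        raise ValueError("ancestral sequence is empty")
    result: dict[str, str] = {}

    def walk(node: Node, seq: str) -> None:
        for child in node.children:
            child_seq = jc_mutate(seq, child.length * rate_scale, rng, orf_span)
            if tir_mirror:
                child_seq = mirror_tirs(child_seq, tir_mirror)
            if child.is_leaf:
                result[child.name] = child_seq
            else:
                walk(child, child_seq)

    walk(tree, ancestral_seq)
    return result


# ---------------------------------------------------------------------------
# the element consensus and planting
# ---------------------------------------------------------------------------


def make_te_consensus(config: SimulationConfig, rng: np.random.Generator) -> tuple[str, dict]:
    """Ancestral element: TIR + pad + single ORF + pad + inverted TIR.

    The TIR starts with a short GC-rich motif followed by an AT-rich
    stretch, the composition reported for Tc1-type element termini.
    """
    T = config.tir_length
    gc_head = random_sequence(min(4, T), 0.9, rng)
    at_mid = random_sequence(min(8, max(0, T - 4)), 0.1, rng)
    rest = random_sequence(max(0, T - len(gc_head) - len(at_mid)), 0.5, rng)
    tir = (gc_head + at_mid + rest)[:T]

    n_codons = config.orf_length_aa  # includes the initial Met
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)]
    orf = "ATG" + "".join(body) + "TAA"

    inner = config.te_length - 2 * T - len(orf)
    if inner < 0:
        raise ValueError("te_length too small for ORF plus TIRs")
    pad_l = inner // 2
    pad_r = inner - pad_l
    seq = tir + random_sequence(pad_l, 0.45, rng) + orf + random_sequence(pad_r, 0.45, rng) + revcomp(tir)
    orf_start = T + pad_l
    meta = {
        "tir_length": T,
        "orf_start": orf_start,
        "orf_end": orf_start + len(orf),   # includes the stop codon
        "length": len(seq),
    }
    return seq, meta


def inject_ht(
    te_seqs: dict[str, str],
    ht_edges: list[tuple[str, str, float]],
    rng: np.random.Generator,
    divergence: Optional[pd.DataFrame] = None,
    orf_span: Optional[tuple[int, int]] = None,
    tir_mirror: Optional[int] = None,
) -> dict[str, str]:
    """Replace each recipient's element lineage with a recent donor derivative.

    Each edge is (donor, recipient, divergence_at_transfer): the recipient's
    element becomes the donor's element evolved for the stated (low)
    divergence.  Empty edge list returns an identical copy of the input.
    """
    out = dict(te_seqs)
    for donor, recipient, t in ht_edges:
        if donor not in te_seqs or recipient not in te_seqs:
            raise ValueError(f"HT edge references unknown species: {(donor, recipient)}")
        if divergence is not None:
            host_d = float(divergence.loc[donor, recipient])
            if t >= host_d:
                raise ValueError(
                    f"transfer divergence {t} not below host divergence {host_d} "
                    f"for edge {(donor, recipient)}"
                )
        moved = jc_mutate(out[donor], t, rng, orf_span)
        if tir_mirror:
            moved = mirror_tirs(moved, tir_mirror)
        out[recipient] = moved
    return out


def expected_te_divergence(
    divergence: pd.DataFrame,
    ht_edges: list[tuple[str, str, float]],
    te_rate_scale: float,
) -> pd.DataFrame:
    """Expected element divergence per species pair given the injected edges.

    Each species' element lineage has an origin species (itself, or its HT
    donor followed transitively) plus the extra divergence accumulated at
    transfer.  Expected divergence between X and Y is the scaled vertical
    divergence between the two origins plus both extras.
    """
    origin = {s: s for s in divergence.index}
    extra = {s: 0.0 for s in divergence.index}
    for donor, recipient, t in ht_edges:
        origin[recipient] = origin[donor]
        extra[recipient] = extra[donor] + t
    out = pd.DataFrame(0.0, index=divergence.index, columns=divergence.columns)
    for a in divergence.index:
        for b in divergence.columns:
            if a == b:
                continue
            oa, ob = origin[a], origin[b]
            base = 0.0 if oa == ob else te_rate_scale * float(divergence.loc[oa, ob])
            out.loc[a, b] = base + extra[a] + extra[b]
    return out


def jc_expected_p(d: float) -> float:
    """Expected proportion of differing sites at JC distance ``d``."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def choose_ht_edges(
    divergence: pd.DataFrame,
    n_edges: int,
    rng: np.random.Generator,
    te_rate_scale: float = 2.0,
    factor: float = 1.2,
    min_identity: float = 70.0,
    transfer_frac: float = 0.25,
    margin: float = 1.4,
    max_tries: int = 2000,
) -> list[tuple[str, str, float]]:
    """Pick HT edges whose expected-distance footprint is exactly themselves.

    Candidate edge sets (disjoint species pairs, transfer divergence =
    ``transfer_frac`` of the pair's host divergence, satisfying the
    transfer <= host/2 premise) are accepted only when evaluating the
    ratio rule on *expected* distances flags exactly the injected pairs,
    with a multiplicative safety ``margin`` on both sides so that finite
    sequences cannot flip a decision.
    """
    species = list(divergence.index)
    for _ in range(max_tries):
        perm = list(rng.permutation(species))
        edges = []
        ok = True
        for k in range(n_edges):
            a, b = perm[2 * k], perm[2 * k + 1]
            d_host = float(divergence.loc[a, b])
            if d_host <= 0:
                ok = False
                break
            edges.append((a, b, transfer_frac * d_host))
        if not ok:
            continue
        d_te = expected_te_divergence(divergence, edges, te_rate_scale)
        edge_pairs = {frozenset((a, b)) for a, b, _ in edges}
        good = True
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                d_host = float(divergence.loc[a, b])
                dte = float(d_te.loc[a, b])
                ident = 100.0 * (1.0 - jc_expected_p(dte))
                pair = frozenset((a, b))
                if pair in edge_pairs:
                    if ident < min_identity + 5.0 or factor * dte * margin >= d_host:
                        good = False
                elif ident >= min_identity - 5.0 and factor * dte < d_host * margin:
                    good = False
                if not good:
                    break
            if not good:
                break
        if good:
            return edges
    raise RuntimeError("could not find an HT edge set with clean expected-distance margins")


def _find_ta_sites(seq: str, min_sep: int, edge_margin: int, rng: np.random.Generator,
                   n_wanted: int, ta_only: bool = True) -> list[int]:
    """Pick well-separated insertion positions (TA dinucleotides by default)."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    if ta_only:
        pos = np.flatnonzero((arr[:-1] == b"T") & (arr[1:] == b"A"))
    else:
        pos = np.arange(len(seq) - 2)
    pos = pos[(pos >= edge_margin) & (pos < len(seq) - edge_margin)]
    if len(pos) == 0:
        return []
    order = rng.permutation(len(pos))
    chosen: list[int] = []
    for k in order:
        p = int(pos[k])
        if all(abs(p - q) >= min_sep for q in chosen):
            chosen.append(p)
            if len(chosen) >= n_wanted:
                break
    return sorted(chosen)


def plant_transposons(
    genomes: dict[str, dict[str, str]],
    te_master: dict[str, str],
    te_meta: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, dict[str, str]], pd.DataFrame]:
    """Insert decayed element copies at TA sites, duplicating the target.

    Insertion at a TA turns ``...TA|rest`` into ``...TA element TA rest``,
    so identical 2-nt TSDs flank every copy.  Each copy independently
    receives JC decay at ``decay_rate`` and, with ``truncation_prob``,
    loses one terminus (at least the whole TIR plus 10 nt, up to 60% of
    the element), which removes that end's TIR.
    """
    T = te_meta["tir_length"]
    os_, oe_ = te_meta["orf_start"], te_meta["orf_end"]
    orf_span = (os_, oe_) if config.preserve_orf else None
    min_sep = config.te_length + 4500
    edge_margin = 2500
    rows = []
    out_genomes: dict[str, dict[str, str]] = {}
    eid = 0
    for species, contigs in genomes.items():
        master = te_master[species]
        out_contigs = {}
        for contig, seq in contigs.items():
            sites = _find_ta_sites(seq, min_sep, edge_margin, rng,
                                   config.copies_per_genome, config.ta_only)
            if not sites:
                logger.warning("no usable TA site in %s:%s; contig skipped", species, contig)
                out_contigs[contig] = seq
                continue
            inserts = []   # (ta_pos, fragment, truthrow-partial)
            for p in sites:
                copy = jc_mutate(master, config.decay_rate, rng, orf_span)
                L0 = len(copy)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    copy = revcomp(copy)
                    orf_f = (L0 - oe_, L0 - os_)
                else:
                    orf_f = (os_, oe_)
                truncated = rng.random() < config.truncation_prob
                trunc_side, trunc_len = "", 0
                tir_left, tir_right = True, True
                off = 0
                if truncated:
                    frac = rng.uniform(0.1, 0.6)
                    trunc_len = max(int(round(frac * L0)), T + 10)
                    trunc_side = "left" if rng.random() < 0.5 else "right"
                    if trunc_side == "left":
                        copy = copy[trunc_len:]
                        tir_left = False
                        off = trunc_len
                    else:
                        copy = copy[:-trunc_len]
                        tir_right = False
                orf_rel = (orf_f[0] - off, orf_f[1] - off)
                inserts.append((p, copy, {
                    "strand": strand, "truncated": truncated,
                    "trunc_side": trunc_side, "trunc_len": trunc_len,
                    "tir_left_present": tir_left, "tir_right_present": tir_right,
                    "orf_rel_start": orf_rel[0], "orf_rel_end": orf_rel[1],
                }))
            # rebuild the contig, left to right
            parts = []
            prev = 0
            shift = 0
            for p, frag, info in inserts:
                parts.append(seq[prev:p + 2])
                parts.append(frag)
                parts.append("TA")
                start = p + 2 + shift
                end = start + len(frag)
                eid += 1
                rows.append({
                    "element_id": f"te{eid:05d}",
                    "species": species, "contig": contig,
                    "start": start, "end": end,
                    "strand": info["strand"],
                    "tir_left_start": start, "tir_left_end": start + T,
                    "tir_right_start": end - T, "tir_right_end": end,
                    "tir_left_present": info["tir_left_present"],
                    "tir_right_present": info["tir_right_present"],
                    "tsd": "TA",
                    "orf_rel_start": info["orf_rel_start"],
                    "orf_rel_end": info["orf_rel_end"],
                    "orf_aa": config.orf_length_aa,
                    "truncated": info["truncated"],
                    "trunc_side": info["trunc_side"],
                    "trunc_len": info["trunc_len"],
                    "decay_rate": config.decay_rate,
                })
                shift += len(frag) + 2
                prev = p + 2
            parts.append(seq[prev:])
            out_contigs[contig] = "".join(parts)
        out_genomes[species] = out_contigs
    truth = pd.DataFrame(rows)
    return out_genomes, truth


def simulate_dataset(config: SimulationConfig) -> SimulationBundle:
    """Run the whole generator: tree, host genes, element lineages, genomes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree, divergence = simulate_species_tree(config.n_species, config.tree_height, rng)
    species = sorted(tree.leaf_names())

    host_genes: dict[str, dict[str, str]] = {}
    for marker in ("RPL3", "RPL4"):
        anc = random_sequence(config.host_gene_length, 0.5, rng)
        host_genes[marker] = evolve_sequences(tree, anc, rng, rate_scale=1.0)

    te_anc, te_meta = make_te_consensus(config, rng)
    orf_span = (te_meta["orf_start"], te_meta["orf_end"]) if config.preserve_orf else None
    te_master = evolve_sequences(tree, te_anc, rng, rate_scale=config.te_rate_scale,
                                 orf_span=orf_span, tir_mirror=config.tir_length)
    te_master = inject_ht(te_master, config.ht_edges, rng, divergence, orf_span,
                          tir_mirror=config.tir_length)

    genomes = {
        sp: {"chr1": random_sequence(config.contig_length, config.background_gc, rng)}
        for sp in species
    }
    genomes, truth = plant_transposons(genomes, te_master, te_meta, config, rng)
    return SimulationBundle(
        config=config, tree=tree, newick=tree.newick(), divergence=divergence,
        host_genes=host_genes, te_master=te_master, te_meta=te_meta,
        genomes=genomes, truth=truth, ht_edges=list(config.ht_edges),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_truth_gff3(path, truth: pd.DataFrame) -> None:
    """Ground truth as GFF3: one element feature with TIR/TSD/ORF children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in truth.iterrows():
            attrs = f"ID={r.element_id};truncated={str(bool(r.truncated)).lower()}"
            fh.write("\t".join([
                r.contig, "tefp_sim", "transposable_element",
                str(r.start + 1), str(r.end), ".", r.strand, ".", attrs]) + "\n")
            if r.tir_left_present:
                fh.write("\t".join([
                    r.contig, "tefp_sim", "terminal_inverted_repeat",
                    str(r.tir_left_start + 1), str(r.tir_left_end), ".", r.strand, ".",
                    f"ID={r.element_id}.tirL;Parent={r.element_id}"]) + "\n")
            if r.tir_right_present:
                fh.write("\t".join([
                    r.contig, "tefp_sim", "terminal_inverted_repeat",
                    str(r.tir_right_start + 1), str(r.tir_right_end), ".", r.strand, ".",
                    f"ID={r.element_id}.tirR;Parent={r.element_id}"]) + "\n")
            fh.write("\t".join([
                r.contig, "tefp_sim", "target_site_duplication",
                str(r.start - 1), str(r.start), ".", r.strand, ".",
                f"ID={r.element_id}.tsdL;Parent={r.element_id}"]) + "\n")


def simulate_to_directory(config: SimulationConfig, outdir) -> SimulationBundle:
    """Run the generator and write FASTA / GFF3 / TSV / Newick artifacts."""
    import os

    bundle = simulate_dataset(config)
    os.makedirs(outdir, exist_ok=True)
    for sp, contigs in bundle.genomes.items():
        write_fasta(os.path.join(outdir, f"{sp}.fa"), contigs)
    for marker, seqs in bundle.host_genes.items():
        write_fasta(os.path.join(outdir, f"{marker}.fa"), seqs)
    write_fasta(os.path.join(outdir, "te_master.fa"), bundle.te_master)
    with open(os.path.join(outdir, "species_tree.nwk"), "w") as fh:
        fh.write(bundle.newick + "\n")
    bundle.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    write_truth_gff3(os.path.join(outdir, "truth.gff3"), bundle.truth)
    return bundle
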