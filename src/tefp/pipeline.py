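"""End-to-end orchestration and survey-style summary tables.

Stage order: translated search -> locus extraction -> TIR/TSD/ORF
annotation -> classification -> per-genome reference building -> clade
assignment (when a reference panel is supplied) -> identity filtering ->
host-gene and element distances -> HT calling -> insertion-site profiles
-> summary tables.  Re-running with an identical configuration and
inputs is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd

from tefp import annotate as ann_mod
from tefp import distances as dist_mod
from tefp import sitepref
from tefp.identity import pairwise_identity
from tefp.msa import align
from tefp.search import ProteinQuery, count_copies, extract_with_flanks, iterative_search

logger = logging.getLogger(__name__)

COPY_BINS = ((1, 9), (10, 99), (100, None))


def percentage(numerator: float, denominator: float) -> float:
    """Percent rounded half-up to 2 decimals (e.g. 142/313 -> 45.37)."""
    if denominator == 0:
        return 0.0
    frac = Decimal(numerator) / Decimal(denominator) * 100
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def mean_sem(values) -> tuple[Optional[float], Optional[float]]:
    """Sample mean and SEM (sd/sqrt(n)); SEM is None for n < 2."""
    v = np.asarray(list(values), dtype=float)
    if len(v) == 0:
        return None, None
    if len(v) < 2:
        return float(v[0]), None
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))


@dataclass
class PipelineConfig:
    """Inputs and thresholds of one profiling run."""

    genomes: dict[str, dict[str, str]]                 # species -> contig -> seq
    queries: list[ProteinQuery]
    host_genes: dict[str, dict[str, str]] = field(default_factory=dict)
    lineage_map: dict[str, str] = field(default_factory=dict)
    reference_panel: Optional[dict[str, tuple[str, str]]] = None
    family_label: str = "TE"
    evalue_max: float = 1e-4
    min_coverage: float = 0.40
    min_identity: float = 90.0
    flank_nt: int = 2000
    min_tir_len: int = 20
    max_tir_len: int = 450
    max_mismatch_frac: float = 0.15
    min_intact_aa: int = 300
    consensus_cutoff: int = 10
    ht_factor: float = 1.2
    ht_min_identity: float = 70.0
    distance_model: str = "TN93-CL"
    search_rounds: int = 1
    profile_window: int = 40
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.min_coverage <= 1:
            raise ValueError("min_coverage must be in [0, 1]")
        if self.ht_factor <= 0 or self.evalue_max <= 0:
            raise ValueError("thresholds must be positive")
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError("duplicate species in manifest")


@dataclass
class SummaryTables:
    species_counts: pd.DataFrame
    full_copy_table: pd.DataFrame
    intact_copy_table: pd.DataFrame
    structure_fractions: dict
    ht_involvement: pd.DataFrame


@dataclass
class PipelineResult:
    config: PipelineConfig
    annotations: list
    annotation_table: pd.DataFrame
    references: dict[str, tuple[str, str]]          # species -> (seq, method)
    copy_counts: pd.DataFrame
    clade_assignments: list
    distance_records: list
    ht_summary: Optional[dist_mod.HTSummary]
    insertion_profile: Optional[sitepref.PositionProfile]
    tables: SummaryTables


def annotate_genome(
    genome: dict[str, str],
    queries: list[ProteinQuery],
    config: PipelineConfig,
    species: str,
) -> list[ann_mod.ElementAnnotation]:
    """Search one genome and annotate every non-overlapping locus."""
    hits = iterative_search(genome, queries, rounds=config.search_rounds,
                            evalue_max=config.evalue_max, genome_id=species)
    annotations = []
    for k, hit in enumerate(hits):
        locus = extract_with_flanks(genome, hit, config.flank_nt)
        a = ann_mod.annotate_locus(
            locus, element_id=f"{species}.e{k + 1:04d}", genome_id=species,
            min_tir_len=config.min_tir_len, max_tir_len=config.max_tir_len,
            max_mismatch_frac=config.max_mismatch_frac,
            min_intact_aa=config.min_intact_aa,
        )
        if a.tir is None:
            # keep the search hit footprint for hit-only copies
            a.start, a.end, a.strand = hit.start, hit.end, hit.strand
        a.family = config.family_label
        a.meta["hit"] = hit
        annotations.append(a)
    return annotations


def annotation_dataframe(annotations) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append({
            "element_id": a.element_id, "species": a.genome_id, "contig": a.contig,
            "start": a.start, "end": a.end, "strand": a.strand,
            "length": a.end - a.start, "classification": a.classification,
            "tir_length": a.tir.length if a.tir else 0,
            "tsd_left": a.tsd_left, "tsd_right": a.tsd_right,
            "orf_aa": a.orf_aa, "family": a.family,
        })
    cols = ["element_id", "species", "contig", "start", "end", "strand", "length",
            "classification", "tir_length", "tsd_left", "tsd_right", "orf_aa", "family"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage on the configured inputs; see module docstring."""
    config.validate()
    if not config.genomes:
        logger.warning("empty manifest: nothing to do")
        empty = SummaryTables(pd.DataFrame(), pd.DataFrame(), pd.DataFrame(), {},
                              pd.DataFrame())
        return PipelineResult(config, [], annotation_dataframe([]), {},
                              pd.DataFrame(), [], [], None, None, empty)

    annotations: list[ann_mod.ElementAnnotation] = []
    for species, genome in config.genomes.items():
        annotations.extend(annotate_genome(genome, config.queries, config, species))

    # per-genome family reference and copy counting
    references: dict[str, tuple[str, str]] = {}
    copy_rows = []
    for species, genome in config.genomes.items():
        copies = [
            (a.element_id,
             _element_sequence(genome, a),
             a.classification)
            for a in annotations
            if a.genome_id == species and a.classification != "hit_only"
        ]
        if not copies:
            copies = [
                (a.element_id, _element_sequence(genome, a), a.classification)
                for a in annotations if a.genome_id == species
            ]
        if not copies:
            continue
        ref, method = ann_mod.build_family_reference(copies, config.consensus_cutoff)
        references[species] = (ref, method)
        n, _ = count_copies(genome, ref, config.min_coverage, config.min_identity)
        n_full = sum(1 for a in annotations
                     if a.genome_id == species and a.classification in ("full", "intact"))
        n_intact = sum(1 for a in annotations
                       if a.genome_id == species and a.classification == "intact")
        copy_rows.append({"species": species, "family": config.family_label,
                          "blast_copies": n, "detected": sum(
                              1 for a in annotations if a.genome_id == species),
                          "full": n_full, "intact": n_intact})
    copy_counts = pd.DataFrame(copy_rows)

    # clade assignment of recovered transposases (optional)
    clade_assignments = []
    if config.reference_panel:
        from tefp.phylo import assign_clades

        proteins = {a.element_id: a.orf.protein for a in annotations
                    if a.orf is not None and len(a.orf.protein) >= 100}
        if proteins:
            clade_assignments = assign_clades(
                proteins, config.reference_panel, n_bootstrap=25, seed=config.seed)
            by_id = {c.sequence_id: c.clade for c in clade_assignments}
            for a in annotations:
                if a.element_id in by_id and by_id[a.element_id] != "other":
                    a.family = by_id[a.element_id]

    # distances and HT calls (need host genes and >= 2 species with references)
    distance_records: list[dist_mod.DistanceRecord] = []
    ht_summary = None
    if config.host_genes and len(references) >= 2:
        te_seqs = {sp: ref for sp, (ref, _) in references.items()}
        te_aligned = align(te_seqs)
        host_aligned = {m: align({sp: s for sp, s in seqs.items() if sp in references})
                        for m, seqs in config.host_genes.items()}
        te_records = dist_mod.distance_table(te_aligned, marker=f"TE:{config.family_label}",
                                             model=config.distance_model)
        distance_records.extend(te_records)
        host_records: dict[str, dict[frozenset, dist_mod.DistanceRecord]] = {}
        for marker, seqs in host_aligned.items():
            recs = dist_mod.distance_table(seqs, marker=marker, model=config.distance_model)
            distance_records.extend(recs)
            host_records[marker] = {frozenset((r.species_a, r.species_b)): r for r in recs}
        calls = []
        for r in te_records:
            pair = frozenset((r.species_a, r.species_b))
            h3 = host_records.get("RPL3", {}).get(pair)
            h4 = host_records.get("RPL4", {}).get(pair)
            if h3 is None or h4 is None:
                continue
            ident = pairwise_identity(te_seqs[r.species_a], te_seqs[r.species_b])
            calls.append(dist_mod.call_ht(
                r.distance, h3.distance, h4.distance, ident,
                factor=config.ht_factor, min_identity=config.ht_min_identity,
                species=(r.species_a, r.species_b), family=config.family_label))
        detected = {config.family_label: set(references)}
        ht_summary = dist_mod.aggregate_ht(calls, detected)

    # insertion-site profile over copies with a located, matching TSD
    profile = None
    windows: list[str] = []
    for species, genome in config.genomes.items():
        els = [a for a in annotations
               if a.genome_id == species and a.tir is not None and a.tsd_flag == "match"]
        windows.extend(sitepref.extract_insertion_windows(genome, els,
                                                          config.profile_window))
    if windows:
        profile = sitepref.build_profile(windows)

    ann_df = annotation_dataframe(annotations)
    tables = summarize_counts(ann_df, ht_summary, config.lineage_map)
    return PipelineResult(config, annotations, ann_df, references, copy_counts,
                          clade_assignments, distance_records, ht_summary,
                          profile, tables)


def _element_sequence(genome: dict[str, str], a) -> str:
    seq = genome[a.contig][a.start:a.end]
    if a.strand == "-":
        from tefp.simulate import revcomp
        seq = revcomp(seq)
    return seq


def _bin_label(n: int) -> Optional[str]:
    for lo, hi in COPY_BINS:
        if n >= lo and (hi is None or n <= hi):
            return f">={lo}" if hi is None else f"{lo}-{hi}"
    return None


def summarize_counts(
    annotations: pd.DataFrame,
    ht_summary: Optional[dist_mod.HTSummary],
    lineage_map: dict[str, str],
) -> SummaryTables:
    """Survey-style aggregation of annotation and HT results.

    Produces per-family/lineage species counts, genome-count bins
    {1-9, 10-99, >=100} for full and intact copies with mean +/- SEM of
    per-genome copy numbers, element-length and TIR-length range
    fractions, and HT involvement fractions.  Every percentage is
    recomputed from its numerator and denominator.
    """
    if annotations.empty:
        return SummaryTables(pd.DataFrame(), pd.DataFrame(), pd.DataFrame(), {},
                              ht_summary.involvement if ht_summary else pd.DataFrame())
    species_in = set(annotations["species"])
    missing = sorted(s for s in species_in if lineage_map and s not in lineage_map)
    if missing:
        raise ValueError(f"species missing from lineage map: {missing}")
    df = annotations.copy()
    df["lineage"] = df["species"].map(lineage_map) if lineage_map else "all"

    species_counts = (
        df.groupby(["family", "lineage"])["species"].nunique()
        .rename("n_species").reset_index()
    )

    def copy_table(class_filter) -> pd.DataFrame:
        per_genome = (
            df[df["classification"].isin(class_filter)]
            .groupby(["family", "lineage", "species"]).size().rename("copies")
            .reset_index()
        )
        rows = []
        for (family, lineage), grp in per_genome.groupby(["family", "lineage"]):
            counts = grp["copies"]
            binned = {f"{lo}-{hi}" if hi else f">={lo}":
                      int(((counts >= lo) & ((counts <= hi) if hi else True)).sum())
                      for lo, hi in COPY_BINS}
            mean, sem = mean_sem(counts)
            rows.append({"family": family, "lineage": lineage, **binned,
                         "total": int(len(counts)), "mean": mean, "sem": sem})
        return pd.DataFrame(rows)

    full_tbl = copy_table(("full", "intact"))
    intact_tbl = copy_table(("intact",))

    intact_df = df[df["classification"] == "intact"]
    n_intact = len(intact_df)
    in_len_range = int(((intact_df["length"] >= 1500) & (intact_df["length"] <= 1700)).sum())
    tirs = df[df["tir_length"] > 0]["tir_length"]
    in_tir_range = int(((tirs >= 180) & (tirs <= 300)).sum())
    genomes_total = df["species"].nunique()
    genomes_full = df[df["classification"].isin(("full", "intact"))]["species"].nunique()
    genomes_intact = intact_df["species"].nunique()
    structure = {
        "n_intact_elements": n_intact,
        "intact_length_1500_1700_pct": percentage(in_len_range, n_intact),
        "n_tirs": int(len(tirs)),
        "tir_length_180_300_pct": percentage(in_tir_range, len(tirs)),
        "genomes_detected": genomes_total,
        "genomes_with_full_pct": percentage(genomes_full, genomes_total),
        "genomes_with_intact_pct": percentage(genomes_intact, genomes_total),
    }
    return SummaryTables(
        species_counts=species_counts,
        full_copy_table=full_tbl,
        intact_copy_table=intact_tbl,
        structure_fractions=structure,
        ht_involvement=ht_summary.involvement if ht_summary else pd.DataFrame(),
    )


def format_copy_table(tbl: pd.DataFrame) -> pd.DataFrame:
    """Render mean +/- SEM as text, with "/" where n < 2 as in print tables."""
    if tbl.empty:
        return tbl
    out = tbl.copy()
    out["average"] = [
        "/" if sem is None or (isinstance(sem, float) and np.isnan(sem))
        else f"{mean:.0f} ± {sem:.2f}"
        for mean, sem in zip(out["mean"], out["sem"])
    ]
    return out.drop(columns=["mean", "sem"])
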