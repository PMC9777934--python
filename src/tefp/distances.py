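"""Inter-species genetic distances and the distance-ratio HT test.

Distances are computed on aligned CDS pairs with pairwise deletion (only
columns where both sequences have an unambiguous base count).  Models:

- ``p``      raw mismatch proportion;
- ``JC``     Jukes-Cantor, d = -(3/4) ln(1 - 4p/3);
- ``K2P``    Kimura two-parameter from transition/transversion proportions;
- ``TN93-CL`` Tamura-Nei with composite-likelihood parameter sharing: the
  base frequencies and the split of substitutions into the two transition
  classes and transversions are estimated once from pooled counts over
  every pair in the dataset, then applied to each pair's own mismatch
  proportion (mirroring the maximum-composite-likelihood behaviour of
  distance packages).

A horizontal-transfer event is called for a species pair when the element
distance times the safety factor (default 1.2) is strictly below the
distance of *both* host genes (RPL3 and RPL4); pairs whose element
identity falls below 70% are excluded from the test altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Optional

import numpy as np
import pandas as pd

MODELS = ("p", "JC", "K2P", "TN93-CL")

_PURINES = {"A", "G"}


@dataclass
class DistanceRecord:
    species_a: str
    species_b: str
    marker: str
    model: str
    distance: float          # substitutions/site; NaN when flagged
    sites_used: int
    flag: str = "ok"         # ok | saturated | insufficient


@dataclass
class CompositeParams:
    """Pooled TN93 quantities shared across pairs (composite likelihood)."""

    freqs: dict[str, float]        # gA, gC, gG, gT
    w_ts_pur: float                # fraction of substitutions that are A<->G
    w_ts_pyr: float                # fraction that are C<->T
    w_tv: float                    # fraction that are transversions


def _pair_counts(seq_a: str, seq_b: str) -> dict:
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    ok = np.isin(a, [b"A", b"C", b"G", b"T"]) & np.isin(b, [b"A", b"C", b"G", b"T"])
    a, b = a[ok], b[ok]
    n = len(a)
    diff = a != b
    ts_pur = int((diff & (((a == b"A") & (b == b"G")) | ((a == b"G") & (b == b"A")))).sum())
    ts_pyr = int((diff & (((a == b"C") & (b == b"T")) | ((a == b"T") & (b == b"C")))).sum())
    mism = int(diff.sum())
    base_counts = {bb: int((a == bb.encode()).sum() + (b == bb.encode()).sum())
                   for bb in "ACGT"}
    return {"n": n, "mismatches": mism, "ts_pur": ts_pur, "ts_pyr": ts_pyr,
            "tv": mism - ts_pur - ts_pyr, "base_counts": base_counts}


def estimate_composite_params(aligned_seqs: dict[str, str]) -> CompositeParams:
    """Pool substitution counts over all pairs of a (pre-aligned) set."""
    names = list(aligned_seqs)
    tot = {"n": 0, "mismatches": 0, "ts_pur": 0, "ts_pyr": 0, "tv": 0}
    bases = {b: 0 for b in "ACGT"}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            c = _pair_counts(aligned_seqs[names[i]], aligned_seqs[names[j]])
            for k in tot:
                tot[k] += c[k]
            for b in "ACGT":
                bases[b] += c["base_counts"][b]
    total_bases = sum(bases.values()) or 1
    freqs = {b: bases[b] / total_bases for b in "ACGT"}
    m = tot["mismatches"]
    if m == 0:
        return CompositeParams(freqs=freqs, w_ts_pur=1 / 6, w_ts_pyr=1 / 6, w_tv=2 / 3)
    return CompositeParams(
        freqs=freqs,
        w_ts_pur=tot["ts_pur"] / m,
        w_ts_pyr=tot["ts_pyr"] / m,
        w_tv=tot["tv"] / m,
    )


def _tn93(p1: float, p2: float, q: float, g: dict[str, float]) -> float:
    gA, gC, gG, gT = g["A"], g["C"], g["G"], g["T"]
    gR, gY = gA + gG, gC + gT
    k1 = 2 * gA * gG / gR if gR else 0.0
    k2 = 2 * gT * gC / gY if gY else 0.0
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1 - p1 / k1 - q / (2 * gR) if k1 else 1.0
    w2 = 1 - p2 / k2 - q / (2 * gY) if k2 else 1.0
    w3 = 1 - q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return float("nan")
    d = 0.0
    if k1:
        d -= k1 * log(w1)
    if k2:
        d -= k2 * log(w2)
    d -= k3 * log(w3)
    return d


def pairwise_distance(
    seq_a: str,
    seq_b: str,
    model: str = "JC",
    min_sites: int = 100,
    shared: Optional[CompositeParams] = None,
    species: tuple[str, str] = ("A", "B"),
    marker: str = "",
) -> DistanceRecord:
    """Distance between one aligned pair under the requested model.

    ``TN93-CL`` uses the pooled ``shared`` parameters when given
    (composite-likelihood sharing); without them it falls back to the
    pair's own counts (per-pair TN93).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    c = _pair_counts(seq_a, seq_b)
    n = c["n"]
    rec = DistanceRecord(species_a=species[0], species_b=species[1],
                         marker=marker, model=model, distance=float("nan"),
                         sites_used=n)
    if n < min_sites:
        rec.flag = "insufficient"
        return rec
    p = c["mismatches"] / n
    if model == "p":
        rec.distance = p
        return rec
    if model == "JC":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            rec.flag = "saturated"
            return rec
        rec.distance = -0.75 * log(arg)
        return rec
    if model == "K2P":
        P = (c["ts_pur"] + c["ts_pyr"]) / n
        Q = c["tv"] / n
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            rec.flag = "saturated"
            return rec
        rec.distance = -0.5 * log(a1) - 0.25 * log(a2)
        return rec
    # TN93-CL
    if shared is not None:
        p1, p2, q = p * shared.w_ts_pur, p * shared.w_ts_pyr, p * shared.w_tv
        g = shared.freqs
    else:
        p1, p2, q = c["ts_pur"] / n, c["ts_pyr"] / n, c["tv"] / n
        tb = sum(c["base_counts"].values()) or 1
        g = {b: c["base_counts"][b] / tb for b in "ACGT"}
    d = _tn93(p1, p2, q, g)
    if np.isnan(d):
        rec.flag = "saturated"
        return rec
    rec.distance = d
    return rec


def distance_table(
    aligned_seqs: dict[str, str],
    marker: str,
    model: str = "TN93-CL",
    min_sites: int = 100,
) -> list[DistanceRecord]:
    """All pairwise distances of a species-labelled aligned sequence set.

    For TN93-CL the shared rate parameters are estimated from this whole
    set (dataset-scoped composite likelihood) before per-pair application.
    """
    shared = estimate_composite_params(aligned_seqs) if model == "TN93-CL" else None
    names = list(aligned_seqs)
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            out.append(pairwise_distance(
                aligned_seqs[names[i]], aligned_seqs[names[j]], model=model,
                min_sites=min_sites, shared=shared,
                species=(names[i], names[j]), marker=marker))
    return out


@dataclass
class HTCall:
    species_a: str
    species_b: str
    family: str
    d_te: float
    d_rpl3: float
    d_rpl4: float
    factor: float
    te_identity: float
    decision: str          # HT | vertical | excluded
    reason: str = ""


def call_ht(
    d_te: float,
    d_rpl3: float,
    d_rpl4: float,
    te_identity: float,
    factor: float = 1.2,
    min_identity: float = 70.0,
    species: tuple[str, str] = ("A", "B"),
    family: str = "",
) -> HTCall:
    """Apply the distance-ratio rule to one species pair.

    Excluded when element identity < ``min_identity`` or any distance is
    unavailable; HT iff ``d_te * factor < min(d_rpl3, d_rpl4)`` (strict);
    otherwise vertical.
    """
    call = HTCall(species_a=species[0], species_b=species[1], family=family,
                  d_te=d_te, d_rpl3=d_rpl3, d_rpl4=d_rpl4, factor=factor,
                  te_identity=te_identity, decision="excluded")
    for name, d in (("d_te", d_te), ("d_rpl3", d_rpl3), ("d_rpl4", d_rpl4)):
        if d is not None and not np.isnan(d) and d < 0:
            raise ValueError(f"negative distance {name}={d}")
    if te_identity < min_identity:
        call.reason = f"element identity {te_identity:.1f}% below {min_identity:g}%"
        return call
    if any(d is None or np.isnan(d) for d in (d_te, d_rpl3, d_rpl4)):
        call.reason = "distance unavailable (saturated or insufficient sites)"
        return call
    if d_te * factor < d_rpl3 and d_te * factor < d_rpl4:
        call.decision = "HT"
        call.reason = (f"{d_te:.4f} x {factor:g} < min({d_rpl3:.4f}, {d_rpl4:.4f})")
    else:
        call.decision = "vertical"
        call.reason = "element distance not below both host-gene distances"
    return call


@dataclass
class HTSummary:
    involvement: pd.DataFrame           # per family: involved / detected / fraction
    involved_sets: dict[str, set[str]]  # family -> species involved (Venn input)
    calls: list[HTCall] = field(default_factory=list)


def aggregate_ht(
    ht_calls: list[HTCall],
    detected_species: Optional[dict[str, set[str]]] = None,
) -> HTSummary:
    """Species-level HT involvement per family plus multi-family overlaps.

    A species is involved for a family iff it appears in at least one
    HT-decision pair of that family.  The fraction denominator is the
    set of species in which the family was detected (all species seen in
    the call grid when not supplied).
    """
    families = sorted({c.family for c in ht_calls})
    involved: dict[str, set[str]] = {f: set() for f in families}
    seen: dict[str, set[str]] = {f: set() for f in families}
    for c in ht_calls:
        seen[c.family].update((c.species_a, c.species_b))
        if c.decision == "HT":
            involved[c.family].update((c.species_a, c.species_b))
    rows = []
    for f in families:
        denom = detected_species.get(f, seen[f]) if detected_species else seen[f]
        rows.append({
            "family": f,
            "species_involved": len(involved[f]),
            "species_detected": len(denom),
            "fraction_pct": 100.0 * len(involved[f]) / len(denom) if denom else 0.0,
        })
    return HTSummary(
        involvement=pd.DataFrame(rows).set_index("family") if rows else pd.DataFrame(),
        involved_sets=involved, calls=list(ht_calls),
    )


def records_to_tsv(records: list[DistanceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("species_a\tspecies_b\tmarker\tmodel\tdistance\tsites_used\tflag\n")
        for r in records:
            fh.write(f"{r.species_a}\t{r.species_b}\t{r.marker}\t{r.model}\t"
                     f"{r.distance:.6f}\t{r.sites_used}\t{r.flag}\n")


def calls_to_tsv(calls: list[HTCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("species_a\tspecies_b\tfamily\td_te\td_rpl3\td_rpl4\tfactor\t"
                 "te_identity\tdecision\treason\n")
        for c in calls:
            fh.write(f"{c.species_a}\t{c.species_b}\t{c.family}\t{c.d_te:.6f}\t"
                     f"{c.d_rpl3:.6f}\t{c.d_rpl4:.6f}\t{c.factor:g}\t"
                     f"{c.te_identity:.2f}\t{c.decision}\t{c.reason}\n")
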