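"""Synthetic reference transposase panel for searches and clade assignment.

The panel is a *synthetic stand-in*: the published ZB and SB100X
transposase sequences and the reference exemplars of the other
Tc1/mariner families are not redistributed here, so deterministic
surrogate proteins with the documented lengths (ZB 341 aa, SB100X
340 aa) and a realistic identity structure are generated in code:
~61% identity between each named clade and its "-like" sibling, ~35%
between the ZB and SB sides, and ~25% to the outgroup family exemplars
(DD34E/Tc1, DD36E/IC, DD37E/TRT, DD41D/VS, DD39D/GT, DD34D/mariner and
DD37D/maT, the last serving as outgroup).  The panel is only a
clustering scaffold — clade assignment depends on relative distances,
not on the actual residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# residue index at which the DNA-binding region (through the linker) ends
# and the catalytic DDE region begins, on the panel proteins
DBD_END = 120

_PANEL_SEED = 20221129


@dataclass
class ReferenceEntry:
    id: str
    clade: str          # ZB / ZB-like / SB / SB-like or an outgroup family name
    family: str
    sequence: str
    outgroup: bool = False


def _mutate_protein(seq: str, frac: float, rng: np.random.Generator) -> str:
    out = list(seq)
    n_mut = int(round(frac * len(seq)))
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = [a for a in AA20 if a != out[p]]
        out[p] = choices[rng.integers(0, 19)]
    return "".join(out)


def synthetic_reference_panel() -> dict[str, ReferenceEntry]:
    """Deterministic panel of surrogate transposases (see module docstring)."""
    rng = np.random.default_rng(_PANEL_SEED)
    base = "M" + "".join(AA20[i] for i in rng.integers(0, 20, size=339))
    sb = base                                        # 340 aa
    zb = _mutate_protein(base, 0.65, rng)
    zb = zb + AA20[rng.integers(0, 20)]              # 341 aa
    entries = [
        ReferenceEntry("SB100X_ref", "SB", "DD34E/Tc1", sb),
        ReferenceEntry("SB_ref2", "SB", "DD34E/Tc1", _mutate_protein(sb, 0.08, rng)),
        ReferenceEntry("SBlike_ref", "SB-like", "DD34E/Tc1", _mutate_protein(sb, 0.39, rng)),
        ReferenceEntry("ZB_ref", "ZB", "DD34E/Tc1", zb),
        ReferenceEntry("ZB_ref2", "ZB", "DD34E/Tc1", _mutate_protein(zb, 0.08, rng)),
        ReferenceEntry("ZBlike_ref", "ZB-like", "DD34E/Tc1", _mutate_protein(zb, 0.39, rng)),
    ]
    # second exemplar of each -like clade, close to its clade founder
    sblike = entries[2].sequence
    zblike = entries[5].sequence
    entries.append(ReferenceEntry("SBlike_ref2", "SB-like", "DD34E/Tc1",
                                  _mutate_protein(sblike, 0.08, rng)))
    entries.append(ReferenceEntry("ZBlike_ref2", "ZB-like", "DD34E/Tc1",
                                  _mutate_protein(zblike, 0.08, rng)))
    outgroups = [
        ("Tc1_DD34E", "DD34E/Tc1"),
        ("IC_DD36E", "DD36E/IC"),
        ("TRT_DD37E", "DD37E/TRT"),
        ("VS_DD41D", "DD41D/VS"),
        ("GT_DD39D", "DD39D/GT"),
        ("mariner_DD34D", "DD34D/mariner"),
        ("maT_DD37D", "DD37D/maT"),
    ]
    for name, fam in outgroups:
        entries.append(ReferenceEntry(
            name, fam, fam, _mutate_protein(base, 0.75, rng),
            outgroup=(fam == "DD37D/maT")))
    return {e.id: e for e in entries}


def default_search_queries():
    """The ZB and SB surrogate transposases as protein search queries."""
    from tefp.search import ProteinQuery

    panel = synthetic_reference_panel()
    return [
        ProteinQuery("ZB_ref", "ZB", panel["ZB_ref"].sequence),
        ProteinQuery("SB100X_ref", "SB", panel["SB100X_ref"].sequence),
    ]


def panel_for_assignment() -> dict[str, tuple[str, str]]:
    """Panel in the (clade, protein) form the clade assigner expects."""
    return {rid: (e.clade, e.sequence) for rid, e in synthetic_reference_panel().items()}
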