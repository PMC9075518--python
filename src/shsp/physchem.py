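"""Sequence-derived physicochemical properties.

Length, average molecular weight, theoretical isoelectric point (pI) and the
grand average of hydropathicity (GRAVY, Kyte–Doolittle) are computed for
whole proteins and for their α-crystallin-domain (ACD) cores.  These four
quantities separate the sHsp subclusters surprisingly well: the smallest and
most acidic proteins, the large basic ones, and the hydrophilic mid-sized
mitochondrial-type groups each occupy a distinct box in (length, pI, GRAVY)
space.

Conventions for the ambiguous residue X: excluded from the GRAVY average
and from the charge model, counted in length, and assigned the mean residue
mass for molecular weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Kyte & Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Average (isotope-abundance-weighted) residue masses, Da
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153
MEAN_RESIDUE_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)

# pKa tables: (n_term, c_term, {sidechain: (pKa, sign)})
# sign +1 = protonated form charged (bases), -1 = deprotonated form charged (acids)
PKA_TABLES: dict[str, dict] = {
    # EMBOSS-style values used by the Sequence Manipulation Suite family of
    # pI calculators.
    "sms": {
        "n_term": 8.6,
        "c_term": 3.6,
        "side": {
            "K": (10.8, +1), "R": (12.5, +1), "H": (6.5, +1),
            "D": (3.9, -1), "E": (4.1, -1), "C": (8.5, -1), "Y": (10.1, -1),
        },
    },
    "lehninger": {
        "n_term": 9.69,
        "c_term": 2.34,
        "side": {
            "K": (10.53, +1), "R": (12.48, +1), "H": (6.0, +1),
            "D": (3.86, -1), "E": (4.25, -1), "C": (8.33, -1), "Y": (10.07, -1),
        },
    },
}


@dataclass
class PhyschemProfile:
    """Per-protein physicochemical profile (whole chain and ACD core)."""

    protein_id: str
    length_aa: int
    mw_kda: float
    pi_protein: float
    gravy_protein: float
    pi_acd: float | None = None
    gravy_acd: float | None = None
    complete: bool = True


def gravy(seq: str) -> float:
    """Grand average of hydropathicity: mean Kyte–Doolittle value per residue.

    X residues are excluded from the average.
    """
    if not seq:
        raise ValueError("empty sequence")
    vals = [KYTE_DOOLITTLE[a] for a in seq if a != "X"]
    if not vals:
        raise ValueError("sequence has no scored residues (all X)")
    return sum(vals) / len(vals)


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water."""
    if not seq:
        raise ValueError("empty sequence")
    return (
        sum(RESIDUE_MASS.get(a, MEAN_RESIDUE_MASS) for a in seq) + WATER_MASS
    )


def net_charge(seq: str, ph: float, pka_table: str = "sms") -> float:
    """Henderson–Hasselbalch net charge at a given pH.

    Termini always contribute; side chains of D, E, C, Y (acidic) and
    K, R, H (basic) contribute per occurrence; X is ignored.
    """
    t = PKA_TABLES[pka_table]
    charge = 1.0 / (1.0 + 10 ** (ph - t["n_term"]))
    charge -= 1.0 / (1.0 + 10 ** (t["c_term"] - ph))
    for aa, (pka, sign) in t["side"].items():
        n = seq.count(aa)
        if not n:
            continue
        if sign > 0:
            charge += n / (1.0 + 10 ** (ph - pka))
        else:
            charge -= n / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(seq: str, pka_table: str = "sms", tol: float = 1e-4) -> float:
    """pH of zero net charge, solved by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so bisection converges to the
    unique root; iteration stops when |charge| < ``tol``.
    """
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(100):
        ph = (lo + hi) / 2.0
        c = net_charge(seq, ph, pka_table)
        if abs(c) < tol:
            break
        if c > 0:
            lo = ph
        else:
            hi = ph
    return ph


def profile_protein(
    protein_id: str,
    seq: str,
    acd_core: str | None = None,
    complete: bool = True,
    pka_table: str = "sms",
) -> PhyschemProfile:
    """Build the full physicochemical profile for one protein."""
    return PhyschemProfile(
        protein_id=protein_id,
        length_aa=len(seq),
        mw_kda=molecular_weight(seq) / 1000.0,
        pi_protein=isoelectric_point(seq, pka_table),
        gravy_protein=gravy(seq),
        pi_acd=isoelectric_point(acd_core, pka_table) if acd_core else None,
        gravy_acd=gravy(acd_core) if acd_core else None,
        complete=complete,
    )


METRICS = ("mw_kda", "length_aa", "pi_protein", "pi_acd", "gravy_protein", "gravy_acd")


@dataclass
class GroupSummary:
    """Interquartile summary of one group's physicochemical metrics.

    Only complete sequences are counted; quartiles use linear interpolation
    between order statistics.  ``iqr[metric] = (Q1, Q3)`` or None for an
    empty group / all-missing metric.
    """

    group: str
    n: int
    iqr: dict[str, tuple[float, float] | None]


def summarize_groups(
    profiles: list[PhyschemProfile], labels: dict[str, str]
) -> list[GroupSummary]:
    """Per-group interquartile ranges over complete sequences only.

    ``labels`` maps protein_id -> group label and must cover every profile.
    """
    missing = [p.protein_id for p in profiles if p.protein_id not in labels]
    if missing:
        raise ValueError(f"profiles without a group label: {missing}")
    groups: dict[str, list[PhyschemProfile]] = {}
    for p in profiles:
        groups.setdefault(labels[p.protein_id], []).append(p)
    out = []
    for g in sorted(groups):
        members = [p for p in groups[g] if p.complete]
        iqr: dict[str, tuple[float, float] | None] = {}
        for m in METRICS:
            vals = [getattr(p, m) for p in members if getattr(p, m) is not None]
            if vals:
                q1, q3 = np.percentile(vals, [25, 75], method="linear")
                iqr[m] = (float(q1), float(q3))
            else:
                iqr[m] = None
        out.append(GroupSummary(group=g, n=len(members), iqr=iqr))
    return out
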