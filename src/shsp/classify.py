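"""Rule-based subcluster assignment and NLS-like motif scanning.

Monomeric sHsps fall into five subclusters. Two are cleanly separated by
size and charge alone: A1 (tiny, very acidic, short-L57 core, no conserved
arginine in β7) and A2 (large, strongly basic).  The three Cluster-B groups
are distinguished by signature motifs inside specific zones of the detected
domain: the lysine-rich β5-L57 motif and/or serine-rich L34 motif of B1,
and the two B3 signatures (β3-L34 L-D-V-X-X-F-X-P-E-E, β5-L57
G-K-H-E-E-(R/K)).  B2 is the residual class: a detected ACD matching no
other rule — mirroring the weak B2/B3 separation seen in tree-based
analyses.  Rules are evaluated in precedence order A1 → A2 → B1 → B3 → B2.

Numeric cut-offs sit just outside the published interquartile boxes (e.g.
A2 requires length ≥ 300 against a printed 359–381 range) to absorb
dispersion beyond the IQR; they are plain module-level constants that can
be overridden per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .detect import AcdHit
from .motifs import (
    B1_ERICH,
    B1_FXSES,
    B1_KRICH,
    B3_GKHEE,
    B3_LDV,
    B7_R,
    NLS_VRKP,
    scan_motif,
)
from .physchem import PhyschemProfile
from .seqio import ProteinRecord

#: editable classifier cut-offs (midpoints just outside the Table-derived IQRs)
DEFAULT_CUTOFFS = {
    "a1_max_core_len": 69,
    "a1_max_protein_len": 130,
    "a1_max_pi": 4.8,
    "a2_min_protein_len": 300,
    "a2_min_pi": 8.5,
}

LABELS = ("A1", "A2", "B1", "B2", "B3", "unassigned")


@dataclass
class ClusterAssignment:
    protein_id: str
    label: str
    fired_rules: list[tuple[str, tuple[int, int] | None]] = field(default_factory=list)
    confidence: float = 0.0

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"bad label {self.label!r}")
        if self.label != "unassigned" and not self.fired_rules:
            raise ValueError("assigned label requires at least one fired rule")


def _zone(hit: AcdHit, *segments: str) -> tuple[int, int]:
    spans = [hit.anchors[s] for s in segments]
    return min(s for s, _ in spans), max(e for _, e in spans)


def _match_in_zone(seq: str, pattern, zone: tuple[int, int]):
    """First motif match fully inside [zone): absolute coordinates or None."""
    a, b = zone
    for s, e in scan_motif(seq[a:b], pattern):
        return (a + s, a + e)
    return None


def assign_cluster(
    protein: ProteinRecord,
    hit: AcdHit,
    profile: PhyschemProfile,
    cutoffs: dict | None = None,
) -> ClusterAssignment:
    """Assign a monomeric sHsp to a subcluster.

    ``hit`` must be the protein's single ACD; proteins with a dimeric (or
    multi-domain) architecture are rejected — the classifier codifies the
    monomeric subcluster structure only.
    """
    if hit.rank != "only":
        raise ValueError(
            f"{protein.id}: monomeric classifier only (hit rank {hit.rank!r})"
        )
    c = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        c.update(cutoffs)
    seq = protein.seq
    core_len = hit.end - hit.start

    # A1: short core, tiny acidic protein, no conserved R in β7
    b7_has_r = _match_in_zone(seq, B7_R, hit.anchors["b7"]) is not None
    a1_conds = {
        "core_len<=%d" % c["a1_max_core_len"]: core_len <= c["a1_max_core_len"],
        "protein_len<%d" % c["a1_max_protein_len"]: profile.length_aa < c["a1_max_protein_len"],
        "pi<%.1f" % c["a1_max_pi"]: profile.pi_protein < c["a1_max_pi"],
        "b7_R_absent": not b7_has_r,
    }
    if all(a1_conds.values()):
        return ClusterAssignment(
            protein.id, "A1",
            fired_rules=[(name, None) for name in a1_conds],
            confidence=1.0,
        )

    # A2: large and basic
    a2_conds = {
        "protein_len>=%d" % c["a2_min_protein_len"]: profile.length_aa >= c["a2_min_protein_len"],
        "pi>=%.1f" % c["a2_min_pi"]: profile.pi_protein >= c["a2_min_pi"],
    }
    if all(a2_conds.values()):
        return ClusterAssignment(
            protein.id, "A2",
            fired_rules=[(name, None) for name in a2_conds],
            confidence=1.0,
        )

    # B1: K-rich β5-L57 motif or serine-rich L34 motif; acidic-rich L57-β7
    # stretch corroborates but is not required
    b1_hits = []
    m = _match_in_zone(seq, B1_KRICH, _zone(hit, "b5", "L57"))
    if m:
        b1_hits.append((B1_KRICH.name, m))
    m = _match_in_zone(seq, B1_FXSES, _zone(hit, "L34"))
    if m:
        b1_hits.append((B1_FXSES.name, m))
    if b1_hits:
        m = _match_in_zone(seq, B1_ERICH, _zone(hit, "L57", "b7"))
        if m:
            b1_hits.append((B1_ERICH.name, m))
        return ClusterAssignment(
            protein.id, "B1", fired_rules=b1_hits,
            confidence=len(b1_hits) / 3.0,
        )

    # B3: either signature motif
    b3_hits = []
    m = _match_in_zone(seq, B3_LDV, _zone(hit, "b3", "L34"))
    if m:
        b3_hits.append((B3_LDV.name, m))
    m = _match_in_zone(seq, B3_GKHEE, _zone(hit, "b5", "L57"))
    if m:
        b3_hits.append((B3_GKHEE.name, m))
    if b3_hits:
        return ClusterAssignment(
            protein.id, "B3", fired_rules=b3_hits,
            confidence=len(b3_hits) / 2.0,
        )

    # B2: the residual class — an ACD was detected but no rule fired
    return ClusterAssignment(
        protein.id, "B2", fired_rules=[("acd_detected_no_signature", None)],
        confidence=1.0,
    )


# ---------------------------------------------------------------------------
# NLS-like motifs

@dataclass
class NlsCandidate:
    protein_id: str
    start: int
    end: int
    kind: str  # "VxP-type" | "basic-rich"
    basic_count: int

    def __post_init__(self):
        if self.kind == "basic-rich" and self.basic_count < 4:
            raise ValueError("basic-rich NLS requires >=4 K/R")


def scan_nls(protein: ProteinRecord, hit: AcdHit | None = None) -> list[NlsCandidate]:
    """Report NLS-like motifs: V-(R/K)-P inside the β4-L45 zone of the
    detected domain, and any maximal region whose 6-residue windows hold at
    least 4 K/R residues (classical basic NLS).
    """
    seq = protein.seq
    out: list[NlsCandidate] = []
    if hit is not None:
        zone = _zone(hit, "b4", "L45")
        m = _match_in_zone(seq, NLS_VRKP, zone)
        if m:
            out.append(NlsCandidate(protein.id, m[0], m[1], "VxP-type", 0))

    # basic-rich: merge overlapping qualifying 6-windows into maximal regions
    w = 6
    region: list[int] | None = None
    for i in range(len(seq) - w + 1):
        window = seq[i : i + w]
        if sum(window.count(a) for a in "KR") >= 4:
            if region and i <= region[1]:
                region[1] = i + w
            else:
                if region:
                    out.append(_basic_candidate(protein.id, seq, region))
                region = [i, i + w]
    if region:
        out.append(_basic_candidate(protein.id, seq, region))
    out.sort(key=lambda n: n.start)
    return out


def _basic_candidate(pid: str, seq: str, region: list[int]) -> NlsCandidate:
    a, b = region
    frag = seq[a:b]
    return NlsCandidate(pid, a, b, "basic-rich", sum(frag.count(x) for x in "KR"))
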