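"""Motif-anchored detection of α-crystallin domains (ACDs).

A candidate domain must satisfy three conditions:

(a) a β9-motif match (L-X-(V/T)-(E/K)-(A/L)-(P/K)) fixing the downstream
    end of the core,
(b) at least one of the conserved L78 doublets (L-P or V-D) at its implied
    position upstream of β9, and
(c) a PSSM score over the implied β3→β9 window at or above the detection
    threshold (calibrated on shuffled decoys).

Because L78, β8, L89 and β9 are modelled at fixed widths, the β9 anchor
pins the whole β7→β9 block; the upstream half of the domain is then placed
by maximizing the PSSM score over the allowed lengths of the three variable
loops (L34, L45, L57).  Loop residues beyond the profiled width are
unscored; skipped loop columns carry no gap penalty (the seed alignment
already encodes the short-loop forms as gaps).

Multiple candidate domains in one protein are selected greedily by score
(ties: leftmost) without overlap; one surviving hit makes the protein
"monomeric", two tandem hits "dimeric".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import AcdModel, build_default_model, default_threshold
from .motifs import B9_MOTIF, L78_LP, L78_VD, scan_motif
from .seqio import ProteinRecord
from .templates import (
    LOOP_SPANS,
    MAX_CORE_LEN,
    MIN_CORE_LEN,
    MODEL_WIDTHS,
    SEGMENT_ORDER,
    STRAND_SEGMENTS,
)


@dataclass
class AcdHit:
    """One detected β3→β9 core."""

    protein_id: str
    start: int
    end: int
    score: float
    anchors: dict[str, tuple[int, int]] = field(default_factory=dict)
    rank: str = "only"  # upstream | downstream | only

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"hit {self.protein_id}: start >= end")


@dataclass
class Architecture:
    """Domain architecture of a protein: number of ACDs and its label."""

    protein_id: str
    n_acd: int
    label: str  # none | monomeric | dimeric | multi

    @staticmethod
    def from_count(protein_id: str, n: int) -> "Architecture":
        label = {0: "none", 1: "monomeric", 2: "dimeric"}.get(n, "multi")
        return Architecture(protein_id=protein_id, n_acd=n, label=label)


# fixed distances from the β9 start backwards (L78, β8, L89 have fixed width)
_B9_W = MODEL_WIDTHS["b9"]
_L89_W = MODEL_WIDTHS["L89"]
_B8_W = MODEL_WIDTHS["b8"]
_L78_W = MODEL_WIDTHS["L78"]
_B7_W = MODEL_WIDTHS["b7"]


def _segment_cols(model: AcdModel, seg: str) -> tuple[int, int]:
    return model.anchor_offsets[seg]


def _score_block(model: AcdModel, seq: str, pos: int, seg: str) -> float:
    """Score a fixed-width strand block starting at ``pos``."""
    c0, c1 = _segment_cols(model, seg)
    return sum(model.column_score(c0 + k, seq[pos + k]) for k in range(c1 - c0))


def _score_loop(model: AcdModel, seq: str, pos: int, length: int, seg: str) -> float:
    """Score a loop of observed ``length`` onto its model columns.

    A loop shorter (or longer) than the profiled width is allowed one
    internal gap: the score is maximized over split points, with the left
    part anchored to the leftmost columns and the right part to the
    rightmost.  For a loop exactly at profile width every split yields the
    same (gapless) score.
    """
    c0, c1 = _segment_cols(model, seg)
    width = c1 - c0
    m = min(length, width)
    if m == 0:
        return 0.0
    left = [0.0]
    for i in range(m):
        left.append(left[-1] + model.column_score(c0 + i, seq[pos + i]))
    right = [0.0]
    for j in range(1, m + 1):
        right.append(
            right[-1] + model.column_score(c1 - j, seq[pos + length - j])
        )
    return max(left[g] + right[m - g] for g in range(m + 1))


def _candidates_at_b9(model: AcdModel, seq: str, p9: int):
    """Best-scoring core layout for a β9 anchor at ``p9`` (or None).

    Enforces conditions (b) (an L78 doublet at its implied position) and
    the [60, 85] core-length band; maximizes PSSM score over the variable
    loop lengths.
    """
    b7_end = p9 - _L89_W - _B8_W - _L78_W
    b7_start = b7_end - _B7_W
    if b7_start < 0:
        return None
    l78_start = b7_end
    l78_seq = seq[l78_start : l78_start + _L78_W]
    if not (scan_motif(l78_seq, L78_LP) or scan_motif(l78_seq, L78_VD)):
        return None

    # downstream fixed block (β7, L78, β8, L89, β9)
    fixed_score = (
        _score_block(model, seq, b7_start, "b7")
        + _score_loop(model, seq, l78_start, _L78_W, "L78")
        + _score_block(model, seq, l78_start + _L78_W, "b8")
        + _score_loop(model, seq, l78_start + _L78_W + _B8_W, _L89_W, "L89")
        + _score_block(model, seq, p9, "b9")
    )

    b3_w, b4_w, b5_w = (MODEL_WIDTHS[s] for s in ("b3", "b4", "b5"))
    best = None
    # nested enumeration: each inner quantity depends only on the loop
    # lengths chosen so far, so partial scores are computed once per prefix
    for l57 in range(*_span("L57")):
        b5_start = b7_start - l57 - b5_w
        if b5_start < 0:
            continue
        s57 = (
            _score_loop(model, seq, b5_start + b5_w, l57, "L57")
            + _score_block(model, seq, b5_start, "b5")
        )
        for l45 in range(*_span("L45")):
            b4_start = b5_start - l45 - b4_w
            if b4_start < 0:
                continue
            s45 = (
                _score_loop(model, seq, b4_start + b4_w, l45, "L45")
                + _score_block(model, seq, b4_start, "b4")
            )
            for l34 in range(*_span("L34")):
                b3_start = b4_start - l34 - b3_w
                if b3_start < 0:
                    continue
                core_len = p9 + _B9_W - b3_start
                if not (MIN_CORE_LEN <= core_len <= MAX_CORE_LEN):
                    continue
                s = (
                    fixed_score + s57 + s45
                    + _score_loop(model, seq, b3_start + b3_w, l34, "L34")
                    + _score_block(model, seq, b3_start, "b3")
                )
                if best is None or s > best[0] + 1e-12:
                    anchors = {
                        "b3": (b3_start, b3_start + b3_w),
                        "L34": (b3_start + b3_w, b4_start),
                        "b4": (b4_start, b4_start + b4_w),
                        "L45": (b4_start + b4_w, b5_start),
                        "b5": (b5_start, b5_start + b5_w),
                        "L57": (b5_start + b5_w, b7_start),
                        "b7": (b7_start, b7_end),
                        "L78": (l78_start, l78_start + _L78_W),
                        "b8": (l78_start + _L78_W, l78_start + _L78_W + _B8_W),
                        "L89": (p9 - _L89_W, p9),
                        "b9": (p9, p9 + _B9_W),
                    }
                    best = (s, b3_start, p9 + _B9_W, anchors)
    return best


def _span(seg: str) -> tuple[int, int]:
    lo, hi = LOOP_SPANS[seg]
    return lo, hi + 1


def detect_acds(
    protein: ProteinRecord,
    model: AcdModel | None = None,
    threshold_bits: float | None = None,
) -> tuple[list[AcdHit], Architecture]:
    """Detect ACDs in one protein and derive its architecture.

    Returns the surviving (non-overlapping, threshold-passing) hits sorted
    by start coordinate, with ranks assigned, plus the Architecture record.
    A protein with no hit is a valid outcome (label "none").
    """
    if model is None:
        model = build_default_model()
    if threshold_bits is None:
        threshold_bits = default_threshold()
    if not (threshold_bits == threshold_bits and abs(threshold_bits) != float("inf")):
        raise ValueError("threshold_bits must be finite")

    seq = protein.seq
    candidates = []
    for p9, _ in scan_motif(seq, B9_MOTIF):
        got = _candidates_at_b9(model, seq, p9)
        if got is None:
            continue
        score, start, end, anchors = got
        if score >= threshold_bits:
            candidates.append(AcdHit(protein.id, start, end, score, anchors))

    # greedy selection: higher score wins, equal scores -> leftmost
    candidates.sort(key=lambda h: (-h.score, h.start))
    chosen: list[AcdHit] = []
    for h in candidates:
        if all(h.end <= c.start or h.start >= c.end for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.start)

    if len(chosen) == 1:
        chosen[0].rank = "only"
    elif len(chosen) >= 2:
        chosen[0].rank = "upstream"
        chosen[-1].rank = "downstream"
        for h in chosen[1:-1]:
            h.rank = "internal"
    return chosen, Architecture.from_count(protein.id, len(chosen))


def trim_core(hit: AcdHit, protein: ProteinRecord) -> str:
    """Extract the β3→β9 core substring for a hit.

    Validates that the hit belongs to the protein and lies in range, and
    that the core length is inside the modelled [60, 85] band.
    """
    if hit.protein_id != protein.id:
        raise ValueError(
            f"hit belongs to {hit.protein_id!r}, not {protein.id!r}"
        )
    if hit.start < 0 or hit.end > len(protein.seq):
        raise ValueError(f"hit [{hit.start},{hit.end}) out of range for {protein.id}")
    core = protein.seq[hit.start : hit.end]
    if not (MIN_CORE_LEN <= len(core) <= MAX_CORE_LEN):
        raise ValueError(f"core length {len(core)} outside [{MIN_CORE_LEN},{MAX_CORE_LEN}]")
    return core
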