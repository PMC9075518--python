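"""Anchored multiple alignment of ACD cores.

Rather than a generic progressive MSA, cores are aligned *to the model
column space*: each core is re-anchored with the detection engine (β-strand
blocks map one-to-one onto model strand columns) and its loop segments are
placed within the loop column blocks by affine-gap pairwise alignment
against the model's loop consensus (BLOSUM62, gap open 10, extend 1).
Loops longer than a model block get insertion columns, which are added to
the shared column space so the result stays rectangular; every column
carries the label of the segment it belongs to.

This mirrors the practice of structure-guided manual alignment: strands are
trusted anchors, variability is confined to loops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .detect import detect_acds
from .model import AcdModel, build_default_model
from .seqio import ProteinRecord
from .templates import MODEL_WIDTHS, SEGMENT_ORDER, STRAND_SEGMENTS


@dataclass
class AnchoredAlignment:
    """A rectangular core alignment with per-column segment labels."""

    ids: list[str]
    rows: list[str]
    column_labels: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment not rectangular")
        if self.rows and len(self.column_labels) != len(self.rows[0]):
            raise ValueError("column labels do not match width")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


class UnalignableCoreError(ValueError):
    pass


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -10.0
    a.extend_gap_score = -1.0
    a.mode = "global"
    return a


def _loop_consensus(model: AcdModel, seg: str) -> str:
    c0, c1 = model.anchor_offsets[seg]
    return model.consensus[c0:c1]


def _align_loop(loop: str, consensus: str, aligner) -> list[str | None]:
    """Place loop residues onto consensus columns.

    Returns a list over loop residues: the consensus column index each
    residue occupies, or None for an insertion after the previous column.
    """
    if not loop:
        return []
    if not consensus:
        return [None] * len(loop)
    aln = aligner.align(loop, consensus)[0]
    placement: list[int | None] = [None] * len(loop)
    for (ls, le), (cs, ce) in zip(*aln.aligned):
        for k in range(le - ls):
            placement[ls + k] = cs + k
    return placement


def align_cores(
    cores: list[tuple[str, str]],
    model: AcdModel | None = None,
) -> AnchoredAlignment:
    """Anchored MSA of (id, core) pairs in the model column space.

    Cores that cannot be re-anchored (fewer than two strand anchors found,
    i.e. the detection engine finds no domain in the bare core) are excluded
    with a warning rather than failing the whole alignment.
    """
    if len(cores) < 2:
        raise ValueError("need at least two cores to align")
    if model is None:
        model = build_default_model()
    aligner = _aligner()

    placed = []  # (id, {seg: residues}, {seg: placement})
    for cid, core in cores:
        # re-anchor with no score gate: geometry only
        hits, _ = detect_acds(ProteinRecord(cid, core), model, threshold_bits=-1e9)
        hit = next((h for h in hits if h.start == 0 and h.end == len(core)), None)
        if hit is None:
            warnings.warn(f"core {cid!r} unalignable (anchors not found); excluded")
            continue
        segs = {}
        place = {}
        for seg in SEGMENT_ORDER:
            a, b = hit.anchors[seg]
            piece = core[a:b]
            segs[seg] = piece
            if seg not in STRAND_SEGMENTS:
                place[seg] = _align_loop(piece, _loop_consensus(model, seg), aligner)
        placed.append((cid, segs, place))

    if len(placed) < 2:
        raise UnalignableCoreError("fewer than two alignable cores")

    # per-loop insertion budget: max insertions after each consensus column
    ins_after: dict[str, dict[int, int]] = {}
    for seg in SEGMENT_ORDER:
        if seg in STRAND_SEGMENTS:
            continue
        width = MODEL_WIDTHS[seg]
        budget = {k: 0 for k in range(-1, width)}
        for _, _, place in placed:
            run_after = -1
            run = 0
            counts = {k: 0 for k in range(-1, width)}
            last_col = -1
            for col in place[seg]:
                if col is None:
                    counts[last_col] += 1
                else:
                    last_col = col
            for k, v in counts.items():
                budget[k] = max(budget[k], v)
        ins_after[seg] = budget

    # build rows segment by segment
    ids, rows = [], []
    labels: list[str] = []
    first = True
    for cid, segs, place in placed:
        row = []
        for seg in SEGMENT_ORDER:
            if seg in STRAND_SEGMENTS:
                row.append(segs[seg])
                if first:
                    labels.extend([seg] * MODEL_WIDTHS[seg])
                continue
            width = MODEL_WIDTHS[seg]
            budget = ins_after[seg]
            # cells: for each slot (-1 insertions, col0, col0 insertions, ...)
            cells: dict[tuple[int, int], str] = {}
            last_col = -1
            ins_count = {k: 0 for k in budget}
            for aa, col in zip(segs[seg], place[seg]):
                if col is None:
                    cells[(last_col, 1 + ins_count[last_col])] = aa
                    ins_count[last_col] += 1
                else:
                    cells[(col, 0)] = aa
                    last_col = col
            for col in range(-1, width):
                if col >= 0:
                    row.append(cells.get((col, 0), "-"))
                    if first:
                        labels.append(seg)
                for k in range(budget[col]):
                    row.append(cells.get((col, 1 + k), "-"))
                    if first:
                        labels.append(seg)
        ids.append(cid)
        rows.append("".join(row))
        first = False

    # drop columns that are gap in every row (e.g. unused loop width)
    keep = [j for j in range(len(labels)) if any(r[j] != "-" for r in rows)]
    rows = ["".join(r[j] for j in keep) for r in rows]
    labels = [labels[j] for j in keep]
    return AnchoredAlignment(ids=ids, rows=rows, column_labels=labels)
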