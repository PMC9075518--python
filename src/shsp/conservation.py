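"""Per-column conservation statistics of an alignment (logo data).

Information content of a column is ``log2(20) − H`` where ``H`` is the
Shannon entropy of the residue frequencies with gaps excluded; the gap
fraction is reported separately.  The consensus residue is the most
frequent residue when its (gap-free) frequency reaches the threshold
``t`` (default 0.5, the usual "50% conservation" convention), else ``x``.
The output doubles as a sequence-logo matrix: per-column residue
frequencies scaled by information content.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

MAX_IC = math.log2(20)


@dataclass
class ColumnStats:
    index: int
    counts: dict[str, int]
    gap_fraction: float
    information: float | None  # None for an all-gap column
    consensus: str

    @property
    def frequencies(self) -> dict[str, float]:
        n = sum(self.counts.values())
        return {a: c / n for a, c in self.counts.items()} if n else {}


def column_stats(rows: list[str], t: float = 0.5) -> list[ColumnStats]:
    """Column statistics for a rectangular alignment (residues + ``-``).

    ``rows`` may also be an AnchoredAlignment's ``rows`` attribute.  X is
    treated like a gap for frequency purposes (unknown residue carries no
    conservation signal).
    """
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment is not rectangular")
    n = len(rows)
    out = []
    for j in range(width):
        col = [r[j] for r in rows]
        counts = Counter(a for a in col if a not in "-X")
        n_res = sum(counts.values())
        gap_fraction = (n - n_res) / n
        if n_res == 0:
            out.append(ColumnStats(j, {}, 1.0, None, "x"))
            continue
        ent = -sum((c / n_res) * math.log2(c / n_res) for c in counts.values())
        ic = MAX_IC - ent
        # strictly above threshold: an exact 50/50 split has no consensus
        top, top_c = max(sorted(counts.items()), key=lambda kv: kv[1])
        consensus = top if top_c / n_res > t else "x"
        out.append(ColumnStats(j, dict(counts), gap_fraction, ic, consensus))
    return out


def consensus_string(stats: list[ColumnStats]) -> str:
    return "".join(s.consensus for s in stats)
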