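"""Degenerate sequence motifs of the α-crystallin domain (ACD).

A motif is an ordered list of tokens, each a fixed residue, an alternative
set such as (R/K), or the wildcard X.  The registry below collects the
diagnostic ACD motifs used throughout the pipeline: the universally
conserved L78 doublets L-P and V-D and the β9 motif that anchor domain
detection, plus the subcluster signatures (lysine-rich β5-L57 motif of B1,
the serine-rich L34 motif, the B3 signatures, the V-(R/K)-P nuclear
localization motif of A1, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import AMINO_ACIDS

REGIONS = (
    "L34", "b3-L34", "b4-L45", "b5-L57", "L57-b7", "b7", "L78", "L89", "b8", "b9",
)


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif: tokens are frozensets of allowed residues.

    The wildcard X is represented as the full 20-letter alphabet.  ``region``
    records which part of the ACD the motif is diagnostic for (used when a
    motif must fall inside the corresponding zone of a detected domain).
    """

    name: str
    tokens: tuple[frozenset, ...]
    region: str | None = None

    def __post_init__(self):
        if not self.tokens:
            raise ValueError(f"motif {self.name!r}: empty token list")
        for t in self.tokens:
            if not t or not t <= AMINO_ACIDS:
                raise ValueError(f"motif {self.name!r}: bad token {sorted(t)!r}")
        if self.region is not None and self.region not in REGIONS:
            raise ValueError(f"motif {self.name!r}: unknown region {self.region!r}")

    def __len__(self) -> int:
        return len(self.tokens)


def motif(name: str, spec: str, region: str | None = None) -> MotifPattern:
    """Build a MotifPattern from compact notation, e.g. ``"V-(R/K)-P"``.

    Tokens are separated by ``-``; alternatives in parentheses separated by
    ``/``; ``X`` is a wildcard.
    """
    tokens = []
    for tok in spec.split("-"):
        tok = tok.strip()
        if tok.startswith("(") and tok.endswith(")"):
            tokens.append(frozenset(tok[1:-1].split("/")))
        elif tok == "X":
            tokens.append(frozenset(AMINO_ACIDS))
        else:
            if len(tok) != 1:
                raise ValueError(f"bad motif token {tok!r} in {spec!r}")
            tokens.append(frozenset(tok))
    return MotifPattern(name=name, tokens=tuple(tokens), region=region)


def scan_motif(seq: str, pattern: MotifPattern) -> list[tuple[int, int]]:
    """All (start, end) windows of ``seq`` matching ``pattern``, left to right.

    An empty sequence yields an empty list.  X in the sequence matches only
    wildcard tokens (an unknown residue cannot be claimed to match a
    constrained position).
    """
    w = len(pattern)
    hits = []
    for i in range(len(seq) - w + 1):
        ok = True
        for j, tok in enumerate(pattern.tokens):
            a = seq[i + j]
            if a == "X":
                if len(tok) < len(AMINO_ACIDS):
                    ok = False
                    break
            elif a not in tok:
                ok = False
                break
        if ok:
            hits.append((i, i + w))
    return hits


# ---------------------------------------------------------------------------
# Registry: universally conserved ACD motifs and subcluster signatures.

# Universal anchors (all subclusters)
L78_LP = motif("L78_LP", "L-P", region="L78")
L78_VD = motif("L78_VD", "V-D", region="L78")
L89_G = motif("L89_G", "G", region="L89")
B9_MOTIF = motif("beta9", "L-X-(V/T)-(E/K)-(A/L)-(P/K)", region="b9")
B4_VK = motif("beta4_VK", "V-K", region="b4-L45")

# Subcluster signatures
NLS_VRKP = motif("NLS_VxP", "V-(R/K)-P", region="b4-L45")          # A1 (NLS-like)
B1_KRICH = motif("B1_Krich", "K-K-K-X-K-K", region="b5-L57")       # B1
B1_ERICH = motif("B1_Erich", "E-E-X-X-E-E", region="L57-b7")       # B1 corroboration
B1_FXSES = motif("B1_FxSES", "F-X-S-E-S", region="L34")            # B1
B3_LDV = motif("B3_LDV", "L-D-V-X-X-F-X-P-E-E", region="b3-L34")   # B3
B3_GKHEE = motif("B3_GKHEE", "G-K-H-E-E-(R/K)", region="b5-L57")   # B3
B8_SSF = motif("beta8_SSF", "S-(S/T)-(F/L)", region="b8")          # Cluster B
B7_R = motif("beta7_R", "R", region="b7")                          # absent in A1

ALL_MOTIFS = {
    m.name: m
    for m in (
        L78_LP, L78_VD, L89_G, B9_MOTIF, B4_VK, NLS_VRKP,
        B1_KRICH, B1_ERICH, B1_FXSES, B3_LDV, B3_GKHEE, B8_SSF, B7_R,
    )
}
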