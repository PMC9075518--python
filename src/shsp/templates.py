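"""Cluster-templated sHsp sequence scaffolds.

The α-crystallin domain (ACD) core used throughout the pipeline runs from
the β3-strand to the β9-strand (the β2-strand is too poorly conserved to
anchor on).  The core is modelled as an alternating chain of β-strand
blocks and connecting loops::

    β3 – L34 – β4 – L45 – β5 – L57 – β7 – L78 – β8 – L89 – β9

Strand blocks have fixed widths; L34, L45 and L57 vary in length between
subclusters (the A1 subcluster has a famously short L57 of 5–6 residues,
which makes its whole core only 63–69 residues long versus 71–79 in the
other groups), while L78 and L89 are kept at fixed width because their
contents (the L-P and V-D doublets; the conserved glycine) are the most
rigidly conserved part of the domain.

Each subcluster template is a concrete protein sequence built from

* fixed positions — signature motifs and anchor residues that define the
  subcluster (never mutated by the noise model), and
* filler positions — residues chosen by a deterministic composition tuner
  so that the template's length, molecular weight, pI and GRAVY fall inside
  the interquartile box reported for its subcluster, both for the whole
  protein and for the ACD core.

The tuner is a greedy hill-climb over the filler composition using
single-residue swaps; pI moves (e.g. N↔D, Q↔E) are nearly GRAVY-neutral and
GRAVY moves (e.g. S↔A, A↔V) are charge-neutral, so the two objectives are
close to orthogonal and the search converges quickly.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field

from .physchem import (
    KYTE_DOOLITTLE,
    MEAN_RESIDUE_MASS,
    PKA_TABLES,
    RESIDUE_MASS,
    WATER_MASS,
)

SEGMENT_ORDER = ("b3", "L34", "b4", "L45", "b5", "L57", "b7", "L78", "b8", "L89", "b9")
STRAND_SEGMENTS = frozenset({"b3", "b4", "b5", "b7", "b8", "b9"})

#: model column width of each segment (loops profiled at their widest form)
MODEL_WIDTHS = {
    "b3": 6, "L34": 7, "b4": 6, "L45": 5, "b5": 5, "L57": 14,
    "b7": 6, "L78": 8, "b8": 5, "L89": 4, "b9": 6,
}

#: allowed loop lengths during detection (strands are rigid)
LOOP_SPANS = {
    "L34": (4, 9), "L45": (3, 7), "L57": (4, 14), "L78": (8, 8), "L89": (4, 4),
}

MIN_CORE_LEN = 60
MAX_CORE_LEN = 85

CLUSTERS = ("A1", "A2", "B1", "B2", "B3")
LABELS = CLUSTERS + ("dimeric",)

# ---------------------------------------------------------------------------
# Published interquartile boxes per subcluster (whole protein and ACD core).

#: (mw_kda, length_aa, pi, gravy) boxes for the whole protein
PROTEIN_BOXES = {
    "A1": {"mw_kda": (9.7, 10.1), "length_aa": (89, 91), "pi": (4.1, 4.3),
           "gravy": (-0.12, -0.04)},
    "A2": {"mw_kda": (40.0, 41.8), "length_aa": (359, 381), "pi": (9.2, 10.2),
           "gravy": (-0.69, -0.54)},
    "B1": {"mw_kda": (16.3, 25.5), "length_aa": (142, 241), "pi": (4.9, 6.0),
           "gravy": (-0.72, -0.46)},
    "B2": {"mw_kda": (17.9, 23.0), "length_aa": (158, 204), "pi": (5.7, 7.5),
           "gravy": (-0.66, -0.58)},
    "B3": {"mw_kda": (21.3, 23.9), "length_aa": (187, 205), "pi": (6.4, 8.0),
           "gravy": (-0.80, -0.65)},
}

#: (pi, gravy) boxes for the ACD core, plus the core length band
ACD_BOXES = {
    "A1": {"pi": (3.9, 4.1), "gravy": (0.01, 0.15), "core_len": (63, 69)},
    "A2": {"pi": (8.6, 10.1), "gravy": (-0.31, -0.16), "core_len": (71, 79)},
    "B1": {"pi": (4.8, 5.2), "gravy": (-0.75, -0.62), "core_len": (71, 79)},
    "B2": {"pi": (6.0, 8.7), "gravy": (-0.75, -0.61), "core_len": (71, 79)},
    "B3": {"pi": (4.5, 6.0), "gravy": (-0.59, -0.44), "core_len": (71, 79)},
}

# ---------------------------------------------------------------------------
# Core scaffolds: per segment (sequence, mask); '*' = fixed (motif/anchor),
# '.' = filler (tunable at template-build time, mutable by the noise model).

_CORE_SPECS: dict[str, list[tuple[str, str, str]]] = {
    # A1: V-(R/K)-P in β4, no conserved R in β7, Cluster-A G in L34 and A in
    # β8, very short L57.
    "A1": [
        ("b3", "VSVIVE", "......"),
        ("L34", "GDSENSA", "*......"),
        ("b4", "TSVKPV", "..***."),
        ("L45", "DESNA", "....."),
        ("b5", "VNVSE", "....."),
        ("L57", "DGSDNE", "......"),
        ("b7", "TVLSEF", "...*.."),
        ("L78", "GLPVDVAE", ".****..."),
        ("b8", "VQAQI", "..*.."),
        ("L89", "SGQD", ".*.."),
        ("b9", "LKVEAP", "******"),
    ],
    # A2: Cluster-A traits (G in L34, A in β8), conserved R in β7, basic
    # K-rich loops, full-length L57.
    "A2": [
        ("b3", "ISIKVE", "......"),
        ("L34", "GKSKNSA", "*......"),
        ("b4", "TSVKVI", "..**.."),
        ("L45", "KSSNA", "....."),
        ("b5", "VNVSK", "....."),
        ("L57", "NGKSKASKGDKSVE", ".............."),
        ("b7", "TVLREF", "...*.."),
        ("L78", "GLPVDVAE", ".****..."),
        ("b8", "VQAKI", "..*.."),
        ("L89", "SGQD", ".*.."),
        ("b9", "LKVEAP", "******"),
    ],
    # B1: F-X-S-E-S in L34, K-K-K-X-K-K spanning β5→L57, E-E-X-X-E-E in
    # L57, Cluster-B S-S-F in β8, conserved R in β7.
    "B1": [
        ("b3", "ISVQTE", "......"),
        ("L34", "FASESGN", "*.***.."),
        ("b4", "LTVKVF", "..**.."),
        ("L45", "DNSNA", "....."),
        ("b5", "SKKKA", ".***."),
        ("L57", "KKSGDEEGDEENP", "**...**..**.."),
        ("b7", "TVLREF", "...*.."),
        ("L78", "GLPVDVAE", ".****..."),
        ("b8", "VSSFE", ".***."),
        ("L89", "SGQD", ".*.."),
        ("b9", "LKVEAP", "******"),
    ],
    # B2: generic Cluster-B template (F in L34, S-S-F in β8, R in β7)
    # without the B1 or B3 signature motifs.
    "B2": [
        ("b3", "ISVETD", "......"),
        ("L34", "FGDEKSN", "*......"),
        ("b4", "LTVKVF", "..**.."),
        ("L45", "ENSNA", "....."),
        ("b5", "VNVSE", "....."),
        ("L57", "SKHDEGSDAVSGE", "............."),
        ("b7", "TVLREF", "...*.."),
        ("L78", "GLPVDVAE", ".****..."),
        ("b8", "VSSFE", ".***."),
        ("L89", "SGQD", ".*.."),
        ("b9", "LKVEAP", "******"),
    ],
    # B3: L-D-V-X-X-F-X-P-E-E spanning β3→L34 and G-K-H-E-E-R in L57.
    "B3": [
        ("b3", "LDVKEF", "***..*"),
        ("L34", "APEEGSF", ".***..*"),
        ("b4", "LTVKVF", "..**.."),
        ("L45", "DNSNA", "....."),
        ("b5", "VNVSE", "....."),
        ("L57", "GKHEERSDGLSSVE", "******........"),
        ("b7", "TVLREF", "...*.."),
        ("L78", "GLPVDVAE", ".****..."),
        ("b8", "VSSFE", ".***."),
        ("L89", "SGQD", ".*.."),
        ("b9", "LKVEAP", "******"),
    ],
}

# flank lengths (NTD includes the initiator M) chosen at the centre of each
# length box given the core length
_FLANKS = {  # label -> (ntd_len, ctd_len)
    "A1": (16, 10),   # 16 + 64 + 10 = 90
    "A2": (180, 118),  # 180 + 72 + 118 = 370
    "B1": (70, 39),   # 70 + 71 + 39 = 180
    "B2": (66, 39),   # 66 + 71 + 39 = 176
    "B3": (80, 44),   # 80 + 72 + 44 = 196
}

# starting filler compositions (the tuner refines these)
_FLANK_SEED_COMP = {
    "A1": "DESTANGQSEPVDTG",
    "A2": "KSKANGQKEPKRTSG",
    "B1": "DESTANGQSEPKDTG",
    "B2": "SESTANGQKEPKDTG",
    "B3": "SKSTANGQKEPKDTG",
}

_DIMER_LINKER_LEN = 24
_DIMER_NTD, _DIMER_CTD = 30, 20


class TemplateError(ValueError):
    """Raised when a template cannot be built inside its target box."""


# ---------------------------------------------------------------------------
# Composition-level physicochemistry (the tuner works on counts, not strings)

def _gravy_counts(counts: Counter) -> float:
    n = sum(v for k, v in counts.items() if k != "X")
    return sum(KYTE_DOOLITTLE[k] * v for k, v in counts.items() if k != "X") / n


def _mw_counts(counts: Counter) -> float:
    return (
        sum(RESIDUE_MASS.get(k, MEAN_RESIDUE_MASS) * v for k, v in counts.items())
        + WATER_MASS
    )


def _pi_counts(counts: Counter, pka_table: str = "sms") -> float:
    t = PKA_TABLES[pka_table]
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(60):
        ph = (lo + hi) / 2.0
        c = 1.0 / (1.0 + 10 ** (ph - t["n_term"]))
        c -= 1.0 / (1.0 + 10 ** (t["c_term"] - ph))
        for aa, (pka, sign) in t["side"].items():
            n = counts.get(aa, 0)
            if not n:
                continue
            if sign > 0:
                c += n / (1.0 + 10 ** (ph - pka))
            else:
                c -= n / (1.0 + 10 ** (pka - ph))
        if c > 0:
            lo = ph
        else:
            hi = ph
    return ph


_TUNE_PALETTE = "ADEGIKNPQRSTV"


def _shrink(box: tuple[float, float], frac: float = 0.15) -> tuple[float, float]:
    # aim inside the box so the finished template never sits on an edge
    lo, hi = box
    pad = frac * (hi - lo)
    return (lo + pad, hi - pad)


def _box_penalty(value: float, lo: float, hi: float, scale: float) -> float:
    if value < lo:
        return ((lo - value) / scale) ** 2
    if value > hi:
        return ((value - hi) / scale) ** 2
    return 0.0


def tune_filler(
    fixed_counts: Counter,
    n_filler: int,
    start_comp: str,
    boxes: dict[str, tuple[float, float]],
    max_sweeps: int = 400,
) -> list[str]:
    """Choose a filler multiset so the total composition lands in ``boxes``.

    ``boxes`` may contain ``pi``, ``gravy`` and ``mw_kda`` entries.  Greedy
    best-improvement hill-climb with single-residue swaps; deterministic.
    Raises TemplateError naming the violated box if no improving move exists.
    """
    filler = Counter(start_comp[i % len(start_comp)] for i in range(n_filler))

    def penalty(fc: Counter) -> float:
        total = fixed_counts + fc
        p = 0.0
        if "pi" in boxes:
            p += _box_penalty(_pi_counts(total), *boxes["pi"], 0.05)
        if "gravy" in boxes:
            p += _box_penalty(_gravy_counts(total), *boxes["gravy"], 0.01)
        if "mw_kda" in boxes:
            p += _box_penalty(_mw_counts(total) / 1000.0, *boxes["mw_kda"], 0.05)
        return p

    cur = penalty(filler)
    for _ in range(max_sweeps):
        if cur == 0.0:
            break
        best = None
        for src in sorted(filler):
            if filler[src] <= 0:
                continue
            for dst in _TUNE_PALETTE:
                if dst == src:
                    continue
                filler[src] -= 1
                filler[dst] += 1
                p = penalty(filler)
                filler[dst] -= 1
                filler[src] += 1
                if p < cur and (best is None or p < best[0]):
                    best = (p, src, dst)
        if best is None:
            break
        cur, src, dst = best
        filler[src] -= 1
        filler[dst] += 1
    if cur != 0.0:
        names = {k: v for k, v in boxes.items()}
        raise TemplateError(f"composition tuning failed to reach boxes {names}")
    return sorted(filler.elements())


# ---------------------------------------------------------------------------
# Template assembly

@dataclass
class TemplateProtein:
    """A fully assembled cluster template with per-position annotation.

    ``categories[i]`` is one of ``strand_fixed``, ``strand_filler``,
    ``loop_fixed``, ``loop_filler``, ``flank_fixed``, ``flank`` and governs
    both the noise model (fixed positions never mutate) and loop-indel
    placement.  ``segments`` maps each core segment of each ACD to its
    (start, end) span in protein coordinates; ``cores`` lists the (start,
    end) spans of the ACD core(s).
    """

    label: str
    seq: str
    categories: list[str]
    segments: list[dict[str, tuple[int, int]]]
    cores: list[tuple[int, int]]

    @property
    def core_seqs(self) -> list[str]:
        return [self.seq[s:e] for s, e in self.cores]


def _assemble_core(label: str, attempt: int = 0) -> tuple[str, list[str], dict]:
    """Build one subcluster core: tune loop filler to the ACD box.

    Returns (core string, per-position categories, segment span map).
    """
    spec = _CORE_SPECS[label]
    # fixed counts: every fixed position plus all strand fillers (strand
    # fillers keep their scaffold residues; only loop fillers are tuned)
    fixed_counts: Counter = Counter()
    n_loop_filler = 0
    for seg, seq, mask in spec:
        for a, m in zip(seq, mask):
            if m == "*" or seg in STRAND_SEGMENTS:
                fixed_counts[a] += 1
            else:
                n_loop_filler += 1
    boxes = {
        "pi": _shrink(ACD_BOXES[label]["pi"]),
        "gravy": _shrink(ACD_BOXES[label]["gravy"]),
    }
    filler = tune_filler(fixed_counts, n_loop_filler, _CORE_FILLER_SEED[label], boxes)
    rng = random.Random(f"{label}-corefill-{attempt}")
    rng.shuffle(filler)

    out: list[str] = []
    cats: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    k = 0
    pos = 0
    for seg, seq, mask in spec:
        start = pos
        for a, m in zip(seq, mask):
            if m == "*":
                out.append(a)
                cats.append("strand_fixed" if seg in STRAND_SEGMENTS else "loop_fixed")
            elif seg in STRAND_SEGMENTS:
                out.append(a)
                cats.append("strand_filler")
            else:
                out.append(filler[k])
                k += 1
                cats.append("loop_filler")
            pos += 1
        spans[seg] = (start, pos)
    return "".join(out), cats, spans


_CORE_FILLER_SEED = {
    "A1": "DNSAVGTE",
    "A2": "KNSAKGTE",
    "B1": "DNSAQGTE",
    "B2": "DNSAQGTE",
    "B3": "DNSAQGTE",
}

# classical basic nuclear localization signal planted in the A2 N-terminal
# domain (fixed; mirrors basic-NLS predictions for the large basic group)
_A2_NLS = "PKKKRKV"


def _assemble_monomer(label: str, attempt: int = 0) -> TemplateProtein:
    core, core_cats, spans = _assemble_core(label, attempt)
    ntd_len, ctd_len = _FLANKS[label]
    n_flank = (ntd_len - 1) + ctd_len  # minus initiator M
    fixed = Counter(core)
    fixed["M"] += 1
    nls = ""
    if label == "A2":
        nls = _A2_NLS
        fixed.update(nls)
        n_flank -= len(nls)
    boxes = {
        "pi": _shrink(PROTEIN_BOXES[label]["pi"]),
        "gravy": _shrink(PROTEIN_BOXES[label]["gravy"]),
        "mw_kda": _shrink(PROTEIN_BOXES[label]["mw_kda"]),
    }
    filler = tune_filler(fixed, n_flank, _FLANK_SEED_COMP[label], boxes)
    rng = random.Random(f"{label}-flankfill-{attempt}")
    rng.shuffle(filler)

    ntd_fill_len = ntd_len - 1 - len(nls)
    ntd = "M" + nls + "".join(filler[:ntd_fill_len])
    ctd = "".join(filler[ntd_fill_len:])
    seq = ntd + core + ctd
    cats = (
        ["flank_fixed"] * (1 + len(nls))
        + ["flank"] * ntd_fill_len
        + core_cats
        + ["flank"] * ctd_len
    )
    segs = {s: (a + len(ntd), b + len(ntd)) for s, (a, b) in spans.items()}
    return TemplateProtein(
        label=label,
        seq=seq,
        categories=cats,
        segments=[segs],
        cores=[(len(ntd), len(ntd) + len(core))],
    )


def _assemble_dimeric(attempt: int = 0) -> TemplateProtein:
    """Two tandem ACD cores: a diverged upstream core and a B2-like
    downstream core, joined by a disordered linker."""
    down_core, down_cats, down_spans = _assemble_core("B2", attempt)
    up_core, up_cats, up_spans = _assemble_core("B2", attempt)

    # diverge the upstream core at ~45% of its filler positions so it sits
    # well apart (>=30%) from every monomeric template, as upstream ACDs do
    rng = random.Random(f"dimeric-upcore-{attempt}")
    up = list(up_core)
    filler_idx = [i for i, c in enumerate(up_cats) if c.endswith("filler")]
    n_change = int(round(0.45 * len(up_core)))
    chosen = sorted(rng.sample(filler_idx, min(n_change, len(filler_idx))))
    alphabet = "ADEFGHIKLMNPQRSTVWY"
    for i in chosen:
        cur = up[i]
        repl = rng.choice([a for a in alphabet if a != cur])
        up[i] = repl
    up_core = "".join(up)

    linker = "".join(
        random.Random(f"dimeric-linker-{attempt}").choices(
            "GSTNEQPADK", k=_DIMER_LINKER_LEN
        )
    )
    ntd = "M" + "".join(
        random.Random(f"dimeric-ntd-{attempt}").choices("GSTNEQPADK", k=_DIMER_NTD - 1)
    )
    ctd = "".join(
        random.Random(f"dimeric-ctd-{attempt}").choices("GSTNEQPADK", k=_DIMER_CTD)
    )
    seq = ntd + up_core + linker + down_core + ctd
    cats = (
        ["flank_fixed"] + ["flank"] * (_DIMER_NTD - 1)
        + up_cats
        + ["flank"] * _DIMER_LINKER_LEN
        + down_cats
        + ["flank"] * _DIMER_CTD
    )
    off1 = len(ntd)
    off2 = len(ntd) + len(up_core) + len(linker)
    segs1 = {s: (a + off1, b + off1) for s, (a, b) in up_spans.items()}
    segs2 = {s: (a + off2, b + off2) for s, (a, b) in down_spans.items()}
    return TemplateProtein(
        label="dimeric",
        seq=seq,
        categories=cats,
        segments=[segs1, segs2],
        cores=[(off1, off1 + len(up_core)), (off2, off2 + len(down_core))],
    )


_TEMPLATE_CACHE: dict[str, TemplateProtein] = {}


def build_template(label: str) -> TemplateProtein:
    """Build (and cache) the deterministic template protein for a label."""
    if label not in LABELS:
        raise TemplateError(f"unknown cluster label {label!r}")
    if label not in _TEMPLATE_CACHE:
        if label == "dimeric":
            _TEMPLATE_CACHE[label] = _assemble_dimeric()
        else:
            _TEMPLATE_CACHE[label] = _assemble_monomer(label)
    return _TEMPLATE_CACHE[label]


def seed_core_alignment() -> list[tuple[str, str]]:
    """The bundled seed alignment: each template core laid onto the model
    column space (strands 1:1; loops left-aligned, gap-padded to width).

    Includes the five monomeric cores and the diverged upstream core of the
    dimeric template, so the scoring model has seen the Cluster-C flavour.
    """
    rows = []
    for label in CLUSTERS:
        t = build_template(label)
        rows.append((label, _project_core(t, 0)))
    dim = build_template("dimeric")
    rows.append(("dimeric_up", _project_core(dim, 0)))
    return rows


def _project_core(t: TemplateProtein, core_idx: int) -> str:
    segs = t.segments[core_idx]
    out = []
    for seg in SEGMENT_ORDER:
        a, b = segs[seg]
        piece = t.seq[a:b]
        width = MODEL_WIDTHS[seg]
        out.append(piece[:width].ljust(width, "-"))
    return "".join(out)
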