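"""Synthetic transcriptome generator with planted sHsp genes.

The generator is the test substrate for the whole pipeline: it emits
nucleotide transcripts carrying cluster-templated monomeric sHsps, dimeric
(two-tandem-ACD) sHsps, decoy ORFs, and untranslated flanks, together with
a ground-truth table mapping every planted element to its cluster label and
ACD coordinates.

Noise model
-----------
Substitutions hit *filler* positions only, at separate rates for strand
and loop/flank positions (strands of the β-sandwich are conserved, loops
and the disordered flanks drift) — signature-motif and anchor positions
are the empirically conserved residues that define the groups and are kept
invariant.  Indels are confined to the variable loops (L34, L45, L57), at
most one per core, and clamped so loop lengths stay inside the detection
spans.  Back-translation draws uniformly among synonymous codons.  All
randomness flows from a single mandatory seed; outputs are byte-identical
across runs with the same config.

Decoys
------
*Random decoys* are background-composition ORFs; *near-miss decoys* carry
exactly one signature motif each (a β9 motif, an L78 doublet pair, or one
subcluster signature) embedded in random sequence, stressing the rule
conjunction in the detector.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .seqio import ProteinRecord, TranscriptRecord, write_fasta
from .templates import (
    LOOP_SPANS,
    STRAND_SEGMENTS,
    TemplateProtein,
    build_template,
)
from .templates import LABELS as TEMPLATE_LABELS

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# standard-code codon table for back-translation
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_STOPS = ["TAA", "TAG", "TGA"]

# one-motif inserts for near-miss decoys (each realizes a single signature)
_NEAR_MISS_MOTIFS = [
    "LKVEAP",        # β9 motif
    "LPSVD",         # both L78 doublets, no β9 downstream
    "KKKAKK",        # B1 lysine-rich
    "FASES",         # B1 serine-rich L34 motif
    "LDVKEFAPEE",    # B3 β3-L34 signature
    "GKHEER",        # B3 β5-L57 signature
]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic repertoire."""

    n_per_cluster: dict[str, int] = field(
        default_factory=lambda: {
            "A1": 5, "A2": 5, "B1": 5, "B2": 5, "B3": 5, "dimeric": 5,
        }
    )
    sub_rate_strand: float = 0.01
    sub_rate_loop: float = 0.05
    loop_indel_rate: float = 0.01
    max_indel: int = 2
    n_random_decoys: int = 20
    n_near_miss_decoys: int = 10
    utr_len: tuple[int, int] = (30, 120)
    frac_truncated: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("GeneratorConfig requires an explicit seed")
        for name in ("sub_rate_strand", "sub_rate_loop", "loop_indel_rate",
                     "frac_truncated"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        bad = set(self.n_per_cluster) - set(TEMPLATE_LABELS)
        if bad:
            raise ValueError(f"unknown cluster labels in config: {sorted(bad)}")
        if self.max_indel < 1:
            raise ValueError("max_indel must be >= 1")


@dataclass
class TruthRecord:
    transcript_id: str
    protein_id: str
    label: str  # cluster label, "dimeric", or "decoy"
    acd_coords: list[tuple[int, int]]  # protein space; empty for decoys
    complete: bool


def make_template(label: str) -> TemplateProtein:
    """The deterministic, box-validated template protein for a cluster label.

    Validated on construction: signature motifs sit in their anchor regions
    and the physicochemical profile falls inside the published box (the
    template builder raises otherwise).
    """
    return build_template(label)


# ---------------------------------------------------------------------------
# mutation machinery

_VARIABLE_LOOPS = ("L34", "L45", "L57")


def _token_list(t: TemplateProtein) -> list[list]:
    """Annotate each template position: [residue, category, core_idx, segment]."""
    seg_of: dict[int, tuple[int, str]] = {}
    for ci, segs in enumerate(t.segments):
        for seg, (a, b) in segs.items():
            for i in range(a, b):
                seg_of[i] = (ci, seg)
    out = []
    for i, (a, cat) in enumerate(zip(t.seq, t.categories)):
        ci, seg = seg_of.get(i, (-1, None))
        out.append([a, cat, ci, seg])
    return out


def _mutate_protein(
    t: TemplateProtein, cfg: GeneratorConfig, rng: random.Random
) -> tuple[str, list[tuple[int, int]]]:
    """Apply substitutions and loop indels to a template instance.

    Returns the mutated protein and the (shifted) ACD core coordinates.
    """
    tokens = _token_list(t)
    for tok in tokens:
        rate = 0.0
        if tok[1] == "strand_filler":
            rate = cfg.sub_rate_strand
        elif tok[1] in ("loop_filler", "flank"):
            rate = cfg.sub_rate_loop
        if rate and rng.random() < rate:
            tok[0] = rng.choice([x for x in AA20 if x != tok[0]])

    # at most one indel per core, confined to variable-loop filler runs and
    # clamped so loop lengths stay inside the detection spans
    if cfg.loop_indel_rate > 0:
        for core_idx in range(len(t.cores)):
            sites = [
                k for k, tok in enumerate(tokens)
                if tok[2] == core_idx and tok[1] == "loop_filler"
                and tok[3] in _VARIABLE_LOOPS
            ]
            p_any = 1.0 - (1.0 - cfg.loop_indel_rate) ** len(sites)
            if not sites or rng.random() >= p_any:
                continue
            k = rng.choice(sites)
            seg = tokens[k][3]
            loop_len = sum(
                1 for tok in tokens if tok[2] == core_idx and tok[3] == seg
            )
            size = rng.randint(1, cfg.max_indel)
            lo, hi = LOOP_SPANS[seg]
            if rng.random() < 0.5:
                size = min(size, loop_len - lo)
                run = [
                    j for j in range(k, min(k + size, len(tokens)))
                    if tokens[j][1] == "loop_filler"
                    and tokens[j][2] == core_idx and tokens[j][3] == seg
                ]
                for j in reversed(run):
                    del tokens[j]
            else:
                size = min(size, hi - loop_len)
                ins = [
                    [rng.choice(AA20), "loop_filler", core_idx, seg]
                    for _ in range(size)
                ]
                tokens[k:k] = ins

    seq = "".join(tok[0] for tok in tokens)
    coords = []
    for core_idx in range(len(t.cores)):
        pos = [k for k, tok in enumerate(tokens) if tok[2] == core_idx]
        coords.append((pos[0], pos[-1] + 1))
    return seq, coords


# ---------------------------------------------------------------------------

def _back_translate(protein: str, rng: random.Random) -> str:
    return "".join(rng.choice(_CODONS[a]) for a in protein)


def _random_utr(rng: random.Random, lo: int, hi: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(rng.randint(lo, hi)))


def _random_protein(rng: random.Random, lo: int = 120, hi: int = 250) -> str:
    return "".join(rng.choice(AA20) for _ in range(rng.randint(lo, hi)))


@dataclass
class Repertoire:
    transcripts: list[TranscriptRecord]
    proteins: list[ProteinRecord]
    truth: list[TruthRecord]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "transcripts": outdir / "transcripts.fna",
            "proteins": outdir / "proteins.faa",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.transcripts, paths["transcripts"])
        write_fasta(self.proteins, paths["proteins"])
        with open(paths["truth"], "w") as fh:
            fh.write("transcript_id\tprotein_id\tlabel\tacd_coords\tcomplete\n")
            for r in self.truth:
                coords = ";".join(f"{a}-{b}" for a, b in r.acd_coords)
                fh.write(
                    f"{r.transcript_id}\t{r.protein_id}\t{r.label}\t"
                    f"{coords}\t{int(r.complete)}\n"
                )
        return paths


def generate_repertoire(config: GeneratorConfig) -> Repertoire:
    """Generate a full synthetic repertoire (deterministic for fixed seed)."""
    rng = random.Random(config.seed)
    transcripts, proteins, truth = [], [], []

    counter = 0
    for label in [l for l in TEMPLATE_LABELS if config.n_per_cluster.get(l, 0) > 0]:
        template = make_template(label)
        for i in range(config.n_per_cluster[label]):
            counter += 1
            pid = f"shsp_{label}_{i+1:03d}"
            tid = f"tx_{counter:04d}"
            pseq, coords = _mutate_protein(template, config, rng)
            truncate = rng.random() < config.frac_truncated
            cds = _back_translate(pseq, rng)
            if truncate:
                # cut mid-CDS after the last ACD: no stop codon, 3' edge ORF
                last_end = 3 * coords[-1][1]
                keep = rng.randint(last_end, len(cds))
                nt = _random_utr(rng, *config.utr_len) + cds[:keep]
                complete = False
            else:
                nt = (
                    _random_utr(rng, *config.utr_len)
                    + cds
                    + rng.choice(_STOPS)
                    + _random_utr(rng, *config.utr_len)
                )
                complete = True
            transcripts.append(TranscriptRecord(tid, nt, f"planted {label}"))
            proteins.append(
                ProteinRecord(pid, pseq, source_transcript=tid, complete=complete)
            )
            truth.append(TruthRecord(tid, pid, label, coords, complete))

    for i in range(config.n_random_decoys):
        counter += 1
        pid = f"decoy_rand_{i+1:03d}"
        tid = f"tx_{counter:04d}"
        pseq = "M" + _random_protein(rng)
        nt = (
            _random_utr(rng, *config.utr_len)
            + _back_translate(pseq, rng)
            + rng.choice(_STOPS)
            + _random_utr(rng, *config.utr_len)
        )
        transcripts.append(TranscriptRecord(tid, nt, "decoy random ORF"))
        proteins.append(ProteinRecord(pid, pseq, source_transcript=tid, complete=True))
        truth.append(TruthRecord(tid, pid, "decoy", [], True))

    for i in range(config.n_near_miss_decoys):
        counter += 1
        pid = f"decoy_miss_{i+1:03d}"
        tid = f"tx_{counter:04d}"
        motif_seq = _NEAR_MISS_MOTIFS[i % len(_NEAR_MISS_MOTIFS)]
        body = list("M" + _random_protein(rng))
        at = rng.randint(30, len(body) - len(motif_seq) - 10)
        body[at : at + len(motif_seq)] = motif_seq
        pseq = "".join(body)
        nt = (
            _random_utr(rng, *config.utr_len)
            + _back_translate(pseq, rng)
            + rng.choice(_STOPS)
            + _random_utr(rng, *config.utr_len)
        )
        transcripts.append(TranscriptRecord(tid, nt, "decoy near-miss"))
        proteins.append(ProteinRecord(pid, pseq, source_transcript=tid, complete=True))
        truth.append(TruthRecord(tid, pid, "decoy", [], True))

    return Repertoire(transcripts=transcripts, proteins=proteins, truth=truth)
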