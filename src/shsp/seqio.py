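"""FASTA input/output and the basic sequence record types.

Transcript records hold assembled nucleotide sequences (the unit of input
for sHsp discovery); protein records hold translated open reading frames
together with their provenance on the source transcript and a completeness
flag (initiator methionine and terminating stop both present inside the
transcript). Incomplete proteins are carried through the pipeline but are
excluded from group-level physicochemical summaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
AMINO_ACIDS_X = AMINO_ACIDS | {"X"}


class SequenceInputError(ValueError):
    """Raised for malformed sequence input (bad alphabet, duplicates, empties)."""


@dataclass
class TranscriptRecord:
    """An assembled nucleotide transcript (or genomic contig)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceInputError("transcript id must be non-empty")
        if not self.seq:
            raise SequenceInputError(f"transcript {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        bad = set(self.seq) - NUCLEOTIDES
        if bad:
            raise SequenceInputError(
                f"transcript {self.id!r}: non-IUPAC nucleotide symbol(s) "
                f"{sorted(bad)!r} (allowed: A,C,G,T,N)"
            )


@dataclass
class ProteinRecord:
    """A translated ORF, or a directly supplied protein sequence.

    Coordinates are 0-based half-open on the forward strand of the source
    transcript; they are ``None`` for proteins read straight from a protein
    FASTA.  ``complete`` is True only when the ORF begins at an initiator M
    encoded inside the transcript and ends at a stop codon inside the
    transcript — ORFs running into a contig edge are flagged incomplete.
    """

    id: str
    seq: str
    source_transcript: str | None = None
    frame: int | None = None
    start_nt: int | None = None
    end_nt: int | None = None
    complete: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceInputError("protein id must be non-empty")
        if not self.seq:
            raise SequenceInputError(f"protein {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        bad = set(self.seq) - AMINO_ACIDS_X
        if bad:
            raise SequenceInputError(
                f"protein {self.id!r}: invalid amino-acid symbol(s) {sorted(bad)!r}"
            )
        if self.frame is not None and self.frame not in (1, 2, 3, -1, -2, -3):
            raise SequenceInputError(f"protein {self.id!r}: bad frame {self.frame}")
        if self.frame is None and (self.start_nt is not None or self.end_nt is not None):
            raise SequenceInputError(
                f"protein {self.id!r}: coordinates given without a frame"
            )


def _check_unique_ids(records: Sequence) -> None:
    seen: dict[str, int] = {}
    for r in records:
        seen[r.id] = seen.get(r.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise SequenceInputError(f"duplicate record ids: {dups}")


def _looks_like_nucleotide(seq: str) -> bool:
    return bool(seq) and set(seq.upper()) <= NUCLEOTIDES


def read_fasta(path: str | Path, kind: str = "auto"):
    """Read a FASTA file into transcript or protein records.

    Parameters
    ----------
    path:
        FASTA file path.
    kind:
        ``"nucleotide"``, ``"protein"``, or ``"auto"`` (classify by alphabet:
        if every sequence is drawn from A/C/G/T/N the file is treated as
        nucleotide).

    Returns
    -------
    list of TranscriptRecord or list of ProteinRecord
    """
    path = Path(path)
    if not path.exists():
        raise SequenceInputError(f"no such file: {path}")
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise SequenceInputError(f"empty or non-FASTA file: {path}")
    if kind == "auto":
        kind = (
            "nucleotide"
            if all(_looks_like_nucleotide(str(r.seq)) for r in raw)
            else "protein"
        )
    if kind == "nucleotide":
        records = [
            TranscriptRecord(r.id, str(r.seq), _strip_id(r.description, r.id))
            for r in raw
        ]
    elif kind == "protein":
        records = [
            ProteinRecord(r.id, str(r.seq), description=_strip_id(r.description, r.id))
            for r in raw
        ]
    else:
        raise ValueError(f"kind must be nucleotide/protein/auto, got {kind!r}")
    _check_unique_ids(records)
    return records


def _strip_id(description: str, rid: str) -> str:
    return description[len(rid):].strip() if description.startswith(rid) else description


def write_fasta(records: Iterable, path: str | Path, width: int = 80) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width`` columns."""
    records = list(records)
    _check_unique_ids(records)
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.id, description=getattr(r, "description", ""))
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(seqrecords)


_ACCESSION_RE = re.compile(r"^[A-Z]{2}\d{6}$")


def parse_accession_range(spec: str) -> list[str]:
    """Expand a GenBank accession range like ``"MZ261736-MZ261811"``.

    Both endpoints must share the two-letter prefix; single accessions are
    accepted as a range of one.
    """
    parts = spec.replace("..", "-").split("-")
    if len(parts) == 1:
        parts = parts * 2
    if len(parts) != 2:
        raise ValueError(f"bad accession range: {spec!r}")
    lo, hi = (p.strip().upper() for p in parts)
    for p in (lo, hi):
        if not _ACCESSION_RE.match(p):
            raise ValueError(f"invalid accession format: {p!r}")
    if lo[:2] != hi[:2]:
        raise ValueError(f"accession range spans prefixes: {spec!r}")
    a, b = int(lo[2:]), int(hi[2:])
    if b < a:
        raise ValueError(f"descending accession range: {spec!r}")
    return [f"{lo[:2]}{n:06d}" for n in range(a, b + 1)]
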