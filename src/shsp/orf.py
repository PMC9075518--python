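"""Six-frame translation and ORF extraction.

Each reading frame of the transcript (three forward, three on the reverse
complement) is split at stop codons; every inter-stop segment long enough to
yield ``min_aa`` residues produces at most one candidate ORF:

* if the segment contains an ATG, the ORF starts at the *first* ATG
  (nested ORFs starting at later ATGs are collapsed into it);
* otherwise the ORF starts at the segment's first full codon — such edge
  fragments are kept because truncated transcripts are common in
  assemblies, but they are flagged ``complete=False``.

``complete`` requires both an initiator ATG and a terminating stop codon
inside the transcript; any ORF abutting a contig edge is incomplete.
Codons containing N translate to X; internal stop codons always terminate.
Coordinates are 0-based half-open on the forward strand, so
``transcript.seq[start_nt:end_nt]`` is exactly the coding sequence
(reverse-complemented for negative frames), excluding the stop codon.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .seqio import ProteinRecord, SequenceInputError, TranscriptRecord

STANDARD_TABLE = 1


def _translate_codon(codon: str, table: CodonTable.CodonTable) -> str:
    if "N" in codon:
        return "X"
    if codon in table.stop_codons:
        return "*"
    return table.forward_table.get(codon, "X")


def translate_six_frames(
    transcript: TranscriptRecord,
    genetic_code: int = STANDARD_TABLE,
    min_aa: int = 50,
) -> list[ProteinRecord]:
    """Extract candidate ORFs of at least ``min_aa`` residues from all six frames.

    Returns proteins ordered by (frame, start). IDs are formed as
    ``{transcript.id}|orf{n}``.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    nt = transcript.seq
    length = len(nt)
    orfs: list[ProteinRecord] = []

    for strand in (+1, -1):
        work = nt if strand == 1 else str(Seq(nt).reverse_complement())
        for offset in (0, 1, 2):
            frame = strand * (offset + 1)
            n_codons = (len(work) - offset) // 3
            if n_codons <= 0:
                continue
            codons = [
                work[offset + 3 * i : offset + 3 * i + 3] for i in range(n_codons)
            ]
            aa = [_translate_codon(c, table) for c in codons]
            # split at stops; each segment is [seg_start, seg_end) in codon index
            seg_start = 0
            for i in range(n_codons + 1):
                at_stop = i < n_codons and aa[i] == "*"
                at_end = i == n_codons
                if not (at_stop or at_end):
                    continue
                seg = aa[seg_start:i]
                has_stop = at_stop
                if seg:
                    orf = _segment_to_orf(
                        seg, seg_start, has_stop, offset, strand, length, min_aa
                    )
                    if orf is not None:
                        orfs.append((frame, orf))
                seg_start = i + 1

    out: list[ProteinRecord] = []
    for n, (frame, (pep, start_codon, end_codon, offset, strand, complete)) in enumerate(
        sorted(orfs, key=lambda t: (_frame_key(t[0]), t[1][1])), start=1
    ):
        # codon coordinates -> nucleotide coordinates on the working strand
        s = offset + 3 * start_codon
        e = offset + 3 * end_codon
        if strand == 1:
            start_nt, end_nt = s, e
        else:  # mirror onto the forward strand
            start_nt, end_nt = length - e, length - s
        out.append(
            ProteinRecord(
                id=f"{transcript.id}|orf{n}",
                seq=pep,
                source_transcript=transcript.id,
                frame=strand * (offset + 1),
                start_nt=start_nt,
                end_nt=end_nt,
                complete=complete,
            )
        )
    return out


_FRAME_ORDER = {1: 0, 2: 1, 3: 2, -1: 3, -2: 4, -3: 5}


def _frame_key(frame: int) -> int:
    # order frames +1,+2,+3,-1,-2,-3
    return _FRAME_ORDER[frame]


def _segment_to_orf(seg, seg_start, has_stop, offset, strand, length, min_aa):
    """Reduce one stop-delimited segment to a single candidate ORF (or None)."""
    try:
        m = seg.index("M")
    except ValueError:
        m = None
    if m is not None:
        pep = "".join(seg[m:])
        start_codon = seg_start + m
        complete = has_stop
    else:
        pep = "".join(seg)
        start_codon = seg_start
        complete = False
    if len(pep) < min_aa:
        return None
    end_codon = seg_start + len(seg)
    return (pep, start_codon, end_codon, offset, strand, complete)


def translate_all(
    transcripts: list[TranscriptRecord],
    genetic_code: int = STANDARD_TABLE,
    min_aa: int = 50,
) -> list[ProteinRecord]:
    """Six-frame translate a batch of transcripts, concatenating the ORF lists."""
    out: list[ProteinRecord] = []
    for t in transcripts:
        out.extend(translate_six_frames(t, genetic_code=genetic_code, min_aa=min_aa))
    return out
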