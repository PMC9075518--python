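"""Retrieval of deposited protein sequences from GenBank, with local cache.

Accession ranges (e.g. ``MZ261736-MZ261811``) are expanded, fetched one
batch at a time through NCBI efetch, and written to a cache directory; a
rerun with a warm cache performs no network access at all.  Missing
accessions are reported and skipped, so a partially available deposition
still yields a usable FASTA.
"""

from __future__ import annotations

import urllib.error
import urllib.parse
import urllib.request
from pathlib import Path

from .seqio import ProteinRecord, parse_accession_range, read_fasta, write_fasta

EFETCH_URL = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


class FetchError(RuntimeError):
    pass


def fetch_accessions(
    range_spec: str,
    cache_dir: str | Path,
    db: str = "protein",
    batch_size: int = 50,
    timeout: float = 30.0,
) -> tuple[list[ProteinRecord], list[str]]:
    """Fetch a protein accession range, caching per accession.

    Returns (records, missing accessions).  Cached accessions are served
    from disk without touching the network; a network failure on uncached
    accessions raises FetchError with a retry hint.
    """
    accessions = parse_accession_range(range_spec)
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)

    records: list[ProteinRecord] = []
    missing: list[str] = []
    to_fetch = [a for a in accessions if not (cache / f"{a}.faa").exists()]

    for i in range(0, len(to_fetch), batch_size):
        batch = to_fetch[i : i + batch_size]
        params = urllib.parse.urlencode(
            {"db": db, "id": ",".join(batch), "rettype": "fasta", "retmode": "text"}
        )
        try:
            with urllib.request.urlopen(
                f"{EFETCH_URL}?{params}", timeout=timeout
            ) as fh:
                text = fh.read().decode()
        except (urllib.error.URLError, OSError) as e:
            raise FetchError(
                f"network fetch failed for {len(batch)} accession(s): {e}; "
                "retry when the network is available (cached accessions are "
                "reused automatically)"
            ) from e
        _write_batch_to_cache(text, batch, cache)

    for a in accessions:
        path = cache / f"{a}.faa"
        if not path.exists():
            missing.append(a)
            continue
        records.extend(read_fasta(path, kind="protein"))
    return records, missing


def _write_batch_to_cache(text: str, batch: list[str], cache: Path) -> None:
    chunks: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        if line.startswith(">"):
            header = line[1:].split()[0]
            current = next(
                (a for a in batch if header.startswith(a)), None
            )
            if current is not None:
                chunks[current] = [line]
        elif current is not None:
            chunks[current].append(line)
    for acc, lines in chunks.items():
        (cache / f"{acc}.faa").write_text("\n".join(lines) + "\n")
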