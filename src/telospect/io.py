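"""FASTQ/FASTA/TSV input-output.

FASTQ reading is streaming (constant memory in read count) with
record-level validation that reports the offending line number — needed
because skimming archives occasionally truncate.  FASTA output is wrapped
at 80 columns via Biopython.  Qualities are Sanger Phred+33 throughout.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FastqRecord(NamedTuple):
    id: str
    sequence: str
    quality: str


class FastqFormatError(ValueError):
    """Malformed FASTQ record; message names the line number."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    """Stream FASTQ records, plain or gzipped.

    Raises FastqFormatError naming the line for truncated files, bad
    header/separator characters, or sequence/quality length mismatches.
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqFormatError(f"line {lineno}: expected '@' header, got {header[:20]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FastqFormatError(f"line {lineno}: truncated record {header[:30]!r}")
            lineno += 3
            if not plus.startswith("+"):
                raise FastqFormatError(f"line {lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"line {lineno}: sequence/quality length mismatch "
                    f"({len(seq)} vs {len(qual)}) in record {header[1:].split()[0]!r}"
                )
            yield FastqRecord(header[1:].split()[0], seq, qual)


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> int:
    """Write FASTQ (gzipped when the path ends in .gz); returns record count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
            n += 1
    return n


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write (id, sequence) pairs as FASTA wrapped at 80 columns."""
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in sequences]
    with _open_text(path, "wt") as fh:
        return SeqIO.write(recs, fh, "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    with _open_text(path) as fh:
        return [(r.id, str(r.seq)) for r in SeqIO.parse(fh, "fasta")]
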