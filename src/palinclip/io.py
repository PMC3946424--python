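"""FASTQ/FASTA input and output and per-read TSV reports.

Thin wrappers around Biopython's SeqIO that translate between on-disk
records and :class:`~palinclip.seqcore.NucleotideRead`.  FASTQ is the
four-line Phred+33 flavour; files ending in ``.gz`` are transparently
(de)compressed.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import (
    NucleotideRead,
    gc_content,
    melting_temperature,
    terminal_palindrome_length,
)

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_read_table",
]

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: PathLike) -> Iterator[NucleotideRead]:
    """Yield reads from a FASTQ(.gz) file as :class:`NucleotideRead`."""
    with _open_text(path, "r") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield NucleotideRead(
                rec.id,
                str(rec.seq),
                list(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[NucleotideRead], path: PathLike) -> int:
    """Write reads to FASTQ(.gz); reads without qualities get Phred 40."""
    n = 0
    with _open_text(path, "w") as handle:
        for read in reads:
            quals = read.qualities
            if quals is None:
                quals = [40] * len(read.sequence)
            rec = SeqRecord(
                Seq(read.sequence),
                id=read.id,
                description="",
                letter_annotations={"phred_quality": quals},
            )
            SeqIO.write(rec, handle, "fastq")
            n += 1
    return n


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA(.gz) file into an ``{id: sequence}`` dict (upper-cased)."""
    with _open_text(path, "r") as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(records: dict[str, str], path: PathLike, width: int = 70) -> None:
    with _open_text(path, "w") as handle:
        for name, seq in records.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


_TABLE_HEADER = "read_id\tlength\tpalindrome_length\tclipped\tclip_length\tgc\ttm\n"


def write_read_table(
    reads: Iterable[NucleotideRead],
    path: PathLike,
    min_clip: int = 4,
) -> int:
    """Write the per-read detector report as TSV.

    Columns: read_id, length, palindrome length L, whether L >= ``min_clip``
    (the clip decision), the clip length that decision implies, GC fraction
    and melting temperature of the (unclipped) read.
    """
    n = 0
    with _open_text(path, "w") as handle:
        handle.write(_TABLE_HEADER)
        for read in reads:
            seq = read.sequence
            L = terminal_palindrome_length(seq)
            clipped = L >= min_clip
            handle.write(
                f"{read.id}\t{len(seq)}\t{L}\t{int(clipped)}\t"
                f"{L if clipped else 0}\t{gc_content(seq):.4f}\t"
                f"{melting_temperature(seq):.2f}\n"
            )
            n += 1
    return n
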