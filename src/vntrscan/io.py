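"""Reading and writing of standard sequence formats.

The detector is mapping-free: alignment records, when given, are used only
as containers of read sequences.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, NamedTuple

import pysam
from Bio import SeqIO


class SequenceRecord(NamedTuple):
    name: str
    sequence: str
    quality: str = ""


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Load a FASTQ file (plain or gzipped) into memory."""
    with _open_text(path) as fh:
        return [
            SequenceRecord(rec.id, str(rec.seq).upper(), "")
            for rec in SeqIO.parse(fh, "fastq")
        ]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    with _open_text(path) as fh:
        return [
            SequenceRecord(rec.id, str(rec.seq).upper(), "")
            for rec in SeqIO.parse(fh, "fasta")
        ]


def read_sequences(path: str | Path) -> list[SequenceRecord]:
    """Load reads from FASTA/FASTQ (optionally .gz) or SAM/BAM by extension."""
    path = Path(path)
    suffixes = path.suffixes
    stem_suffix = suffixes[-2] if suffixes and suffixes[-1] == ".gz" else path.suffix
    if stem_suffix in {".sam", ".bam", ".cram"}:
        return read_alignment_sequences(path)
    if stem_suffix in {".fa", ".fasta", ".fna"}:
        return read_fasta(path)
    return read_fastq(path)


def read_alignment_sequences(path: str | Path) -> list[SequenceRecord]:
    """Extract read sequences from SAM/BAM, discarding all alignment info.

    Reverse-strand alignments are returned as stored (the detector scans
    both orientations anyway); secondary/supplementary records are skipped
    so each read contributes once.
    """
    out: list[SequenceRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_sequence:
                out.append(SequenceRecord(rec.query_name, rec.query_sequence.upper(), ""))
    return out


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality or "?" * len(rec.sequence)
            fh.write(f"@{rec.name}\n{rec.sequence}\n+\n{qual}\n")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n{rec.sequence}\n")
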