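"""Sequence utilities and FASTA/FASTQ io.

Internal convention: all sequences are stored uppercase in the DNA alphabet
(T, not U) and all coordinates are 0-based half-open.  Conversion to the RNA
alphabet happens only at report boundaries (miRNA sequences in tables, the
substitution spectrum, the NTA profile).
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def to_rna(seq: str) -> str:
    """DNA -> RNA alphabet (report-time conversion)."""
    return seq.replace("T", "U").replace("t", "u")


def to_dna(seq: str) -> str:
    """Accept RNA or DNA input (e.g. miRBase mature files) and normalise."""
    return seq.upper().replace("U", "T")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase DNA sequence} dict.

    RNA-alphabet input (miRBase dialect) is converted to DNA.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = to_dna(str(rec.seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality string) from a Sanger-quality FASTQ.

    A malformed record raises ValueError naming the (0-based) record index.
    """
    idx = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield (
                rec.id,
                str(rec.seq).upper(),
                "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]),
            )
            idx += 1
    except ValueError as err:
        raise ValueError(f"malformed FASTQ record at index {idx}: {err}") from err


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def phred(qual: str) -> list[int]:
    """Sanger-encoded quality string -> list of Phred scores."""
    return [ord(c) - 33 for c in qual]
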