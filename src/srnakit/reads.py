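"""Raw-read cleaning and collapsing into unique tags.

The cleaning cascade applies, in fixed first-failure order:
quality -> 3' adapter -> polyA -> length window.  Every raw read is counted
exactly once, either as clean or under the first filter it fails, so the
discard ledger always balances: raw = clean + sum(discards).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .seqs import phred, read_fastq

FILTERS = ("low_quality", "adapter_only_or_missing", "polyA", "length_out_of_range")


@dataclass(frozen=True)
class CleanTag:
    """A unique clean insert sequence with its read count."""

    sequence: str
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


@dataclass
class LibrarySummary:
    raw_reads: int = 0
    clean_reads: int = 0
    unique_tags: int = 0
    discards: dict[str, int] = field(default_factory=lambda: {f: 0 for f in FILTERS})

    @property
    def clean_fraction(self) -> float:
        return self.clean_reads / self.raw_reads if self.raw_reads else 0.0

    def check(self) -> None:
        if self.raw_reads != self.clean_reads + sum(self.discards.values()):
            raise AssertionError("read accounting does not balance")


def pct(numerator: float, denominator: float) -> float:
    """Report-style percentage, rounded to 2 decimals at report time only."""
    return round(100.0 * numerator / denominator, 2)


def find_adapter(seq: str, adapter3: str, min_prefix: int = 6) -> int:
    """Start of the longest exact adapter-prefix match in ``seq``, or -1.

    Tries prefixes of the adapter from full length down to ``min_prefix`` and
    returns the leftmost occurrence of the longest one found.
    """
    for k in range(len(adapter3), min_prefix - 1, -1):
        pos = seq.find(adapter3[:k])
        if pos != -1:
            return pos
    return -1


def is_polya(insert: str, frac: float = 0.8) -> bool:
    return bool(insert) and insert.count("A") / len(insert) >= frac


def clean_reads(
    reads: Iterable[tuple[str, str, str]],
    adapter3: str,
    min_len: int = 18,
    max_len: int = 30,
    min_quality: int = 20,
    max_low_quality_bases: int = 1,
    polya_fraction: float = 0.8,
) -> tuple[list[str], LibrarySummary]:
    """Clean (id, seq, qual) reads into adapter-trimmed inserts.

    Quality rule: a read with more than ``max_low_quality_bases`` bases below
    Phred ``min_quality`` is discarded as low quality.
    """
    inserts: list[str] = []
    summary = LibrarySummary()
    for _rid, seq, qual in reads:
        summary.raw_reads += 1
        if sum(q < min_quality for q in phred(qual)) > max_low_quality_bases:
            summary.discards["low_quality"] += 1
            continue
        pos = find_adapter(seq, adapter3)
        if pos <= 0:  # no adapter, or adapter-only read (empty insert)
            summary.discards["adapter_only_or_missing"] += 1
            continue
        insert = seq[:pos]
        if is_polya(insert, polya_fraction):
            summary.discards["polyA"] += 1
            continue
        if not min_len <= len(insert) <= max_len:
            summary.discards["length_out_of_range"] += 1
            continue
        inserts.append(insert)
        summary.clean_reads += 1
    summary.unique_tags = len(set(inserts))
    summary.check()
    return inserts, summary


def clean_fastq(path, adapter3: str, **kwargs) -> tuple[list[str], LibrarySummary]:
    return clean_reads(read_fastq(path), adapter3, **kwargs)


def collapse_unique(inserts: Iterable[str]) -> list[CleanTag]:
    """Collapse inserts into unique tags, descending count then lexicographic."""
    counts = Counter(inserts)
    return [
        CleanTag(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def length_distribution(tags: Iterable[CleanTag]) -> dict[int, tuple[int, float]]:
    """Read counts and fractions per insert length; fractions sum to 1."""
    reads_per_len: Counter[int] = Counter()
    for tag in tags:
        reads_per_len[len(tag.sequence)] += tag.count
    total = sum(reads_per_len.values())
    return {
        ln: (n, n / total if total else 0.0) for ln, n in sorted(reads_per_len.items())
    }


def common_specific(tags_a: Iterable[CleanTag], tags_b: Iterable[CleanTag]) -> dict[str, int]:
    """Unique-tag overlap between two libraries."""
    set_a = {t.sequence for t in tags_a}
    set_b = {t.sequence for t in tags_b}
    common = len(set_a & set_b)
    return {"common": common, "A_only": len(set_a) - common, "B_only": len(set_b) - common}


def write_collapsed_fasta(tags: Iterable[CleanTag], path) -> None:
    """Write tags in the common collapsed-FASTA dialect ``>tag{i}_x{count}``."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{tag.count}\n{tag.sequence}\n")


def write_summary_tsv(summaries: dict[str, LibrarySummary], path) -> None:
    with open(path, "w") as fh:
        cols = ["library", "raw_reads", "clean_reads", "clean_pct", "unique_tags", *FILTERS]
        fh.write("\t".join(cols) + "\n")
        for lib, s in summaries.items():
            row = [
                lib,
                s.raw_reads,
                s.clean_reads,
                pct(s.clean_reads, s.raw_reads) if s.raw_reads else 0.0,
                s.unique_tags,
                *[s.discards[f] for f in FILTERS],
            ]
            fh.write("\t".join(str(v) for v in row) + "\n")
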