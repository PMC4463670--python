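"""Genome mapping (<=1 mismatch) and ncRNA category annotation.

The mapper is a deterministic pigeonhole seed-and-verify scheme: a tag with
at most one substitution must match one of its two halves exactly, so exact
half-matches against a k-mer positional index propose candidate loci which
are then verified by Hamming comparison.  Both strands are searched; minus
strand hits are verified against the reverse complement of the tag and
reported with forward-strand coordinates.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .reads import CleanTag, pct
from .seqs import revcomp

CATEGORY_PRIORITY = (
    "rRNA",
    "scRNA",
    "snRNA",
    "snoRNA",
    "tRNA",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
)

# categories whose sense/antisense split is resolved by hit strand
_STRANDED = {"exon": ("exon_sense", "exon_antisense"), "intron": ("intron_sense", "intron_antisense")}

_KNOWN_REF_LABELS = {"rRNA", "scRNA", "snRNA", "snoRNA", "tRNA", "repeat", "exon", "intron", "mRNA_fragment"}


@dataclass(frozen=True)
class MappingHit:
    tag: str
    reference: str
    start: int  # 0-based on the forward strand
    strand: str  # "+" or "-"
    mismatches: int


@dataclass(frozen=True)
class AnnotationRecord:
    tag: str
    category: str  # one of CATEGORY_PRIORITY or "unannotated"


class ReferenceIndex:
    """Positional k-mer index over a set of reference sequences."""

    def __init__(self, references: dict[str, str]):
        self.references = {name: seq.upper() for name, seq in references.items()}
        self._kmer_index: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _index_for(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._kmer_index:
            idx: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for name, seq in self.references.items():
                for i in range(len(seq) - k + 1):
                    idx[seq[i : i + k]].append((name, i))
            self._kmer_index[k] = idx
        return self._kmer_index[k]

    def _candidates(self, query: str) -> set[tuple[str, int]]:
        L = len(query)
        half = L // 2
        cands: set[tuple[str, int]] = set()
        for offset, k in ((0, half), (half, L - half)):
            for name, pos in self._index_for(k).get(query[offset : offset + k], ()):
                start = pos - offset
                if start >= 0 and start + L <= len(self.references[name]):
                    cands.add((name, start))
        return cands

    def map_query(self, tag: str, max_mismatch: int = 1) -> list[MappingHit]:
        """All loci where the tag (either strand) matches with <=max_mismatch."""
        hits = []
        for strand, query in (("+", tag), ("-", revcomp(tag))):
            for name, start in self._candidates(query):
                ref = self.references[name]
                mm = sum(a != b for a, b in zip(query, ref[start : start + len(query)]))
                if mm <= max_mismatch:
                    hits.append(MappingHit(tag, name, start, strand, mm))
        return sorted(hits, key=lambda h: (h.reference, h.start, h.strand))


def map_tags(
    tags: Sequence[CleanTag],
    genome: dict[str, str],
    max_mismatch: int = 1,
    index: ReferenceIndex | None = None,
) -> tuple[dict[str, list[MappingHit]], dict[str, float]]:
    """Map unique tags to the genome; summarize read- and tag-level rates.

    A tag counts as mapped if it has at least one hit anywhere (multi-locus
    tags are counted once).  Summary percentages follow the report convention
    mapped_reads/clean_reads and mapped_unique/total_unique.
    """
    if not genome or not any(genome.values()):
        raise ValueError("genome is empty")
    index = index or ReferenceIndex(genome)
    hits: dict[str, list[MappingHit]] = {}
    mapped_reads = mapped_unique = 0
    total_reads = sum(t.count for t in tags)
    for tag in tags:
        tag_hits = index.map_query(tag.sequence, max_mismatch)
        if tag_hits:
            hits[tag.sequence] = tag_hits
            mapped_unique += 1
            mapped_reads += tag.count
    summary = mapping_percentages(mapped_reads, total_reads, mapped_unique, len(tags))
    summary.update(
        mapped_reads=mapped_reads,
        total_reads=total_reads,
        mapped_unique=mapped_unique,
        total_unique=len(tags),
    )
    return hits, summary


def mapping_percentages(
    mapped_reads: int, clean_reads: int, mapped_unique: int, unique_tags: int
) -> dict[str, float]:
    """Mapping-report percentages from the four library-level counts."""
    return {
        "mapped_reads_pct": pct(mapped_reads, clean_reads),
        "mapped_unique_pct": pct(mapped_unique, unique_tags),
    }


def annotate_tags(
    tags: Sequence[CleanTag],
    category_references: dict[str, dict[str, str]],
    max_mismatch: int = 1,
) -> list[AnnotationRecord]:
    """Assign each tag to exactly one ncRNA/genomic category.

    ``category_references`` maps a reference label (rRNA, tRNA, ..., exon,
    intron; ``mRNA_fragment`` is accepted as an alias for exon) to its
    {name: sequence} references.  A tag matches a category when it is a
    substring of a reference with <=max_mismatch substitutions on either
    strand; the first matching category in the fixed priority order wins and
    strand resolves the sense/antisense split for exon/intron classes.
    """
    for label in category_references:
        if label not in _KNOWN_REF_LABELS:
            raise ValueError(f"unknown category label in references: {label!r}")

    refs = {("exon" if lab == "mRNA_fragment" else lab): seqs for lab, seqs in category_references.items()}
    indexes = {lab: ReferenceIndex(seqs) for lab, seqs in refs.items() if seqs}

    def _category(seq: str) -> str:
        matched: dict[str, set[str]] = {}
        for lab, index in indexes.items():
            strands = {h.strand for h in index.map_query(seq, max_mismatch)}
            if strands:
                matched[lab] = strands
        for cat in CATEGORY_PRIORITY:
            base = cat.split("_")[0]
            if base in _STRANDED:
                sense, antisense = _STRANDED[base]
                strands = matched.get(base, set())
                if cat == sense and "+" in strands:
                    return cat
                if cat == antisense and strands == {"-"}:
                    return cat
            elif cat in matched:
                return cat
        return "unannotated"

    return [AnnotationRecord(t.sequence, _category(t.sequence)) for t in tags]


def retain_for_mirna(
    records: Iterable[AnnotationRecord], tags: Sequence[CleanTag]
) -> list[CleanTag]:
    """Tags left unannotated by every ncRNA/genomic category."""
    unannotated = {r.tag for r in records if r.category == "unannotated"}
    return [t for t in tags if t.sequence in unannotated]


def annotation_summary(
    records: Iterable[AnnotationRecord], tags: Sequence[CleanTag]
) -> dict[str, dict[str, int]]:
    """Unique-tag and read counts per category (Fig-2-style table)."""
    counts = {t.sequence: t.count for t in tags}
    out: dict[str, dict[str, int]] = {}
    for rec in records:
        row = out.setdefault(rec.category, {"unique": 0, "reads": 0})
        row["unique"] += 1
        row["reads"] += counts.get(rec.tag, 0)
    return out
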