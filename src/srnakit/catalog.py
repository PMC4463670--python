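"""Conserved miRNA identification, families, abundance ranks, duplex pairs.

A tag supports a known miRNA when it decomposes against the mature
reference within the identification gate: at most one substitution and 5'/3'
end offsets of at most ``max_shift`` nucleotides each, templated parts lying
on the hairpin.  Candidate matures are proposed by a 6-mer index over the
hairpin windows around each arm, so identification is independent of tag
input order and linear in the number of tags.
"""

from __future__ import annotations

import re
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .isomir import IsomiRRecord, decompose
from .reads import CleanTag
from .seqs import to_rna
from .simulate import ArmAnnotation

_CAND_K = 6  # with <=1 substitution plus a <=4 nt NTA tail on an 18-nt tag,
# the longest clean templated stretch can shrink to 6 nt; a 6-mer probe is
# therefore guaranteed to hit the index for every gateable tag


@dataclass
class MiRNACatalogEntry:
    name: str
    family: str
    arm: str  # 5p / 3p / unknown
    sequence: str  # canonical mature, DNA alphabet
    count_a: int = 0
    count_b: int = 0
    tags: list[str] = field(default_factory=list)
    ambiguous: bool = False

    @property
    def total(self) -> int:
        return self.count_a + self.count_b

    def count(self, library: str) -> int:
        return {"A": self.count_a, "B": self.count_b}[library]


@dataclass(frozen=True)
class DuplexPair:
    hairpin: str
    mature: MiRNACatalogEntry
    star: MiRNACatalogEntry
    overhang_mature3: int  # 3' overhang at the mature strand's 3' end
    overhang_star3: int  # 3' overhang at the star strand's 3' end


def family_name(name: str) -> str:
    """miRNA family from a name: strip species code, arm suffix and variant
    letters/duplicate index; 'mam-miR-199a-3p' -> 'miR-199', 'mam-let-7d' ->
    'let-7'."""
    base = re.sub(r"^[a-z]{3,4}-", "", name).rstrip("*")
    base = re.sub(r"-(5p|3p)$", "", base)
    m = re.match(r"(?i)^(let|mir)-?(\d+)", base)
    if m:
        prefix = "let" if m.group(1).lower() == "let" else "miR"
        return f"{prefix}-{m.group(2)}"
    return base


class MatureIndex:
    """6-mer candidate index over hairpin windows around each mature arm."""

    def __init__(
        self,
        mature: dict[str, str],
        hairpins: dict[str, str] | None,
        arms: dict[str, ArmAnnotation] | None,
        max_shift: int = 4,
    ):
        self.mature = mature
        self.context: dict[str, tuple[str | None, tuple[int, int] | None]] = {}
        self.kmers: dict[str, set[str]] = defaultdict(set)
        arm_of: dict[str, tuple[str, int, int]] = {}
        for hp, arm in (arms or {}).items():
            arm_of[arm.mature_name] = (hp, arm.mature_start, arm.mature_end)
            if arm.star_name:
                arm_of[arm.star_name] = (hp, arm.star_start, arm.star_end)
        for name, seq in mature.items():
            hp_seq, interval = None, None
            if name in arm_of and hairpins:
                hp, ms, me = arm_of[name]
                hp_seq = hairpins.get(hp)
                if hp_seq is not None and hp_seq[ms:me] == seq:
                    interval = (ms, me)
                else:
                    hp_seq = None
            if hp_seq is None and hairpins is not None:
                # fall back to locating the mature on any hairpin
                for hp, hseq in hairpins.items():
                    pos = hseq.find(seq)
                    if pos != -1:
                        hp_seq, interval = hseq, (pos, pos + len(seq))
                        break
            if hp_seq is None and hairpins is not None:
                warnings.warn(f"mature sequence {name} absent from every hairpin")
            self.context[name] = (hp_seq, interval)
            window = seq
            if hp_seq is not None:
                ms, me = interval
                window = hp_seq[max(0, ms - max_shift) : min(len(hp_seq), me + max_shift)]
            for i in range(len(window) - _CAND_K + 1):
                self.kmers[window[i : i + _CAND_K]].add(name)

    def candidates(self, tag: str) -> set[str]:
        out: set[str] = set()
        for i in range(len(tag) - _CAND_K + 1):
            out |= self.kmers.get(tag[i : i + _CAND_K], set())
        return out


def assign_tags(
    sequences: Iterable[str],
    index: MatureIndex,
    max_mismatch: int = 1,
    max_shift: int = 4,
) -> dict[str, list[IsomiRRecord]]:
    """Decompose each unique tag against every gateable mature reference."""
    out: dict[str, list[IsomiRRecord]] = {}
    for seq in sequences:
        records = []
        for name in sorted(index.candidates(seq)):
            hp_seq, interval = index.context[name]
            rec = decompose(
                seq, name, index.mature[name], hp_seq, interval, max_mismatch, max_shift
            )
            if rec is not None:
                records.append(rec)
        if records:
            out[seq] = records
    return out


def identify_conserved(
    tags_a: Sequence[CleanTag],
    tags_b: Sequence[CleanTag],
    mature: dict[str, str],
    hairpins: dict[str, str] | None = None,
    arms: dict[str, ArmAnnotation] | None = None,
    max_mismatch: int = 1,
    max_shift: int = 4,
) -> tuple[dict[str, MiRNACatalogEntry], dict[str, list[IsomiRRecord]]]:
    """Build the conserved-miRNA catalog from both libraries' clean tags.

    Returns (catalog, assignments); assignments map each supporting tag
    sequence to its isomiR decompositions (one per supported miRNA name).
    A miRNA is identified in a library when its summed supporting-tag count
    there is >= 1.
    """
    counts_a = {t.sequence: t.count for t in tags_a}
    counts_b = {t.sequence: t.count for t in tags_b}
    index = MatureIndex(mature, hairpins, arms, max_shift)
    assignments = assign_tags(
        sorted(set(counts_a) | set(counts_b)), index, max_mismatch, max_shift
    )

    catalog: dict[str, MiRNACatalogEntry] = {}
    for seq in sorted(assignments):
        records = assignments[seq]
        for rec in records:
            name = rec.parent
            if name not in catalog:
                hp_seq, interval = index.context[name]
                if hp_seq is None or interval is None:
                    arm = "unknown"
                else:
                    arm = "5p" if interval[0] < len(hp_seq) / 2 else "3p"
                catalog[name] = MiRNACatalogEntry(
                    name, family_name(name), arm, mature[name]
                )
            entry = catalog[name]
            entry.count_a += counts_a.get(seq, 0)
            entry.count_b += counts_b.get(seq, 0)
            entry.tags.append(seq)
            if len(records) > 1:
                entry.ambiguous = True
    expressed = {
        n: e for n, e in catalog.items() if e.count_a + e.count_b >= 1
    }
    return expressed, assignments


def group_families(catalog: dict[str, MiRNACatalogEntry]) -> dict[str, list[MiRNACatalogEntry]]:
    """Partition catalog entries into miRNA families."""
    out: dict[str, list[MiRNACatalogEntry]] = defaultdict(list)
    for entry in catalog.values():
        out[entry.family].append(entry)
    return dict(out)


def rank_abundance(
    catalog: dict[str, MiRNACatalogEntry], library: str, k: int = 10
) -> tuple[list[MiRNACatalogEntry], float]:
    """Top-k entries in one library and their cumulative fraction of all
    reads mapped to the mature reference set."""
    entries = sorted(catalog.values(), key=lambda e: (-e.count(library), e.name))
    total = sum(e.count(library) for e in entries)
    top = entries[:k]
    frac = sum(e.count(library) for e in top) / total if total else 0.0
    return top, frac


def base_bias(
    tags: Sequence[CleanTag], weighted: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(first-base frequency per tag length, per-position base frequency).

    Rows are normalised over {A, C, G, U}; ``weighted`` uses read counts,
    otherwise each unique tag counts once.
    """
    bases = list("ACGU")
    first: dict[int, dict[str, float]] = defaultdict(lambda: {b: 0.0 for b in bases})
    pos: dict[int, dict[str, float]] = defaultdict(lambda: {b: 0.0 for b in bases})
    for tag in tags:
        w = tag.count if weighted else 1
        seq = to_rna(tag.sequence)
        first[len(seq)][seq[0]] += w
        for i, b in enumerate(seq):
            pos[i + 1][b] += w
    def _norm(table):
        df = pd.DataFrame(table).T.sort_index()[bases]
        return df.div(df.sum(axis=1), axis=0)
    return _norm(first), _norm(pos)


def detect_duplexes(
    catalog: dict[str, MiRNACatalogEntry],
    arms: dict[str, ArmAnnotation],
    hairpins: dict[str, str],
) -> list[DuplexPair]:
    """miRNA:miRNA* pairs: hairpins whose both arms have catalog entries with
    at least one read in either library.  Overhangs follow the ideal fold
    geometry (position i pairs with H-1-i)."""
    pairs = []
    for hp, arm in arms.items():
        if not arm.star_name:
            continue
        m = catalog.get(arm.mature_name)
        s = catalog.get(arm.star_name)
        if m is None or s is None or m.total < 1 or s.total < 1:
            continue
        H = len(hairpins[hp])
        pairs.append(
            DuplexPair(
                hp,
                m,
                s,
                overhang_mature3=arm.star_start - (H - arm.mature_end),
                overhang_star3=arm.mature_start - (H - arm.star_end),
            )
        )
    return pairs


def catalog_table(catalog: dict[str, MiRNACatalogEntry]) -> pd.DataFrame:
    rows = [
        {
            "name": e.name,
            "family": e.family,
            "arm": e.arm,
            "sequence": to_rna(e.sequence),
            "count_A": e.count_a,
            "count_B": e.count_b,
            "n_tags": len(e.tags),
            "ambiguous": e.ambiguous,
        }
        for e in sorted(catalog.values(), key=lambda e: (-e.total, e.name))
    ]
    return pd.DataFrame(
        rows,
        columns=["name", "family", "arm", "sequence", "count_A", "count_B", "n_tags", "ambiguous"],
    )
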