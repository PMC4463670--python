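"""isomiR decomposition against a parent mature miRNA and its hairpin.

A tag supporting a miRNA is explained as the mature sequence with
  * a signed 5' end offset (negative = trimmed, positive = templated
    extension into the hairpin flank),
  * a signed 3' end offset, whose extension part is split into a templated
    run (matching the hairpin continuation) and a non-templated suffix (NTA)
    starting at the first non-matching base,
  * at most one substitution on the overlapping mature region, reported in
    1-based mature coordinates (seed region = positions 2-8).

Among admissible explanations the decomposition minimises
|offset5| + |offset3| + #substitutions, ties broken by smaller |offset5| —
the minimal-edit parsimony convention of isomiR catalogues.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .seqs import to_rna

SEED_RANGE = (2, 8)  # 1-based, inclusive, on the mature sequence


@dataclass(frozen=True)
class IsomiRRecord:
    tag: str
    parent: str
    offset5: int
    offset3: int
    templated3: bool
    nta: str
    substitutions: tuple[tuple[int, str, str], ...]

    @property
    def seed_substitutions(self) -> tuple[tuple[int, str, str], ...]:
        lo, hi = SEED_RANGE
        return tuple(s for s in self.substitutions if lo <= s[0] <= hi)

    @property
    def cost(self) -> int:
        return abs(self.offset5) + abs(self.offset3) + len(self.substitutions)

    def is_canonical(self) -> bool:
        return self.cost == 0


def decompose(
    tag: str,
    parent: str,
    mature: str,
    hairpin: str | None = None,
    interval: tuple[int, int] | None = None,
    max_mismatch: int = 1,
    max_shift: int = 4,
) -> IsomiRRecord | None:
    """Best parsimony decomposition of ``tag`` against one mature miRNA.

    Returns None when no explanation exists within the gate
    (|offsets| <= max_shift, substitutions <= max_mismatch).  When the
    hairpin context is missing the mature sequence itself is the template:
    5' extensions are inadmissible and any 3' extension is non-templated.
    """
    if hairpin is None or interval is None:
        hairpin, interval = mature, (0, len(mature))
    ms, me = interval
    if hairpin[ms:me] != mature:
        raise ValueError("mature sequence is not at the stated hairpin interval")
    L = len(tag)
    best: IsomiRRecord | None = None
    for off5 in sorted(range(-max_shift, max_shift + 1), key=lambda d: (abs(d), -d)):
        s = ms - off5
        if s < 0 or s >= len(hairpin):
            continue
        off3 = (s + L) - me
        if abs(off3) > max_shift:
            continue
        subs: list[tuple[int, str, str]] = []
        nta = ""
        ok = True
        for j in range(L):
            p = s + j
            if nta:
                nta += tag[j]
            elif p < ms:
                if tag[j] != hairpin[p]:  # 5' extension must be templated
                    ok = False
                    break
            elif p < me:
                if tag[j] != mature[p - ms]:
                    subs.append((p - ms + 1, mature[p - ms], tag[j]))
                    if len(subs) > max_mismatch:
                        ok = False
                        break
            elif p < len(hairpin) and tag[j] == hairpin[p]:
                pass  # templated 3' extension
            else:
                nta = tag[j]
        if not ok:
            continue
        rec = IsomiRRecord(
            tag, parent, off5, off3, off3 > 0 and not nta, nta, tuple(subs)
        )
        if best is None or rec.cost < best.cost:
            best = rec
    return best


def classify_isomir(
    tag: str,
    parent: str,
    mature: str,
    hairpin: str | None = None,
    interval: tuple[int, int] | None = None,
    max_mismatch: int = 1,
    max_shift: int = 4,
) -> IsomiRRecord:
    rec = decompose(tag, parent, mature, hairpin, interval, max_mismatch, max_shift)
    if rec is None:
        raise ValueError(f"tag {tag!r} has no decomposition against {parent} within the gate")
    return rec


def reconstruct(
    record: IsomiRRecord,
    mature: str,
    hairpin: str | None = None,
    interval: tuple[int, int] | None = None,
) -> str:
    """Rebuild the tag from its decomposition; must be byte-exact."""
    if hairpin is None or interval is None:
        hairpin, interval = mature, (0, len(mature))
    ms, me = interval
    s = ms - record.offset5
    t = me + record.offset3 - len(record.nta)
    seq = list(hairpin[s:t])
    for pos, _old, new in record.substitutions:
        seq[ms + pos - 1 - s] = new
    return "".join(seq) + record.nta


SUBSTITUTION_TYPES = [
    (a, b) for a, b in product("ACGU", "ACGU") if a != b
]  # 12 ordered base pairs, RNA alphabet


def substitution_spectrum(
    records, seed_only: bool = True
) -> pd.DataFrame:
    """12-type single-nucleotide substitution spectrum over unique tags.

    Counts one unit per (record, substitution); records are unique tags, not
    read-weighted.  Percentages sum to 100 when any substitution exists and
    are reported as 0 otherwise.
    """
    counter: Counter[tuple[str, str]] = Counter()
    for rec in records:
        subs = rec.seed_substitutions if seed_only else rec.substitutions
        for _pos, old, new in subs:
            counter[(to_rna(old), to_rna(new))] += 1
    total = sum(counter.values())
    rows = []
    for old, new in SUBSTITUTION_TYPES:
        n = counter.get((old, new), 0)
        rows.append(
            {
                "substitution": f"{old}to{new}",
                "count": n,
                "percentage": 100.0 * n / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def nta_profile(records) -> dict[str, tuple[int, float]]:
    """First non-templated 3' base profile (RNA alphabet) over records."""
    counter: Counter[str] = Counter()
    for rec in records:
        if rec.nta:
            counter[to_rna(rec.nta[0])] += 1
    total = sum(counter.values())
    return {b: (n, n / total) for b, n in sorted(counter.items())}


def isomir_table(parent: str, records, counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Per-variant table for one precursor, sorted by total count descending.

    ``counts`` maps tag sequence -> (count_A, count_B).
    """
    rows = []
    for rec in records:
        if rec.parent != parent:
            continue
        ca, cb = counts.get(rec.tag, (0, 0))
        rows.append(
            {
                "sequence": to_rna(rec.tag),
                "length": len(rec.tag),
                "count_A": ca,
                "count_B": cb,
                "count": ca + cb,
                "offset5": rec.offset5,
                "offset3": rec.offset3,
                "nta": to_rna(rec.nta),
                "substitutions": ";".join(
                    f"{p}:{to_rna(o)}>{to_rna(n)}" for p, o, n in rec.substitutions
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "sequence", "length", "count_A", "count_B", "count",
            "offset5", "offset3", "nta", "substitutions",
        ],
    )
    return df.sort_values(["count", "sequence"], ascending=[False, True]).reset_index(drop=True)
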