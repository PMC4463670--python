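"""Seed-match target-site scanning on transcript sequences.

Operationalises "strong seed pairing" with the canonical site taxonomy.
With miRNA positions numbered 1..n from the 5' end, the seed core is
positions 2-7; on the transcript (5'->3') a core match is the reverse
complement of those six bases.  Because the duplex is antiparallel, the
match to miRNA position 8 (7mer-m8) sits one base 5' of the core on the
transcript, and the adenine opposite position 1 (7mer-A1) sits immediately
3' of the core; an 8mer has both.  Site ``start`` is the 0-based transcript
position of the 6-nt core, so 8mer sites are a subset of 7mer-m8 sites and
those of 6mer sites, position for position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .seqs import revcomp, to_dna

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class TargetSite:
    mirna: str
    transcript: str
    start: int  # 0-based start of the 6-nt seed core on the transcript
    site_type: str


def scan_targets(
    mirnas: dict[str, str], transcripts: dict[str, str]
) -> list[TargetSite]:
    """All seed-match sites of every type for each miRNA x transcript pair."""
    sites: list[TargetSite] = []
    for name in sorted(mirnas):
        seq = to_dna(mirnas[name])
        if len(seq) < 8:
            continue
        core = revcomp(seq[1:7])  # complement of positions 2-7
        m8 = _COMPLEMENT[seq[7]]  # transcript base pairing miRNA position 8
        for tx_name in sorted(transcripts):
            tx = to_dna(transcripts[tx_name])
            pos = tx.find(core)
            while pos != -1:
                has_m8 = pos >= 1 and tx[pos - 1] == m8
                has_a1 = pos + 6 < len(tx) and tx[pos + 6] == "A"
                sites.append(TargetSite(name, tx_name, pos, "6mer"))
                if has_m8:
                    sites.append(TargetSite(name, tx_name, pos, "7mer-m8"))
                if has_a1:
                    sites.append(TargetSite(name, tx_name, pos, "7mer-A1"))
                if has_m8 and has_a1:
                    sites.append(TargetSite(name, tx_name, pos, "8mer"))
                pos = tx.find(core, pos + 1)
    return sites


def sites_table(sites: Iterable[TargetSite]):
    import pandas as pd

    return pd.DataFrame(
        [
            {"mirna": s.mirna, "transcript": s.transcript, "start": s.start, "site_type": s.site_type}
            for s in sites
        ],
        columns=["mirna", "transcript", "start", "site_type"],
    )
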