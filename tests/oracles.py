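"""Independent brute-force oracles used to pin the package's algorithms.

These deliberately avoid the implementation paths they check: the mapper
oracle is a full Hamming scan over every genome offset, the p-value oracle
sums the conditional count distribution term by term, and the seed-site
oracle re-verifies complementarity base by base.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def hamming_scan(tag: str, references: dict[str, str], max_mismatch: int):
    """All (reference, start, strand, mismatches) loci by exhaustive scan."""
    hits = []
    for strand, query in (("+", tag), ("-", revcomp(tag))):
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        for name, ref in references.items():
            r = np.frombuffer(ref.encode(), dtype=np.uint8)
            n = len(ref) - len(query) + 1
            if n <= 0:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(r, len(query))
            mism = (windows != q).sum(axis=1)
            for start in np.nonzero(mism <= max_mismatch)[0]:
                hits.append((name, int(start), strand, int(mism[start])))
    return sorted(hits)


def ac_pvalue_by_summation(x: int, y: int, n_a: float, n_b: float) -> float:
    """Two-sided Audic-Claverie p by direct summation of
    p(k|x) = (N_B/N_A)^k (x+k)! / (x! k! (1+N_B/N_A)^(x+k+1)),
    with the same canonical conditioning orientation as the package."""
    if (y, n_b) < (x, n_a):
        x, y, n_a, n_b = y, x, n_b, n_a
    r = n_b / n_a
    q = r / (1.0 + r)
    kmax = max(2000, 40 * (x + y + 10))
    k = np.arange(kmax)
    # p(0|x) = (1+r)^-(x+1); p(k+1)/p(k) = q (x+k+1)/(k+1)
    ratios = q * (x + k[:-1] + 1) / (k[:-1] + 1)
    pmf = np.empty(kmax)
    pmf[0] = np.exp(-(x + 1) * np.log1p(r))
    pmf[1:] = pmf[0] * np.cumprod(ratios)
    lower = pmf[: y + 1].sum()
    upper = pmf[y:].sum()
    return min(1.0, 2.0 * min(lower, upper))


def seed_sites_bruteforce(mirnas: dict[str, str], transcripts: dict[str, str]):
    """All seed-match sites by per-base complementarity checks."""

    def pairs(mir_base: str, tx_base: str) -> bool:
        return _COMP[mir_base] == tx_base

    sites = []
    for name in sorted(mirnas):
        mir = mirnas[name].upper().replace("U", "T")
        if len(mir) < 8:
            continue
        for tx_name in sorted(transcripts):
            tx = transcripts[tx_name].upper().replace("U", "T")
            for start in range(len(tx) - 5):
                # core: miRNA positions 2..7 pair tx[start..start+5] antiparallel
                if not all(pairs(mir[1 + i], tx[start + 5 - i]) for i in range(6)):
                    continue
                sites.append((name, tx_name, start, "6mer"))
                has_m8 = start >= 1 and pairs(mir[7], tx[start - 1])
                has_a1 = start + 6 < len(tx) and tx[start + 6] == "A"
                if has_m8:
                    sites.append((name, tx_name, start, "7mer-m8"))
                if has_a1:
                    sites.append((name, tx_name, start, "7mer-A1"))
                if has_m8 and has_a1:
                    sites.append((name, tx_name, start, "8mer"))
    return sorted(sites)
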