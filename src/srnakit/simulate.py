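"""Synthetic two-library small-RNA-seq generator with ground truth.

Emulates a pair of single-end (SE50) small-RNA libraries from two tissues:
reads derive from known hairpin precursors (mature arm, optionally a star
arm with the canonical 2-nt 3' overhang geometry), carry a 3' sequencing
adapter, and are perturbed by configurable isomiR processes — 5'/3'
trimming, templated 3' extension, non-templated 3' additions (uridine
dominant) and seed-region substitutions.  A configurable fraction of reads
comes from contaminating ncRNA classes (rRNA, tRNA, snoRNA, degraded mRNA
fragments) and a fraction is flagged low quality.  A chosen fraction of
miRNAs is truly differential between the two libraries at a fixed log2
fold change.

Everything is driven by one integer seed and is bit-reproducible.  The
generator records complete per-read ground truth so downstream stages can
be tested by exact recovery rather than by eyeballing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqs import DNA_BASES, revcomp, write_fasta, write_fastq

# Illumina TruSeq small-RNA 3' adapter; what follows it on a longer read.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
_POST_ADAPTER = "ATCTCGTATGCCGTCTTCTGCTTG"

_MATURE_OFFSET = 10  # 5' flank length before the mature arm on each hairpin


def _default_contaminants() -> dict[str, float]:
    return {"rRNA": 0.012, "tRNA": 0.008, "snoRNA": 0.005, "mRNA_fragment": 0.005}


def _default_isomir_rates() -> dict[str, float]:
    return {
        "trim5": 0.02,
        "trim3": 0.05,
        "ext3_templated": 0.03,
        "nta3": 0.05,
        "seed_substitution": 0.01,
    }


def _default_nta_weights() -> dict[str, float]:
    # U-dominant non-templated tailing (written as T in the DNA alphabet).
    return {"A": 0.10, "C": 0.05, "G": 0.05, "T": 0.80}


@dataclass
class SimulationConfig:
    n_hairpins: int = 60
    hairpin_len: int = 80
    mature_len_range: tuple[int, int] = (20, 23)
    reads_per_library: int = 100_000
    frac_contaminant: dict[str, float] = field(default_factory=_default_contaminants)
    isomir_rates: dict[str, float] = field(default_factory=_default_isomir_rates)
    nta_base_weights: dict[str, float] = field(default_factory=_default_nta_weights)
    de_fraction: float = 0.10
    de_log2fc: float = 2.0
    star_fraction: float = 0.30
    adapter3: str = DEFAULT_ADAPTER3
    low_quality_fraction: float = 0.005
    read_len: int = 50
    abundance_sigma: float = 0.8  # lognormal spread of per-miRNA abundance
    star_rel_abundance: float = 0.05  # star arm abundance relative to its mature
    seed: int = 0

    def validate(self) -> None:
        if self.n_hairpins < 1:
            raise ValueError("n_hairpins must be >= 1")
        if self.reads_per_library < 1:
            raise ValueError("reads_per_library must be > 0")
        lo, hi = self.mature_len_range
        if not (0 < lo <= hi):
            raise ValueError("invalid mature_len_range")
        # mature and star arms (2-nt overhang geometry) must both fit
        if _MATURE_OFFSET + hi > self.hairpin_len or self.hairpin_len < 2 * (_MATURE_OFFSET + hi) - 2:
            raise ValueError("mature arm interval exceeds hairpin bounds")
        for name, frac in [
            ("de_fraction", self.de_fraction),
            ("star_fraction", self.star_fraction),
            ("low_quality_fraction", self.low_quality_fraction),
            *self.frac_contaminant.items(),
            *self.isomir_rates.items(),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {name} outside [0, 1]")
        if sum(self.frac_contaminant.values()) >= 1.0:
            raise ValueError("contaminant fractions sum to >= 1")
        r = self.isomir_rates
        if r["trim3"] + r["ext3_templated"] + r["nta3"] > 1.0:
            raise ValueError("3' event rates sum to > 1")


@dataclass
class ArmAnnotation:
    """0-based half-open mature/star intervals on one hairpin."""

    hairpin: str
    mature_name: str
    mature_start: int
    mature_end: int
    star_name: str | None = None
    star_start: int = -1
    star_end: int = -1


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    hairpins: dict[str, str]
    mature: dict[str, str]  # includes star sequences, named "<mirna>*"
    arms: dict[str, ArmAnnotation]
    ncrna: dict[str, list[tuple[str, str]]]  # category -> [(id, seq)]

    def hairpin_of(self, mature_name: str) -> str:
        for hp, arm in self.arms.items():
            if arm.mature_name == mature_name or arm.star_name == mature_name:
                return hp
        raise KeyError(mature_name)

    def interval_of(self, mature_name: str) -> tuple[int, int]:
        arm = self.arms[self.hairpin_of(mature_name)]
        if arm.mature_name == mature_name:
            return arm.mature_start, arm.mature_end
        return arm.star_start, arm.star_end

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "hairpin": outdir / "hairpin.fa",
            "mature": outdir / "mature.fa",
            "arms": outdir / "arms.tsv",
            "ncrna": outdir / "ncrna.fa",
            "transcripts": outdir / "transcripts.fa",
        }
        write_fasta(self.genome.items(), paths["genome"])
        write_fasta(self.hairpins.items(), paths["hairpin"])
        write_fasta(self.mature.items(), paths["mature"])
        with open(paths["arms"], "w") as fh:
            fh.write("hairpin_id\tmature_name\tmature_start\tmature_end\tstar_name\tstar_start\tstar_end\n")
            for arm in self.arms.values():
                fh.write(
                    f"{arm.hairpin}\t{arm.mature_name}\t{arm.mature_start}\t{arm.mature_end}\t"
                    f"{arm.star_name or '.'}\t{arm.star_start}\t{arm.star_end}\n"
                )
        ncrna_records = []
        tx_records = []
        for cat, entries in self.ncrna.items():
            for name, seq in entries:
                if cat == "mRNA_fragment":
                    tx_records.append((name, seq))
                else:
                    ncrna_records.append((f"{name} category={cat}", seq))
        write_fasta(ncrna_records, paths["ncrna"])
        write_fasta(tx_records, paths["transcripts"])
        return paths


@dataclass
class ReadEvent:
    """Per-read ground truth: how the read insert was built."""

    read_id: str
    category: str  # "miRNA" or a contaminant class
    parent: str | None  # miRNA name for miRNA-derived reads
    offset5: int = 0  # negative = 5'-trimmed relative to the mature start
    offset3: int = 0  # negative = 3'-trimmed; positive = extension (incl. NTA)
    nta: str = ""  # non-templated 3' suffix, DNA alphabet
    substitutions: tuple[tuple[int, str, str], ...] = ()  # (1-based mature pos, from, to)
    n_events: int = 0  # number of distinct perturbation processes applied
    low_quality: bool = False
    insert: str = ""


@dataclass
class GroundTruth:
    expected_counts: dict[str, tuple[float, float]]  # miRNA -> expected (A, B)
    realized_counts: dict[str, tuple[int, int]]  # miRNA -> drawn (A, B)
    de_labels: dict[str, float]  # miRNA -> true log2(B/A) (0.0 = not DE)
    contaminant_counts: dict[str, tuple[int, int]]
    events: dict[str, ReadEvent]  # read id -> event record

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "truth_mirna.tsv", "w") as fh:
            fh.write("mirna\texpected_A\texpected_B\trealized_A\trealized_B\ttrue_log2fc\n")
            for name, (ea, eb) in self.expected_counts.items():
                ra, rb = self.realized_counts[name]
                fh.write(f"{name}\t{ea:.4f}\t{eb:.4f}\t{ra}\t{rb}\t{self.de_labels.get(name, 0.0)}\n")
        with open(outdir / "truth_events.json", "w") as fh:
            json.dump(
                {rid: dataclasses.asdict(ev) for rid, ev in self.events.items()},
                fh,
                indent=0,
            )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_BASES), size=length))


def _mirna_names(n: int) -> list[str]:
    names = []
    for i in range(n):
        if i < 7:
            names.append(f"mam-let-7{'abcdefg'[i]}")
        else:
            names.append(f"mam-miR-{100 + i}")
    return names


def generate_references(config: SimulationConfig) -> ReferenceBundle:
    """Build the genome surrogate, hairpin/mature FASTA and ncRNA references.

    Each hairpin contains its mature arm as an exact substring on the 5' arm;
    hairpins flagged by ``star_fraction`` additionally carry a star arm placed
    by the canonical duplex geometry (both strands of the fold offset by the
    2-nt 3' overhang), disjoint from the mature arm.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    H = config.hairpin_len
    lo, hi = config.mature_len_range

    names = _mirna_names(config.n_hairpins)
    hairpins: dict[str, str] = {}
    mature: dict[str, str] = {}
    arms: dict[str, ArmAnnotation] = {}
    n_star = int(round(config.star_fraction * config.n_hairpins))
    star_flags = np.zeros(config.n_hairpins, dtype=bool)
    star_flags[:n_star] = True

    for i, name in enumerate(names):
        hp_name = name.replace("miR", "mir").replace("let", "let") + "-hp"
        seq = _random_seq(rng, H)
        mlen = int(rng.integers(lo, hi + 1))
        ms, me = _MATURE_OFFSET, _MATURE_OFFSET + mlen
        arm = ArmAnnotation(hp_name, name, ms, me)
        if star_flags[i]:
            # 2-nt 3' overhangs under the ideal fold pairing i <-> H-1-i
            ss, se = H - me + 2, H - ms + 2
            if se > H or ss < me:
                raise ValueError("mature arm interval exceeds hairpin bounds")
            arm.star_name = name + "*"
            arm.star_start, arm.star_end = ss, se
            mature[arm.star_name] = seq[ss:se]
        hairpins[hp_name] = seq
        mature[name] = seq[ms:me]
        arms[hp_name] = arm

    ncrna: dict[str, list[tuple[str, str]]] = {
        "rRNA": [(f"rRNA-{j+1}", _random_seq(rng, 150)) for j in range(2)],
        "tRNA": [(f"tRNA-{j+1}", _random_seq(rng, 76)) for j in range(4)],
        "snoRNA": [(f"snoRNA-{j+1}", _random_seq(rng, 100)) for j in range(3)],
        "mRNA_fragment": [(f"tx-{j+1}", _random_seq(rng, 400)) for j in range(3)],
    }

    # genome surrogate: hairpins and ncRNA loci separated by intergenic filler
    parts = [_random_seq(rng, 40)]
    for hp_seq in hairpins.values():
        parts.append(hp_seq)
        parts.append(_random_seq(rng, 40))
    for entries in ncrna.values():
        for _, seq in entries:
            parts.append(seq)
            parts.append(_random_seq(rng, 40))
    genome = {"chr1": "".join(parts)}
    return ReferenceBundle(genome, hairpins, mature, arms, ncrna)


def _choose_sub(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in DNA_BASES if b != base]
    return choices[int(rng.integers(0, 3))]


def _draw_nta(rng: np.random.Generator, weights: dict[str, float], exclude: str | None) -> str:
    bases = list(weights)
    w = np.array([weights[b] for b in bases], dtype=float)
    if exclude in bases:
        w = w.copy()
        w[bases.index(exclude)] = 0.0
    if w.sum() == 0:
        raise ValueError("nta_base_weights leave no admissible base")
    w = w / w.sum()
    return bases[int(rng.choice(len(bases), p=w))]


def _perturb_read(
    rng: np.random.Generator,
    config: SimulationConfig,
    hairpin: str,
    ms: int,
    me: int,
) -> tuple[str, int, int, str, tuple, int]:
    """Apply isomiR processes to one mature arm; return insert + event fields."""
    rates = config.isomir_rates
    n_events = 0

    trim5 = 0
    if rng.random() < rates["trim5"]:
        trim5 = int(rng.integers(1, 3))
        n_events += 1

    # 3' end: mutually exclusive process choice
    u = rng.random()
    trim3, ext3, nta = 0, 0, ""
    if u < rates["trim3"]:
        trim3 = int(rng.integers(1, 3))
        n_events += 1
    elif u < rates["trim3"] + rates["ext3_templated"]:
        ext3 = int(rng.integers(1, 3))
        n_events += 1
    elif u < rates["trim3"] + rates["ext3_templated"] + rates["nta3"]:
        nta_len = int(rng.integers(1, 3))
        n_events += 1
    else:
        nta_len = 0

    # keep the insert inside the 18-30 nt size window
    while (me - ms) - trim5 - trim3 < 18 and trim3 > 0:
        trim3 -= 1
    while (me - ms) - trim5 - trim3 < 18 and trim5 > 0:
        trim5 -= 1
    if u < rates["trim3"] and trim3 == 0:
        n_events -= 1

    s = ms + trim5
    t = me - trim3 + ext3
    t = min(t, len(hairpin))
    seq = list(hairpin[s:t])

    if u >= rates["trim3"] + rates["ext3_templated"] and u < sum(
        rates[k] for k in ("trim3", "ext3_templated", "nta3")
    ):
        for k in range(nta_len):
            # first base must differ from the templated continuation (a
            # matching base would be templated by definition); later bases
            # are unconstrained.  If the weights admit no base (all weight
            # on the continuation base), the tail is unobservable: drop it.
            cont = hairpin[t] if (k == 0 and t < len(hairpin)) else None
            try:
                nta += _draw_nta(rng, config.nta_base_weights, cont)
            except ValueError:
                break
        if nta_len and not nta:
            n_events -= 1

    subs: list[tuple[int, str, str]] = []
    if rng.random() < rates["seed_substitution"]:
        # 1-based seed positions 2-8 on the mature, restricted to kept bases
        avail = [p for p in range(2, 9) if trim5 < p <= (me - ms) - trim3]
        if avail:
            pos = int(rng.choice(avail))
            old = hairpin[ms + pos - 1]
            new = _choose_sub(rng, old)
            seq[ms + pos - 1 - s] = new
            subs.append((pos, old, new))
            n_events += 1

    insert = "".join(seq) + nta
    offset5 = -trim5
    offset3 = (t + len(nta)) - me
    return insert, offset5, offset3, nta, tuple(subs), n_events


def simulate_libraries(
    config: SimulationConfig, refs: ReferenceBundle
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], GroundTruth]:
    """Draw two FASTQ libraries (A = IB-like, B = CT-like) plus ground truth.

    Returns (reads_A, reads_B, truth) with reads as (id, seq, qual) tuples.
    """
    config.validate()
    if not refs.mature:
        raise ValueError("empty reference set")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    mirna_names = list(refs.mature)
    primary = [n for n in mirna_names if not n.endswith("*")]
    base = {}
    for name in primary:
        base[name] = float(rng.lognormal(0.0, config.abundance_sigma))
    for name in mirna_names:
        if name.endswith("*"):
            base[name] = base[name[:-1]] * config.star_rel_abundance

    n_de = int(round(config.de_fraction * len(primary)))
    de_idx = rng.choice(len(primary), size=n_de, replace=False)
    de_labels = {name: 0.0 for name in mirna_names}
    for j, idx in enumerate(sorted(de_idx)):
        sign = 1.0 if j % 2 == 0 else -1.0
        de_labels[primary[idx]] = sign * config.de_log2fc

    w_a = np.array([base[n] for n in mirna_names])
    w_b = np.array([base[n] * 2.0 ** de_labels[n] for n in mirna_names])

    contam_cats = list(config.frac_contaminant)
    contam_frac = np.array([config.frac_contaminant[c] for c in contam_cats])
    mirna_share = 1.0 - contam_frac.sum()

    R = config.reads_per_library
    expected: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(mirna_names):
        expected[name] = (
            R * mirna_share * w_a[i] / w_a.sum(),
            R * mirna_share * w_b[i] / w_b.sum(),
        )

    def _draw_library(lib: str, weights: np.ndarray) -> tuple[list, dict, dict]:
        probs = np.concatenate([mirna_share * weights / weights.sum(), contam_frac])
        counts = rng.multinomial(R, probs)
        mirna_counts = dict(zip(mirna_names, counts[: len(mirna_names)]))
        contam_counts = dict(zip(contam_cats, counts[len(mirna_names):]))
        parents = np.repeat(np.arange(len(probs)), counts)
        rng.shuffle(parents)
        reads = []
        for ridx, pidx in enumerate(parents):
            rid = f"{lib}_{ridx:07d}"
            if pidx < len(mirna_names):
                name = mirna_names[pidx]
                hp = refs.hairpins[refs.hairpin_of(name)]
                ms, me = refs.interval_of(name)
                insert, o5, o3, nta, subs, nev = _perturb_read(rng, config, hp, ms, me)
                ev = ReadEvent(rid, "miRNA", name, o5, o3, nta, subs, nev, False, insert)
            else:
                cat = contam_cats[pidx - len(mirna_names)]
                ref_id, ref_seq = refs.ncrna[cat][int(rng.integers(0, len(refs.ncrna[cat])))]
                ln = int(rng.integers(18, min(28, len(ref_seq)) + 1))
                start = int(rng.integers(0, len(ref_seq) - ln + 1))
                insert = ref_seq[start : start + ln]
                if rng.random() < 0.5:
                    insert = revcomp(insert)
                ev = ReadEvent(rid, cat, None, insert=insert)
            low_q = rng.random() < config.low_quality_fraction
            ev.low_quality = low_q
            full = insert + config.adapter3
            filler = (_POST_ADAPTER * 3)[: max(0, config.read_len - len(full))]
            seq = (full + filler)[: config.read_len]
            qual = "I" * len(seq)
            if low_q:
                qual = qual[:2] + "#" * 6 + qual[8:]
            reads.append((rid, seq, qual))
            events[rid] = ev
        return reads, mirna_counts, contam_counts

    events: dict[str, ReadEvent] = {}
    reads_a, cnt_a, contam_a = _draw_library("A", w_a)
    reads_b, cnt_b, contam_b = _draw_library("B", w_b)

    realized = {n: (int(cnt_a[n]), int(cnt_b[n])) for n in mirna_names}
    contam = {c: (int(contam_a[c]), int(contam_b[c])) for c in contam_cats}
    truth = GroundTruth(expected, realized, de_labels, contam, events)
    return reads_a, reads_b, truth


def write_libraries(reads_a, reads_b, outdir) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pa, pb = outdir / "library_A.fastq", outdir / "library_B.fastq"
    write_fastq(reads_a, pa)
    write_fastq(reads_b, pb)
    return pa, pb
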