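"""Conserved-miRNA identification, families, ranks, base bias, duplexes."""

import numpy as np
import pytest

from srnakit.catalog import (
    MiRNACatalogEntry,
    base_bias,
    detect_duplexes,
    family_name,
    group_families,
    identify_conserved,
    rank_abundance,
)
from srnakit.reads import CleanTag, clean_reads, collapse_unique
from srnakit.simulate import ArmAnnotation


def _entry(name, a=0, b=0, seq="ACGT" * 5):
    return MiRNACatalogEntry(name, family_name(name), "5p", seq, a, b)


def test_exact_mature_tag_supports_its_mirna(pristine_sim):
    _cfg, refs, *_ = pristine_sim
    name = next(n for n in refs.mature if not n.endswith("*"))
    seq = refs.mature[name]
    catalog, assign = identify_conserved(
        [CleanTag(seq, 3)], [], refs.mature, refs.hairpins, refs.arms
    )
    assert name in catalog and catalog[name].count_a == 3
    rec = next(r for r in assign[seq] if r.parent == name)
    assert (rec.offset5, rec.offset3) == (0, 0) and not rec.substitutions


def test_two_internal_mismatches_support_nothing(pristine_sim):
    _cfg, refs, *_ = pristine_sim
    name = next(iter(refs.mature))
    seq = list(refs.mature[name])
    for i in (4, 12):
        seq[i] = "ACGT"[("ACGT".index(seq[i]) + 2) % 4]
    catalog, assign = identify_conserved(
        [CleanTag("".join(seq), 1)], [], refs.mature, refs.hairpins, refs.arms
    )
    assert "".join(seq) not in assign


def test_counts_match_truth_exactly_when_unperturbed(pristine_sim):
    cfg, refs, reads_a, reads_b, truth = pristine_sim
    tags_a = collapse_unique(clean_reads(reads_a, cfg.adapter3)[0])
    tags_b = collapse_unique(clean_reads(reads_b, cfg.adapter3)[0])
    catalog, _ = identify_conserved(tags_a, tags_b, refs.mature, refs.hairpins, refs.arms)
    expressed_truth = {
        n for n, (a, b) in truth.realized_counts.items() if a + b >= 1
    }
    assert set(catalog) == expressed_truth
    for name, entry in catalog.items():
        assert (entry.count_a, entry.count_b) == truth.realized_counts[name]


def test_identification_is_order_independent(pristine_sim):
    cfg, refs, reads_a, _b, _t = pristine_sim
    tags = collapse_unique(clean_reads(reads_a, cfg.adapter3)[0])
    cat1, _ = identify_conserved(tags, [], refs.mature, refs.hairpins, refs.arms)
    cat2, _ = identify_conserved(tags[::-1], [], refs.mature, refs.hairpins, refs.arms)
    assert {n: (e.count_a, e.count_b) for n, e in cat1.items()} == {
        n: (e.count_a, e.count_b) for n, e in cat2.items()
    }


@pytest.mark.parametrize(
    "name,family",
    [
        ("mam-let-7a", "let-7"),
        ("mam-let-7f", "let-7"),
        ("mam-miR-199-3p", "miR-199"),
        ("mam-miR-199a-3p", "miR-199"),
        ("mam-miR-206", "miR-206"),
        ("mam-miR-133a-3p", "miR-133"),
        ("mam-miR-21*", "miR-21"),
        ("dre-miR-1-2", "miR-1"),
    ],
)
def test_family_grammar(name, family):
    assert family_name(name) == family


def test_families_partition_catalog():
    catalog = {
        n: _entry(n, 1)
        for n in ("mam-let-7a", "mam-let-7b", "mam-let-7f", "mam-miR-199-3p", "mam-miR-199a-3p")
    }
    fams = group_families(catalog)
    assert set(fams) == {"let-7", "miR-199"}
    assert sum(len(v) for v in fams.values()) == len(catalog)
    assert len(fams["let-7"]) == 3


def test_rank_abundance_fractions():
    one = {"m1": _entry("m1", a=7)}
    top, frac = rank_abundance(one, "A", k=10)
    assert [e.name for e in top] == ["m1"] and frac == 1.0
    two = {"m1": _entry("m1", a=90), "m2": _entry("m2", a=10)}
    top, frac = rank_abundance(two, "A", k=1)
    assert top[0].name == "m1" and frac == pytest.approx(0.9)


def test_rank_abundance_dominant_mirna(small_sim, small_sim_tags):
    cfg, refs, *_ = small_sim
    tags_a, tags_b = small_sim_tags["tags_a"], small_sim_tags["tags_b"]
    catalog, _ = identify_conserved(tags_a, tags_b, refs.mature, refs.hairpins, refs.arms)
    _top, frac = rank_abundance(catalog, "A", k=10)
    ranked = sorted(catalog.values(), key=lambda e: -e.count_a)
    manual = sum(e.count_a for e in ranked[:10]) / sum(e.count_a for e in ranked)
    assert frac == pytest.approx(manual)


def test_base_bias_rows_normalised():
    first, per_pos = base_bias([CleanTag("TGAGGTAGTAGGTTGTATAGTT", 4)])
    assert first.loc[22, "U"] == 1.0
    assert np.allclose(first.sum(axis=1), 1.0)
    assert np.allclose(per_pos.sum(axis=1), 1.0)
    assert per_pos.loc[1, "U"] == 1.0


def test_base_bias_uniform_tags(rng):
    tags = [
        CleanTag("".join(rng.choice(list("ACGT"), 22)) + str(), 1) for _ in range(800)
    ]
    tags = [CleanTag(t.sequence, 1) for t in {t.sequence: t for t in tags}.values()]
    first, _ = base_bias(tags)
    # binomial error: 3 sigma around 0.25 with n=len(tags)
    sd = np.sqrt(0.25 * 0.75 / len(tags))
    assert np.all(np.abs(first.loc[22] - 0.25) < 4 * sd)


def test_duplex_geometry_on_constructed_hairpin():
    # H=60, mature [10,32), star placed with the canonical 2-nt 3' overhangs
    H, ms, me = 60, 10, 32
    ss, se = H - me + 2, H - ms + 2
    hairpin = {"hp1": "A" * H}
    arms = {"hp1": ArmAnnotation("hp1", "mam-miR-500", ms, me, "mam-miR-500*", ss, se)}
    catalog = {
        "mam-miR-500": _entry("mam-miR-500", a=10),
        "mam-miR-500*": _entry("mam-miR-500*", b=2),
    }
    (pair,) = detect_duplexes(catalog, arms, hairpin)
    assert pair.overhang_mature3 == 2 and pair.overhang_star3 == 2
    # reads on one arm only -> no pair
    catalog["mam-miR-500*"] = _entry("mam-miR-500*")
    assert detect_duplexes(catalog, arms, hairpin) == []


def test_star_expression_yields_duplexes(small_sim, small_sim_tags):
    cfg, refs, *_ = small_sim
    catalog, _ = identify_conserved(
        small_sim_tags["tags_a"], small_sim_tags["tags_b"], refs.mature, refs.hairpins, refs.arms
    )
    pairs = detect_duplexes(catalog, refs.arms, refs.hairpins)
    expected = sum(
        1
        for arm in refs.arms.values()
        if arm.star_name
        and arm.mature_name in catalog
        and arm.star_name in catalog
    )
    assert len(pairs) == expected > 0
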