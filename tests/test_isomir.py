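"""isomiR decomposition, round trips, spectra and tail profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from srnakit.isomir import (
    IsomiRRecord,
    classify_isomir,
    decompose,
    isomir_table,
    nta_profile,
    reconstruct,
    substitution_spectrum,
)

HAIRPIN = "CCTAGGTGAGGTAGTAGGTTGTATAGTTGACCTATCTCACTGGGAGATAACTATACAATCTACTGTCTTTCCT"
MS, ME = 6, 28  # mature = TGAGGTAGTAGGTTGTATAGTT (let-7 like)
MATURE = HAIRPIN[MS:ME]


def _rec(tag):
    return classify_isomir(tag, "let-7x", MATURE, HAIRPIN, (MS, ME))


def test_canonical_tag_decomposes_to_identity():
    rec = _rec(MATURE)
    assert (rec.offset5, rec.offset3, rec.nta, rec.substitutions) == (0, 0, "", ())
    assert rec.is_canonical()


def test_nontemplated_tail_detected():
    # hairpin continues with G after the mature arm; a trailing T is NTA
    assert HAIRPIN[ME] == "G"
    rec = _rec(MATURE + "T")
    assert rec.nta == "T" and rec.offset3 == 1 and not rec.templated3
    # trailing G matches the hairpin -> templated extension, no NTA
    rec = _rec(MATURE + "G")
    assert rec.nta == "" and rec.offset3 == 1 and rec.templated3


def test_trims_and_seed_substitution():
    rec = _rec(MATURE[2:])
    assert (rec.offset5, rec.offset3) == (-2, 0)
    rec = _rec(MATURE[:-2])
    assert (rec.offset5, rec.offset3) == (0, -2)
    tag = list(MATURE)
    tag[3] = "C"  # position 4, seed region
    rec = _rec("".join(tag))
    assert rec.substitutions == ((4, MATURE[3], "C"),)
    assert rec.seed_substitutions == rec.substitutions


def test_no_decomposition_outside_gate():
    with pytest.raises(ValueError):
        classify_isomir("ACGT" * 6, "let-7x", MATURE, HAIRPIN, (MS, ME))
    assert decompose(MATURE[6:], "let-7x", MATURE, HAIRPIN, (MS, ME)) is None


def test_parsimony_prefers_single_substitution_over_double_shift():
    tag = list(MATURE)
    tag[7] = "A" if MATURE[7] != "A" else "C"
    rec = _rec("".join(tag))
    assert rec.cost == 1 and len(rec.substitutions) == 1


@settings(derandomize=True, max_examples=120)
@given(
    off5=st.integers(-3, 2),
    ext=st.integers(-3, 3),
    nta_len=st.integers(0, 2),
    sub_pos=st.integers(0, 8),
)
def test_roundtrip_regenerates_tag(off5, ext, nta_len, sub_pos):
    """reconstruct(decompose(tag)) == tag for randomly perturbed variants."""
    if ext < 0 and nta_len:
        nta_len = 0
    nta_len = min(nta_len, 4 - max(ext, 0))  # total 3' offset within the gate
    s = MS - off5
    t = ME + ext
    seq = list(HAIRPIN[s:t])
    if sub_pos >= 2:  # seed substitution at mature position sub_pos
        idx = MS + sub_pos - 1 - s
        seq[idx] = "A" if seq[idx] != "A" else "G"
    nta = ""
    for k in range(nta_len):
        cont = HAIRPIN[t + k]
        nta += "T" if cont != "T" else "C"
    tag = "".join(seq) + nta
    rec = decompose(tag, "let-7x", MATURE, HAIRPIN, (MS, ME))
    assert rec is not None
    assert reconstruct(rec, MATURE, HAIRPIN, (MS, ME)) == tag


def test_classification_without_hairpin_context():
    rec = classify_isomir(MATURE + "T", "let-7x", MATURE)
    assert rec.nta == "T"
    rec = classify_isomir(MATURE + "G", "let-7x", MATURE)
    assert rec.nta == "G"  # no hairpin: any extension is non-templated


def test_spectrum_counts_and_percentages():
    recs = [
        IsomiRRecord("t1", "m", 0, 0, False, "", ((3, "T", "A"),)),
        IsomiRRecord("t2", "m", 0, 0, False, "", ((5, "T", "A"),)),
        IsomiRRecord("t3", "m", 0, 0, False, "", ((4, "G", "A"),)),
        IsomiRRecord("t4", "m", 0, 0, False, "", ((12, "C", "A"),)),  # outside seed
    ]
    spec = substitution_spectrum(recs)
    by = spec.set_index("substitution")
    assert by.loc["UtoA", "count"] == 2
    assert by.loc["UtoA", "percentage"] == pytest.approx(200 / 3)
    assert by.loc["GtoA", "percentage"] == pytest.approx(100 / 3)
    assert spec["percentage"].sum() == pytest.approx(100.0, abs=0.01)
    empty = substitution_spectrum([recs[3]])  # only a non-seed substitution
    assert (empty["percentage"] == 0).all() and empty["count"].sum() == 0


def test_spectrum_uniform_generator_is_flat(rng):
    bases = "ACGU"
    recs = []
    types = [(a, b) for a in bases for b in bases if a != b]
    draws = rng.integers(0, 12, size=2400)
    for i, d in enumerate(draws):
        old, new = types[d]
        recs.append(
            IsomiRRecord(f"t{i}", "m", 0, 0, False, "", ((3, old.replace("U", "T"), new.replace("U", "T")),))
        )
    spec = substitution_spectrum(recs)
    assert np.all(np.abs(spec["percentage"] - 100 / 12) < 3 * 100 * np.sqrt((1 / 12) * (11 / 12) / 2400))


def test_nta_profile_fractions():
    recs = [IsomiRRecord(f"t{i}", "m", 0, 1, False, "T", ()) for i in range(4)]
    recs.append(IsomiRRecord("t9", "m", 0, 1, False, "A", ()))
    prof = nta_profile(recs)
    assert prof["U"] == (4, 0.8) and prof["A"] == (1, 0.2)
    assert nta_profile([]) == {}


def test_nta_profile_matches_generator_weights(small_sim):
    _cfg, _refs, _a, _b, truth = small_sim
    firsts = [ev.nta[0] for ev in truth.events.values() if ev.nta]
    frac_u = firsts.count("T") / len(firsts)
    # generator weight 0.8 on U, renormalised when U is the continuation base
    assert 0.65 <= frac_u <= 0.92


def test_isomir_table_conserves_counts():
    recs = [
        IsomiRRecord(MATURE, "let-7x", 0, 0, False, "", ()),
        IsomiRRecord(MATURE + "T", "let-7x", 0, 1, False, "T", ()),
        IsomiRRecord(MATURE[1:], "let-7x", -1, 0, False, "", ()),
    ]
    counts = {MATURE: (50, 40), MATURE + "T": (5, 3), MATURE[1:]: (2, 0)}
    table = isomir_table("let-7x", recs, counts)
    assert len(table) == 3
    assert table["count"].tolist() == sorted(table["count"], reverse=True)
    assert table["count"].sum() == sum(a + b for a, b in counts.values())
    assert set(table["length"]) == {21, 22, 23}
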