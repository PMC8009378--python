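"""In-silico PCR, pattern classification, and contiguity mapping."""

import numpy as np
import pytest

from bfbsim import (
    GENOTYPES,
    Karyotype,
    PCRPattern,
    PRIMERS,
    SimParams,
    circle_contiguity,
    classify_pattern,
    genotype_colony,
    insilico_pcr,
    repair_break,
    realize_sequence,
    reverse_complement,
    summarize_cohort,
)
from bfbsim.assay import (
    ABSENT,
    REDUCED,
    WILDTYPE,
    make_tile_primers,
    patterns_to_table,
    table_to_patterns,
)
from bfbsim.genome import random_dna


def _event(ref, pathway, seed=0):
    rng = np.random.default_rng(seed)
    while True:
        ev = repair_break(100_000, ref, SimParams(), GENOTYPES["WT"], rng)
        if ev.pathway == pathway:
            return ev


def test_gc_amplicon_is_932bp_on_unrearranged_reference(ref65):
    prods = insilico_pcr(ref65.sequence, PRIMERS["GC1"], PRIMERS["GC2"])
    assert len(prods) == 1
    assert prods[0][2] == 932


def test_hybrid_pair_silent_on_reference_but_amplifies_ssa(ref65):
    assert insilico_pcr(
        ref65.sequence, PRIMERS["GC1"], PRIMERS["eC2"], max_amplicon=6000
    ) == []
    ev = _event(ref65, "SSA")
    seq = realize_sequence(ev.products[0], ref65)
    prods = insilico_pcr(seq, PRIMERS["GC1"], PRIMERS["eC2"])
    assert len(prods) == 1
    # oracle: coordinate arithmetic on the derivative's segment map
    cfg = ref65.config
    expected = (
        cfg.cassette_homology_interval[1] - cfg.cassette_interval[0] + 1
        + cfg.ecen_region_interval[1] - cfg.ecen_homology_interval[1]
    )
    assert prods[0][2] == expected


def test_template_without_sites_yields_no_products():
    rng = np.random.default_rng(0)
    assert insilico_pcr(random_dna(2000, 0.38, rng), PRIMERS["GC1"],
                        PRIMERS["GC2"]) == []


def test_insilico_pcr_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    fwd, rev = PRIMERS["GC1"], PRIMERS["eC2"]
    for trial in range(10):
        seq = list(random_dna(3000, 0.38, rng))
        for site, primer in (
            (int(rng.integers(0, 800)), fwd),
            (int(rng.integers(1000, 1800)), reverse_complement(rev)),
            (int(rng.integers(2000, 2800)), reverse_complement(rev)),
        ):
            seq[site: site + len(primer)] = primer
        template = "".join(seq)

        def occurrences(needle):
            return [i for i in range(len(template) - len(needle) + 1)
                    if template[i: i + len(needle)] == needle]

        expected = set()
        for left, right in ((fwd, rev), (rev, fwd)):
            rc = reverse_complement(right)
            for i in occurrences(left):
                for j in occurrences(rc):
                    if j >= i and j + len(rc) - i <= 6000:
                        expected.add((i + 1, j + len(rc), j + len(rc) - i))
        assert set(insilico_pcr(template, fwd, rev)) == expected


def test_genotype_of_ej_derivative_shows_reduced_parental(ref123):
    ev = _event(ref123, "EJ")
    pat = genotype_colony(Karyotype(ev.products), ref123)
    if ev.deleted_centromere == "GALCEN3":
        assert pat.states["GALCEN3"] == REDUCED
        assert pat.lengths["GALCEN3"] == 932 - ev.deletion_size
        assert pat.states["eCEN3"] == WILDTYPE
    else:
        assert pat.states["eCEN3"] == REDUCED
        assert pat.states["GALCEN3"] == WILDTYPE
    assert not pat.present("rearrangement")
    assert not pat.present("reciprocal")


def test_genotype_of_rco_karyotype_shows_both_hybrids_only(ref463):
    ev = _event(ref463, "RCO")
    pat = genotype_colony(Karyotype(ev.products), ref463)
    assert pat.present("rearrangement") and pat.present("reciprocal")
    assert pat.states["GALCEN3"] == ABSENT
    assert pat.states["eCEN3"] == ABSENT


def test_genotype_of_unbroken_dicentric_is_unrearranged(ref463):
    pat = genotype_colony(ref463.initial_karyotype(), ref463)
    assert classify_pattern(pat) == "unrearranged"


KEY_PATTERNS = [
    # (eCEN3, GALCEN3, rearrangement, reciprocal) -> class
    ((ABSENT, ABSENT, WILDTYPE, WILDTYPE), "HR"),
    ((WILDTYPE, ABSENT, WILDTYPE, ABSENT), "aneuploid"),
    ((ABSENT, WILDTYPE, WILDTYPE, ABSENT), "aneuploid"),
    ((WILDTYPE, WILDTYPE, WILDTYPE, WILDTYPE), "aneuploid"),
    ((ABSENT, ABSENT, WILDTYPE, ABSENT), "SSA"),
    ((WILDTYPE, ABSENT, ABSENT, WILDTYPE), "SSA_plus_EJ"),
    ((WILDTYPE, WILDTYPE, ABSENT, ABSENT), "unrearranged"),
    ((WILDTYPE, REDUCED, ABSENT, ABSENT), "EJ"),
    ((REDUCED, WILDTYPE, ABSENT, ABSENT), "EJ"),
    ((WILDTYPE, ABSENT, ABSENT, ABSENT), "EJ"),
    # patterns outside the key
    ((ABSENT, WILDTYPE, ABSENT, WILDTYPE), "unclassified"),
    ((ABSENT, ABSENT, ABSENT, ABSENT), "unclassified"),
]


@pytest.mark.parametrize("states,expected", KEY_PATTERNS)
def test_decision_key_maps_each_pattern_to_one_class(states, expected):
    ecen, gal, rearr, recip = states
    pat = PCRPattern("x", {
        "eCEN3": ecen, "GALCEN3": gal,
        "rearrangement": rearr, "reciprocal": recip,
    })
    assert classify_pattern(pat) == expected


def test_classifier_is_total_over_all_state_combinations():
    from itertools import product

    classes = set()
    for states in product((ABSENT, WILDTYPE, REDUCED), repeat=4):
        pat = PCRPattern("x", dict(zip(
            ("eCEN3", "GALCEN3", "rearrangement", "reciprocal"), states
        )))
        classes.add(classify_pattern(pat))
    assert classes <= {"HR", "SSA", "EJ", "unrearranged", "aneuploid",
                       "SSA_plus_EJ", "unclassified"}


def test_summarize_uniform_cohort_and_empty_error():
    pats = [
        PCRPattern(f"c{i}", {"rearrangement": WILDTYPE}) for i in range(30)
    ]
    df = summarize_cohort(pats)
    assert df.loc["SSA", "percent"] == 100.0
    assert df["percent"].sum() == pytest.approx(100.0, abs=0.1)
    with pytest.raises(ValueError):
        summarize_cohort([])


def test_end_to_end_pathway_to_class_consistency(ref463):
    expectations = {
        "SSA": "SSA", "RCO": "HR", "EJ": "EJ", "refusion": "unrearranged",
    }
    for pathway, expected in expectations.items():
        ev = _event(ref463, pathway)
        pat = genotype_colony(Karyotype(ev.products), ref463)
        assert classify_pattern(pat) == expected, pathway
    # nondisjunction followed by repair in one copy -> aneuploid
    ev = _event(ref463, "SSA")
    kt = Karyotype(ev.products + tuple(ref463.initial_karyotype()))
    assert classify_pattern(genotype_colony(kt, ref463)) == "aneuploid"


def test_circle_contiguity_full_coverage_and_gap(ref463):
    ev = _event(ref463, "RCO")
    kt = Karyotype(ev.products)
    reports = circle_contiguity(kt, ref463)
    assert len(reports) == 1
    assert reports[0].full_coverage
    assert reports[0].covered_fraction == 1.0
    # linear-only karyotype: nothing to map
    assert circle_contiguity(Karyotype(ev.products[:1]), ref463) == []
    # ablate one tile primer: its amplicon disappears and a gap is reported
    circle = [c for c in ev.products if c.topology == "circular"][0]
    seq = realize_sequence(circle, ref463)
    pairs = make_tile_primers(seq)
    pairs[3] = (pairs[3][0][::-1], pairs[3][1])
    broken = circle_contiguity(kt, ref463, tile_primers=pairs)[0]
    assert not broken.full_coverage
    assert broken.n_amplified == broken.n_tiles - 1
    assert broken.gaps


def test_pattern_table_round_trip(ref123):
    ev = _event(ref123, "EJ")
    pats = [genotype_colony(Karyotype(ev.products), ref123, colony_id="c1"),
            genotype_colony(ref123.initial_karyotype(), ref123,
                            colony_id="c2")]
    back = table_to_patterns(patterns_to_table(pats))
    assert [p.states for p in back] == [p.states for p in pats]
    assert [p.lengths for p in back] == [p.lengths for p in pats]
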