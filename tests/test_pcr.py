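"""In-silico PCR: primer sites, amplicons, genotype calls, origin classes."""

import random
from collections import Counter

import pytest
from hypothesis import given, strategies as st

from sinescan.pcr import (
    GenotypeCall,
    PolymorphismClass,
    PrimerPair,
    TABLE1_GROUPS,
    classify_polymorphism,
    count_classes,
    find_primer_sites,
    genotype,
    load_genotype_table,
    predict_amplicons,
    presence_rows,
    species_presence,
)
from sinescan.seqio import GenomeSet, revcomp
from sinescan.simulate import (
    random_element,
    random_sequence,
    simulate_insertion_site_panel,
)

from .oracles import enumerate_amplicons, scan_primer_sites


def test_primer_sites_present_and_absent():
    template = random_sequence(400, 1)
    primer = template[100:120]
    sites = find_primer_sites(template, primer)
    assert 100 in sites["+"]
    absent = find_primer_sites(template, "T" * 25)
    assert absent == {"+": [], "-": []}


@given(st.integers(0, 2 ** 31 - 1))
def test_primer_sites_match_sliding_window_oracle(seed):
    rng = random.Random(seed)
    template = "".join(rng.choice("ACGT") for _ in range(300))
    primer = template[rng.randint(0, 280):][:18]
    sites = find_primer_sites(template, primer)
    assert sites["+"] == scan_primer_sites(template, primer)
    assert sites["-"] == scan_primer_sites(template, revcomp(primer))


def test_full_site_is_empty_plus_element():
    """Inserting the 181-bp element between the primer sites of a 218-bp
    empty-site product yields a 399-bp full-site product."""
    template = random_sequence(700, 2)
    fwd = template[100:122]
    rev = revcomp(template[296:318])  # empty product spans [100, 318) = 218
    pair = PrimerPair("p", "g", fwd, rev)
    empty = predict_amplicons("t", template, pair)
    assert [a.length for a in empty] == [218]
    element = random_element(181, seed=5).sequence
    full_template = template[:200] + element + template[200:]
    full = predict_amplicons("t", full_template, pair)
    assert [a.length for a in full] == [399]


def test_wrong_orientation_gives_no_product():
    template = random_sequence(500, 3)
    fwd = template[100:120]
    rev = template[300:320]  # same strand as fwd: divergent primers
    pair = PrimerPair("p", "g", fwd, rev)
    products = predict_amplicons("t", template, pair)
    oracle = enumerate_amplicons(template, fwd, rev, 5000)
    assert {(a.start, a.end) for a in products} == oracle == set()


def test_nested_second_site_yields_two_products():
    template = random_sequence(800, 4)
    fwd = template[100:120]
    rev = revcomp(template[500:520])
    nested = template[:300] + fwd + template[300:]
    pair = PrimerPair("p", "g", fwd, rev)
    products = predict_amplicons("t", nested, pair)
    oracle = enumerate_amplicons(nested, fwd, rev, 5000)
    assert {(a.start, a.end) for a in products} == oracle
    assert len(products) == 2


def test_genotype_matches_planted_panel(consensus):
    presence = {"AA": [False, False], "DD": [True, False],
                "AABB": [False, False], "AABBDD": [True, True]}
    panel, pair, species_of, truth = simulate_insertion_site_panel(
        presence, consensus, rng=21, tsd_len=7)
    calls = genotype(panel, pair, consensus.length,
                     consensus=consensus.sequence)
    for r in truth.itertuples():
        want = GenotypeCall.full if r.carrier else GenotypeCall.empty
        assert calls[r.accession] is want
    row = species_presence(calls, species_of)
    assert row == {"AA": False, "DD": True, "AABB": False, "AABBDD": True}


def test_full_minus_empty_equals_element_plus_tsd(consensus):
    for tsd_len in (0, 9):
        panel, pair, _, _ = simulate_insertion_site_panel(
            {"X": [True], "Y": [False]}, consensus, rng=5, tsd_len=tsd_len)
        full = predict_amplicons("t", panel["X_1"].sequences["locus"], pair)
        empty = predict_amplicons("t", panel["Y_1"].sequences["locus"], pair)
        assert full[0].length - empty[0].length == consensus.length + tsd_len


def test_genotype_no_product_is_none_call():
    pair = PrimerPair("p", "g", "ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA")
    panel = {"acc": GenomeSet("acc", {"c": random_sequence(300, 6)})}
    calls = genotype(panel, pair, 181)
    assert calls["acc"] is GenotypeCall.none


GROUPS = {"AA": "diploid_AA", "BB1": "diploid_BB", "BB2": "diploid_BB",
          "DD": "diploid_DD", "AABB": "tetraploid", "AABBDD": "hexaploid"}


@pytest.mark.parametrize("row,want", [
    # hexaploid-only pattern (printed case 8)
    (dict(AA=False, BB1=False, BB2=False, DD=False, AABB=False, AABBDD=True),
     PolymorphismClass.hexaploid_only),
    # DD-inherited pattern (printed case 27)
    (dict(AA=False, BB1=False, BB2=False, DD=True, AABB=False, AABBDD=True),
     PolymorphismClass.diploid_inherited_DD),
    (dict(AA=True, BB1=True, BB2=True, DD=True, AABB=True, AABBDD=True),
     PolymorphismClass.monomorphic_present),
    (dict(AA=False, BB1=False, BB2=False, DD=False, AABB=True, AABBDD=True),
     PolymorphismClass.tetra_and_hexaploid),
    # tetraploid present, hexaploid missing (printed case 24)
    (dict(AA=False, BB1=False, BB2=False, DD=False, AABB=True, AABBDD=None),
     PolymorphismClass.tetra_and_hexaploid),
    (dict(AA=True, BB1=False, BB2=True, DD=False, AABB=True, AABBDD=True),
     PolymorphismClass.multiple_diploid),
    # tetraploid only, hexaploid observed absent: unnamed pattern
    (dict(AA=False, BB1=False, BB2=False, DD=False, AABB=True, AABBDD=False),
     PolymorphismClass.other),
])
def test_classify_polymorphism_patterns(row, want):
    assert classify_polymorphism(row, GROUPS) is want


def test_classify_polymorphism_missing_group_named():
    with pytest.raises(ValueError, match="AABBDD"):
        classify_polymorphism(dict(AA=True), {"AA": "diploid_AA",
                                              "AABBDD": "hexaploid"})


@given(st.lists(st.sampled_from([True, False, None]), min_size=6, max_size=6))
def test_classify_polymorphism_total_over_patterns(values):
    """Every presence pattern maps to exactly one class, no exceptions."""
    row = dict(zip(GROUPS, values))
    assert classify_polymorphism(row, GROUPS) in PolymorphismClass


def test_packaged_panel_monomorphic_and_intron_counts():
    """The packaged 40-gene genotype panel has 6 monomorphic-present genes
    and 35 insertions located in introns."""
    df = load_genotype_table()
    assert len(df) == 40
    classes = [classify_polymorphism(row, TABLE1_GROUPS)
               for _, row, _ in presence_rows(df)]
    tally = count_classes(classes)
    assert tally[PolymorphismClass.monomorphic_present] == 6
    introns = sum(1 for _, _, loc in presence_rows(df)
                  if loc.strip().lower() == "intron")
    assert introns == 35
    assert count_classes([]) == Counter()


def test_primer_pair_validation():
    with pytest.raises(ValueError):
        PrimerPair("p", "g", "ACGT", "ACGTACGTACGTACGT")
    with pytest.raises(ValueError):
        PrimerPair("p", "g", "ACGTACGTACGTACGNN", "ACGTACGTACGTACGT")
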