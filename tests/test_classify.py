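import itertools

import pytest
from hypothesis import given, settings, strategies as st

from dnabind.classify import (ContactType, TooFewDomains, build_reports,
                              classify_corpus, domain_union,
                              enumerate_possible_modes,
                              family_interaction_class, interaction_mode,
                              mode_label)
from dnabind.contacts import Contact
from dnabind.dna import DnaElement
from dnabind.protein import ProteinElement

CT = list(ContactType)


def make_contact(p_el, d_el, kind="hbond"):
    return Contact(kind, ("A", 1, ""), ("D", 1, ""), 0, 1, 3.0, p_el, d_el)


def make_mode(types, sid="s", dom="d", fam="f"):
    from dnabind.classify import InteractionMode
    return InteractionMode(sid, f"{sid}/i", dom, fam, frozenset(types))


def test_nine_contact_types():
    assert len(ContactType) == 9
    pairs = {(t.protein_element, t.dna_element) for t in ContactType}
    assert pairs == set(itertools.product(ProteinElement, DnaElement))


def test_contact_type_labels():
    assert ContactType.H_MJ.label == "H-Mj"
    assert ContactType.L_BB.label == "L-Bb"
    assert ContactType.from_elements(ProteinElement.HELIX,
                                     DnaElement.MAJOR) is ContactType.H_MJ


def test_enumerate_modes_is_511():
    assert enumerate_possible_modes() == 511


def test_enumerate_modes_single_type():
    assert enumerate_possible_modes(1) == 1


def test_enumerate_matches_exhaustive_subset_count():
    labels = [t.label for t in ContactType]
    subsets = {frozenset(c) for r in range(1, 10)
               for c in itertools.combinations(labels, r)}
    assert len(subsets) == enumerate_possible_modes()


def test_interaction_mode_collapses_duplicates():
    contacts = [make_contact(ProteinElement.HELIX, DnaElement.BACKBONE)
                for _ in range(5)]
    m = interaction_mode("s", "i", "d", "f", contacts)
    assert m.types == frozenset({ContactType.H_BB})


def test_unclassified_dna_atom_discarded():
    contacts = [make_contact(ProteinElement.HELIX, None),
                make_contact(ProteinElement.LOOP, DnaElement.BACKBONE)]
    m = interaction_mode("s", "i", "d", "f", contacts)
    assert m.types == frozenset({ContactType.L_BB})


def test_empty_mode_flagged_non_interacting():
    m = interaction_mode("s", "i", "d", "f", [])
    assert m.non_interacting
    assert m.label == "non-interacting"


def test_mode_label_canonical_order():
    assert mode_label({ContactType.L_MN, ContactType.H_BB}) == "(H-Bb) (L-Mn)"
    assert mode_label({ContactType.L_BB, ContactType.H_MJ, ContactType.H_BB,
                       ContactType.L_MN}) == "(H-Bb) (H-Mj) (L-Bb) (L-Mn)"


def test_domain_union():
    a, b, c = CT[0], CT[1], CT[2]
    m1 = make_mode({a})
    m2 = make_mode({a, b})
    assert domain_union([m1, m2]) == frozenset({a, b})
    assert domain_union([m1]) == frozenset({a})
    with pytest.raises(ValueError):
        domain_union([])


def test_family_class_intersection():
    a, b, c = CT[0], CT[1], CT[2]
    cls = family_interaction_class(
        {"d1": frozenset({a, b}), "d2": frozenset({a, c}),
         "d3": frozenset({a})}, "fam")
    assert cls.characteristic_types == frozenset({a})
    assert not cls.miscellaneous


def test_family_class_miscellaneous():
    cls = family_interaction_class(
        {"d1": frozenset({CT[0]}), "d2": frozenset({CT[1]}),
         "d3": frozenset({CT[2]})}, "fam")
    assert cls.miscellaneous
    assert cls.label == "miscellaneous"


def test_family_class_needs_three_domains():
    with pytest.raises(TooFewDomains, match="too few"):
        family_interaction_class({"d1": frozenset({CT[0]}),
                                  "d2": frozenset({CT[0]})}, "fam")


@settings(max_examples=60, deadline=None)
@given(st.lists(st.lists(st.sets(st.sampled_from(CT), min_size=0,
                                 max_size=9),
                         min_size=1, max_size=4),
                min_size=3, max_size=6))
def test_class_against_brute_force_set_oracle(domains):
    """Intersection-of-unions equals a brute-force check that every
    characteristic type occurs in at least one mode of every domain."""
    unions = {f"d{i}": frozenset().union(*[frozenset(m) for m in modes])
              for i, modes in enumerate(domains)}
    cls = family_interaction_class(unions, "fam")
    for t in ContactType:
        expected = all(any(t in m for m in modes) for modes in domains)
        assert (t in cls.characteristic_types) == expected
    # intersection property: class within every union
    for u in unions.values():
        assert cls.characteristic_types <= u


@settings(max_examples=40, deadline=None)
@given(st.sets(st.sampled_from(CT), min_size=0, max_size=9),
       st.sets(st.sampled_from(CT), min_size=0, max_size=9),
       st.sets(st.sampled_from(CT), min_size=1, max_size=9))
def test_monotonicity(u1, u2, extra):
    """Adding a structure can only grow a union; adding a domain can
    only shrink (or keep) the class."""
    grown = frozenset(u1) | frozenset(extra)
    assert frozenset(u1) <= grown
    base = {"d1": frozenset(u1) | {CT[0]}, "d2": frozenset(u2) | {CT[0]},
            "d3": frozenset(extra) | {CT[0]}}
    cls = family_interaction_class(base, "f")
    bigger = dict(base, d4=frozenset(extra))
    cls2 = family_interaction_class(bigger, "f")
    assert cls2.characteristic_types <= cls.characteristic_types


def test_every_mode_is_an_enumerable_subset():
    all_subsets = {frozenset(c) for r in range(1, 10)
                   for c in itertools.combinations(CT, r)}
    m = make_mode({CT[0], CT[4], CT[8]})
    assert m.types in all_subsets


def test_build_reports_counts():
    a, b = CT[0], CT[3]
    modes = [make_mode({a}, sid="s1", dom="d1", fam="f1"),
             make_mode({a}, sid="s2", dom="d2", fam="f2"),
             make_mode({a, b}, sid="s3", dom="d3", fam="f2")]
    classes, skipped = classify_corpus(modes)
    mode_table, class_table = build_reports(modes, classes)
    shared = next(r for r in mode_table if r["mode"] == mode_label({a}))
    assert shared["n_families"] == 2
    assert shared["n_structures"] == 2
    assert classes == {}            # both families below three domains
    assert set(skipped) == {"f1", "f2"}


def test_build_reports_empty_corpus():
    mode_table, class_table = build_reports([], {})
    assert mode_table == [] and class_table == []


def test_corpus_classification():
    a, b, c = CT[0], CT[1], CT[2]
    modes = []
    for d, types in (("d1", [{a}, {a, b}]), ("d2", [{a, c}]),
                     ("d3", [{a}])):
        for i, t in enumerate(types):
            modes.append(make_mode(t, sid=f"{d}s{i}", dom=d, fam="fam"))
    classes, skipped = classify_corpus(modes)
    assert classes["fam"].characteristic_types == frozenset({a})
    assert classes["fam"].n_domains == 3
    assert classes["fam"].n_structures == 4
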