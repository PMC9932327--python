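"""Morphology loading, synthesis, and path extraction."""

import math

import pytest

from pcseq.morphology import (Compartment, CType, Morphology, MorphologyError,
                              PathError, ReducedSpec, count_by_type,
                              generate_reduced, read_genesis_p, read_swc,
                              straight_path, write_genesis_p, write_swc)


def test_read_swc_three_point_linear(tmp_path):
    p = tmp_path / "lin.swc"
    p.write_text("# comment\n"
                 "1 1 0 0 0 5.0 -1\n"
                 "2 3 10 0 0 1.0 1\n"
                 "3 3 20 0 0 1.0 2\n")
    m = read_swc(p)
    assert len(m) == 3
    assert sum(1 for c in m.compartments if c.parent_id is not None) == 2
    assert m[1].ctype is CType.SOMA and m[2].ctype is CType.SPINY
    assert m[3].length == pytest.approx(10.0)


def test_read_swc_malformed_line_reports_lineno(tmp_path):
    p = tmp_path / "bad.swc"
    p.write_text("1 1 0 0 0 5.0 -1\n2 3 x 0 0 1.0 1\n")
    with pytest.raises(MorphologyError, match=":2"):
        read_swc(p)


def test_read_swc_multiple_roots_rejected(tmp_path):
    p = tmp_path / "two_roots.swc"
    p.write_text("1 1 0 0 0 5.0 -1\n2 1 50 0 0 5.0 -1\n")
    with pytest.raises(MorphologyError, match="root"):
        read_swc(p)


def test_cycle_rejected():
    comps = [
        Compartment(1, None, CType.SOMA, 10, 5),
        Compartment(2, 3, CType.SPINY, 10, 1),
        Compartment(3, 2, CType.SPINY, 10, 1),
    ]
    with pytest.raises(MorphologyError):
        Morphology(comps)


def test_swc_round_trip_preserves_geometry(tmp_path, linear11):
    p1, p2 = tmp_path / "a.swc", tmp_path / "b.swc"
    write_swc(linear11, p1)
    m2 = read_swc(p1, type_map={1: CType.SOMA, 3: CType.SPINY, 4: CType.MAIN})
    write_swc(m2, p2)
    m3 = read_swc(p2, type_map={1: CType.SOMA, 3: CType.SPINY, 4: CType.MAIN})
    assert len(m2) == len(m3) == len(linear11)
    for c2, c3 in zip(m2.compartments, m3.compartments):
        assert c2.parent_id == c3.parent_id
        assert math.isclose(c2.length, c3.length, abs_tol=1e-9)
        assert math.isclose(c2.radius, c3.radius, abs_tol=1e-9)


def test_genesis_p_round_trip_and_counts(tmp_path, linear11):
    p = tmp_path / "m.p"
    write_genesis_p(linear11, p)
    m2 = read_genesis_p(p)
    assert count_by_type(m2) == count_by_type(linear11)
    for c1, c2 in zip(linear11.compartments, m2.compartments):
        assert math.isclose(c1.length, c2.length, rel_tol=1e-5)
        assert math.isclose(c1.radius, c2.radius, rel_tol=1e-5)


def test_genesis_p_two_line_fixture(tmp_path):
    p = tmp_path / "two.p"
    p.write_text("*relative\nsoma none 30 0 0 30\nmain1 soma 40 0 0 6\n")
    m = read_genesis_p(p)
    assert len(m) == 2
    assert m[2].parent_id == 1 and m[2].ctype is CType.MAIN


def test_genesis_p_unknown_parent_rejected(tmp_path):
    p = tmp_path / "orphan.p"
    p.write_text("soma none 30 0 0 30\nspiny1 ghost 40 0 0 2\n")
    with pytest.raises(MorphologyError, match="ghost"):
        read_genesis_p(p)


def test_full_scale_type_counts_via_p_round_trip(tmp_path):
    """A synthetic tree with the full model's layer counts (1 soma, 9 main,
    105 smooth, 1,485 spiny = 1,600 compartments) survives the .p dialect."""
    m = generate_reduced(ReducedSpec(n_main=9, n_smooth=105, n_spiny=1485,
                                     branching=3))
    p = tmp_path / "full_synthetic.p"
    write_genesis_p(m, p)
    m2 = read_genesis_p(p)
    counts = count_by_type(m2)
    assert counts == {CType.SOMA: 1, CType.MAIN: 9, CType.SMOOTH: 105,
                      CType.SPINY: 1485}
    assert sum(counts.values()) == 1600 == len(m2)


def test_generate_reduced_linear_layout(linear11):
    assert [c.ctype for c in linear11.compartments] == (
        [CType.SOMA] + [CType.MAIN] * 2 + [CType.SMOOTH] * 3 + [CType.SPINY] * 5)
    # a chain: every compartment except the root has the previous as parent
    for prev, cur in zip(linear11.compartments, linear11.compartments[1:]):
        assert cur.parent_id == prev.id


def test_generate_reduced_deterministic():
    a = generate_reduced(ReducedSpec(seed=7, jitter=0.1))
    b = generate_reduced(ReducedSpec(seed=7, jitter=0.1))
    assert a.to_json() == b.to_json()
    c = generate_reduced(ReducedSpec(seed=8, jitter=0.1))
    assert a.to_json() != c.to_json()


def test_generate_reduced_branching_limit():
    m = generate_reduced(ReducedSpec(n_main=2, n_smooth=4, n_spiny=12, branching=2))
    for c in m.compartments:
        if c.ctype is CType.SMOOTH:
            assert len(m.children(c.id)) <= 2


def test_generate_reduced_too_small():
    with pytest.raises(MorphologyError):
        generate_reduced(ReducedSpec(n_main=0, n_smooth=0, n_spiny=0))


def test_count_by_type_sums_to_total(reduced_default):
    counts = count_by_type(reduced_default)
    assert sum(counts.values()) == len(reduced_default)
    assert counts[CType.SOMA] == 1


def test_count_by_type_soma_only():
    m = Morphology([Compartment(1, None, CType.SOMA, 30, 15)])
    assert count_by_type(m) == {CType.SOMA: 1, CType.MAIN: 0,
                                CType.SMOOTH: 0, CType.SPINY: 0}


def test_straight_path_single(linear11):
    assert straight_path(linear11, 7, 1) == [7]


def test_straight_path_from_tip_toward_soma(linear11):
    tip = 11
    assert straight_path(linear11, tip, 5, toward_soma=True) == [11, 10, 9, 8, 7]


def test_straight_path_never_includes_soma(linear11):
    with pytest.raises(PathError):
        straight_path(linear11, 2, 3, toward_soma=True)  # only 1 non-soma above


def test_straight_path_largest_radius_branch():
    comps = [
        Compartment(1, None, CType.SOMA, 30, 15),
        Compartment(2, 1, CType.SMOOTH, 40, 2.0),
        Compartment(3, 2, CType.SPINY, 40, 1.0),
        Compartment(4, 2, CType.SPINY, 40, 2.0),
        Compartment(5, 4, CType.SPINY, 40, 1.0),
    ]
    m = Morphology(comps)
    assert straight_path(m, 2, 3, toward_soma=False) == [2, 4, 5]


def test_straight_path_reports_achievable_length(linear11):
    with pytest.raises(PathError, match="only 3"):
        straight_path(linear11, 9, 9, toward_soma=False)


def test_straight_path_consecutive_parent_child(reduced_default):
    tip = max(c.id for c in reduced_default.compartments)
    path = straight_path(reduced_default, tip, 8, toward_soma=True)
    assert len(set(path)) == len(path)
    for a, b in zip(path, path[1:]):
        assert reduced_default[a].parent_id == b


def test_json_round_trip(reduced_default):
    m2 = Morphology.from_json(reduced_default.to_json())
    assert m2.to_json() == reduced_default.to_json()
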