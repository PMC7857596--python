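import pytest

from mesfinder.classify import FamilyCall, SplitMetECall
from mesfinder.formats import GeneFeature
from mesfinder.repertoire import (
    build_repertoire,
    cooccurrence,
    find_operon_pairs,
    sole_synthase,
)


def _call(pid, genome, family, non_enzymatic=False):
    return FamilyCall(
        protein_id=pid, genome_id=genome, family=None if non_enzymatic else family,
        bit_score=300.0, identity=50.0, non_enzymatic=non_enzymatic,
        family_like=family if non_enzymatic else None,
    )


def test_multiple_copies_counted():
    calls = [_call("p1", "g1", "MesB"), _call("p2", "g1", "MesB")]
    matrix = build_repertoire(calls)
    assert matrix.at["g1", "MesB"] == 2


def test_genome_without_calls_gets_zero_row():
    matrix = build_repertoire([_call("p1", "g1", "MesA")], genomes=["g1", "g2"])
    assert matrix.loc["g2"].sum() == 0


def test_non_enzymatic_homolog_not_counted():
    calls = [_call("p1", "g1", "MesB", non_enzymatic=True)]
    matrix = build_repertoire(calls, genomes=["g1"])
    assert matrix.at["g1", "MesB"] == 0


def test_split_mete_counted_once_per_genome():
    split = SplitMetECall("g1", catalytic_id="a", folate_id="b")
    matrix = build_repertoire([], [split])
    assert matrix.at["g1", "SplitMetE"] == 1


def test_duplicate_genome_request_rejected():
    with pytest.raises(ValueError):
        build_repertoire([], genomes=["g1", "g1"])


def test_counts_match_call_totals():
    calls = [
        _call("p1", "g1", "MesB"), _call("p2", "g1", "AcsC"),
        _call("p3", "g2", "MesB"), _call("p4", "g2", "MesB", non_enzymatic=True),
    ]
    matrix = build_repertoire(calls)
    enzymatic = [c for c in calls if not c.non_enzymatic]
    for fam in ("MesB", "AcsC"):
        assert matrix[fam].sum() == sum(1 for c in enzymatic if c.family == fam)


def test_cooccurrence_counts_and_fraction():
    calls = []
    for g, fams in (
        ("g1", ["MesB", "AcsC", "AcsD"]), ("g2", ["MesB", "AcsC", "AcsD"]),
        ("g3", ["MesB", "AcsC", "AcsD"]), ("g4", ["MesB", "AcsC"]),
    ):
        calls += [_call(f"{g}_{f}", g, f) for f in fams]
    matrix = build_repertoire(calls)
    both = cooccurrence(matrix, "MesB", ["AcsC", "AcsD"], mode="all")
    assert (both.numerator, both.denominator) == (3, 4)
    assert both.fraction == pytest.approx(0.75)
    either = cooccurrence(matrix, "MesB", ["AcsC", "AcsD"], mode="any")
    assert either.fraction == pytest.approx(1.0)


def test_cooccurrence_empty_family_is_undefined_not_error():
    matrix = build_repertoire([_call("p1", "g1", "MesA")])
    c = cooccurrence(matrix, "MesD", ["MesX"])
    assert c.denominator == 0 and c.fraction is None


def test_sole_synthase_and_none_category():
    calls = [
        _call("g1_b", "g1", "MesB"),
        _call("g2_d", "g2", "MesD"), _call("g2_h", "g2", "MetH"),
        _call("g3_c", "g3", "AcsC"),  # not a synthase
    ]
    matrix = build_repertoire(calls, genomes=["g1", "g2", "g3"])
    soles = sole_synthase(matrix)
    assert soles["g1"] == "MesB"
    assert soles["g2"] == "MetH"  # MesD without MesX does not count by default
    assert soles["g3"] == "none"


def test_mesd_counts_with_mesx_or_with_switch():
    calls = [_call("g1_d", "g1", "MesD"), _call("g1_x", "g1", "MesX")]
    matrix = build_repertoire(calls, genomes=["g1", "g2"])
    assert sole_synthase(matrix)["g1"] == "MesD"
    calls2 = [_call("g2_d", "g2", "MesD")]
    matrix2 = build_repertoire(calls2, genomes=["g2"])
    assert sole_synthase(matrix2)["g2"] == "none"
    assert sole_synthase(matrix2, mesd_requires_mesx=False)["g2"] == "MesD"


def _feat(gid, start, end, strand, contig="c1", genome="g"):
    return GeneFeature(gid, genome, contig, start, end, strand)


def test_operon_pair_within_gap():
    feats = [_feat("a", 1000, 2000, "+"), _feat("b", 2100, 3000, "+")]
    pairs = find_operon_pairs(feats, {"a"}, {"b"}, max_intergenic_bp=300)
    assert pairs == [("g", "a", "b", 99)]


def test_opposite_strand_blocks_pair():
    feats = [_feat("a", 1000, 2000, "+"), _feat("b", 2100, 3000, "-")]
    assert find_operon_pairs(feats, {"a"}, {"b"}) == []
    assert len(find_operon_pairs(feats, {"a"}, {"b"}, require_same_strand=False)) == 1


def test_intervening_gene_blocks_pair():
    feats = [
        _feat("a", 1000, 2000, "+"),
        _feat("x", 2050, 2080, "+"),
        _feat("b", 2100, 3000, "+"),
    ]
    assert find_operon_pairs(feats, {"a"}, {"b"}) == []


def test_pairs_symmetric_in_sets():
    feats = [_feat("a", 1000, 2000, "+"), _feat("b", 2100, 3000, "+")]
    fwd = find_operon_pairs(feats, {"a"}, {"b"})
    rev = find_operon_pairs(feats, {"b"}, {"a"})
    assert {(p[1], p[2]) for p in fwd} == {(p[2], p[1]) for p in rev}


def test_unknown_ids_reported():
    feats = [_feat("a", 1, 10, "+")]
    with pytest.raises(ValueError, match="ghost"):
        find_operon_pairs(feats, {"a"}, {"ghost"})
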