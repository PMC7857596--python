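import numpy as np
import pytest

from mesfinder.classify import (
    FamilyReference,
    assign_family,
    call_metH,
    catalytic_candidate_ok,
    detect_split_mete,
    folate_candidate_ok,
)
from mesfinder.formats import GeneFeature, ProteinRecord
from mesfinder.references import ARCHITECTURES, FAMILY_IDENTITY_RANGES
from mesfinder.synthetic_data import generate_family_member


def _member(refs, rng, family, identity, status="intact"):
    rec = generate_family_member(
        refs.seeds[family], identity, status, rng, family=family
    )
    return ProteinRecord(f"{family}_test", rec.sequence, genome_id="g")


def test_above_threshold_member_gets_its_family(refs, rng):
    protein = _member(refs, rng, "MesA", 0.6)
    call = assign_family(protein, refs.families)
    assert call.family == "MesA" and call.bit_score >= 174


def test_cross_hit_resolved_by_identity(refs, rng):
    """A MesA protein also exceeds the permissive MesC threshold; the
    disambiguation rule must keep it in MesA (higher identity to its query)."""
    protein = _member(refs, rng, "MesA", 0.55)
    mesa = refs.family("MesA")
    mesc = refs.family("MesC")
    call = assign_family(protein, [mesa, mesc])
    assert call.family == "MesA"
    assert call.disambiguated  # the MesC hit existed and was disregarded


def test_broken_zinc_site_demotes_to_non_enzymatic(refs, rng):
    protein = _member(refs, rng, "MesB", 0.7, status="broken")
    call = assign_family(protein, refs.families)
    assert call.family is None
    assert call.non_enzymatic and call.family_like == "MesB"
    assert call.zinc_verdict.overall == "broken"


def test_decoy_gets_no_family(refs, rng):
    from mesfinder.synthetic_data import _decoy

    protein = ProteinRecord("decoy", _decoy(rng, refs), genome_id="g")
    call = assign_family(protein, refs.families)
    assert call.family is None and not call.non_enzymatic


def test_raising_threshold_never_adds_calls(refs, rng):
    """Family calling is monotone in the threshold."""
    proteins = [
        _member(refs, rng, fam, ident)
        for fam in ("MesA", "MesB", "MesC")
        for ident in (0.45, 0.8)
    ]
    base = refs
    raised = refs.with_thresholds(
        {f.name: f.threshold * 2 for f in refs.families if f.query is not None}
    )
    for p in proteins:
        lo = assign_family(p, base.families)
        hi = assign_family(p, raised.families)
        if hi.family is not None:
            assert lo.family is not None


def test_no_references_rejected(refs, rng):
    with pytest.raises(ValueError):
        assign_family(_member(refs, rng, "MesA", 0.8), [])


def test_metE_requires_full_length(refs, rng):
    """A core-synthase-length protein may hit the full MetE reference but
    must not be called MetE (minimum length policy)."""
    protein = _member(refs, rng, "SplitCat", 0.9)
    call = assign_family(protein, [refs.family("MetE")])
    assert call.family is None


@pytest.mark.parametrize(
    "bits,length,expected",
    [(210.0, 380, True), (210.0, 401, False), (199.9, 380, False), (200.0, 400, True)],
)
def test_catalytic_component_rules(bits, length, expected):
    assert catalytic_candidate_ok(bits, length) is expected


@pytest.mark.parametrize(
    "n_bits,c_bits,length,expected",
    [
        (700.0, 10.0, 350, True),   # clean N-domain hit
        (700.0, 10.0, 401, False),  # too long
        (600.0, 10.0, 350, False),  # below N cutoff
        (700.0, 710.0, 350, False),  # matches both, catalytic wins -> excluded
        (720.0, 700.0, 350, True),   # matches both, N strictly higher -> kept
        (700.0, 700.0, 350, False),  # exact tie is not "strictly higher"
    ],
)
def test_folate_component_rules(n_bits, c_bits, length, expected):
    assert folate_candidate_ok(n_bits, c_bits, length, 650.0, 676.0) is expected


def test_split_detection_on_constructed_genome(refs, rng):
    cat = _member(refs, rng, "SplitCat", 0.8)
    fol = _member(refs, rng, "SplitN", 0.8)
    fol = ProteinRecord("fol", fol.sequence, genome_id="g")
    cat = ProteinRecord("cat", cat.sequence, genome_id="g")
    feats = [
        GeneFeature("cat", "g", "c1", 1000, 2000, "+"),
        GeneFeature("fol", "g", "c1", 2100, 3000, "+"),
    ]
    call = detect_split_mete(
        [cat, fol], refs.seeds["SplitCat"],
        refs.profiles["met_synt_1"], refs.profiles["met_synt_2"], features=feats,
    )
    assert call.present and call.catalytic_id == "cat" and call.folate_id == "fol"
    assert call.adjacent


def test_split_absent_without_folate_component(refs, rng):
    cat = ProteinRecord("cat", _member(refs, rng, "SplitCat", 0.8).sequence, genome_id="g")
    call = detect_split_mete(
        [cat], refs.seeds["SplitCat"],
        refs.profiles["met_synt_1"], refs.profiles["met_synt_2"],
    )
    assert not call.present and call.catalytic_id == "cat"


def test_highest_scoring_catalytic_candidate_kept(refs, rng):
    strong = ProteinRecord("a_strong", _member(refs, rng, "SplitCat", 0.9).sequence, genome_id="g")
    weak = ProteinRecord("b_weak", _member(refs, rng, "SplitCat", 0.6).sequence, genome_id="g")
    call = detect_split_mete(
        [weak, strong], refs.seeds["SplitCat"],
        refs.profiles["met_synt_1"], refs.profiles["met_synt_2"],
    )
    assert call.catalytic_id == "a_strong"


def test_metH_identity_and_coverage(refs, rng):
    seed = refs.seeds["MetH"]
    assert call_metH(seed, seed)
    # a fragment covering half of the reference fails the 80% coverage rule
    half = ProteinRecord("half", seed.sequence[: seed.length // 2], genome_id="g")
    assert not call_metH(half, seed)
    ident = _member(refs, rng, "MetH", 0.8)
    assert call_metH(ident, seed)
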