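import math

import pytest

from mesfinder.formats import ProteinRecord
from mesfinder.references import ARCHITECTURES
from mesfinder.sites import (
    ReferenceSites,
    classify_zinc_site,
    column_information,
    logo_data,
    map_reference_sites,
)

ZINC = (641, 643, 665, 726)


def _obs(pattern):
    return dict(zip(ZINC, pattern))


def test_self_mapping_is_identity(refs):
    scaffold = refs.scaffold
    smap = map_reference_sites(scaffold, refs.scaffold_sites, scaffold)
    for pos in refs.scaffold_sites.all_positions:
        assert smap.mapping[pos] == pos
        assert smap.observed[pos] == scaffold.sequence[pos - 1]


def test_nterminal_extension_shifts_every_position(refs):
    scaffold = refs.scaffold
    extended = ProteinRecord("ext", "M" * 10 + scaffold.sequence)
    smap = map_reference_sites(scaffold, refs.scaffold_sites, extended)
    for pos in refs.scaffold_sites.all_positions:
        assert smap.mapping[pos] == pos + 10


@pytest.mark.parametrize("family", ["MesA", "MesB", "MesC", "MesD"])
def test_scaffold_sites_map_to_family_architecture_positions(refs, family):
    """Aligning the full-length scaffold to each family seed must land the
    zinc and substrate positions exactly where the architecture places them."""
    arch = ARCHITECTURES[family]
    smap = map_reference_sites(refs.scaffold, refs.scaffold_sites, refs.seeds[family])
    for ref_pos, seed_pos in {**arch.zinc, **arch.substrate}.items():
        assert smap.mapping[ref_pos] == seed_pos, (family, ref_pos)


def test_site_position_beyond_reference_rejected():
    ref = ProteinRecord("r", "ACDE")
    sites = ReferenceSites("r", zinc_positions=(1, 2, 3, 10), substrate_positions=())
    with pytest.raises(ValueError, match="beyond"):
        map_reference_sites(ref, sites, ProteinRecord("c", "ACDE"))


@pytest.mark.parametrize(
    "pattern,overall",
    [
        ("HCEC", "intact"),  # canonical zinc ligands
        ("HCDC", "compatible"),  # Asp for Glu665
        ("HHEC", "compatible"),  # His for Cys643
        ("HYEC", "compatible"),  # Tyr for Cys643
        ("HCEN", "compatible"),  # Asn for Cys726
        ("FSHG", "broken"),
        ("YCDQ", "broken"),
        ("YREQ", "broken"),
        ("HCGC", "broken"),  # Gly for Glu665 cannot coordinate zinc
    ],
)
def test_zinc_site_classification(pattern, overall):
    assert classify_zinc_site(_obs(pattern)).overall == overall


def test_unaligned_zinc_position_breaks_verdict():
    verdict = classify_zinc_site({641: "H", 643: "C", 665: "E", 726: None})
    assert verdict.per_site[726] == "unaligned"
    assert verdict.overall == "broken"


def test_verdict_monotone_in_single_site_degradation():
    """Replacing one conserved site by an incompatible residue never
    improves the overall verdict."""
    order = {"intact": 0, "compatible": 1, "broken": 2}
    base = classify_zinc_site(_obs("HCEC"))
    for pos in ZINC:
        worse = dict(_obs("HCEC"))
        worse[pos] = "W"
        assert order[classify_zinc_site(worse).overall] >= order[base.overall]


def test_column_information_closed_forms():
    assert column_information("AAAA") == pytest.approx(math.log2(20))
    assert column_information("ACDEFGHIKLMNPQRSTVWY") == pytest.approx(0.0)
    assert column_information("AACC") == pytest.approx(math.log2(20) - 1)


def test_column_information_ignores_gaps():
    assert column_information("AA--") == pytest.approx(math.log2(20))
    with pytest.raises(ValueError):
        column_information("----")


def test_column_information_bounds(rng):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(50):
        col = "".join(rng.choice(list(aa), size=rng.integers(1, 30)))
        ic = column_information(col)
        assert 0.0 <= ic <= math.log2(20) + 1e-12


def test_logo_heights_sum_to_information():
    heights = logo_data(["AC", "AC", "AG"])
    assert sum(heights[0].values()) == pytest.approx(column_information("AAA"))
    assert sum(heights[1].values()) == pytest.approx(column_information("CCG"))
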