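import numpy as np
import pytest

from mesfinder.classify import assign_family
from mesfinder.formats import ProteinRecord
from mesfinder.pairwise import align_local, percent_identity
from mesfinder.references import ARCHITECTURES, build_reference_set
from mesfinder.repertoire import find_operon_pairs
from mesfinder.sites import classify_zinc_site, map_reference_sites, ReferenceSites
from mesfinder.synthetic_data import (
    GeneEntry,
    GenomeSpec,
    generate_barseq,
    generate_family_member,
    generate_genome,
    generate_panel,
)


def test_target_identity_one_returns_seed(refs, rng):
    member = generate_family_member(refs.seeds["MesA"], 1.0, "intact", rng, family="MesA")
    assert member.sequence == refs.seeds["MesA"].sequence


def test_member_identity_tracks_target(refs, rng):
    """Measured identity to the seed stays within 3 points of the target."""
    seed = refs.seeds["MesB"]
    for _ in range(15):
        member = generate_family_member(seed, 0.4, "intact", rng, family="MesB")
        aln = align_local(seed, ProteinRecord("m", member.sequence))
        assert abs(percent_identity(aln, rounded=False) - 40.0) <= 3.0


def test_broken_member_classifies_broken(refs, rng):
    arch = ARCHITECTURES["MesB"]
    seed = refs.seeds["MesB"]
    member = generate_family_member(seed, 0.7, "broken", rng, family="MesB")
    rec = ProteinRecord("m", member.sequence)
    sites = ReferenceSites(
        seed.protein_id,
        zinc_positions=tuple(arch.zinc[p] for p in sorted(arch.zinc)),
        substrate_positions=(),
    )
    smap = map_reference_sites(seed, sites, rec)
    observed = {
        scaff: smap.observed[arch.zinc[scaff]] for scaff in sorted(arch.zinc)
    }
    assert classify_zinc_site(observed).overall == "broken"


def test_same_seed_gives_identical_output(refs):
    p1, f1, t1 = generate_panel(refs, seed=99, n_genomes=4)
    p2, f2, t2 = generate_panel(refs, seed=99, n_genomes=4)
    assert [(r.protein_id, r.sequence) for r in p1] == [
        (r.protein_id, r.sequence) for r in p2
    ]
    assert f1 == f2
    assert t1.frame().equals(t2.frame())


def test_truth_manifest_consistent_with_files(refs):
    proteins, features, truth = generate_panel(refs, seed=5, n_genomes=4)
    pids = [p.protein_id for p in proteins]
    assert len(pids) == len(set(pids))
    assert sorted(pids) == sorted(t.protein_id for t in truth.proteins)
    assert sorted(pids) == sorted(f.gene_id for f in features)


def test_operon_layout_recovered(refs, rng):
    spec = GenomeSpec(
        genome_id="g",
        genes=[
            GeneEntry("MesB", operon_group="wl"),
            GeneEntry("AcsC", operon_group="wl"),
            GeneEntry("AcsD", operon_group="wl"),
        ],
        n_decoys=0,
    )
    proteins, features, truths = generate_genome(spec, refs, rng)
    mesb = {t.protein_id for t in truths if t.family == "MesB"}
    acsc = {t.protein_id for t in truths if t.family == "AcsC"}
    pairs = find_operon_pairs(features, mesb, acsc, max_intergenic_bp=300)
    assert len(pairs) == 1


def test_empty_spec_gives_empty_genome(refs, rng):
    proteins, features, truths = generate_genome(
        GenomeSpec(genome_id="g", genes=[], n_decoys=0), refs, rng
    )
    assert proteins == [] and features == [] and truths == []


def test_decoy_genomes_stay_clean(refs, rng):
    """Shuffled decoys should essentially never reach a synthase threshold."""
    synthases = {"MesA", "MesB", "MesC", "MesD", "MetE", "MetH", "SplitCat"}
    clean = 0
    n_genomes = 8
    for g in range(n_genomes):
        proteins, _, _ = generate_genome(
            GenomeSpec(genome_id=f"g{g}", genes=[], n_decoys=8), refs, rng
        )
        calls = [assign_family(p, refs.families) for p in proteins]
        if not any(c.family in synthases for c in calls):
            clean += 1
    assert clean >= n_genomes - 1


def test_barseq_neutral_genes_keep_abundance(rng):
    truth = {f"g{i}": 0.0 for i in range(50)}
    table = generate_barseq(truth, rng, n_strains_per_gene=4, depth=200_000)
    before = table.counts["before"].sum()
    after = table.counts["after"].sum()
    ratio = table.counts["after"].mean() / table.counts["before"].mean()
    assert 0.97 <= ratio <= 1.03
    assert before > 0 and after > 0


def test_barseq_strong_depletion_direction(rng):
    truth = {"dead": -5.0, **{f"n{i}": 0.0 for i in range(20)}}
    table = generate_barseq(truth, rng, n_strains_per_gene=5, depth=100_000)
    dead = [b for b, (g, _) in table.strains.items() if g == "dead"]
    neutral = [b for b, (g, _) in table.strains.items() if g != "dead"]
    dead_ratio = table.counts.loc[dead, "after"].sum() / table.counts.loc[dead, "before"].sum()
    neut_ratio = table.counts.loc[neutral, "after"].sum() / table.counts.loc[neutral, "before"].sum()
    assert dead_ratio < 0.1 * neut_ratio


def test_inter_family_seed_identity_below_30_percent(refs):
    """The four core-family seeds are mutually related at under 30%
    alignment identity, like genuinely distinct families."""
    fams = ["MesA", "MesB", "MesC", "MesD"]
    for i, a in enumerate(fams):
        for b in fams[i + 1 :]:
            aln = align_local(refs.seeds[a], refs.seeds[b])
            assert percent_identity(aln, rounded=False) < 30.0, (a, b)


def test_identity_unreachable_with_pinned_sites_rejected(refs, rng):
    with pytest.raises(ValueError):
        generate_family_member(refs.seeds["MesA"], 0.1, "intact", rng, family="MesA")
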