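"""Miniature genome collections with known truth.

Real screens of this kind run over thousands of reference proteomes; this
module generates a faithful miniature: genomes whose proteomes contain family
members diverged to a controlled identity from the packaged seeds, with
intact or deliberately broken catalytic sites, laid out on a contig with
operon structure (a MesB-like gene next to the corrinoid-protein genes, a
MesD-like gene next to its MesX partner, the two split-MetE components
adjacent), padded with composition-matched shuffled decoys.  Every generated
protein is recorded in a truth manifest so that each pipeline stage can be
scored against ground truth.

The default 50-genome panel mirrors the qualitative structure of the real
taxonomic distribution: MesA in methanogen-like genomes (with and without
the Wood-Ljungdahl genes), MesB only alongside AcsB/AcsC/AcsD and usually in
an operon with AcsC/AcsD, a zinc-site-broken MesB-like subfamily in genomes
that carry another synthase, MesC with the Wood-Ljungdahl genes, MesD always
with MesX and frequently with MetH and/or MetE, split MetE as the sole
synthase of its genomes, plus ordinary MetE/MetH genomes and a few genomes
with no methionine synthase at all.

Sequence evolution is substitution-only (no indels), with substitutions
drawn proportional to BLOSUM62-positive exchange scores; this preserves
alignability by construction, which is what the downstream tests need, and
is the main way these data are easier than real proteomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import CountTable, GeneFeature, ProteinRecord, write_fasta, write_features
from .references import (
    ARCHITECTURES,
    BROKEN_ZINC_PATTERNS,
    FAMILY_IDENTITY_RANGES,
    ReferenceSet,
    mutate_to_identity,
)

#: genome layout defaults (nucleotides)
OPERON_GAP = 60
NON_OPERON_GAP = 500


@dataclass
class ProteinTruth:
    protein_id: str
    genome_id: str
    family: str | None  # None = decoy
    target_identity: float | None
    site_status: str  # intact | broken | n/a
    operon_group: str | None


@dataclass
class SyntheticTruth:
    seed: int
    proteins: list[ProteinTruth] = field(default_factory=list)
    gene_fitness: dict[str, float] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genome_id": t.genome_id,
                    "protein_id": t.protein_id,
                    "family": t.family or "",
                    "target_identity": t.target_identity if t.target_identity else "",
                    "site_status": t.site_status,
                    "operon_group": t.operon_group or "",
                }
                for t in self.proteins
            ]
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# truth manifest\tseed\t{self.seed}\n")
            self.frame().to_csv(fh, sep="\t", index=False)


@dataclass
class GeneEntry:
    """One gene to place in a genome."""

    family: str
    identity: float | None = None  # None: draw from the family's range
    site_status: str = "intact"
    operon_group: str | None = None


@dataclass
class GenomeSpec:
    genome_id: str
    genes: list[GeneEntry] = field(default_factory=list)
    n_decoys: int = 10


def generate_family_member(
    seed_record: ProteinRecord,
    target_identity: float,
    site_status: str,
    rng: np.random.Generator,
    family: str | None = None,
) -> ProteinRecord:
    """A diverged family member with its functional sites held intact or
    replaced by one of the broken zinc patterns (FSHG / YCDQ / YREQ)."""
    name = family or seed_record.protein_id.removesuffix("_seed")
    arch = ARCHITECTURES.get(name)
    pinned: dict[int, str] = {}
    if arch is not None:
        pinned = dict(arch.site_residues)
        if site_status == "broken":
            pattern = BROKEN_ZINC_PATTERNS[rng.integers(0, len(BROKEN_ZINC_PATTERNS))]
            zinc_seed_positions = [arch.zinc[p] for p in sorted(arch.zinc)]
            for pos, res in zip(zinc_seed_positions, pattern):
                pinned[pos] = res
    elif site_status == "broken":
        raise ValueError(f"no site architecture for family {name!r}")
    seq = mutate_to_identity(seed_record.sequence, target_identity, rng, pinned)
    return ProteinRecord(protein_id="member", sequence=seq)


def _decoy(rng: np.random.Generator, refs: ReferenceSet) -> str:
    """Composition-matched decoy: a shuffled family seed."""
    names = sorted(refs.seeds)
    seed = refs.seeds[names[rng.integers(0, len(names))]]
    return "".join(np.array(list(seed.sequence))[rng.permutation(seed.length)])


def generate_genome(
    spec: GenomeSpec,
    refs: ReferenceSet,
    rng: np.random.Generator,
) -> tuple[list[ProteinRecord], list[GeneFeature], list[ProteinTruth]]:
    """Generate one genome: proteome, gene features on one contig, truth.

    Genes belonging to the same ``operon_group`` are placed consecutively on
    the same strand separated by short intergenic gaps; everything else gets
    long gaps and a random strand.
    """
    proteins: list[ProteinRecord] = []
    features: list[GeneFeature] = []
    truths: list[ProteinTruth] = []

    # order genes so operon groups are contiguous, preserving spec order
    ordered: list[GeneEntry] = []
    seen_groups: set[str] = set()
    for entry in spec.genes:
        if entry.operon_group is None:
            ordered.append(entry)
        elif entry.operon_group not in seen_groups:
            seen_groups.add(entry.operon_group)
            ordered.extend(
                e for e in spec.genes if e.operon_group == entry.operon_group
            )

    pos = 1
    prev_group: str | None = None
    strand = "+"
    counter = 0
    for entry in ordered:
        counter += 1
        pid = f"{spec.genome_id}_p{counter:03d}"
        lo, hi = FAMILY_IDENTITY_RANGES[entry.family]
        ident = entry.identity if entry.identity is not None else float(rng.uniform(lo, hi))
        member = generate_family_member(
            refs.seeds[entry.family], ident, entry.site_status, rng, family=entry.family
        )
        rec = ProteinRecord(pid, member.sequence, genome_id=spec.genome_id)
        proteins.append(rec)
        truths.append(
            ProteinTruth(
                protein_id=pid,
                genome_id=spec.genome_id,
                family=entry.family,
                target_identity=round(ident, 3),
                site_status=entry.site_status if entry.family in ARCHITECTURES else "n/a",
                operon_group=entry.operon_group,
            )
        )
        same_operon = entry.operon_group is not None and entry.operon_group == prev_group
        if not same_operon:
            strand = "+" if rng.random() < 0.5 else "-"
            gap = NON_OPERON_GAP if features else 0
        else:
            gap = OPERON_GAP
        start = pos + gap
        end = start + 3 * rec.length + 2  # CDS length incl. stop
        features.append(
            GeneFeature(
                gene_id=pid, genome_id=spec.genome_id, contig="contig1",
                start=start, end=end, strand=strand,
            )
        )
        pos = end
        prev_group = entry.operon_group

    for _ in range(spec.n_decoys):
        counter += 1
        pid = f"{spec.genome_id}_p{counter:03d}"
        rec = ProteinRecord(pid, _decoy(rng, refs), genome_id=spec.genome_id)
        proteins.append(rec)
        truths.append(
            ProteinTruth(
                protein_id=pid, genome_id=spec.genome_id, family=None,
                target_identity=None, site_status="n/a", operon_group=None,
            )
        )
        start = pos + NON_OPERON_GAP
        end = start + 3 * rec.length + 2
        features.append(
            GeneFeature(
                gene_id=pid, genome_id=spec.genome_id, contig="contig1",
                start=start, end=end, strand="+" if rng.random() < 0.5 else "-",
            )
        )
        pos = end
    return proteins, features, truths


def default_panel_specs(n_genomes: int = 50) -> list[GenomeSpec]:
    """The default study panel: archetype mixture mirroring the qualitative
    taxonomic structure of the real distribution (proportions fixed)."""
    archetypes: list[tuple[str, list[GeneEntry], int]] = [
        ("mesA_wl", [
            GeneEntry("MesA"),
            GeneEntry("AcsB", operon_group="acs"),
            GeneEntry("AcsC", operon_group="acs"),
            GeneEntry("AcsD", operon_group="acs"),
        ], 5),
        ("mesA_only", [GeneEntry("MesA")], 3),
        ("mesB_wl", [
            GeneEntry("MesB", operon_group="wl"),
            GeneEntry("AcsC", operon_group="wl"),
            GeneEntry("AcsD", operon_group="wl"),
            GeneEntry("AcsB"),
        ], 7),
        ("mesB_two_copies", [
            GeneEntry("MesB", operon_group="wl"),
            GeneEntry("AcsC", operon_group="wl"),
            GeneEntry("AcsD", operon_group="wl"),
            GeneEntry("MesB"),
            GeneEntry("AcsB"),
        ], 1),
        ("mesB_methanogen", [
            GeneEntry("MesA"),
            GeneEntry("MesB", operon_group="wl"),
            GeneEntry("AcsC", operon_group="wl"),
            GeneEntry("AcsD", operon_group="wl"),
            GeneEntry("AcsB"),
        ], 2),
        ("chloroflexi_like", [
            GeneEntry("MesB", site_status="broken"),
            GeneEntry("MetE"),
            GeneEntry("MetF"),
        ], 3),
        ("mesC_archaeon", [
            GeneEntry("MesC"),
            GeneEntry("AcsC", operon_group="acs"),
            GeneEntry("AcsD", operon_group="acs"),
        ], 4),
        ("mesC_two_copies", [
            GeneEntry("MesC"),
            GeneEntry("MesC"),
            GeneEntry("AcsC", operon_group="acs"),
            GeneEntry("AcsD", operon_group="acs"),
        ], 2),
        ("mesD_metH", [
            GeneEntry("MesD", operon_group="dx"),
            GeneEntry("MesX", operon_group="dx"),
            GeneEntry("MetH"),
        ], 5),
        ("mesD_metH_metE", [
            GeneEntry("MesD", operon_group="dx"),
            GeneEntry("MesX", operon_group="dx"),
            GeneEntry("MetH"),
            GeneEntry("MetE"),
            GeneEntry("MetF"),
        ], 2),
        ("mesD_sole", [
            GeneEntry("MesD", operon_group="dx"),
            GeneEntry("MesX", operon_group="dx"),
        ], 3),
        ("split_mete", [
            GeneEntry("SplitCat", operon_group="split"),
            GeneEntry("SplitN", operon_group="split"),
        ], 6),
        ("metE_bacterium", [GeneEntry("MetE"), GeneEntry("MetF")], 3),
        ("metH_bacterium", [GeneEntry("MetH")], 2),
        ("no_synthase", [], 2),
    ]
    specs: list[GenomeSpec] = []
    i = 0
    while len(specs) < n_genomes:
        for name, genes, count in archetypes:
            for k in range(count):
                if len(specs) >= n_genomes:
                    break
                i += 1
                specs.append(
                    GenomeSpec(
                        genome_id=f"g{i:03d}_{name}",
                        genes=[GeneEntry(e.family, e.identity, e.site_status, e.operon_group)
                               for e in genes],
                    )
                )
    return specs


def generate_panel(
    refs: ReferenceSet,
    seed: int,
    n_genomes: int = 50,
    specs: list[GenomeSpec] | None = None,
) -> tuple[list[ProteinRecord], list[GeneFeature], SyntheticTruth]:
    """Generate the full panel deterministically from one seed."""
    rng = np.random.default_rng(seed)
    specs = default_panel_specs(n_genomes) if specs is None else specs
    proteins: list[ProteinRecord] = []
    features: list[GeneFeature] = []
    truth = SyntheticTruth(seed=seed)
    for spec in specs:
        p, f, t = generate_genome(spec, refs, rng)
        proteins.extend(p)
        features.extend(f)
        truth.proteins.extend(t)
    return proteins, features, truth


def write_panel(
    proteins: list[ProteinRecord],
    features: list[GeneFeature],
    truth: SyntheticTruth,
    out_dir: str | Path,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(proteins, out / "proteomes.faa")
    write_features(features, out / "features.tsv")
    truth.write(out / "truth.tsv")


def generate_barseq(
    true_fitness: dict[str, float],
    rng: np.random.Generator,
    n_strains_per_gene: int = 5,
    depth: int = 500_000,
    samples: tuple[str, ...] = ("after",),
) -> CountTable:
    """Barcode counts for a pooled competitive-growth experiment.

    Each gene gets ``n_strains_per_gene`` strains with uniform insertion
    positions; strain abundance after growth is proportional to the initial
    abundance times 2**fitness; counts are Poisson draws at the given
    sequencing depth for the before sample and each after sample.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    genes = sorted(true_fitness)
    barcodes: list[str] = []
    strains: dict[str, tuple[str | None, float]] = {}
    abundance: list[float] = []
    fit: list[float] = []
    for gene in genes:
        for k in range(n_strains_per_gene):
            bc = f"{gene}_s{k}"
            barcodes.append(bc)
            strains[bc] = (gene, float(rng.uniform(0.0, 1.0)))
            abundance.append(float(rng.uniform(0.5, 1.5)))
            fit.append(true_fitness[gene])
    abundance_arr = np.array(abundance)
    p_before = abundance_arr / abundance_arr.sum()
    counts = {"before": rng.poisson(depth * p_before)}
    for sample in samples:
        after = abundance_arr * np.exp2(fit)
        p_after = after / after.sum()
        counts[sample] = rng.poisson(depth * p_after)
    frame = pd.DataFrame(counts, index=pd.Index(barcodes, name="barcode"))
    return CountTable(strains=strains, counts=frame)
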