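"""End-to-end orchestration of the screen.

One call runs every stage over a genome collection: family classification,
split-MetE detection, the repertoire matrix, co-occurrence statistics,
sole-synthase detection, operon pairs, catalytic-site reports, per-family
logo data, the MesB-relatives tree, and (when counts are provided) gene
fitness.  Every output is a TSV with a header line and a provenance footer
(tool version and a hash of the configuration); the tree is Newick.
"""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (
    FamilyCall,
    SplitMetECall,
    assign_family,
    calls_to_frame,
    detect_split_mete,
    split_calls_to_frame,
)
from .formats import GeneFeature, ProteinRecord, read_counts, read_fasta, read_features
from .fitness import fitness_table
from .msa import progressive_align, trim_blocks, write_alignment_fasta
from .phylo import distance_matrix, neighbor_joining
from .references import ReferenceSet, build_reference_set
from .repertoire import (
    build_repertoire,
    cooccurrence,
    find_operon_pairs,
    sole_synthase,
)
from .sites import ReferenceSites, classify_zinc_site, logo_data, map_reference_sites

CORE_FAMILIES = ("MesA", "MesB", "MesC", "MesD")


@dataclass
class PipelineConfig:
    proteomes: str | None = None  # FASTA; ids must match the feature table
    features: str | None = None  # TSV
    counts: str | None = None  # barcode counts TSV (optional)
    out_dir: str = "out"
    thresholds: dict[str, float] = field(default_factory=dict)
    max_intergenic_bp: int = 300
    mesd_preset: str = "uniprot"
    seed: int = 0
    simulate_genomes: int = 0  # >0: generate a synthetic panel instead

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=index)
        fh.write(f"# mesfinder {__version__} config {cfg.config_hash()}\n")


def _group_by_genome(proteins: list[ProteinRecord]) -> dict[str, list[ProteinRecord]]:
    out: dict[str, list[ProteinRecord]] = defaultdict(list)
    for p in proteins:
        out[p.genome_id].append(p)
    return out


def classify_collection(
    proteins: list[ProteinRecord], refs: ReferenceSet
) -> list[FamilyCall]:
    return [assign_family(p, refs.families) for p in proteins]


def split_collection(
    proteins: list[ProteinRecord],
    refs: ReferenceSet,
    features: list[GeneFeature] | None,
    max_intergenic_bp: int = 300,
) -> list[SplitMetECall]:
    feats_by_genome: dict[str, list[GeneFeature]] = defaultdict(list)
    for f in features or []:
        feats_by_genome[f.genome_id].append(f)
    out = []
    for genome, prots in sorted(_group_by_genome(proteins).items()):
        out.append(
            detect_split_mete(
                prots,
                refs.seeds["SplitCat"],
                refs.profiles["met_synt_1"],
                refs.profiles["met_synt_2"],
                features=feats_by_genome.get(genome),
                catalytic_threshold=refs.family("SplitCat").threshold,
                max_intergenic_bp=max_intergenic_bp,
            )
        )
    return out


def site_report(
    proteins: list[ProteinRecord], calls: list[FamilyCall], refs: ReferenceSet
) -> pd.DataFrame:
    """Zinc and substrate residues of every core-family call (enzymatic or
    not), mapped through alignment to the family seed."""
    by_id = {p.protein_id: p for p in proteins}
    rows = []
    for call in calls:
        fam = call.family or call.family_like
        if fam not in CORE_FAMILIES:
            continue
        arch = refs.architectures[fam]
        seed = refs.seeds[fam]
        sites = ReferenceSites(
            reference_id=seed.protein_id,
            zinc_positions=tuple(arch.zinc[p] for p in sorted(arch.zinc)),
            substrate_positions=tuple(arch.substrate[p] for p in sorted(arch.substrate)),
        )
        smap = map_reference_sites(seed, sites, by_id[call.protein_id])
        observed = {
            scaffold_pos: smap.observed[arch.zinc[scaffold_pos]]
            for scaffold_pos in sorted(arch.zinc)
        }
        verdict = classify_zinc_site(observed)
        row = {
            "genome_id": call.genome_id,
            "protein_id": call.protein_id,
            "family": fam,
            "verdict": verdict.overall,
            "non_enzymatic": call.non_enzymatic,
        }
        for scaffold_pos in sorted(arch.zinc):
            row[f"zinc_{scaffold_pos}"] = smap.observed[arch.zinc[scaffold_pos]] or "."
        for scaffold_pos in sorted(arch.substrate):
            row[f"substrate_{scaffold_pos}"] = (
                smap.observed[arch.substrate[scaffold_pos]] or "."
            )
        rows.append(row)
    return pd.DataFrame(rows)


def family_logos(
    proteins: list[ProteinRecord], calls: list[FamilyCall], refs: ReferenceSet
) -> dict[str, pd.DataFrame]:
    """Per-family logo data from the family's own member alignment."""
    by_id = {p.protein_id: p for p in proteins}
    members: dict[str, list[ProteinRecord]] = defaultdict(list)
    for call in calls:
        if call.family in CORE_FAMILIES and not call.non_enzymatic:
            members[call.family].append(by_id[call.protein_id])
    out: dict[str, pd.DataFrame] = {}
    for fam, recs in sorted(members.items()):
        if len(recs) < 2:
            continue
        msa = progressive_align(recs)
        heights = logo_data(msa.rows)
        rows = []
        for j, col in enumerate(heights):
            for res, h in sorted(col.items()):
                rows.append({"column": j + 1, "residue": res, "height": round(h, 4)})
        out[fam] = pd.DataFrame(rows)
    return out


def mesb_tree(
    proteins: list[ProteinRecord], calls: list[FamilyCall], refs: ReferenceSet
) -> tuple[str, pd.DataFrame] | None:
    """Align MesB members plus zinc-broken MesB-like homologs, trim, and
    build an NJ tree; returns (newick, per-leaf annotation)."""
    by_id = {p.protein_id: p for p in proteins}
    leaves: list[tuple[ProteinRecord, str]] = []
    for call in calls:
        if call.family == "MesB":
            leaves.append((by_id[call.protein_id], "MesB"))
        elif call.family_like == "MesB" and call.non_enzymatic:
            leaves.append((by_id[call.protein_id], "MesB_like_nonenzymatic"))
    if len(leaves) < 3:
        return None
    msa = progressive_align([rec for rec, _ in leaves])
    trimmed = trim_blocks(msa)
    dm = distance_matrix(trimmed)
    newick = neighbor_joining(dm)
    annot = pd.DataFrame(
        [
            {"protein_id": rec.protein_id, "genome_id": rec.genome_id, "group": grp}
            for rec, grp in leaves
        ]
    )
    return newick, annot


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    Deterministic given the configuration (including the seed when
    simulating); output TSVs carry a provenance footer.
    """
    out = Path(config.out_dir)
    refs = build_reference_set(
        thresholds=config.thresholds or None, mesd_preset=config.mesd_preset
    )

    if config.simulate_genomes > 0:
        from .synthetic_data import generate_panel, write_panel

        proteins, features, truth = generate_panel(
            refs, seed=config.seed, n_genomes=config.simulate_genomes
        )
        out.mkdir(parents=True, exist_ok=True)
        write_panel(proteins, features, truth, out)
    else:
        if not config.proteomes:
            raise FileNotFoundError("no proteome FASTA configured and simulation off")
        if not Path(config.proteomes).exists():
            raise FileNotFoundError(f"missing input: {config.proteomes}")
        if config.features and not Path(config.features).exists():
            raise FileNotFoundError(f"missing input: {config.features}")
        out.mkdir(parents=True, exist_ok=True)
        proteins = read_fasta(config.proteomes)
        features = read_features(config.features) if config.features else []
        # genome membership from the feature table when absent from FASTA ids
        gmap = {f.gene_id: f.genome_id for f in features}
        proteins = [
            ProteinRecord(p.protein_id, p.sequence, genome_id=gmap.get(p.protein_id, p.genome_id or "genome"))
            for p in proteins
        ]

    calls = classify_collection(proteins, refs)
    _write_tsv(calls_to_frame(calls), out / "calls.tsv", config)

    splits = split_collection(proteins, refs, features, config.max_intergenic_bp)
    _write_tsv(split_calls_to_frame(splits), out / "split_mete.tsv", config)

    matrix = build_repertoire(calls, splits)
    _write_tsv(matrix.reset_index(), out / "repertoire.tsv", config)

    cooc_rows = []
    for fam, cond, mode in (
        ("MesB", ["AcsC", "AcsD"], "all"),
        ("MesB", ["AcsC", "AcsD"], "any"),
        ("MesC", ["AcsC", "AcsD"], "any"),
        ("MesD", ["MesX"], "all"),
    ):
        c = cooccurrence(matrix, fam, cond, mode=mode)
        cooc_rows.append(
            {
                "family": c.family, "condition": c.condition,
                "numerator": c.numerator, "denominator": c.denominator,
                "fraction": "" if c.fraction is None else round(c.fraction, 4),
            }
        )
    _write_tsv(pd.DataFrame(cooc_rows), out / "cooccurrence.tsv", config)

    soles = sole_synthase(matrix)
    _write_tsv(
        soles.rename_axis("genome_id").reset_index(), out / "sole_synthase.tsv", config
    )

    if features:
        calls_by_family: dict[str, set[str]] = defaultdict(set)
        for c in calls:
            fam = c.family or c.family_like
            if fam:
                calls_by_family[fam].add(c.protein_id)
        operon_rows = []
        for fam_a, fam_b in (("MesB", "AcsC"), ("MesB", "AcsD"), ("MesD", "MesX")):
            for genome, ga, gb, gap in find_operon_pairs(
                features,
                calls_by_family.get(fam_a, set()),
                calls_by_family.get(fam_b, set()),
                max_intergenic_bp=config.max_intergenic_bp,
            ):
                operon_rows.append(
                    {"genome_id": genome, "family_a": fam_a, "family_b": fam_b,
                     "gene_a": ga, "gene_b": gb, "gap_bp": gap}
                )
        _write_tsv(pd.DataFrame(operon_rows), out / "operon_pairs.tsv", config)

    _write_tsv(site_report(proteins, calls, refs), out / "sites.tsv", config)

    for fam, frame in family_logos(proteins, calls, refs).items():
        _write_tsv(frame, out / f"logo_{fam}.tsv", config)

    tree = mesb_tree(proteins, calls, refs)
    if tree is not None:
        newick, annot = tree
        (out / "mesb_tree.nwk").write_text(newick + "\n")
        _write_tsv(annot, out / "mesb_tree_groups.tsv", config)

    if config.counts:
        table = read_counts(config.counts)
        mat = fitness_table(table, before_sample="before")
        _write_tsv(mat.rename_axis("gene_id").reset_index(), out / "fitness.tsv", config)

    return out
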