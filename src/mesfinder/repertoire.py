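"""Genome-level repertoires: presence/absence, co-occurrence, operons.

The family calls of a whole genome collection are collapsed into one row per
genome counting each family's (enzymatic) members.  On top of that matrix the
module answers the comparative-genomics questions of the screen: how often a
family co-occurs with a condition (e.g. corrinoid iron-sulfur protein
subunits AcsC and AcsD in genomes carrying a MesB-like synthase), which
genomes rely on a single methionine-synthase family — or on none — and which
gene pairs sit next to each other on the chromosome like an operon.

"Adjacent" means consecutive genes on the same contig and strand with an
intergenic gap of at most 300 bp by default: the standard operon heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import FamilyCall, SplitMetECall
from .formats import GeneFeature

#: families that satisfy a genome's methionine requirement on their own;
#: MesD is special-cased (active only with MesX)
SYNTHASE_FAMILIES = ("MesA", "MesB", "MesC", "MesD", "MetE", "MetH", "SplitMetE")

#: all columns of a repertoire row
REPERTOIRE_FAMILIES = (
    "MesA", "MesB", "MesC", "MesD", "MesX", "MetE", "MetH",
    "SplitMetE", "MetF", "AcsB", "AcsC", "AcsD",
)


def build_repertoire(
    calls: list[FamilyCall],
    split_calls: list[SplitMetECall] | None = None,
    genomes: list[str] | None = None,
) -> pd.DataFrame:
    """One row per genome with per-family counts of enzymatic calls.

    Non-enzymatic (zinc-broken) homologs are excluded from the counts.
    Split MetE is counted once per genome when both components are present.
    """
    split_calls = split_calls or []
    genome_ids: list[str] = []
    seen = set()
    for c in calls:
        if c.genome_id not in seen:
            seen.add(c.genome_id)
            genome_ids.append(c.genome_id)
    for s in split_calls:
        if s.genome_id not in seen:
            seen.add(s.genome_id)
            genome_ids.append(s.genome_id)
    if genomes is not None:
        extra = [g for g in genomes if g not in seen]
        dupes = [g for g in genomes if genomes.count(g) > 1]
        if dupes:
            raise ValueError(f"duplicate genome rows requested: {sorted(set(dupes))}")
        genome_ids += extra

    rows = pd.DataFrame(
        0, index=pd.Index(genome_ids, name="genome_id"), columns=list(REPERTOIRE_FAMILIES)
    )
    for c in calls:
        if c.family is None or c.non_enzymatic:
            continue
        if c.family == "SplitCat":
            continue  # split MetE is a genome-level call, counted below
        if c.family in rows.columns:
            rows.at[c.genome_id, c.family] += 1
    for s in split_calls:
        if s.present:
            rows.at[s.genome_id, "SplitMetE"] = 1
    return rows


@dataclass(frozen=True)
class Cooccurrence:
    family: str
    condition: str
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float | None:
        """None when no genome carries the family (undefined, not an error)."""
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator


def cooccurrence(
    matrix: pd.DataFrame,
    family: str,
    condition_families: list[str],
    mode: str = "all",
) -> Cooccurrence:
    """Fraction of family-positive genomes that also satisfy a condition
    (``mode="all"``: every condition family present; ``"any"``: at least one).
    """
    if matrix.empty:
        raise ValueError("empty repertoire matrix")
    has_family = matrix[family] > 0
    present = matrix[condition_families] > 0
    cond = present.all(axis=1) if mode == "all" else present.any(axis=1)
    return Cooccurrence(
        family=family,
        condition=f"{mode}({','.join(condition_families)})",
        numerator=int((has_family & cond).sum()),
        denominator=int(has_family.sum()),
    )


def sole_synthase(
    matrix: pd.DataFrame, mesd_requires_mesx: bool = True
) -> pd.Series:
    """Per genome: the single synthase family present, "none" if the genome
    has no methionine synthase at all, or "" when several are present.

    With ``mesd_requires_mesx`` (default) MesD only counts as a synthase in
    genomes that also carry MesX, treating the MesD/MesX pair as the
    functional unit.
    """
    out: dict[str, str] = {}
    for genome, row in matrix.iterrows():
        present = []
        for fam in SYNTHASE_FAMILIES:
            n = row.get(fam, 0)
            if fam == "MesD" and mesd_requires_mesx and row.get("MesX", 0) == 0:
                n = 0
            if n > 0:
                present.append(fam)
        if len(present) == 1:
            out[genome] = present[0]
        elif not present:
            out[genome] = "none"
        else:
            out[genome] = ""
    return pd.Series(out, name="sole_synthase")


def find_operon_pairs(
    features: list[GeneFeature],
    set_a: set[str],
    set_b: set[str],
    max_intergenic_bp: int = 300,
    require_same_strand: bool = True,
) -> list[tuple[str, str, str, int]]:
    """(genome, gene_a, gene_b, gap) for consecutive a/b gene pairs.

    A pair is reported when a gene from ``set_a`` and one from ``set_b`` are
    *consecutive* on the same contig (no gene in between), on the same strand
    when required, with intergenic distance at most ``max_intergenic_bp``.
    The relation is symmetric in a and b.
    """
    known = {f.gene_id for f in features}
    unknown = sorted((set_a | set_b) - known)
    if unknown:
        raise ValueError(f"unknown gene ids: {unknown}")
    pairs: list[tuple[str, str, str, int]] = []
    ordered = sorted(features, key=lambda f: (f.genome_id, f.contig, f.start))
    for prev, cur in zip(ordered, ordered[1:]):
        if prev.genome_id != cur.genome_id or prev.contig != cur.contig:
            continue
        ab = prev.gene_id in set_a and cur.gene_id in set_b
        ba = prev.gene_id in set_b and cur.gene_id in set_a
        if not (ab or ba):
            continue
        if require_same_strand and prev.strand != cur.strand:
            continue
        gap = cur.start - prev.end - 1
        if gap <= max_intergenic_bp:
            a_id, b_id = (prev.gene_id, cur.gene_id) if ab else (cur.gene_id, prev.gene_id)
            pairs.append((prev.genome_id, a_id, b_id, gap))
    return pairs
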