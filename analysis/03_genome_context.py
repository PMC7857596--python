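"""Genome-context analysis: repertoires, co-occurrence, operons.

Builds the genome x family repertoire matrix from the calls, then asks the
comparative-genomics questions: do MesB/MesC genomes carry the corrinoid
iron-sulfur protein genes (AcsC/AcsD)?  Does every MesD genome carry MesX?
Which genomes rely on a single synthase family?  And which mesB/acsC/acsD
and mesD/mesX gene pairs sit in operon-like adjacency?
"""

import sys
from collections import defaultdict
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _shared import RESULTS, load_calls, load_splits

from mesfinder.formats import read_features
from mesfinder.repertoire import (
    build_repertoire,
    cooccurrence,
    find_operon_pairs,
    sole_synthase,
)


def main() -> None:
    calls, splits = load_calls(), load_splits()
    features = read_features(RESULTS / "panel" / "features.tsv")

    matrix = build_repertoire(calls, splits)
    matrix.reset_index().to_csv(RESULTS / "repertoire.tsv", sep="\t", index=False)

    for fam, cond, mode in (("MesB", ["AcsC", "AcsD"], "all"),
                            ("MesC", ["AcsC", "AcsD"], "any"),
                            ("MesD", ["MesX"], "all")):
        c = cooccurrence(matrix, fam, cond, mode=mode)
        frac = "n/a" if c.fraction is None else f"{c.fraction:.0%}"
        print(f"{fam} genomes with {c.condition}: {c.numerator}/{c.denominator} ({frac})")

    soles = sole_synthase(matrix)
    soles.rename_axis("genome_id").reset_index().to_csv(
        RESULTS / "sole_synthase.tsv", sep="\t", index=False
    )
    counts = soles.value_counts()
    print("sole-synthase genomes:", dict(counts[counts.index != ""]))

    by_fam: dict[str, set[str]] = defaultdict(set)
    for c in calls:
        fam = c.family or c.family_like
        if fam:
            by_fam[fam].add(c.protein_id)
    rows = []
    for fa, fb in (("MesB", "AcsC"), ("MesB", "AcsD"), ("MesD", "MesX")):
        pairs = find_operon_pairs(features, by_fam.get(fa, set()), by_fam.get(fb, set()))
        print(f"operon-like {fa}-{fb} pairs: {len(pairs)}")
        rows += [{"genome_id": g, "family_a": fa, "family_b": fb,
                  "gene_a": a, "gene_b": b, "gap_bp": gap} for g, a, b, gap in pairs]
    pd.DataFrame(rows).to_csv(RESULTS / "operon_pairs.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS}/repertoire.tsv, sole_synthase.tsv, operon_pairs.tsv")


if __name__ == "__main__":
    main()
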