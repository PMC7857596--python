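"""Gene fitness from barcoded-transposon (BarSeq) count tables.

In a pooled fitness experiment every mutant strain carries a unique DNA
barcode; sequencing the barcodes before and after competitive growth gives
per-strain counts.  Strain fitness is the log2 change in *relative*
abundance,

    f_s = log2( ((n_after + pc) / N_after) / ((n_before + pc) / N_before) ),

with a pseudocount pc (default 1) guarding zero counts.  Gene fitness is an
inverse-variance weighted mean of the strain values, using only strains whose
insertion lies in the central 10-90% of the gene (insertions at the extreme
ends often leave the product functional), with weights

    w_s = 1 / ( 1/(1 + n_before) + 1/(1 + n_after) ).

Per-sample values are centered on the median so that typical (neutral) genes
sit near zero.  A gene fitness of -2 means mutants in that gene fell to a
quarter of their initial relative abundance over the experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import CountTable

DEFAULT_WINDOW = (0.1, 0.9)


@dataclass(frozen=True)
class GeneFitness:
    gene_id: str
    sample: str
    fitness: float
    n_strains: int
    total_before: int
    total_after: int


def strain_fitness(
    count_before: int,
    count_after: int,
    depth_before: int,
    depth_after: int,
    pseudocount: float = 1.0,
) -> float:
    """Unnormalized log2 relative-abundance change of one strain."""
    if count_before < 0 or count_after < 0:
        raise ValueError("counts must be non-negative")
    if depth_before <= 0 or depth_after <= 0:
        raise ValueError("depths must be positive")
    rel_after = (count_after + pseudocount) / depth_after
    rel_before = (count_before + pseudocount) / depth_before
    return math.log2(rel_after / rel_before)


def _strain_weight(count_before: int, count_after: int) -> float:
    return 1.0 / (1.0 / (1.0 + count_before) + 1.0 / (1.0 + count_after))


def gene_fitness(
    strains: list[tuple[float, int, int, float]],
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> tuple[float, int, int, int] | None:
    """Weighted-mean gene fitness from per-strain data.

    ``strains`` holds (strain_fitness, count_before, count_after,
    insertion_pos_fraction) tuples.  Returns (fitness, n_strains_used,
    total_before, total_after), or None when no strain has a qualifying
    central insertion — the gene is then not measurable.
    """
    lo, hi = window
    used = [(f, cb, ca) for f, cb, ca, pos in strains if lo <= pos <= hi]
    if not used:
        return None
    weights = [_strain_weight(cb, ca) for _, cb, ca in used]
    total_w = sum(weights)
    fit = sum(w * f for w, (f, _, _) in zip(weights, used)) / total_w
    return (
        fit,
        len(used),
        sum(cb for _, cb, _ in used),
        sum(ca for _, _, ca in used),
    )


def normalize_sample(values: pd.Series) -> pd.Series:
    """Center a sample's gene fitness values on their median."""
    if len(values) == 0:
        raise ValueError("no values to normalize")
    return values - values.median()


def fitness_table(
    table: CountTable,
    before_sample: str,
    after_samples: list[str] | None = None,
    pseudocount: float = 1.0,
    window: tuple[float, float] = DEFAULT_WINDOW,
    normalize: bool = True,
) -> pd.DataFrame:
    """Gene x sample fitness matrix from a barcode count table.

    ``before_sample`` names the inoculation-time column; every other column
    (or the explicit ``after_samples``) is one growth experiment.  Genes with
    no qualifying strain in a sample are NaN.
    """
    counts = table.counts
    if before_sample not in counts.columns:
        raise ValueError(f"unknown before-sample {before_sample!r}")
    if after_samples is None:
        after_samples = [c for c in counts.columns if c != before_sample]
    depth_before = int(counts[before_sample].sum())
    result: dict[str, dict[str, float]] = {}
    genes = sorted(
        {g for g, _ in table.strains.values() if g is not None}
    )
    by_gene: dict[str, list[str]] = {g: [] for g in genes}
    for barcode, (gene, _) in table.strains.items():
        if gene is not None:
            by_gene[gene].append(barcode)
    for sample in after_samples:
        depth_after = int(counts[sample].sum())
        col: dict[str, float] = {}
        for gene in genes:
            per_strain = []
            for barcode in by_gene[gene]:
                cb = int(counts.at[barcode, before_sample])
                ca = int(counts.at[barcode, sample])
                f = strain_fitness(cb, ca, depth_before, depth_after, pseudocount)
                per_strain.append((f, cb, ca, table.strains[barcode][1]))
            res = gene_fitness(per_strain, window)
            col[gene] = math.nan if res is None else res[0]
        series = pd.Series(col)
        if normalize:
            series = normalize_sample(series.dropna()).reindex(series.index)
        result[sample] = series.to_dict()
    return pd.DataFrame(result).reindex(genes)


def write_fitness_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.4f")
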