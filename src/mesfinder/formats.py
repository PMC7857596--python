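"""Core records and plain-text I/O.

The pipeline exchanges three kinds of files: protein FASTA (one proteome per
genome, or reference query sets), a tab-separated gene-feature table used for
gene-neighborhood analysis, and tab-separated barcode count tables for fitness
experiments.  All coordinates are 1-based inclusive; proteins and genes share
one id namespace so a proteome and its feature table join directly on id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

#: Amino-acid alphabet accepted in sequences.  ``X`` is an unknown residue and
#: scores zero against everything downstream.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_ALPHASET = frozenset(ALPHABET)


class FormatError(ValueError):
    """Raised for malformed input files or records."""


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence and the genome it belongs to."""

    protein_id: str
    sequence: str
    genome_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"{self.protein_id}: empty sequence")
        for i, ch in enumerate(self.sequence):
            if ch not in _ALPHASET:
                raise FormatError(
                    f"{self.protein_id}: illegal character {ch!r} at position {i + 1}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """Location of a gene on a contig (1-based inclusive coordinates)."""

    gene_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: unknown strand {self.strand!r}")


def read_fasta(path: str | Path, genome_id: str = "") -> list[ProteinRecord]:
    """Parse a protein FASTA file into records.

    The token before the first whitespace of each header becomes the
    protein id.  Wrapped sequence lines are concatenated.  Duplicate ids and
    illegal characters are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    pid: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if pid is None:
            return
        records.append(ProteinRecord(pid, "".join(chunks), genome_id=genome_id))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                pid = line[1:].split()[0] if line[1:].split() else ""
                if not pid:
                    raise FormatError(f"{path}: empty FASTA header")
                if pid in seen:
                    raise FormatError(f"{path}: duplicate id {pid!r}")
                seen.add(pid)
                chunks = []
            else:
                if pid is None:
                    raise FormatError(f"{path}: sequence before first header")
                chunks.append(line.strip())
        flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_FEATURE_COLS = ["genome_id", "gene_id", "contig", "start", "end", "strand"]


def read_features(path: str | Path) -> list[GeneFeature]:
    """Read a tab-separated feature table; rows come back sorted by
    (genome, contig, start)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _FEATURE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    feats = [
        GeneFeature(
            gene_id=row.gene_id,
            genome_id=row.genome_id,
            contig=row.contig,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
        )
        for row in df.itertuples()
    ]
    feats.sort(key=lambda f: (f.genome_id, f.contig, f.start, f.gene_id))
    return feats


def write_features(features: Iterable[GeneFeature], path: str | Path) -> None:
    rows = [
        (f.genome_id, f.gene_id, f.contig, f.start, f.end, f.strand) for f in features
    ]
    pd.DataFrame(rows, columns=_FEATURE_COLS).to_csv(path, sep="\t", index=False)


@dataclass
class CountTable:
    """Barcode counts for a pooled fitness experiment.

    ``strains`` maps barcode id -> (gene_id or None, insertion position as a
    fraction of gene length).  ``counts`` is a DataFrame indexed by barcode
    with one column per sample.
    """

    strains: dict[str, tuple[str | None, float]] = field(default_factory=dict)
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any() if self.counts.size else False:
            raise FormatError("negative counts")


def read_counts(path: str | Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("barcode", "gene_id", "pos_fraction"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    if df["barcode"].duplicated().any():
        dup = df["barcode"][df["barcode"].duplicated()].iloc[0]
        raise FormatError(f"{path}: barcode {dup!r} appears twice")
    strains = {
        row.barcode: (None if pd.isna(row.gene_id) else row.gene_id, float(row.pos_fraction))
        for row in df.itertuples()
    }
    sample_cols = [c for c in df.columns if c not in ("barcode", "gene_id", "pos_fraction")]
    counts = df.set_index("barcode")[sample_cols].astype(int)
    if (counts.values < 0).any():
        raise FormatError(f"{path}: negative counts")
    return CountTable(strains=strains, counts=counts)


def write_counts(table: CountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.insert(0, "pos_fraction", [table.strains[b][1] for b in df.index])
    df.insert(0, "gene_id", [table.strains[b][0] for b in df.index])
    df.index.name = "barcode"
    df.to_csv(path, sep="\t")
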