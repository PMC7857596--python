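"""Pairwise local alignment with affine gaps and bit-score conversion.

Every family-assignment threshold in the screen is a bit score produced by
this module: a Smith-Waterman alignment under BLOSUM62 with affine gap
penalties, converted to bits with the Karlin-Altschul transformation

    bits = (lambda * raw - ln K) / ln 2

using the standard gapped BLASTp constants (lambda = 0.267 nats per score
unit, K = 0.041).  The bit scale is therefore comparable to, but not
identical with, phmmer or BLASTp output; all downstream thresholds are
configuration rather than constants for that reason.

Conventions
-----------
* A gap of length n costs gap_open + n * gap_extend (BLAST convention, so the
  default 11/1 scheme charges 12 for a single-residue gap).
* Percent identity is identities over aligned columns *including* gap columns
  (BLAST ``pident``).
* ``X`` scores 0 against every residue.
* Tie-breaks are deterministic: among equally scoring end cells the smallest
  subject then query coordinate wins; the traceback prefers a diagonal step,
  then a gap in the subject, then a gap in the query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .formats import ALPHABET, ProteinRecord

_CODE = {ch: i for i, ch in enumerate(ALPHABET)}


def _blosum62_table() -> np.ndarray:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    table = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            if a == "X" or b == "X":
                table[i, j] = 0
            else:
                table[i, j] = int(blosum[a, b])
    return table


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus gap and Karlin-Altschul constants."""

    matrix_name: str = "BLOSUM62"
    matrix: np.ndarray = field(default_factory=_blosum62_table)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or not (0 < self.K < 1):
            raise ValueError("need lambda > 0 and 0 < K < 1")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    """A local alignment between a query and a subject.

    ``column_map`` lists one (query_pos, subject_pos) pair per alignment
    column, 1-based, with ``None`` on the gapped side.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    identities: int
    aligned_columns: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    column_map: tuple[tuple[int | None, int | None], ...]

    @property
    def is_empty(self) -> bool:
        return self.aligned_columns == 0

    def query_coverage(self, query_length: int) -> float:
        """Fraction of the query spanned by the alignment."""
        if self.is_empty:
            return 0.0
        return (self.query_end - self.query_start + 1) / query_length


def encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


@njit(cache=True)
def _sw_fill(a, b, table, gap_first, gap_ext):  # pragma: no cover - numba
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -(10**8), dtype=np.int32)
    F = np.full((n + 1, m + 1), -(10**8), dtype=np.int32)
    # pointers: ptrH 0=stop 1=diag 2=from F (gap in subject) 3=from E (gap in query)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = extend existing gap
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_first
            e_ext = E[i, j - 1] - gap_ext
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - gap_first
            f_ext = F[i - 1, j] - gap_ext
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
            diag = H[i - 1, j - 1] + table[a[i - 1], b[j - 1]]
            # preference order on ties: diagonal, subject-gap (F), query-gap (E)
            h = np.int32(0)
            p = np.uint8(0)
            if diag >= h:
                h = diag
                p = np.uint8(1)
            if F[i, j] > h:
                h = F[i, j]
                p = np.uint8(2)
            if E[i, j] > h:
                h = E[i, j]
                p = np.uint8(3)
            if h <= 0:
                h = np.int32(0)
                p = np.uint8(0)
            H[i, j] = h
            ptrH[i, j] = p
            if h > best or (h == best and h > 0 and (j < bj or (j == bj and i < bi))):
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptrH, ptrE, ptrF


def align_local(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> AlignmentResult:
    """Optimal Smith-Waterman alignment of ``a`` (query) against ``b``.

    Returns an empty zero-score alignment when no residue pair scores
    positively.
    """
    qa = a if isinstance(a, ProteinRecord) else ProteinRecord("query", a)
    qb = b if isinstance(b, ProteinRecord) else ProteinRecord("subject", b)
    if not qa.sequence or not qb.sequence:
        raise ValueError("cannot align empty sequence")
    ca, cb = encode(qa.sequence), encode(qb.sequence)
    gap_first = scheme.gap_open + scheme.gap_extend
    best, bi, bj, ptrH, ptrE, ptrF = _sw_fill(
        ca, cb, scheme.matrix, np.int32(gap_first), np.int32(scheme.gap_extend)
    )
    best = int(best)
    bits = bit_score(best, scheme)
    if best == 0:
        return AlignmentResult(qa.protein_id, qb.protein_id, 0, bits, 0, 0, 0, 0, 0, 0, ())

    # traceback
    cols: list[tuple[int | None, int | None]] = []
    i, j = bi, bj
    state = 0  # 0 = in H
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                cols.append((i, j))
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:  # F: gap in subject, consume query residue
            cols.append((i, None))
            ext = ptrF[i, j]
            i -= 1
            if ext == 0:
                state = 0
        else:  # E: gap in query, consume subject residue
            cols.append((None, j))
            ext = ptrE[i, j]
            j -= 1
            if ext == 0:
                state = 0
    cols.reverse()
    identities = sum(
        1
        for q, s in cols
        if q is not None and s is not None and qa.sequence[q - 1] == qb.sequence[s - 1]
    )
    qpos = [q for q, _ in cols if q is not None]
    spos = [s for _, s in cols if s is not None]
    return AlignmentResult(
        query_id=qa.protein_id,
        subject_id=qb.protein_id,
        raw_score=best,
        bit_score=bits,
        identities=identities,
        aligned_columns=len(cols),
        query_start=min(qpos),
        query_end=max(qpos),
        subject_start=min(spos),
        subject_end=max(spos),
        column_map=tuple(cols),
    )


def bit_score(raw: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    return (scheme.lam * raw - math.log(scheme.K)) / math.log(2)


def percent_identity(aln: AlignmentResult, rounded: bool = True) -> float:
    """Identity over aligned columns (gap columns included), as a percent.

    Reported values are rounded to the nearest integer percent; pass
    ``rounded=False`` for the raw value.
    """
    if aln.aligned_columns == 0:
        raise ValueError("percent identity undefined for an empty alignment")
    pct = 100.0 * aln.identities / aln.aligned_columns
    return float(round(pct)) if rounded else pct


def write_hits_tsv(alignments: list[AlignmentResult], path: str | Path) -> None:
    import pandas as pd

    rows = [
        (
            a.query_id,
            a.subject_id,
            a.raw_score,
            round(a.bit_score, 2),
            0.0 if a.is_empty else round(percent_identity(a, rounded=False), 1),
            a.query_start,
            a.query_end,
            a.subject_start,
            a.subject_end,
        )
        for a in alignments
    ]
    pd.DataFrame(
        rows,
        columns=[
            "query", "subject", "raw", "bits", "pident",
            "qstart", "qend", "sstart", "send",
        ],
    ).to_csv(path, sep="\t", index=False)
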