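"""Progressive multiple alignment and block trimming.

This stage feeds residue mapping, sequence logos, and the distance/tree
pipeline.  It is deliberately simple: a UPGMA guide tree from 3-mer set
distances, then profile-profile global alignment up the tree under the
pairwise scoring scheme.  It is not MUSCLE.  The trimmer honors exactly two
rules — drop columns with more than ``max_gap_fraction`` gaps, then keep only
runs of surviving columns at least ``min_block`` long — and nothing else.

The result is deterministic regardless of input order: guide-tree ties are
broken by lexicographically smallest member id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .formats import ALPHABET, ProteinRecord
from .pairwise import DEFAULT_SCHEME, ScoringScheme

GAP = "-"
_SYM = ALPHABET  # residue symbols; gaps handled separately
_SYM_INDEX = {c: i for i, c in enumerate(_SYM)}


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]
    #: original column indices (0-based) retained by trimming; identity map
    #: for an untrimmed alignment
    column_provenance: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise ValueError("alignment rows differ in length")
            if not self.column_provenance:
                self.column_provenance = list(range(n))

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, idx: int) -> str:
        return self.rows[idx].replace(GAP, "")

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


def _kmer_set(seq: str, k: int = 3) -> frozenset[str]:
    if len(seq) < k:
        return frozenset((seq,))
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - fraction of shared k-mers relative to the smaller k-mer set."""
    sa, sb = _kmer_set(a, k), _kmer_set(b, k)
    denom = min(len(sa), len(sb))
    if denom == 0:
        return 1.0
    return 1.0 - len(sa & sb) / denom


@njit(cache=True)
def _nw_profile_fill(C, gap_first, gap_ext):  # pragma: no cover - numba
    """Global affine-gap DP over a precomputed column-score matrix C."""
    n, m = C.shape
    NEG = -1e30
    H = np.empty((n + 1, m + 1))
    E = np.empty((n + 1, m + 1))  # gap in A (consume B column)
    F = np.empty((n + 1, m + 1))  # gap in B (consume A column)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 diag, 2 up(F), 3 left(E)
    H[0, 0] = 0.0
    E[0, 0] = NEG
    F[0, 0] = NEG
    for j in range(1, m + 1):
        E[0, j] = -(gap_first + gap_ext * (j - 1))
        H[0, j] = E[0, j]
        F[0, j] = NEG
        ptr[0, j] = 3
    for i in range(1, n + 1):
        F[i, 0] = -(gap_first + gap_ext * (i - 1))
        H[i, 0] = F[i, 0]
        E[i, 0] = NEG
        ptr[i, 0] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_first, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - gap_first, F[i - 1, j] - gap_ext)
            diag = H[i - 1, j - 1] + C[i - 1, j - 1]
            best = diag
            p = np.uint8(1)
            if F[i, j] > best:
                best = F[i, j]
                p = np.uint8(2)
            if E[i, j] > best:
                best = E[i, j]
                p = np.uint8(3)
            H[i, j] = best
            ptr[i, j] = p
    return ptr


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """Per-column residue frequencies (gaps excluded from the distribution
    but reflected as missing mass)."""
    n = len(rows[0])
    freq = np.zeros((n, len(_SYM)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != GAP:
                freq[j, _SYM_INDEX[ch]] += 1
    return freq / len(rows)


def _align_groups(
    rows_a: list[str], rows_b: list[str], scheme: ScoringScheme
) -> tuple[list[str], list[str]]:
    fa = _profile_freqs(rows_a)
    fb = _profile_freqs(rows_b)
    C = fa @ scheme.matrix.astype(float) @ fb.T
    ptr = _nw_profile_fill(
        C, float(scheme.gap_open + scheme.gap_extend), float(scheme.gap_extend)
    )
    i, j = len(rows_a[0]), len(rows_b[0])
    ops: list[int] = []
    while i > 0 or j > 0:
        p = ptr[i, j]
        ops.append(p)
        if p == 1:
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for p in ops:
        if p == 1:
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ia += 1
            ib += 1
        elif p == 2:
            for r, row in enumerate(rows_a):
                out_a[r] += row[ia]
            for r in range(len(rows_b)):
                out_b[r] += GAP
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += GAP
            for r, row in enumerate(rows_b):
                out_b[r] += row[ib]
            ib += 1
    return out_a, out_b


def progressive_align(
    seqs: list[ProteinRecord], scheme: ScoringScheme = DEFAULT_SCHEME, k: int = 3
) -> MultipleAlignment:
    """Align sequences progressively along a UPGMA guide tree.

    Deterministic: guide-tree merge ties are resolved by the lexicographically
    smallest id in each cluster, so input order never changes the result.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    seqs = sorted(seqs, key=lambda r: r.protein_id)
    # clusters: (sorted ids, rows, representative-id for tie-breaks)
    clusters: list[tuple[list[str], list[str]]] = [
        ([s.protein_id], [s.sequence]) for s in seqs
    ]
    dist: dict[tuple[str, str], float] = {}
    for x in range(len(seqs)):
        for y in range(x + 1, len(seqs)):
            d = kmer_distance(seqs[x].sequence, seqs[y].sequence, k)
            dist[(seqs[x].protein_id, seqs[y].protein_id)] = d

    def cluster_dist(ca: tuple[list[str], list[str]], cb: tuple[list[str], list[str]]) -> float:
        total = 0.0
        for ida in ca[0]:
            for idb in cb[0]:
                key = (ida, idb) if (ida, idb) in dist else (idb, ida)
                total += dist[key]
        return total / (len(ca[0]) * len(cb[0]))

    while len(clusters) > 1:
        best_pair: tuple[int, int] | None = None
        best_d = np.inf
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = cluster_dist(clusters[x], clusters[y])
                key = tuple(sorted((clusters[x][0][0], clusters[y][0][0])))
                if d < best_d - 1e-12:
                    best_d, best_pair, best_key = d, (x, y), key
                elif abs(d - best_d) <= 1e-12 and best_pair is not None and key < best_key:
                    best_pair, best_key = (x, y), key
        x, y = best_pair  # type: ignore[misc]
        ca, cb = clusters[x], clusters[y]
        if cb[0][0] < ca[0][0]:
            ca, cb = cb, ca
        rows_a, rows_b = _align_groups(ca[1], cb[1], scheme)
        merged = (ca[0] + cb[0], rows_a + rows_b)
        clusters = [c for idx, c in enumerate(clusters) if idx not in (x, y)]
        clusters.append(merged)

    ids, rows = clusters[0]
    # restore the caller-meaningful order: sorted ids (deterministic)
    order = sorted(range(len(ids)), key=lambda r: ids[r])
    msa = MultipleAlignment([ids[r] for r in order], [rows[r] for r in order])
    for idx, rec in enumerate(sorted(seqs, key=lambda r: r.protein_id)):
        assert msa.degapped(idx) == rec.sequence, "alignment altered a sequence"
    return msa


def trim_blocks(
    msa: MultipleAlignment, max_gap_fraction: float = 0.5, min_block: int = 2
) -> MultipleAlignment:
    """Keep columns with gap fraction <= ``max_gap_fraction``, then keep only
    maximal runs of kept columns at least ``min_block`` long."""
    n_rows = len(msa.rows)
    keep_gap = [
        sum(1 for r in msa.rows if r[j] == GAP) / n_rows <= max_gap_fraction
        for j in range(msa.n_columns)
    ]
    kept: list[int] = []
    j = 0
    while j < msa.n_columns:
        if not keep_gap[j]:
            j += 1
            continue
        run_start = j
        while j < msa.n_columns and keep_gap[j]:
            j += 1
        if j - run_start >= min_block:
            kept.extend(range(run_start, j))
    if not kept:
        raise ValueError("trimming removed every column; input not alignable")
    rows = ["".join(r[j] for j in kept) for r in msa.rows]
    return MultipleAlignment(
        ids=list(msa.ids),
        rows=rows,
        column_provenance=[msa.column_provenance[j] for j in kept],
    )


def write_alignment_fasta(msa: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")


def read_alignment_fasta(path) -> MultipleAlignment:
    ids: list[str] = []
    rows: list[str] = []
    with open(path) as fh:
        cur: list[str] = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if ids:
                    rows.append("".join(cur))
                ids.append(line[1:].split()[0])
                cur = []
            elif line:
                cur.append(line)
        if ids:
            rows.append("".join(cur))
    return MultipleAlignment(ids=ids, rows=rows)
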