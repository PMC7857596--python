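"""Distances on trimmed alignments and neighbor-joining trees.

The tree stage is a topology-level approximation: distances are mismatch
fractions over mutually ungapped columns with a Kimura-style correction

    d = -ln(1 - p - p^2 / 5),

and the tree is Saitou-Nei neighbor joining with deterministic tie-breaks
(smallest joined pair by taxon-id order).  This is sufficient to group
subfamilies — e.g. separating enzymatic members from a zinc-site-broken
sister clade — and makes no likelihood claims.

On additive distance matrices NJ is exact: the output tree reproduces every
pairwise path length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa import GAP, MultipleAlignment

#: p above this is clamped before the log correction (singularity at ~0.8541)
P_CAP = 0.85


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    clamped_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\t" + "\t".join(self.ids) + "\n")
            for i, tid in enumerate(self.ids):
                fh.write(tid + "\t" + "\t".join(f"{v:.6f}" for v in self.matrix[i]) + "\n")


def distance_matrix(msa: MultipleAlignment, correction: str = "kimura") -> DistanceMatrix:
    """Pairwise distances from a (trimmed) alignment.

    p is the mismatch fraction over columns where neither row has a gap;
    ``correction="kimura"`` applies d = -ln(1 - p - p^2/5), ``"none"`` keeps p.
    """
    n = len(msa.rows)
    if n < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    if msa.n_columns < 1:
        raise ValueError("empty alignment")
    mat = np.zeros((n, n))
    clamped: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = msa.rows[i], msa.rows[j]
            pairs = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
            if not pairs:
                raise ValueError(
                    f"no comparable columns between {msa.ids[i]} and {msa.ids[j]}"
                )
            p = sum(1 for x, y in pairs if x != y) / len(pairs)
            if correction == "kimura":
                if p > P_CAP:
                    clamped.append((msa.ids[i], msa.ids[j]))
                    p = P_CAP
                d = -np.log(1.0 - p - p * p / 5.0)
            elif correction == "none":
                d = p
            else:
                raise ValueError(f"unknown correction {correction!r}")
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids=list(msa.ids), matrix=mat, clamped_pairs=clamped)


def _format_branch(length: float) -> str:
    return f"{length:.17g}".rstrip()


def neighbor_joining(dist: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string.

    Ties in the Q criterion are broken by the smallest pair of taxon ids
    (ordering by the original id list).  Negative branch lengths are clamped
    to zero with the deficit moved onto the sister branch, preserving the
    path length between the joined pair.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = dist.matrix.astype(float).copy()
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    # node label (newick fragment) and sort key for deterministic tie-breaks
    nodes = list(dist.ids)
    keys = list(dist.ids)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for x in range(m):
            for y in range(x + 1, m):
                q = (m - 2) * sub[x, y] - r[x] - r[y]
                pair_key = tuple(sorted((keys[active[x]], keys[active[y]])))
                if (
                    best is None
                    or q < best[0] - 1e-12
                    or (abs(q - best[0]) <= 1e-12 and pair_key < best[3])
                ):
                    best = (q, x, y, pair_key)
        _, x, y, _ = best
        i, j = active[x], active[y]
        dij = sub[x, y]
        li = 0.5 * dij + (r[x] - r[y]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, move deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new_label = (
            f"({nodes[i]}:{_format_branch(li)},{nodes[j]}:{_format_branch(lj)})"
        )
        new_key = min(keys[i], keys[j])
        # distances from the new node u to every other active node
        d_new = {}
        for z in active:
            if z in (i, j):
                continue
            d_new[z] = 0.5 * (D[i, z] + D[j, z] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for z, dv in d_new.items():
            D[u, z] = D[z, u] = dv
        nodes.append(new_label)
        keys.append(new_key)
        active = [z for z in active if z not in (i, j)] + [u]

    # resolve the final three nodes as an unrooted star (three-point formula)
    i, j, k = sorted(active, key=lambda z: keys[z])
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    li, lj, lk = (max(0.0, v) for v in (li, lj, lk))
    return (
        f"({nodes[i]}:{_format_branch(li)},{nodes[j]}:{_format_branch(lj)},"
        f"{nodes[k]}:{_format_branch(lk)});"
    )
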