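"""Independent reference implementations used only by the tests.

These deliberately avoid the package's vectorized dynamic-programming code:
one scorer is a direct memoized recursion written from the definition of a
local alignment with affine gaps; the other literally enumerates every
alignment path (feasible only for very short sequences) and scores it.
"""

from __future__ import annotations

from functools import lru_cache

NEG = float("-inf")


def sw_recursive_score(a: str, b: str, matrix, code, gap_open: int, gap_extend: int) -> int:
    """Best local alignment score by recursion on alignment end state.

    M(i, j): best score of an alignment ending in a match/mismatch at
    (a_i, b_j); X/Y: ending in a gap.  A gap of length n costs
    gap_open + n * gap_extend.
    """
    first = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def M(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return NEG
        s = matrix[code[a[i]], code[b[j]]]
        best_prev = max(0.0, M(i - 1, j - 1), X(i - 1, j - 1), Y(i - 1, j - 1))
        return s + best_prev

    @lru_cache(maxsize=None)
    def X(i: int, j: int) -> float:  # gap in the query, consuming b_j
        if i < 0 or j < 0:
            return NEG
        return max(M(i, j - 1) - first, X(i, j - 1) - gap_extend)

    @lru_cache(maxsize=None)
    def Y(i: int, j: int) -> float:  # gap in the subject, consuming a_i
        if i < 0 or j < 0:
            return NEG
        return max(M(i - 1, j) - first, Y(i - 1, j) - gap_extend)

    best = 0.0
    for i in range(len(a)):
        for j in range(len(b)):
            best = max(best, M(i, j))
    return int(best)


def sw_enumerate_score(a: str, b: str, matrix, code, gap_open: int, gap_extend: int) -> int:
    """Best local score by exhaustive enumeration of alignment paths.

    Every path starts at some (i, j) with a match column and extends with
    match / gap-in-a / gap-in-b moves; each prefix ending in a match is a
    candidate local alignment.  Exponential: keep sequences at length <= 5.
    """
    first = gap_open + gap_extend
    best = 0

    def extend(i: int, j: int, score: int, state: str) -> None:
        nonlocal best
        if state == "M":
            best = max(best, score)
        # match move
        if i < len(a) and j < len(b):
            extend(i + 1, j + 1, score + matrix[code[a[i]], code[b[j]]], "M")
        # gap in query (consume b)
        if j < len(b):
            cost = gap_extend if state == "X" else first
            extend(i, j + 1, score - cost, "X")
        # gap in subject (consume a)
        if i < len(a):
            cost = gap_extend if state == "Y" else first
            extend(i + 1, j, score - cost, "Y")

    for i in range(len(a)):
        for j in range(len(b)):
            extend(i + 1, j + 1, int(matrix[code[a[i]], code[b[j]]]), "M")
    return best


def split_mete_rule_table(
    cat_bits: float,
    cat_length: int,
    n_bits: float,
    c_bits: float,
    fol_length: int,
    cat_threshold: float = 200.0,
    n_cutoff: float = 650.0,
    c_cutoff: float = 676.0,
    max_length: int = 400,
) -> bool:
    """Plain restatement of the split-MetE presence rules as a flat table."""
    catalytic_ok = cat_bits >= cat_threshold and cat_length <= max_length
    folate_ok = (
        fol_length <= max_length
        and n_bits >= n_cutoff
        and (c_bits < c_cutoff or n_bits > c_bits)
    )
    return catalytic_ok and folate_ok
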