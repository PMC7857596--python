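from io import StringIO

import numpy as np
import pytest

from mesfinder.msa import MultipleAlignment
from mesfinder.phylo import DistanceMatrix, distance_matrix, neighbor_joining


def _tree_distances(newick, ids):
    from skbio import TreeNode

    tree = TreeNode.read(StringIO(newick))
    out = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out


def test_identical_rows_have_zero_distance():
    msa = MultipleAlignment(["a", "b", "c"], ["ACDE", "ACDE", "AAAA"])
    dm = distance_matrix(msa)
    assert dm.matrix[0, 1] == 0.0


def test_kimura_correction_hand_value():
    # p = 0.1 -> d = -ln(1 - 0.1 - 0.01/5) = -ln(0.898)
    msa = MultipleAlignment(["a", "b", "c"], ["A" * 10, "A" * 9 + "C", "A" * 10])
    dm = distance_matrix(msa)
    assert dm.matrix[0, 1] == pytest.approx(-np.log(0.898), abs=1e-12)


def test_gapped_columns_excluded_from_comparison():
    msa = MultipleAlignment(["a", "b", "c"], ["AC-E", "ACDE", "ACDE"])
    dm = distance_matrix(msa)
    assert dm.matrix[0, 1] == 0.0  # only the 3 mutually ungapped columns count


def test_matrix_symmetric_zero_diagonal(rng):
    aa = list("ACDEFGHIKL")
    rows = ["".join(rng.choice(aa, size=50)) for _ in range(5)]
    dm = distance_matrix(MultipleAlignment([f"t{i}" for i in range(5)], rows))
    assert np.allclose(dm.matrix, dm.matrix.T)
    assert np.allclose(np.diag(dm.matrix), 0.0)


def test_saturated_pair_is_clamped_and_flagged():
    msa = MultipleAlignment(
        ["a", "b", "c"], ["A" * 20, "C" * 20, "A" * 20]
    )
    dm = distance_matrix(msa)
    assert ("a", "b") in dm.clamped_pairs
    assert np.isfinite(dm.matrix[0, 1])


def test_three_taxon_closed_form():
    dm = DistanceMatrix(
        ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float), []
    )
    assert neighbor_joining(dm) == "(A:1,B:1,C:3);"


@pytest.mark.parametrize("n_taxa", [4, 8])
def test_additive_matrix_recovered_exactly(n_taxa, rng):
    """Distances generated on a random tree are reproduced by the NJ tree's
    path lengths to machine precision."""
    # random additive matrix from a random caterpillar tree
    ids = [f"t{i}" for i in range(n_taxa)]
    # build random tree distances via random positive branch lengths
    import itertools

    # internal chain with leaves hanging off it
    chain = rng.uniform(0.5, 2.0, size=n_taxa - 1)
    leaf = rng.uniform(0.1, 3.0, size=n_taxa)
    # leaf i attaches at chain node min(i, n-2)
    def node_pos(k):
        return float(np.sum(chain[:k]))

    D = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        ni, nj = min(i, n_taxa - 2), min(j, n_taxa - 2)
        D[i, j] = D[j, i] = leaf[i] + leaf[j] + abs(node_pos(ni) - node_pos(nj))
    dm = DistanceMatrix(ids, D, [])
    newick = neighbor_joining(dm)
    got = _tree_distances(newick, ids)
    for (a, b), d in got.items():
        assert d == pytest.approx(D[ids.index(a), ids.index(b)], abs=1e-9)


def test_newick_reparses_to_same_leaf_set(rng):
    n = 6
    ids = [f"x{i}" for i in range(n)]
    M = rng.uniform(1, 5, size=(n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0)
    newick = neighbor_joining(DistanceMatrix(ids, D, []))
    from skbio import TreeNode

    tree = TreeNode.read(StringIO(newick))
    assert {t.name for t in tree.tips()} == set(ids)


def test_relabeling_preserves_topology(rng):
    n = 5
    M = rng.uniform(1, 5, size=(n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0)
    ids1 = [f"a{i}" for i in range(n)]
    ids2 = [f"z{i}" for i in range(n)]
    t1 = neighbor_joining(DistanceMatrix(ids1, D, []))
    t2 = neighbor_joining(DistanceMatrix(ids2, D, []))
    assert t1 == t2.replace("z", "a")


def test_agrees_with_library_neighbor_joining(rng):
    """Independent cross-check: same pairwise tree distances as skbio's NJ
    on an additive input built from an explicit tree."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    ids = ["a", "b", "c", "d", "e"]
    # tree: ((a:1,b:2):1.5,(c:1,d:2.5):0.5,e:3)
    attach = {"a": 0, "b": 0, "c": 1, "d": 1, "e": 2}
    leaf_len = {"a": 1, "b": 2, "c": 1, "d": 2.5, "e": 3}
    internal = np.array([[0, 2.0, 1.5], [2.0, 0, 0.5], [1.5, 0.5, 0]])
    D = np.zeros((5, 5))
    for i, x in enumerate(ids):
        for j, y in enumerate(ids):
            if i != j:
                D[i, j] = leaf_len[x] + leaf_len[y] + internal[attach[x], attach[y]]
    ours = _tree_distances(neighbor_joining(DistanceMatrix(ids, D, [])), ids)
    theirs_tree = nj(SkbioDM(D, ids))
    for (a, b), d in ours.items():
        assert d == pytest.approx(
            theirs_tree.find(a).distance(theirs_tree.find(b)), abs=1e-6
        )


def test_asymmetric_matrix_rejected_at_construction():
    D = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float)
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b", "c"], D, [])
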