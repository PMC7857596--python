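import math

import numpy as np
import pytest

from mesfinder.formats import ALPHABET, ProteinRecord
from mesfinder.pairwise import (
    DEFAULT_SCHEME,
    ScoringScheme,
    align_local,
    bit_score,
    percent_identity,
)

from oracles import sw_enumerate_score, sw_recursive_score

CODE = {c: i for i, c in enumerate(ALPHABET)}
AA20 = ALPHABET[:20]


def test_identical_sequences_score_diagonal_sum():
    # BLOSUM62 diagonal for A, C, D, E is 4 + 9 + 6 + 5
    aln = align_local("ACDE", "ACDE")
    assert aln.raw_score == 24
    assert aln.identities == 4 and aln.aligned_columns == 4
    assert percent_identity(aln) == 100.0


def test_no_positive_pair_gives_empty_alignment():
    aln = align_local("ACDE", "WWWW")
    assert aln.raw_score == 0 and aln.is_empty
    with pytest.raises(ValueError):
        percent_identity(aln)


def test_known_mismatch_identity():
    aln = align_local("ACDE", "ACDD")
    assert percent_identity(aln) == 75.0


def test_bit_score_hand_value():
    assert bit_score(24) == pytest.approx(13.853, abs=0.001)


def test_bit_score_zero_point_and_monotonicity():
    # raw score where lambda * raw == ln K gives exactly 0 bits
    raw0 = math.log(DEFAULT_SCHEME.K) / DEFAULT_SCHEME.lam
    assert bit_score(raw0) == pytest.approx(0.0, abs=1e-12)
    assert bit_score(10) < bit_score(11) < bit_score(100)


def test_score_symmetry(rng):
    for _ in range(10):
        a = "".join(rng.choice(list(AA20), size=rng.integers(5, 40)))
        b = "".join(rng.choice(list(AA20), size=rng.integers(5, 40)))
        assert align_local(a, b).raw_score == align_local(b, a).raw_score


def test_matching_extension_never_lowers_score(rng):
    for _ in range(10):
        a = "".join(rng.choice(list(AA20), size=10))
        b = "".join(rng.choice(list(AA20), size=10))
        base = align_local(a, b).raw_score
        assert align_local(a + "W", b + "W").raw_score >= base


def test_column_map_positions_strictly_increasing(rng):
    for _ in range(10):
        a = "".join(rng.choice(list(AA20), size=30))
        b = "".join(rng.choice(list(AA20), size=25))
        aln = align_local(a, b)
        q = [p for p, _ in aln.column_map if p is not None]
        s = [p for _, p in aln.column_map if p is not None]
        assert q == sorted(q) and len(set(q)) == len(q)
        assert s == sorted(s) and len(set(s)) == len(s)
        assert aln.identities <= aln.aligned_columns


def test_matches_recursive_oracle_short_pairs(rng):
    scheme = DEFAULT_SCHEME
    for _ in range(60):
        a = "".join(rng.choice(list(AA20), size=rng.integers(1, 9)))
        b = "".join(rng.choice(list(AA20), size=rng.integers(1, 9)))
        expected = sw_recursive_score(
            a, b, scheme.matrix, CODE, scheme.gap_open, scheme.gap_extend
        )
        assert align_local(a, b).raw_score == expected, (a, b)


def test_matches_exhaustive_path_enumeration(rng):
    """Full enumeration of every alignment path for very short pairs."""
    scheme = DEFAULT_SCHEME
    for _ in range(25):
        a = "".join(rng.choice(list(AA20), size=rng.integers(1, 5)))
        b = "".join(rng.choice(list(AA20), size=rng.integers(1, 5)))
        expected = max(
            0,
            sw_enumerate_score(
                a, b, scheme.matrix, CODE, scheme.gap_open, scheme.gap_extend
            ),
        )
        assert align_local(a, b).raw_score == expected, (a, b)


def test_matches_independent_library_implementation(rng):
    """Cross-check raw scores against an independent C implementation."""
    import biotite.sequence as bseq
    import biotite.sequence.align as ba

    mat = ba.SubstitutionMatrix.std_protein_matrix()
    for _ in range(15):
        a = "".join(rng.choice(list(AA20), size=rng.integers(10, 80)))
        b = "".join(rng.choice(list(AA20), size=rng.integers(10, 80)))
        # biotite charges open+ (n-1)*extend, ours open + n*extend
        ref = ba.align_optimal(
            bseq.ProteinSequence(a), bseq.ProteinSequence(b), mat,
            gap_penalty=(-12, -1), local=True, max_number=1,
        )[0].score
        assert align_local(a, b).raw_score == ref, (a, b)


def test_x_scores_zero_everywhere():
    aln = align_local("AXA", "AXA")
    # A-A (4) + X-X (0) + A-A (4)
    assert aln.raw_score == 8


def test_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(gap_open=0)
    with pytest.raises(ValueError):
        ScoringScheme(lam=-1)
    with pytest.raises(ValueError):
        ScoringScheme(K=1.5)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_local("", "ACDE")
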