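"""Tag codec: link encoding, collision priority, decoding, oracle."""

import itertools

import numpy as np
import pytest

from gptriple.tag_codec import (
    decode_tensor,
    encode_triples,
    oracle_decode,
    resolve_collision,
    sparse_to_tensor,
    tensor_to_sparse,
)
from gptriple.types import EntitySpan, Triple


def T(sh, st, k, oh, ot):
    return Triple(EntitySpan(sh, st), k, EntitySpan(oh, ot))


class TestResolveCollision:
    @pytest.mark.parametrize(
        "existing,incoming,winner",
        [
            (3, 1, 1),  # single-char object: tag 3 overwritten by tag 1
            (1, 3, 1),
            (0, 2, 2),
            (2, 0, 2),
            (2, 3, 2),  # single-char subject: tail link beats head-tail link
            (3, 2, 2),
            (1, 2, 1),
            (0, 0, 0),
        ],
    )
    def test_priority_order(self, existing, incoming, winner):
        assert resolve_collision(existing, incoming) == winner
        # winner independent of write order
        assert resolve_collision(incoming, existing) == winner

    def test_invalid_tag_rejected(self):
        with pytest.raises(ValueError):
            resolve_collision(4, 1)
        with pytest.raises(ValueError):
            resolve_collision(1, -1)


class TestEncode:
    def test_multichar_pair_writes_three_cells(self):
        # nested object at the head of the subject: subject (4,7), object (4,5)
        M = encode_triples(8, [T(4, 7, 0, 4, 5)], 1)
        expected = {(4, 0, 4): 1, (7, 0, 5): 2, (4, 0, 5): 3}
        assert {tuple(c): int(M[tuple(c)]) for c in np.argwhere(M)} == expected

    def test_single_char_object_overwrites_tag3(self):
        M = encode_triples(6, [T(2, 3, 0, 2, 2)], 1)
        expected = {(2, 0, 2): 1, (3, 0, 2): 2}
        assert {tuple(c): int(M[tuple(c)]) for c in np.argwhere(M)} == expected

    def test_empty_set_encodes_all_zero(self):
        M = encode_triples(5, [], 3)
        assert M.shape == (5, 3, 5) and not M.any()

    def test_at_most_three_cells_per_triple(self, rng):
        for _ in range(50):
            L = int(rng.integers(2, 15))
            sh, oh = rng.integers(0, L, 2)
            st = int(rng.integers(sh, L))
            ot = int(rng.integers(oh, L))
            M = encode_triples(L, [T(int(sh), st, 0, int(oh), ot)], 1)
            assert 1 <= (M != 0).sum() <= 3

    def test_out_of_range_span_rejected(self):
        with pytest.raises(ValueError):
            encode_triples(4, [T(1, 4, 0, 0, 1)], 1)
        with pytest.raises(ValueError):
            encode_triples(4, [T(0, 1, 2, 0, 1)], 2)


class TestDecode:
    @pytest.mark.parametrize(
        "L,triple",
        [
            (8, T(4, 7, 0, 4, 5)),   # multi/multi, nested
            (6, T(2, 3, 0, 2, 2)),   # single-char object
            (6, T(2, 2, 0, 3, 5)),   # single-char subject
            (5, T(1, 1, 0, 3, 3)),   # both single-char
            (7, T(0, 2, 1, 4, 6)),   # disjoint multi/multi
        ],
    )
    def test_single_triple_round_trip(self, L, triple):
        M = encode_triples(L, [triple], 2)
        assert decode_tensor(M) == {triple}
        assert oracle_decode(M) == {triple}

    def test_all_zero_decodes_empty(self):
        assert decode_tensor(np.zeros((5, 2, 5), dtype=np.int8)) == set()

    def test_lone_tag1_is_both_single_char(self):
        M = np.zeros((5, 1, 5), dtype=np.int8)
        M[1, 0, 3] = 1
        expected = {T(1, 1, 0, 3, 3)}
        assert decode_tensor(M) == expected
        assert oracle_decode(M) == expected

    def test_tag3_alone_yields_nothing(self):
        M = np.zeros((5, 1, 5), dtype=np.int8)
        M[0, 0, 3] = 3
        assert decode_tensor(M) == set()
        assert oracle_decode(M) == set()

    def test_invalid_values_rejected(self):
        M = np.zeros((3, 1, 3), dtype=np.int8)
        M[0, 0, 0] = 5
        with pytest.raises(ValueError):
            decode_tensor(M)

    def test_epo_shares_cells_across_relations(self):
        triples = {T(0, 1, 0, 3, 4), T(0, 1, 1, 3, 4)}
        M = encode_triples(6, triples, 2)
        assert decode_tensor(M) == triples

    def test_seo_distinct_relations(self):
        triples = {T(0, 1, 0, 3, 4), T(0, 1, 1, 6, 7)}
        M = encode_triples(8, triples, 2)
        assert decode_tensor(M) == triples


class TestOracleEquivalence:
    def test_exhaustive_sparse_small(self):
        """decode == oracle for every tensor with <= 2 nonzero cells, L=4, K=2."""
        L, K = 4, 2
        cells = list(itertools.product(range(L), range(K), range(L)))
        checked = 0
        for c1, c2 in itertools.combinations(cells, 2):
            for t1, t2 in itertools.product((1, 2, 3), repeat=2):
                M = np.zeros((L, K, L), dtype=np.int8)
                M[c1], M[c2] = t1, t2
                assert decode_tensor(M) == oracle_decode(M)
                checked += 1
        for c in cells:
            for t in (1, 2, 3):
                M = np.zeros((L, K, L), dtype=np.int8)
                M[c] = t
                assert decode_tensor(M) == oracle_decode(M)
                checked += 1
        assert checked > 4000

    def test_random_tensors(self, rng):
        for _ in range(250):
            L = int(rng.integers(1, 13))
            K = int(rng.integers(1, 4))
            M = np.zeros((L, K, L), dtype=np.int8)
            for _ in range(int(rng.integers(0, 9))):
                M[rng.integers(L), rng.integers(K), rng.integers(L)] = rng.integers(1, 4)
            assert decode_tensor(M) == oracle_decode(M)

    def test_random_encoded_triple_sets(self, rng):
        """Equivalence also on structured (encoded) tensors."""
        for _ in range(100):
            L = int(rng.integers(4, 13))
            K = int(rng.integers(1, 4))
            triples = []
            for _ in range(int(rng.integers(1, 4))):
                sh, oh = int(rng.integers(L)), int(rng.integers(L))
                triples.append(
                    T(sh, int(rng.integers(sh, L)), int(rng.integers(K)),
                      oh, int(rng.integers(oh, L)))
                )
            M = encode_triples(L, triples, K)
            assert decode_tensor(M) == oracle_decode(M)


class TestProperties:
    def test_monotone_emptiness_of_general_case(self, rng):
        """Clearing a nonzero cell never creates a new full-pattern triple."""
        for _ in range(40):
            L, K = 8, 2
            M = np.zeros((L, K, L), dtype=np.int8)
            for _ in range(6):
                M[rng.integers(L), rng.integers(K), rng.integers(L)] = rng.integers(1, 4)
            full = {
                t for t in decode_tensor(M)
                if not t.subject.is_single_char and not t.object.is_single_char
            }
            nz = np.argwhere(M)
            if len(nz) == 0:
                continue
            i, k, j = nz[rng.integers(len(nz))]
            M2 = M.copy()
            M2[i, k, j] = 0
            full2 = {
                t for t in decode_tensor(M2)
                if not t.subject.is_single_char and not t.object.is_single_char
            }
            assert full2 <= full

    def test_duplicate_triples_collapse(self):
        t = T(0, 1, 0, 3, 4)
        M = encode_triples(6, [t, t], 1)
        assert decode_tensor(M) == {t}


class TestSparseSerialization:
    def test_round_trip(self, rng):
        M = encode_triples(9, [T(1, 3, 0, 5, 7), T(2, 2, 1, 0, 0)], 2)
        payload = tensor_to_sparse(M)
        M2 = sparse_to_tensor(payload)
        assert np.array_equal(M, M2)

    def test_all_zero_round_trip(self):
        M = np.zeros((4, 1, 4), dtype=np.int8)
        assert np.array_equal(sparse_to_tensor(tensor_to_sparse(M)), M)
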