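"""Encoding, Boolean function evaluation and transition-matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbnctrl import (
    BooleanFunction,
    InvalidInputError,
    ProbabilisticBooleanNetwork,
    build_transition_matrix,
    constituent_networks,
    decode_state,
    encode_control,
    encode_state,
    evaluate_function,
    reachable_set,
)
from pbnctrl.generate import generate_random_pbn

from conftest import identity_fn, model_of, negation_fn


@pytest.mark.parametrize(
    "bits,expected",
    [((0, 0), 1), ((1, 0), 3), ((0, 1), 2), ((1, 1, 1, 1, 1, 1), 64), ((0,), 1), ((1,), 2)],
)
def test_encode_state_decimal_representation(bits, expected):
    assert encode_state(bits) == expected


@pytest.mark.parametrize("bits,expected", [((0,), 1), ((1,), 2), ((1, 0), 3)])
def test_encode_control(bits, expected):
    assert encode_control(bits) == expected


def test_encode_rejects_non_binary():
    with pytest.raises(InvalidInputError):
        encode_state((0, 2))
    with pytest.raises(InvalidInputError):
        decode_state(5, 2)


@pytest.mark.parametrize("n", range(1, 13))
def test_encode_decode_bijection(n):
    """encode/decode are mutually inverse on [1, 2^n] (exhaustive)."""
    seen = set()
    for z in range(1, (1 << n) + 1):
        bits = decode_state(z, n)
        assert encode_state(bits) == z
        seen.add(bits)
    assert len(seen) == 1 << n


@pytest.mark.parametrize(
    "parents,table,internal,control,expected",
    [
        ((1,), (0, 1), (1, 0), (), 1),       # identity of v1
        ((1,), (1, 0), (0, 1), (), 1),       # negation of v1 on input 0
        ((2, 1), (0, 1, 1, 0), (1, 1), (), 0),  # XOR, first parent = MSB
        ((2,), (0, 1), (0,), (1,), 1),       # control node as parent
    ],
)
def test_evaluate_function(parents, table, internal, control, expected):
    f = BooleanFunction(parents=parents, table=table)
    assert evaluate_function(f, internal, control) == expected


def test_table_length_validated():
    with pytest.raises(Exception):
        BooleanFunction(parents=(1, 2), table=(0, 1))


def test_constituent_expansion_product():
    """Per-gene expansion follows q_j = prod_i c_{j_i}^(i)."""
    pbn = ProbabilisticBooleanNetwork(
        n=2,
        genes=[
            [identity_fn(1, 0.5), negation_fn(1, 0.5)],
            [identity_fn(2, 0.3), negation_fn(2, 0.7)],
        ],
    )
    consts = constituent_networks(pbn)
    assert len(consts) == 4
    assert [round(c.q, 10) for c in consts] == [0.15, 0.35, 0.15, 0.35]
    assert abs(sum(c.q for c in consts) - 1.0) < 1e-12


def test_single_function_genes_give_single_constituent(identity_bn2):
    consts = constituent_networks(identity_bn2)
    assert len(consts) == 1 and consts[0].q == 1.0


def test_identity_bn_transition_matrix(identity_bn2):
    A = build_transition_matrix(identity_bn2).toarray()
    assert np.array_equal(A, np.eye(4))


def test_flip_pbn_matrix(flip_pbn1):
    A = build_transition_matrix(flip_pbn1).toarray()
    assert np.allclose(A, [[0.6, 0.4], [0.4, 0.6]])


def test_copy_gene1_matrix(copy_gene1_bn2):
    """f1 = f2 = v1 maps 00,01 -> 00 and 10,11 -> 11."""
    A = build_transition_matrix(copy_gene1_bn2).toarray()
    expected = np.zeros((4, 4))
    expected[0, 0] = expected[0, 1] = 1.0  # states 1,2 -> 1
    expected[3, 2] = expected[3, 3] = 1.0  # states 3,4 -> 4
    assert np.array_equal(A, expected)


@pytest.mark.parametrize("structure", ["constituents", "per_gene"])
@pytest.mark.parametrize("seed", range(5))
def test_random_pbn_column_stochastic(structure, seed):
    pbn = generate_random_pbn(5, 1, 3, 2, seed=seed, structure=structure)
    for u in (1, 2):
        A = build_transition_matrix(pbn, u)
        sums = np.asarray(A.sum(axis=0)).ravel()
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert (A.toarray() >= 0).all()


@pytest.mark.parametrize("seed", range(5))
def test_per_gene_matrix_matches_constituent_expansion(seed):
    """The per-gene product assembly equals explicit constituent enumeration."""
    pbn = generate_random_pbn(4, 1, 3, 2, seed=seed, structure="per_gene")
    explicit = ProbabilisticBooleanNetwork(
        n=pbn.n, m=pbn.m, K=pbn.K, constituents=constituent_networks(pbn)
    )
    for u in (1, 2):
        A1 = build_transition_matrix(pbn, u).toarray()
        A2 = build_transition_matrix(explicit, u).toarray()
        assert np.allclose(A1, A2, atol=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_deterministic_bn_columns_are_unit(seed):
    """A single constituent BN gives exactly one 1 per column, and singleton
    reachable sets."""
    pbn = generate_random_pbn(5, 0, 1, 2, seed=seed)
    A = build_transition_matrix(pbn)
    dense = A.toarray()
    assert ((dense == 0) | (dense == 1)).all()
    assert np.array_equal(dense.sum(axis=0), np.ones(32))
    model = model_of(pbn)
    for z in range(1, 33):
        assert len(reachable_set(model, z, 1)) == 1


def test_reachable_set_examples(identity_bn2, flip_pbn1):
    m_id = model_of(identity_bn2)
    for z in range(1, 5):
        assert reachable_set(m_id, z, 1) == {z}
    m_flip = model_of(flip_pbn1)
    assert reachable_set(m_flip, 1, 1) == {1, 2}


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_constituent_probabilities_sum_to_one(seed):
    pbn = generate_random_pbn(3, 0, 3, 2, seed=seed, structure="per_gene")
    consts = constituent_networks(pbn)
    assert len(consts) == 27
    assert abs(sum(c.q for c in consts) - 1.0) < 1e-9
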