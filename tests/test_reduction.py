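"""State reduction: inflow, critical states, deletion loop, soundness."""

import numpy as np
import pytest

from pbnctrl import (
    ControlledTransitionModel,
    ReductionConfig,
    critical_states,
    deletable_states,
    inflow,
    reachable_set,
    reduce_network,
    reduction_rate,
)
from pbnctrl.generate import generate_random_pbn

from conftest import model_of


def test_inflow_identity(identity_bn2):
    model = model_of(identity_bn2)
    for z in range(1, 5):
        assert inflow(model.matrices, z, range(1, 5)) == [1.0]


def test_inflow_unreachable_state(copy_gene1_bn2):
    model = model_of(copy_gene1_bn2)
    assert inflow(model.matrices, 2, range(1, 5)) == [0.0]
    # removing a feeder column lowers inflow by exactly that entry
    assert inflow(model.matrices, 1, {1, 3, 4}) == [1.0]  # was 2.0 with state 2


def test_critical_states_identity(identity_bn2):
    model = model_of(identity_bn2)
    assert critical_states(model, 1) == {1, 2, 3, 4}


def test_critical_states_copy_gene(copy_gene1_bn2):
    model = model_of(copy_gene1_bn2)
    assert critical_states(model, 2) == {1, 2, 4}


def test_critical_states_two_cycle(negation_bn1):
    model = model_of(negation_bn1)
    assert critical_states(model, 1) == {1, 2}


def test_deletable_states(identity_bn2, copy_gene1_bn2):
    m_id = model_of(identity_bn2)
    assert deletable_states(
        m_id.matrices, set(range(1, 5)), ReductionConfig(), xi=0.0
    ) == set()
    m_copy = model_of(copy_gene1_bn2)
    cfg = ReductionConfig(preserve=frozenset({1, 4}))
    assert deletable_states(m_copy.matrices, set(range(1, 5)), cfg, xi=0.0) == {2, 3}


def test_reduce_identity_deletes_nothing(identity_bn2):
    result = reduce_network(model_of(identity_bn2))
    assert result.kept == (1, 2, 3, 4) and result.deleted == []
    assert reduction_rate(result, 2) == 0.0


def test_reduce_copy_gene(copy_gene1_bn2):
    model = model_of(copy_gene1_bn2)
    cfg = ReductionConfig(preserve=frozenset(critical_states(model, 1)))
    result = reduce_network(model, cfg)
    assert result.kept == (1, 4)
    assert reduction_rate(result, 2) == 50.0
    # reduced matrices are the restriction of A to kept rows/columns
    B = result.reduced_matrices[0].toarray()
    A = model.matrices[0].toarray()
    assert np.array_equal(B, A[np.ix_([0, 3], [0, 3])])


@pytest.mark.parametrize("seed", range(8))
def test_soundness_deleted_states_unreachable(seed):
    """p=0: every deleted state has zero inflow from the kept set at deletion
    time under every control, and no trajectory from z0 visits a deleted
    state (exhaustive enumeration, 10 steps)."""
    pbn = generate_random_pbn(6, 1, 4, 2, seed=seed)
    model = model_of(pbn)
    z0 = 1
    cfg = ReductionConfig(preserve=frozenset(critical_states(model, z0)))
    result = reduce_network(model, cfg)

    # inflow check at deletion time
    deleted_at = dict(result.deleted)
    for state, it in result.deleted:
        kept_then = {s for s in range(1, model.n_states + 1)
                     if deleted_at.get(s, it + 1) >= it}
        assert all(v <= 1e-9 for v in inflow(model.matrices, state, kept_then))

    # exhaustive trajectory enumeration under all control choices
    deleted = {s for s, _ in result.deleted}
    frontier = {z0}
    visited = set(frontier)
    for _ in range(10):
        nxt = set()
        for z in frontier:
            for u in range(1, model.n_controls + 1):
                nxt |= reachable_set(model, z, u)
        frontier = nxt - visited
        visited |= nxt
    assert visited.isdisjoint(deleted)
    assert set(result.kept) >= visited


@pytest.mark.parametrize("seed", range(5))
def test_monotone_in_threshold(seed):
    """Raising xi can only shrink the kept set (fixed matrices)."""
    pbn = generate_random_pbn(5, 0, 4, 2, seed=seed, structure="per_gene")
    model = model_of(pbn)
    kept_prev = None
    for xi in (0.0, 0.05, 0.2, 0.5):
        kept = set(reduce_network(model, ReductionConfig(xi=xi,
                   preserve=frozenset({1}))).kept)
        if kept_prev is not None:
            assert kept <= kept_prev
        kept_prev = kept


@pytest.mark.parametrize("seed", range(4))
def test_idempotent(seed):
    """Re-running the reduction on the reduced model deletes nothing."""
    pbn = generate_random_pbn(5, 0, 4, 2, seed=seed)
    model = model_of(pbn)
    cfg = ReductionConfig(preserve=frozenset(critical_states(model, 1)))
    first = reduce_network(model, cfg)
    # operate directly on the reduced matrices with the same xi
    again = deletable_states(
        first.reduced_matrices,
        set(range(1, first.n_kept + 1)),
        ReductionConfig(preserve=frozenset(
            {first.index_map[s] + 1 for s in cfg.preserve if s in first.index_map}
        )),
        xi=first.xi,
    )
    assert again == set()


def test_preserved_states_survive_any_threshold(copy_gene1_bn2):
    model = model_of(copy_gene1_bn2)
    cfg = ReductionConfig(xi=10.0, preserve=frozenset({2}))
    result = reduce_network(model, cfg)
    assert result.kept == (2,)


def test_one_at_a_time_matches_batch_for_zero_threshold(copy_gene1_bn2):
    model = model_of(copy_gene1_bn2)
    cfg_b = ReductionConfig(preserve=frozenset({1, 4}))
    cfg_s = ReductionConfig(preserve=frozenset({1, 4}), batch=False)
    assert reduce_network(model, cfg_b).kept == reduce_network(model, cfg_s).kept


@pytest.mark.parametrize("p", [0.0, 0.001, 0.01])
def test_equiprobable_constituents_make_rate_p_invariant(p):
    """With q_j = 1/N every positive A entry is >= 1/N > xi/(1-p)^n, so the
    threshold rule deletes exactly the zero-inflow cascade at every p."""
    pbn = generate_random_pbn(6, 0, 4, 2, seed=11, p=p)
    model = model_of(pbn)
    cfg = ReductionConfig(preserve=frozenset(critical_states(model, 1)))
    kept = reduce_network(model, cfg).kept
    pbn0 = generate_random_pbn(6, 0, 4, 2, seed=11, p=0.0)
    model0 = model_of(pbn0)
    cfg0 = ReductionConfig(preserve=frozenset(critical_states(model0, 1)))
    assert kept == reduce_network(model0, cfg0).kept
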