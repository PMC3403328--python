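"""Shared fixtures: small hand-built networks with known dynamics."""

import numpy as np
import pytest

from pbnctrl import (
    BooleanFunction,
    Constituent,
    ControlledTransitionModel,
    ProbabilisticBooleanNetwork,
)


def identity_fn(i: int, c: float = 1.0) -> BooleanFunction:
    return BooleanFunction(parents=(i,), table=(0, 1), c=c)


def negation_fn(i: int, c: float = 1.0) -> BooleanFunction:
    return BooleanFunction(parents=(i,), table=(1, 0), c=c)


@pytest.fixture
def identity_bn2():
    """n=2 BN where every state is a fixed point (A = I4)."""
    return ProbabilisticBooleanNetwork(
        n=2, genes=[[identity_fn(1)], [identity_fn(2)]]
    )


@pytest.fixture
def copy_gene1_bn2():
    """n=2 BN with f1 = f2 = v1: states 00 and 11 are fixed points, the
    states 01 (state 2) and 10 (state 3) have no preimage."""
    return ProbabilisticBooleanNetwork(
        n=2, genes=[[identity_fn(1)], [identity_fn(1)]]
    )


@pytest.fixture
def flip_pbn1():
    """n=1 PBN: identity with c=0.6, negation with c=0.4."""
    return ProbabilisticBooleanNetwork(
        n=1, genes=[[identity_fn(1, 0.6), negation_fn(1, 0.4)]]
    )


@pytest.fixture
def negation_bn1():
    """n=1 deterministic 2-cycle: v1(t+1) = not v1(t)."""
    return ProbabilisticBooleanNetwork(n=1, genes=[[negation_fn(1)]])


@pytest.fixture
def controllable_bn():
    """n=1, m=1 single BN where the gene copies the control bit."""
    return ProbabilisticBooleanNetwork(
        n=1, m=1, genes=[[BooleanFunction(parents=(2,), table=(0, 1))]]
    )


@pytest.fixture
def uncontrollable_negation():
    """n=1, m=1: the gene negates itself, the control bit is ignored."""
    return ProbabilisticBooleanNetwork(n=1, m=1, genes=[[negation_fn(1)]])


def model_of(pbn, **kw) -> ControlledTransitionModel:
    return ControlledTransitionModel.from_pbn(pbn, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
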