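"""Combinatorics of in-degree-1 Boolean networks and their zero rows.

When every gene reads exactly one parent gene, a gene's update is either the
parent's value or its negation (constants are outside this space), so there
are ``(2n)^n`` possible BNs on ``n`` genes.  The one-step state map of such a
BN misses a state exactly when some bit pattern has no preimage; the number of
*nonzero rows* of the 2^n x 2^n transition matrix equals the image size of the
state map, which is ``2^d`` where ``d`` is the number of distinct parents
used.  The networks whose matrix has a nonzero entry in every row number
``n! 2^n``, and their share ``n!/n^n`` of all BNs vanishes as ``n`` grows —
the combinatorial reason state reduction bites on sparse-in-degree networks.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np

from .model import InvalidInputError, state_bits_matrix


class InstanceTooLargeError(ValueError):
    pass


class K1Function(NamedTuple):
    """A single-parent update: the parent gene and whether it is negated."""

    parent: int       # 1-based gene index
    negated: bool


#: exhaustive enumeration guard: (2n)^n networks, each on 2^n states
MAX_ENUM_N = 6


def enumerate_k1_bns(n: int) -> Iterator[tuple[K1Function, ...]]:
    """Yield all ``(2n)^n`` in-degree-1 BNs on ``n`` genes, one
    :class:`K1Function` per gene, in deterministic order (parent ascending,
    identity before negation)."""
    if n < 1:
        raise InvalidInputError("need at least one gene")
    if n > MAX_ENUM_N:
        raise InstanceTooLargeError(f"enumeration guarded to n <= {MAX_ENUM_N}")
    options = [K1Function(p, neg) for p in range(1, n + 1) for neg in (False, True)]
    yield from itertools.product(options, repeat=n)


@dataclass(frozen=True)
class ImageDistribution:
    """How many of the ``(2n)^n`` BNs have each possible number of nonzero
    rows (= image size of the state map, always a power of two)."""

    n: int
    counts: dict[int, int]
    total: int


def image_distribution(n: int) -> ImageDistribution:
    """Brute-force distribution of nonzero-row counts over all K=1 BNs.

    For each BN the deterministic map on ``2**n`` states is built and the
    number of distinct successor states counted.  Along the way the structural
    identity *image size = 2^(number of distinct parents)* is asserted.
    """
    bits = state_bits_matrix(n)  # (2^n, n)
    shifts = (n - 1 - np.arange(n)).astype(np.int64)
    counts: Counter[int] = Counter()
    total = 0
    for bn in enumerate_k1_bns(n):
        cols = np.empty_like(bits, dtype=np.int64)
        for i, f in enumerate(bn):
            col = bits[:, f.parent - 1].astype(np.int64)
            cols[:, i] = 1 - col if f.negated else col
        codes = (cols << shifts).sum(axis=1)
        image = len(np.unique(codes))
        assert image == 1 << len({f.parent for f in bn})
        counts[image] += 1
        total += 1
    assert total == (2 * n) ** n
    return ImageDistribution(n=n, counts=dict(counts), total=total)


def count_full_image(n: int) -> int:
    """Closed form ``n! * 2**n`` for the number of K=1 BNs with no zero row
    (every state has a predecessor)."""
    if n < 1:
        raise InvalidInputError("need at least one gene")
    return math.factorial(n) * (1 << n)


def full_image_ratio(n: int) -> float:
    """Share ``n!/n**n`` of full-image BNs among all ``(2n)^n``; strictly
    decreasing and -> 0."""
    if n < 1:
        raise InvalidInputError("need at least one gene")
    return math.factorial(n) / n**n
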