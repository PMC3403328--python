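"""Random PBN generator emulating the experimental design.

Two structures are supported:

``constituents``
    ``N`` whole constituent BNs with equal selection probabilities
    ``q_j = 1/N``; each BN assigns every gene one random function.

``per_gene``
    every gene carries ``N`` candidate functions with equal selection
    probabilities ``c = 1/N`` (the random-PBN convention of the PBN toolbox);
    genes select independently, so transition probabilities are products of
    per-gene terms and take values on a much finer grid.

In both structures a function is drawn by picking an in-degree uniformly from
``1..K`` (K is a *maximum* in-degree), then that many distinct parents
uniformly from the ``n+m`` nodes, then a truth table uniformly from all
``2**2**k`` tables.  The same seed reproduces the same network bit for bit.
"""

from __future__ import annotations

import numpy as np

from .model import (
    BooleanFunction,
    Constituent,
    InvalidInputError,
    ProbabilisticBooleanNetwork,
)


def _random_function(rng: np.random.Generator, n_nodes: int, K: int, c: float) -> BooleanFunction:
    k = int(rng.integers(1, K + 1))
    parents = tuple(sorted(int(p) + 1 for p in rng.choice(n_nodes, size=k, replace=False)))
    table = tuple(int(b) for b in rng.integers(0, 2, size=1 << k))
    return BooleanFunction(parents=parents, table=table, c=c)


def generate_random_pbn(
    n: int,
    m: int,
    N: int,
    K: int,
    seed: int | np.random.Generator | None = None,
    structure: str = "constituents",
    p: float = 0.0,
) -> ProbabilisticBooleanNetwork:
    """Draw a random PBN with ``n`` internal genes, ``m`` control nodes,
    ``N`` constituent BNs (or candidate functions per gene) and maximum
    in-degree ``K``."""
    if K > n + m:
        raise InvalidInputError(f"K={K} exceeds the {n + m} available nodes")
    if N < 1 or n < 1 or m < 0:
        raise InvalidInputError("need N >= 1, n >= 1, m >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_nodes = n + m
    if structure == "constituents":
        consts = [
            Constituent(
                q=1.0 / N,
                functions=tuple(
                    _random_function(rng, n_nodes, K, 1.0) for _ in range(n)
                ),
            )
            for _ in range(N)
        ]
        return ProbabilisticBooleanNetwork(n=n, m=m, p=p, K=K, constituents=consts)
    if structure == "per_gene":
        genes = [
            [_random_function(rng, n_nodes, K, 1.0 / N) for _ in range(N)]
            for _ in range(n)
        ]
        return ProbabilisticBooleanNetwork(n=n, m=m, p=p, K=K, genes=genes)
    raise InvalidInputError(f"unknown structure {structure!r}")
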