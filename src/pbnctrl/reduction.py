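"""Transition-probability-based state reduction.

A state's *inflow* is the row sum of the transition matrix restricted to the
currently kept columns: the total one-step probability of entering it from
surviving states.  States whose inflow is at or below the threshold

    xi = 1 - (1-p)^n

under EVERY control value are deleted in batches, the truncated sums are
recomputed on the shrunken state set with xi held fixed, and the process
iterates to a fixpoint.  With ``p = 0`` (xi = 0) this is exactly the
iterative removal of states that can never be entered from the surviving
set.  Critical states — the recurrent states (bottom strongly connected
components of the union support digraph) plus the initial state — can be
passed as a preserve set and are then never deleted.

The reduced model keeps the unperturbed ``A(u)`` restricted to the kept
rows/columns; the minimax solver consumes its support, which the deletion
criterion guarantees never leaves the kept set for the regimes studied here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .model import (
    ControlledTransitionModel,
    InvalidInputError,
    SUPPORT_TOL,
)
from .perturbation import perturbation_threshold

#: slack added to "inflow <= xi" comparisons; the first deletion pass hits
#: exact equality (inflow == row sum of P == xi) up to float rounding
XI_ATOL = 1e-9


@dataclass
class ReductionConfig:
    """Parameters of the deletion loop.

    ``xi=None`` means the default threshold ``1-(1-p)^n`` (0 when p=0).
    ``preserve`` lists states that are never deleted; callers running the
    control pipeline pass ``critical_states(...)`` here.  ``batch=False``
    deletes one state (smallest index) per iteration instead of all
    simultaneously deletable ones.
    """

    xi: float | None = None
    preserve: frozenset[int] = frozenset()
    max_iterations: int | None = None
    batch: bool = True

    def resolve_xi(self, model: ControlledTransitionModel) -> float:
        if self.xi is not None:
            if self.xi < 0:
                raise InvalidInputError(f"threshold xi={self.xi} must be >= 0")
            return self.xi
        return perturbation_threshold(model.n, model.p)


@dataclass
class ReductionResult:
    """Outcome of :func:`reduce_network`.

    ``kept`` is the surviving state set R (ascending); ``deleted`` records
    (state, iteration) pairs; ``reduced_matrices[u-1]`` is the unperturbed
    ``A(u)`` restricted to R; ``index_map`` sends an original state to its
    0-based index in the reduced matrices.
    """

    kept: tuple[int, ...]
    deleted: list[tuple[int, int]]
    reduced_matrices: list[sp.csc_matrix]
    index_map: dict[int, int]
    xi: float

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def critical_states(model: ControlledTransitionModel, z0: int) -> frozenset[int]:
    """Initial state plus all recurrent states of the support digraph.

    For each control value the bottom strongly connected components of the
    support digraph of the unperturbed ``A(u)`` are collected (for a single
    deterministic BN these are exactly the classical attractor states); the
    union over controls plus ``z0`` is returned.
    """
    if not 1 <= z0 <= model.n_states:
        raise InvalidInputError(f"initial state {z0} outside [1, {model.n_states}]")
    crit: set[int] = {int(z0)}
    for A in model.matrices:
        support = (A > SUPPORT_TOL).astype(np.int8)
        # csgraph reads entry (i, j) as edge i -> j; our A has j -> i
        nc, labels = connected_components(support.T, directed=True, connection="strong")
        coo = support.tocoo()
        has_exit = np.zeros(nc, dtype=bool)
        src, dst = labels[coo.col], labels[coo.row]  # edge col -> row
        has_exit[src[src != dst]] = True
        bottom = ~has_exit
        crit.update(int(s) + 1 for s in np.flatnonzero(bottom[labels]))
    return frozenset(crit)


def _inflow_rows(matrix, kept_idx: np.ndarray) -> np.ndarray:
    """Row sums over the kept columns, for all rows (dense vector)."""
    sub = matrix[:, kept_idx]
    if sp.issparse(sub):
        return np.asarray(sub.sum(axis=1)).ravel()
    return np.asarray(sub).sum(axis=1)


def inflow(matrices, i: int, kept) -> list[float]:
    """Per-control inflow of state ``i`` from the kept set: the truncated row
    sum ``sum_{j in kept} M(u)[i, j]``."""
    kept_idx = np.asarray(sorted(int(k) - 1 for k in kept), dtype=np.intp)
    out = []
    for M in matrices:
        row = M[i - 1, :]
        if sp.issparse(row):
            row = row.toarray().ravel()
        else:
            row = np.asarray(row).ravel()
        out.append(float(row[kept_idx].sum()))
    return out


def deletable_states(matrices, kept, config: ReductionConfig, xi: float) -> set[int]:
    """States of ``kept`` (outside the preserve set) whose inflow from the
    kept set is ``<= xi`` under every control value."""
    kept_sorted = np.asarray(sorted(int(k) for k in kept), dtype=np.intp)
    kept_idx = kept_sorted - 1
    ok = np.ones(len(kept_sorted), dtype=bool)
    for M in matrices:
        rows = _inflow_rows(M, kept_idx)[kept_idx]
        ok &= rows <= xi + XI_ATOL
    cand = set(int(s) for s in kept_sorted[ok])
    return cand - set(config.preserve)


def reduce_network(
    model: ControlledTransitionModel, config: ReductionConfig | None = None
) -> ReductionResult:
    """Iteratively delete low-inflow states until no state qualifies.

    Uses the perturbed matrices when the model carries them (``p > 0``),
    otherwise the plain ``A(u)``; the threshold xi stays fixed while the
    truncated sums shrink as columns are removed.  Deletion is batched per
    iteration by default (deterministic, order independent).
    """
    config = config or ReductionConfig()
    xi = config.resolve_xi(model)
    matrices = model.effective_matrices()
    kept: set[int] = set(range(1, model.n_states + 1))
    deleted: list[tuple[int, int]] = []
    max_iter = config.max_iterations or model.n_states + 1
    iteration = 0
    while True:
        iteration += 1
        if iteration > max_iter:
            raise RuntimeError(
                f"reduction did not terminate within {max_iter} iterations"
            )
        dels = deletable_states(matrices, kept, config, xi)
        if not dels:
            break
        if not config.batch:
            dels = {min(dels)}
        deleted.extend((s, iteration) for s in sorted(dels))
        kept -= dels
    kept_sorted = tuple(sorted(kept))
    idx = np.asarray([s - 1 for s in kept_sorted], dtype=np.intp)
    reduced = [sp.csc_matrix(A[np.ix_(idx, idx)]) for A in
               (M.toarray() if sp.issparse(M) else np.asarray(M)
                for M in model.matrices)]
    index_map = {s: i for i, s in enumerate(kept_sorted)}
    return ReductionResult(
        kept=kept_sorted,
        deleted=deleted,
        reduced_matrices=reduced,
        index_map=index_map,
        xi=xi,
    )


def reduction_rate(result: ReductionResult, n: int) -> float:
    """Percentage of the ``2**n`` states removed by the reduction."""
    total = 1 << n
    return 100.0 * (total - result.n_kept) / total
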