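"""Boolean and probabilistic Boolean network models with external control nodes.

A Boolean network (BN) updates ``n`` binary genes synchronously, each gene by a
fixed Boolean function of its parent nodes.  A probabilistic Boolean network
(PBN) attaches to each gene a set of candidate functions with selection
probabilities; sampling one function per gene independently at every step turns
the dynamics into a Markov chain on the ``2**n`` joint states.  ``m`` extra
*control* nodes may appear among the parents; their joint value is the control
input ``u``.

States use the decimal representation ``z = 1 + sum_i 2**(n-i) * v_i`` (first
gene is the most significant bit), so states live in ``[1, 2**n]`` and controls
in ``[1, 2**m]``.  Truth tables follow the same convention: the first listed
parent is the most significant bit of the row index.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

#: entries of a transition matrix below this are treated as structural zeros
SUPPORT_TOL = 1e-12

#: tolerance for probability-sum checks (selection probabilities, column sums)
PROB_TOL = 1e-9


class InvalidInputError(ValueError):
    """Raised when an argument violates an operation's precondition."""


class InvalidModelError(ValueError):
    """Raised when a network definition is internally inconsistent."""


# ---------------------------------------------------------------------------
# state / control encoding
# ---------------------------------------------------------------------------

def _check_bits(bits: Sequence[int], what: str) -> tuple[int, ...]:
    out = tuple(int(b) for b in bits)
    for b in out:
        if b not in (0, 1):
            raise InvalidInputError(f"{what} must be 0/1 bits, got {bits!r}")
    return out


def encode_state(bits: Sequence[int]) -> int:
    """Map a gene bit vector to its decimal state ``1 + sum 2**(n-i) v_i``."""
    bits = _check_bits(bits, "state bits")
    z = 1
    n = len(bits)
    for i, b in enumerate(bits, start=1):
        z += (1 << (n - i)) * b
    return z


def decode_state(z: int, n: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_state`: state ``z`` back to ``n`` bits."""
    z = int(z)
    if not 1 <= z <= (1 << n):
        raise InvalidInputError(f"state {z} outside [1, 2^{n}]")
    w = z - 1
    return tuple((w >> (n - i)) & 1 for i in range(1, n + 1))


def encode_control(bits: Sequence[int]) -> int:
    """Map control-node bits to the control value ``1 + sum 2**(m-i) v_{n+i}``."""
    return encode_state(bits)


def decode_control(u: int, m: int) -> tuple[int, ...]:
    """Control value ``u`` back to ``m`` control bits (empty tuple if m=0)."""
    if m == 0:
        if u != 1:
            raise InvalidInputError("control must be 1 when m = 0")
        return ()
    return decode_state(u, m)


def state_bits_matrix(n: int) -> np.ndarray:
    """All ``2**n`` states as rows of bits, row ``z-1`` = bits of state ``z``."""
    codes = np.arange(1 << n)[:, None]
    shifts = n - 1 - np.arange(n)[None, :]
    return ((codes >> shifts) & 1).astype(np.int8)


# ---------------------------------------------------------------------------
# Boolean functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BooleanFunction:
    """One predictor function: ordered parents, truth table, selection probability.

    ``parents`` are 1-based node indices; internal genes are ``1..n`` and
    control nodes ``n+1..n+m``.  ``table`` has length ``2**len(parents)`` with
    the first parent as the most significant bit of the row index.  ``c`` is
    the selection probability of this function within its gene's set.
    """

    parents: tuple[int, ...]
    table: tuple[int, ...]
    c: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(int(p) for p in self.parents))
        object.__setattr__(self, "table", _check_bits(self.table, "truth table"))
        k = len(self.parents)
        if len(self.table) != (1 << k):
            raise InvalidModelError(
                f"truth table length {len(self.table)} != 2^{k} for parents {self.parents}"
            )
        if any(p < 1 for p in self.parents):
            raise InvalidInputError(f"parent indices must be >= 1, got {self.parents}")
        if not 0.0 <= self.c <= 1.0 + PROB_TOL:
            raise InvalidModelError(f"selection probability {self.c} outside [0, 1]")

    @property
    def k(self) -> int:
        return len(self.parents)


def evaluate_function(
    f: BooleanFunction,
    internal_bits: Sequence[int],
    control_bits: Sequence[int] = (),
) -> int:
    """Evaluate ``f`` on the concatenated (internal ++ control) bit vector."""
    bits = _check_bits(internal_bits, "internal bits") + _check_bits(
        control_bits, "control bits"
    )
    row = 0
    k = f.k
    for j, p in enumerate(f.parents, start=1):
        if p > len(bits):
            raise InvalidInputError(
                f"parent {p} out of range for {len(bits)} available nodes"
            )
        row += (1 << (k - j)) * bits[p - 1]
    return f.table[row]


def _function_columns(f: BooleanFunction, all_bits: np.ndarray) -> np.ndarray:
    """Vectorized evaluation of ``f`` on every row of ``all_bits`` (2^n x (n+m))."""
    if f.parents and max(f.parents) > all_bits.shape[1]:
        raise InvalidInputError(
            f"parent {max(f.parents)} out of range for {all_bits.shape[1]} nodes"
        )
    k = f.k
    rows = np.zeros(all_bits.shape[0], dtype=np.int64)
    for j, p in enumerate(f.parents, start=1):
        rows += (1 << (k - j)) * all_bits[:, p - 1].astype(np.int64)
    return np.asarray(f.table, dtype=np.int8)[rows]


# ---------------------------------------------------------------------------
# the PBN container (dual representation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constituent:
    """One constituent BN: a selection probability and one function per gene."""

    q: float
    functions: tuple[BooleanFunction, ...]


@dataclass
class ProbabilisticBooleanNetwork:
    """A PBN over ``n`` internal genes and ``m`` control nodes.

    Exactly one of ``genes`` (per-gene candidate-function lists, the form of
    the ``c_j^(i)`` selection probabilities) or ``constituents`` (explicit
    constituent-BN list with probabilities ``q_j``) is given.  ``p`` is the
    single-gene random-perturbation probability; ``K`` the declared maximum
    in-degree (checked if set).
    """

    n: int
    m: int = 0
    p: float = 0.0
    K: int | None = None
    genes: list[list[BooleanFunction]] | None = None
    constituents: list[Constituent] | None = None

    def __post_init__(self) -> None:
        if (self.genes is None) == (self.constituents is None):
            raise InvalidModelError("give exactly one of genes= or constituents=")
        if not 0.0 <= self.p < 1.0:
            raise InvalidModelError(f"perturbation probability {self.p} outside [0, 1)")
        if self.genes is not None:
            if len(self.genes) != self.n:
                raise InvalidModelError(
                    f"{len(self.genes)} gene function sets for n={self.n} genes"
                )
            for i, fs in enumerate(self.genes, start=1):
                if not fs:
                    raise InvalidModelError(f"gene {i} has no functions")
                total = sum(f.c for f in fs)
                if abs(total - 1.0) > PROB_TOL:
                    raise InvalidModelError(
                        f"gene {i} selection probabilities sum to {total}, not 1"
                    )
                self._check_functions(fs, f"gene {i}")
        else:
            assert self.constituents is not None
            total = sum(c.q for c in self.constituents)
            if abs(total - 1.0) > PROB_TOL:
                raise InvalidModelError(f"constituent probabilities sum to {total}")
            for j, c in enumerate(self.constituents, start=1):
                if c.q < -PROB_TOL:
                    raise InvalidModelError(f"constituent {j} has negative q")
                if len(c.functions) != self.n:
                    raise InvalidModelError(
                        f"constituent {j} assigns {len(c.functions)} functions "
                        f"for n={self.n} genes"
                    )
                self._check_functions(c.functions, f"constituent {j}")

    def _check_functions(self, fs: Iterable[BooleanFunction], where: str) -> None:
        for f in fs:
            if f.parents and max(f.parents) > self.n + self.m:
                raise InvalidModelError(
                    f"{where}: parent {max(f.parents)} exceeds n+m={self.n + self.m}"
                )
            if self.K is not None and f.k > self.K:
                raise InvalidModelError(
                    f"{where}: in-degree {f.k} exceeds declared K={self.K}"
                )

    @property
    def representation(self) -> str:
        return "per_gene" if self.genes is not None else "constituents"

    @property
    def n_states(self) -> int:
        return 1 << self.n

    @property
    def n_controls(self) -> int:
        return 1 << self.m


def constituent_networks(pbn: ProbabilisticBooleanNetwork) -> list[Constituent]:
    """Expand a per-gene PBN into its constituent BNs with ``q_j = prod c``.

    Explicit-form PBNs are returned unchanged.  The number of constituents is
    the product of the per-gene function counts.
    """
    if pbn.constituents is not None:
        return list(pbn.constituents)
    assert pbn.genes is not None
    out: list[Constituent] = []
    for combo in itertools.product(*pbn.genes):
        q = math.prod(f.c for f in combo)
        out.append(Constituent(q=q, functions=tuple(combo)))
    return out


# ---------------------------------------------------------------------------
# transition model
# ---------------------------------------------------------------------------

def _all_bits_for_control(pbn: ProbabilisticBooleanNetwork, u: int) -> np.ndarray:
    bits = state_bits_matrix(pbn.n)
    cb = decode_control(u, pbn.m)
    if pbn.m:
        ctrl = np.tile(np.asarray(cb, dtype=np.int8), (bits.shape[0], 1))
        bits = np.hstack([bits, ctrl])
    return bits


def build_transition_matrix(pbn: ProbabilisticBooleanNetwork, u: int = 1) -> sp.csc_matrix:
    """One-step transition matrix ``A(u)`` with ``A[i-1, j-1] = Pr(z'=i | z=j, u)``.

    Column stochastic: entry ``(i, j)`` sums the selection probabilities of all
    function combinations mapping state ``j`` (with the control bits of ``u``)
    to state ``i``.  Per-gene PBNs are assembled from per-gene bit
    probabilities (genes select functions independently), explicit PBNs by
    enumerating constituents; the two routes agree.
    """
    if not 1 <= u <= pbn.n_controls:
        raise InvalidInputError(f"control {u} outside [1, {pbn.n_controls}]")
    nstates = pbn.n_states
    all_bits = _all_bits_for_control(pbn, u)

    if pbn.genes is not None:
        # per-gene bit probabilities: pb[i, j] = Pr(gene i+1 -> 1 | state j+1)
        pb = np.zeros((pbn.n, nstates))
        for i, fs in enumerate(pbn.genes):
            for f in fs:
                pb[i] += f.c * _function_columns(f, all_bits)
        # expand gene by gene; gene 1 is the most significant state bit, so
        # interleave: new row index = 2 * old + bit
        A = np.ones((1, nstates))
        for i in range(pbn.n):
            new = np.empty((2 * A.shape[0], nstates))
            new[0::2] = A * (1.0 - pb[i])
            new[1::2] = A * pb[i]
            A = new
        mat = sp.csc_matrix(A)
        mat.eliminate_zeros()
    else:
        cols = np.arange(nstates)
        rows_all: list[np.ndarray] = []
        data_all: list[np.ndarray] = []
        for c in constituent_networks(pbn):
            nxt = np.zeros(nstates, dtype=np.int64)
            for i, f in enumerate(c.functions, start=1):
                nxt += _function_columns(f, all_bits).astype(np.int64) << (pbn.n - i)
            rows_all.append(nxt)
            data_all.append(np.full(nstates, c.q))
        mat = sp.coo_matrix(
            (np.concatenate(data_all), (np.concatenate(rows_all), np.tile(cols, len(rows_all)))),
            shape=(nstates, nstates),
        ).tocsc()

    sums = np.asarray(mat.sum(axis=0)).ravel()
    if np.any(np.abs(sums - 1.0) > PROB_TOL):
        raise InvalidModelError(
            f"transition matrix for u={u} is not column stochastic "
            f"(worst column sum {sums[np.argmax(np.abs(sums - 1.0))]})"
        )
    return mat


@dataclass
class ControlledTransitionModel:
    """Per-control transition matrices of a PBN, optionally with perturbation.

    ``matrices[u-1]`` is the unperturbed ``A(u)``; ``perturbed[u-1]`` (dense)
    is ``(1-p)^n A(u) + P`` when ``p > 0``.
    """

    n: int
    m: int
    matrices: list[sp.csc_matrix]
    p: float = 0.0
    perturbed: list[np.ndarray] | None = None

    @classmethod
    def from_pbn(
        cls, pbn: ProbabilisticBooleanNetwork, perturb: bool | None = None
    ) -> "ControlledTransitionModel":
        """Build all ``A(u)``; apply the perturbation model when ``pbn.p > 0``."""
        from .perturbation import build_perturbed_matrix  # local: avoid cycle

        mats = [build_transition_matrix(pbn, u) for u in range(1, pbn.n_controls + 1)]
        if perturb is None:
            perturb = pbn.p > 0
        pert = None
        if perturb and pbn.p > 0:
            pert = [build_perturbed_matrix(A, pbn.n, pbn.p) for A in mats]
        return cls(n=pbn.n, m=pbn.m, matrices=mats, p=pbn.p if perturb else 0.0,
                   perturbed=pert)

    @property
    def n_states(self) -> int:
        return 1 << self.n

    @property
    def n_controls(self) -> int:
        return 1 << self.m

    def effective_matrices(self) -> list:
        """The matrices the reduction criterion reads: perturbed if available."""
        return self.perturbed if self.perturbed is not None else self.matrices


def reachable_set(model: ControlledTransitionModel, z: int, u: int) -> frozenset[int]:
    """One-step successor set ``F(z, u)``: support of column ``z`` of the
    *unperturbed* ``A(u)``.  Never empty for a valid model."""
    if not 1 <= z <= model.n_states:
        raise InvalidInputError(f"state {z} outside [1, {model.n_states}]")
    if not 1 <= u <= model.n_controls:
        raise InvalidInputError(f"control {u} outside [1, {model.n_controls}]")
    col = model.matrices[u - 1].getcol(z - 1)
    rows = col.tocoo().row[col.tocoo().data > SUPPORT_TOL]
    out = frozenset(int(r) + 1 for r in rows)
    if not out:
        raise InvalidModelError(f"state {z} has no successors under control {u}")
    return out
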