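"""Random gene perturbation: the Kronecker-product perturbation model.

Each gene independently flips with probability ``p`` at every step.  The
single-gene kernel is ``Q = [[1-p, p], [p, 1-p]]``; the joint flip matrix is
``Q^{(x) n}`` and the perturbation matrix removes the no-flip mass:

    P = Q (x) ... (x) Q  -  (1-p)^n I

so every row and column of ``P`` sums to ``xi = 1 - (1-p)^n``, the probability
that at least one gene flips.  The perturbed chain is then

    A~ = (1-p)^n A + P

which stays column stochastic.  Gene 1 is the outermost Kronecker factor,
matching the most-significant-bit state encoding.
"""

from __future__ import annotations

from functools import reduce

import numpy as np
import scipy.sparse as sp

from .model import InvalidInputError

#: dense materialization is cheap up to this many genes (2^12 x 2^12 doubles)
MAX_DENSE_N = 12


def _check_p(p: float) -> float:
    p = float(p)
    if not 0.0 <= p < 1.0:
        raise InvalidInputError(f"perturbation probability {p} outside [0, 1)")
    return p


def perturbation_threshold(n: int, p: float) -> float:
    """``xi = 1 - (1-p)^n``: probability of at least one flip, and the common
    row/column sum of the perturbation matrix."""
    return 1.0 - (1.0 - _check_p(p)) ** n


def build_single_gene_kernel(p: float) -> np.ndarray:
    """The 2x2 single-gene flip kernel ``Q = [[1-p, p], [p, 1-p]]``."""
    p = _check_p(p)
    return np.array([[1.0 - p, p], [p, 1.0 - p]])


def perturbation_entry(n: int, p: float, h: int) -> float:
    """Entry of ``P`` between two states at Hamming distance ``h``:
    ``p^h (1-p)^(n-h)`` for ``h >= 1`` and 0 on the diagonal."""
    p = _check_p(p)
    if h == 0:
        return 0.0
    return p**h * (1.0 - p) ** (n - h)


def build_perturbation_matrix(n: int, p: float) -> np.ndarray:
    """Dense ``P = Q^{(x) n} - (1-p)^n I`` (guarded to n <= 12)."""
    p = _check_p(p)
    if n < 1:
        raise InvalidInputError("need at least one gene")
    if n > MAX_DENSE_N:
        raise InvalidInputError(
            f"dense perturbation matrix limited to n <= {MAX_DENSE_N}; "
            "use perturbation_entry for entrywise access"
        )
    Q = build_single_gene_kernel(p)
    full = reduce(np.kron, [Q] * n)
    # the diagonal of Q^{(x) n} is exactly (1-p)^n; zero it directly instead
    # of subtracting, avoiding one-ulp negative residues
    np.fill_diagonal(full, 0.0)
    return full


def build_perturbed_matrix(A, n: int, p: float) -> np.ndarray:
    """``A~ = (1-p)^n A + P`` for a column-stochastic ``A`` (sparse or dense)."""
    p = _check_p(p)
    if sp.issparse(A):
        A = A.toarray()
    A = np.asarray(A, dtype=float)
    if A.shape != (1 << n, 1 << n):
        raise InvalidInputError(
            f"matrix shape {A.shape} does not match 2^{n} states"
        )
    if p == 0.0:
        return A.copy()
    return (1.0 - p) ** n * A + build_perturbation_matrix(n, p)
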