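"""Prior precision structures for the spatial and temporal random effects.

* :func:`icar_precision` — intrinsic CAR (degree minus adjacency) over the
  county graph; improper, null space spanned by per-island constants.
* :func:`rw1_precision` — first differences over an ordered index, optionally
  cyclic (December adjacent to January for the seasonal month effect).
* :func:`constraint_basis` — orthonormal basis of the sum-to-zero subspace
  used to parameterize each constrained block with a nonsingular prior.
* :func:`sample_constrained` — exact draws from the improper prior restricted
  to the constrained subspace (used by the synthetic generator).
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .data_model import CountyGraph

__all__ = ["icar_precision", "rw1_precision", "constraint_basis",
           "sample_constrained"]


def icar_precision(graph: CountyGraph) -> sp.csr_matrix:
    """ICAR structure matrix Q = D - A in the graph's ``county_ids`` order.

    Symmetric, row sums exactly zero, diagonal = vertex degree, off-diagonal
    -1 for neighbors. Rank is n minus the number of connected components.
    """
    n = graph.n
    if n == 0:
        raise ValueError("empty graph")
    pos = {c: i for i, c in enumerate(graph.county_ids)}
    rows, cols, vals = [], [], []
    deg = np.zeros(n)
    for e in graph.edges:
        a, b = tuple(e)
        i, j = pos[a], pos[b]
        rows += [i, j]
        cols += [j, i]
        vals += [-1.0, -1.0]
        deg[i] += 1
        deg[j] += 1
    rows += list(range(n))
    cols += list(range(n))
    vals += list(deg)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def rw1_precision(n: int, cyclic: bool = False) -> sp.csr_matrix:
    """First-order random-walk structure matrix D'D over first differences.

    Non-cyclic: tridiagonal with diagonal (1, 2, ..., 2, 1). Cyclic adds the
    wrap-around (n, 1) difference, making every diagonal entry 2. Row sums
    are zero; rank n-1 in both cases.
    """
    if n < 2:
        raise ValueError("rw1 needs n >= 2")
    pairs = [(i, i + 1) for i in range(n - 1)]
    if cyclic:
        pairs.append((n - 1, 0))
    rows, cols, vals = [], [], []
    deg = np.zeros(n)
    for i, j in pairs:
        rows += [i, j]
        cols += [j, i]
        vals += [-1.0, -1.0]
        deg[i] += 1
        deg[j] += 1
    rows += list(range(n))
    cols += list(range(n))
    vals += list(deg)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def constraint_basis(n: int, groups=None) -> np.ndarray:
    """Orthonormal basis of the subspace with a zero sum within each group.

    ``groups`` is a list of index arrays partitioning ``range(n)`` (default:
    one group of everything). Each group of size g contributes g-1 columns
    (a singleton group contributes none — its effect is pinned to zero, the
    iid fallback covering it). Returns an (n, sum(g-1)) dense matrix whose
    columns are orthonormal and sum to zero within every group.
    """
    if groups is None:
        groups = [np.arange(n)]
    cols = []
    for g in groups:
        g = np.asarray(g, dtype=int)
        m = len(g)
        if m <= 1:
            continue
        ns = scipy.linalg.null_space(np.ones((1, m)))  # (m, m-1), orthonormal
        block = np.zeros((n, m - 1))
        block[g, :] = ns
        cols.append(block)
    if not cols:
        return np.zeros((n, 0))
    return np.hstack(cols)


def sample_constrained(Q, sd: float, rng: np.random.Generator,
                       groups=None) -> np.ndarray:
    """One draw from the improper Gaussian with structure Q and marginal
    scale ``sd``, restricted to the per-group sum-to-zero subspace.

    The draw is built in the eigenbasis of the constrained structure
    precision (eigenvalue lambda_i -> coefficient variance sd^2 / lambda_i),
    so group sums are exactly zero. ``sd`` plays the role of 1/sqrt(tau).
    ``sd = 0`` returns zeros.
    """
    Q = np.asarray(Q.todense()) if sp.issparse(Q) else np.asarray(Q, dtype=float)
    n = Q.shape[0]
    if sd == 0:
        return np.zeros(n)
    A = constraint_basis(n, groups)
    if A.shape[1] == 0:
        return np.zeros(n)
    S = A.T @ Q @ A
    lam, V = scipy.linalg.eigh(S)
    if np.any(lam <= 1e-10 * max(lam.max(), 1.0)):
        raise ValueError("structure matrix singular on the constrained subspace")
    z = rng.standard_normal(len(lam))
    v = V @ (z * sd / np.sqrt(lam))
    return A @ v
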