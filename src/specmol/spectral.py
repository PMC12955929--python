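"""Graph-spectral operators and closed-form frequency filters.

A node signal ``x`` on an undirected molecular graph decomposes along the
eigenvectors of the symmetrically normalized Laplacian
``L_norm = I - D^{-1/2} A D^{-1/2} = I - P``; eigenvalues in [0, 2] play the
role of frequencies.  Two fixed spectral filters are used throughout:

* high-pass ``g(lambda) = lambda``   -> closed form ``(I - P) x``
* low-pass  ``g(lambda) = 2 - lambda`` -> closed form ``(I + P) x``

Both are evaluated sparsely (one neighbor sum per node, Eq. of the
``1/sqrt(|N_i||N_j|)`` weighting) without any eigendecomposition; a dense
eigendecomposition oracle is provided for verification only.

Isolated nodes (degree 0) get all-zero rows/columns in ``P`` so both filters
act as the identity there and the complementarity identity
``high + low = 2x`` holds on every graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["SpectralOperators", "SpectralBasis", "build_operators",
           "high_pass", "low_pass", "spectral_oracle"]

_ORACLE_MAX_N = 500


@dataclass
class SpectralOperators:
    """All matrix operators derived from one undirected graph.

    Attributes
    ----------
    A : CSR adjacency, symmetric {0,1}, zero diagonal.
    degrees : node degree vector.
    L : combinatorial Laplacian D - A.
    L_norm : symmetrically normalized Laplacian I - P.
    P : normalized adjacency D^{-1/2} A D^{-1/2} (zero rows for isolated nodes).
    Lk : k-th matrix power of L_norm (or of L when ``laplacian="combinatorial"``).
    k : hop order of ``Lk``.
    """

    n: int
    A: sp.csr_matrix
    degrees: np.ndarray
    L: sp.csr_matrix
    L_norm: sp.csr_matrix
    P: sp.csr_matrix
    Lk: sp.csr_matrix
    k: int
    _P_dense: np.ndarray | None = field(default=None, repr=False)

    @property
    def P_dense(self) -> np.ndarray:
        if self._P_dense is None:
            self._P_dense = self.P.toarray()
        return self._P_dense


@dataclass
class SpectralBasis:
    """Dense eigendecomposition L_norm = U diag(Lambda) U^T, ascending order."""

    U: np.ndarray
    Lambda: np.ndarray


def _edge_array(edges) -> np.ndarray:
    arr = np.asarray(list(edges), dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    return arr.reshape(-1, 2)


def build_operators(edges, n: int, k: int = 2,
                    laplacian: str = "normalized") -> SpectralOperators:
    """Build adjacency, Laplacians and the k-hop operator for one graph.

    Parameters
    ----------
    edges : iterable of (i, j) undirected edges, 0-based, no self-loops.
    n : number of nodes.
    k : hop order for the higher-order Laplacian power (k >= 0).
    laplacian : which Laplacian to raise to the k-th power; ``"normalized"``
        keeps the spectrum bounded in [0, 2] and is the default,
        ``"combinatorial"`` uses D - A.
    """
    if k < 0:
        raise ValueError(f"hop order k must be >= 0, got {k}")
    if laplacian not in ("normalized", "combinatorial"):
        raise ValueError(f"unknown laplacian kind {laplacian!r}")
    e = _edge_array(edges)
    if e.size and (e.min() < 0 or e.max() >= n):
        raise ValueError("edge index out of range")
    if e.size and np.any(e[:, 0] == e[:, 1]):
        raise ValueError("self-loops are not allowed")

    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    data = np.ones(rows.shape[0], dtype=np.float64)
    A = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    A.sum_duplicates()
    A.data[:] = np.minimum(A.data, 1.0)  # duplicate edges collapse to 1

    deg = np.asarray(A.sum(axis=1)).ravel()
    D = sp.diags(deg)
    L = (D - A).tocsr()

    with np.errstate(divide="ignore"):
        dinv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    Dinv = sp.diags(dinv_sqrt)
    P = (Dinv @ A @ Dinv).tocsr()
    I = sp.identity(n, format="csr")
    L_norm = (I - P).tocsr()

    base = L_norm if laplacian == "normalized" else L
    Lk = sp.identity(n, format="csr")
    for _ in range(k):
        Lk = (Lk @ base).tocsr()

    return SpectralOperators(n=n, A=A, degrees=deg, L=L, L_norm=L_norm,
                             P=P, Lk=Lk, k=k)


def _check_signal(ops: SpectralOperators, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != ops.n:
        raise ValueError(
            f"signal has {x.shape[0]} rows, graph has {ops.n} nodes")
    return x


def high_pass(ops: SpectralOperators, x: np.ndarray) -> np.ndarray:
    """High-frequency component (I - P) x, sparse closed form.

    Per node: ``x_i - sum_{j in N(i)} x_j / sqrt(|N_i| |N_j|)``.
    """
    x = _check_signal(ops, x)
    return x - ops.P @ x


def low_pass(ops: SpectralOperators, x: np.ndarray) -> np.ndarray:
    """Low-frequency component (I + P) x, sparse closed form."""
    x = _check_signal(ops, x)
    return x + ops.P @ x


def eigendecompose(ops: SpectralOperators) -> SpectralBasis:
    """Dense symmetric eigendecomposition of L_norm, ascending eigenvalues."""
    if ops.n > _ORACLE_MAX_N:
        raise ValueError(
            f"dense eigendecomposition limited to n <= {_ORACLE_MAX_N}")
    lam, U = np.linalg.eigh(ops.L_norm.toarray())
    return SpectralBasis(U=U, Lambda=lam)


def spectral_oracle(ops: SpectralOperators, g, x: np.ndarray) -> np.ndarray:
    """Exact dense spectral convolution ``U g(Lambda) U^T x``.

    ``g`` is a scalar function applied elementwise to the eigenvalues of
    L_norm.  Intended for verification of the sparse closed forms, not for
    production filtering; refuses graphs larger than 500 nodes.
    """
    x = _check_signal(ops, x)
    basis = eigendecompose(ops)
    glam = np.asarray([g(l) for l in basis.Lambda], dtype=np.float64)
    x2 = x if x.ndim == 2 else x[:, None]
    out = basis.U @ (glam[:, None] * (basis.U.T @ x2))
    return out if x.ndim == 2 else out.ravel()
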