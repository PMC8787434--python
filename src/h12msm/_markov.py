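"""Shared linear algebra for row-stochastic transition matrices.

These helpers operate on plain ndarrays so that both the synthetic
generators (which know the ground-truth matrix) and the estimators
(which produce one) can use the same spectral machinery.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla
from scipy.sparse import csgraph, csr_matrix

__all__ = [
    "assert_stochastic",
    "stationary_distribution",
    "sorted_eigenvalues",
    "implied_timescales",
    "strongly_connected_sets",
    "is_reversible",
]

#: eigenvalues whose modulus exceeds this are treated as exactly 1
_UNIT_EV_TOL = 1e-12


def assert_stochastic(T: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Validate that ``T`` is a square row-stochastic matrix."""
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {T.shape}")
    if np.any(T < -tol) or np.any(T > 1 + tol):
        raise ValueError("transition matrix entries must lie in [0, 1]")
    resid = np.max(np.abs(T.sum(axis=1) - 1.0))
    if resid > tol:
        raise ValueError(f"rows must sum to 1 (max residual {resid:.3e})")
    return T


def strongly_connected_sets(C: np.ndarray) -> list[np.ndarray]:
    """Strongly connected components of the graph with an edge i->j iff C[i,j] > 0.

    Components are sorted by size (descending); ties broken so that the
    component containing the smallest state index comes first.
    """
    C = np.asarray(C)
    n = C.shape[0]
    n_comp, labels = csgraph.connected_components(
        csr_matrix((C > 0).astype(np.int8)), directed=True, connection="strong"
    )
    comps = [np.flatnonzero(labels == k) for k in range(n_comp)]
    comps.sort(key=lambda idx: (-idx.size, idx.min() if idx.size else n))
    return comps


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi @ T = pi, pi >= 0, sum(pi) = 1.

    Raises if the chain is reducible (no unique stationary vector); the
    error names the disconnected blocks.
    """
    T = assert_stochastic(T)
    comps = strongly_connected_sets(T)
    if len(comps) > 1:
        blocks = ", ".join(str(list(c)) for c in comps)
        raise ValueError(
            f"transition matrix is reducible; strongly connected blocks: {blocks}"
        )
    evals, evecs = sla.eig(T, left=True, right=False)
    i = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def sorted_eigenvalues(T: np.ndarray) -> np.ndarray:
    """Eigenvalues of ``T`` sorted by decreasing modulus (lambda_1 = 1 first)."""
    evals = np.linalg.eigvals(np.asarray(T, dtype=float))
    order = np.argsort(-np.abs(evals), kind="stable")
    return evals[order]


def implied_timescales(
    T: np.ndarray, n_timescales: int, lag: float = 1.0
) -> np.ndarray:
    """Relaxation timescales t_i = -lag / ln|lambda_{i+1}| for i = 1..n.

    Eigenvalues with modulus within 1e-12 of 1 (beyond the Perron root)
    signal disconnected or periodic dynamics and are reported as ``inf``.
    """
    evals = sorted_eigenvalues(T)
    if n_timescales >= evals.size:
        raise ValueError(
            f"requested {n_timescales} timescales from a {evals.size}-state model"
        )
    mods = np.abs(evals[1 : n_timescales + 1])
    ts = np.empty(n_timescales)
    for i, m in enumerate(mods):
        if m >= 1.0 - _UNIT_EV_TOL:
            ts[i] = np.inf
        elif m <= 0.0:
            ts[i] = 0.0
        else:
            ts[i] = -lag / np.log(m)
    return ts


def is_reversible(T: np.ndarray, pi: np.ndarray, tol: float = 1e-8) -> bool:
    """True when the detailed-balance residual max|pi_i T_ij - pi_j T_ji| < tol."""
    flux = pi[:, None] * T
    return bool(np.max(np.abs(flux - flux.T)) < tol)
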