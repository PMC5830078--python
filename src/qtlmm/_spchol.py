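"""Sparse Cholesky factorization (up-looking, CSC) for SPD covariances.

SciPy ships no sparse Cholesky, and LU ignores the symmetry of a covariance
matrix, so the sparse likelihood path uses this compact port of the
classical up-looking algorithm (elimination-tree reachability to discover
each row's pattern, then a sparse triangular solve per row), compiled with
numba. A fill-reducing symmetric minimum-degree ordering is borrowed from
SuperLU's symbolic stage once per pattern. Work is proportional to the
fill-in flops, so factorization cost degrades smoothly as a relationship
matrix densifies.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap(a[0]) if a and callable(a[0]) else wrap


@njit(cache=True)
def _etree(n, Ap, Ai):
    """Elimination tree of a symmetric matrix given by its upper triangle."""
    parent = np.full(n, -1, dtype=np.int64)
    ancestor = np.full(n, -1, dtype=np.int64)
    for k in range(n):
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i != -1 and i < k:
                inext = ancestor[i]
                ancestor[i] = k
                if inext == -1:
                    parent[i] = k
                i = inext
    return parent


@njit(cache=True)
def _chol_numeric(n, Ap, Ai, Ax, parent):
    """Up-looking Cholesky of the upper-triangular CSC of a SPD matrix.

    Returns (Lp, Li, Lx, ok): L in CSC with the diagonal entry first in each
    column; ok = False when a non-positive pivot is met (matrix not PD).
    """
    # pass 1: column counts of L via elimination-tree reachability
    w = np.full(n, -1, dtype=np.int64)
    stack = np.empty(n, dtype=np.int64)
    count = np.ones(n, dtype=np.int64)  # diagonal entries
    for k in range(n):
        w[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i >= k:
                continue
            while w[i] != k:
                w[i] = k
                count[i] += 1
                i = parent[i]
    Lp = np.zeros(n + 1, dtype=np.int64)
    for j in range(n):
        Lp[j + 1] = Lp[j] + count[j]
    nz = Lp[n]
    Li = np.empty(nz, dtype=np.int64)
    Lx = np.zeros(nz, dtype=np.float64)
    head = Lp[:n].copy()  # next free slot per column (diag goes first)

    x = np.zeros(n, dtype=np.float64)
    w[:] = -1
    s = np.empty(n, dtype=np.int64)
    for k in range(n):
        # pattern of row k of L (ascending via etree reach), values into x
        top = n
        w[k] = k
        d = 0.0
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i > k:
                continue
            if i == k:
                d = Ax[p]
                continue
            x[i] = Ax[p]
            length = 0
            while w[i] != k:
                stack[length] = i
                length += 1
                w[i] = k
                i = parent[i]
            while length > 0:
                length -= 1
                top -= 1
                s[top] = stack[length]
        # sparse triangular solve across the pattern (topological order)
        for idx in range(top, n):
            j = s[idx]
            lkj = x[j] / Lx[Lp[j]]
            x[j] = 0.0
            for p in range(Lp[j] + 1, head[j]):
                x[Li[p]] -= Lx[p] * lkj
            d -= lkj * lkj
            Li[head[j]] = k
            Lx[head[j]] = lkj
            head[j] += 1
        if d <= 0.0:
            return Lp, Li, Lx, False
        Li[Lp[k]] = k
        Lx[Lp[k]] = np.sqrt(d)
        head[k] += 1
    return Lp, Li, Lx, True


@njit(cache=True)
def _solve_llt(n, Lp, Li, Lx, B):
    """Solve L L' Z = B in place (B is n x m, overwritten with Z)."""
    m = B.shape[1]
    for c in range(m):
        # forward: L y = b
        for j in range(n):
            yj = B[j, c] / Lx[Lp[j]]
            B[j, c] = yj
            for p in range(Lp[j] + 1, Lp[j + 1]):
                B[Li[p], c] -= Lx[p] * yj
        # backward: L' z = y
        for j in range(n - 1, -1, -1):
            zj = B[j, c]
            for p in range(Lp[j] + 1, Lp[j + 1]):
                zj -= Lx[p] * B[Li[p], c]
            B[j, c] = zj / Lx[Lp[j]]
    return B


def amd_ordering(pattern: sp.csc_matrix) -> np.ndarray:
    """Fill-reducing symmetric ordering (SuperLU's MMD on A + A')."""
    n = pattern.shape[0]
    if n <= 2:
        return np.arange(n)
    probe = (pattern + sp.eye(n, format="csc")).astype(np.float64)
    probe.data[:] = 1.0
    probe = probe + sp.diags(np.full(n, float(n)), format="csc")
    lu = spla.splu(probe, permc_spec="MMD_AT_PLUS_A",
                   diag_pivot_thresh=0.0,
                   options=dict(SymmetricMode=True))
    return np.asarray(lu.perm_c, dtype=np.int64)


class SparseCholesky:
    """Cholesky factor of P S P' for a SPD sparse matrix S.

    Raises np.linalg.LinAlgError when S is not positive definite.
    """

    def __init__(self, S: sp.spmatrix, perm: np.ndarray | None = None):
        S = S.tocsc()
        n = S.shape[0]
        self.perm = amd_ordering(S) if perm is None else perm
        Sp = S[self.perm][:, self.perm].tocsc()
        upper = sp.triu(Sp, format="csc")
        upper.sort_indices()
        Ap = upper.indptr.astype(np.int64)
        Ai = upper.indices.astype(np.int64)
        Ax = upper.data.astype(np.float64)
        parent = _etree(n, Ap, Ai)
        Lp, Li, Lx, ok = _chol_numeric(n, Ap, Ai, Ax, parent)
        if not ok:
            raise np.linalg.LinAlgError(
                "sparse Cholesky failed: matrix is not positive definite")
        self.n = n
        self.Lp, self.Li, self.Lx = Lp, Li, Lx

    @property
    def logdet(self) -> float:
        return 2.0 * float(np.sum(np.log(self.Lx[self.Lp[:-1]])))

    def solve(self, B: np.ndarray) -> np.ndarray:
        B = np.asarray(B, dtype=np.float64)
        one_d = B.ndim == 1
        if one_d:
            B = B[:, None]
        Bp = B[self.perm].copy()
        _solve_llt(self.n, self.Lp, self.Li, self.Lx, Bp)
        out = np.empty_like(Bp)
        out[self.perm] = Bp
        return out[:, 0] if one_d else out
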