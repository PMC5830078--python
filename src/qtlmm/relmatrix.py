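"""Identifier-indexed symmetric PSD relationship/covariance matrices."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .errors import AlignmentError, NotPSDError

SYMMETRY_TOL = 1e-12
PSD_TOL = 1e-8


class RelMatrix:
    """Symmetric positive semi-definite matrix indexed by string identifiers.

    Parameters
    ----------
    ids : ordered unique tokens labelling rows/columns.
    values : (n, n) array, symmetric within 1e-12; PSD up to tolerance
        (smallest eigenvalue >= -psd_tol * max(1, largest eigenvalue)).
    validate : skip the symmetry/PSD checks when False (internal fast path;
        used where PSD holds by construction).
    """

    def __init__(self, ids, values, *, validate: bool = True,
                 psd_tol: float = PSD_TOL):
        self.ids = [str(i) for i in ids]
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("RelMatrix ids are not unique")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.ids), len(self.ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match {len(self.ids)} ids")
        if validate:
            asym = np.max(np.abs(values - values.T)) if values.size else 0.0
            if asym > SYMMETRY_TOL:
                raise ValueError(f"matrix is asymmetric (max |A-A'| = {asym:g})")
            values = 0.5 * (values + values.T)
            if values.size:
                w = np.linalg.eigvalsh(values)
                if w[0] < -psd_tol * max(1.0, w[-1]):
                    raise NotPSDError(
                        f"matrix is not PSD (min eigenvalue {w[0]:g})",
                        min_eigenvalue=w[0])
        self.values = values
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def sparsity(self) -> float:
        return matrix_sparsity(self)

    @property
    def storage(self) -> str:
        """Suggested storage: 'sparse' when at least half the cells are zero."""
        return "sparse" if self.sparsity >= 0.5 else "dense"

    def to_sparse(self) -> sp.csr_matrix:
        return sp.csr_matrix(self.values)

    def subset(self, ids) -> "RelMatrix":
        """Rows/columns for the given ids, in the given order.

        Raises AlignmentError listing identifiers absent from this matrix.
        """
        ids = [str(i) for i in ids]
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise AlignmentError(
                f"{len(missing)} ids not found in relationship matrix: "
                f"{missing[:10]}")
        pos = np.array([self._index[i] for i in ids])
        return RelMatrix(ids, self.values[np.ix_(pos, pos)], validate=False)

    def __repr__(self):
        return (f"RelMatrix(n={self.n}, sparsity={self.sparsity:.3f}, "
                f"storage={self.storage!r})")


def matrix_sparsity(m: RelMatrix | np.ndarray) -> float:
    """Fraction of cells that are exactly zero (no epsilon threshold)."""
    values = m.values if isinstance(m, RelMatrix) else np.asarray(m)
    if values.size == 0:
        return 0.0
    return float(np.count_nonzero(values == 0.0)) / values.size


def densify(m: RelMatrix, target_sparsity: float, fill_value: float = 0.01,
            seed: int = 0) -> RelMatrix:
    """Fill randomly chosen zero cells with a small constant.

    Symmetric pairs of zero off-diagonal cells (and zero diagonal cells, if
    any) are set to ``fill_value`` until the zero fraction drops to within
    0.01 of ``target_sparsity``. When any cell was filled, ``fill_value * I``
    is added, and the diagonal shifted further if needed, so the result stays
    PSD. Reproducible under ``seed``.
    """
    if not 0.0 <= target_sparsity <= 1.0:
        raise ValueError("target_sparsity must be in [0, 1]")
    cur = matrix_sparsity(m)
    if target_sparsity > cur + 1e-12:
        raise ValueError(
            f"target sparsity {target_sparsity} exceeds current {cur:.4f}")
    if abs(target_sparsity - cur) <= 1e-12:
        return RelMatrix(m.ids, m.values.copy(), validate=False)

    n = m.n
    values = m.values.copy()
    rng = np.random.default_rng(seed)
    n_cells = n * n
    n_zero = int(round(cur * n_cells))
    n_fill = n_zero - int(np.ceil(target_sparsity * n_cells))

    iu, ju = np.where(np.triu(values == 0.0, k=1))
    order = rng.permutation(len(iu))
    filled = 0
    for k in order:
        if filled >= n_fill:
            break
        i, j = iu[k], ju[k]
        values[i, j] = values[j, i] = fill_value
        filled += 2
    if filled < n_fill:  # resort to zero diagonal cells, if any
        for i in np.flatnonzero(np.diag(values) == 0.0):
            if filled >= n_fill:
                break
            values[i, i] = fill_value
            filled += 1

    values[np.diag_indices(n)] += fill_value
    wmin = np.linalg.eigvalsh(values)[0]
    if wmin < 0.0:
        values[np.diag_indices(n)] += -wmin + 1e-10
    return RelMatrix(m.ids, values, validate=False)
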