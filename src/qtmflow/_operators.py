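"""Sparse finite-difference operators on regular 3D grids.

All operators act on C-order flattened volumes of a fixed ``shape`` and are
returned as CSR matrices so that adjoints are exact transposes.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def _d1_central(n: int, h: float) -> sp.csr_matrix:
    """1D first derivative: central in the interior, one-sided at both ends."""
    if n < 2:
        return sp.csr_matrix((n, n))
    D = sp.lil_matrix((n, n))
    for i in range(1, n - 1):
        D[i, i - 1] = -0.5 / h
        D[i, i + 1] = 0.5 / h
    D[0, 0], D[0, 1] = -1.0 / h, 1.0 / h
    D[n - 1, n - 2], D[n - 1, n - 1] = -1.0 / h, 1.0 / h
    return D.tocsr()


def _d1_forward(n: int, h: float) -> sp.csr_matrix:
    """1D forward difference with a zero (Neumann) row at the far end."""
    if n < 2:
        return sp.csr_matrix((n, n))
    main = -np.ones(n) / h
    main[-1] = 0.0
    upper = np.ones(n - 1) / h
    return sp.diags([main, upper], [0, 1]).tocsr()


def _embed(d1: sp.spmatrix, shape: tuple[int, int, int], axis: int) -> sp.csr_matrix:
    """Lift a 1D operator to the flattened 3D grid via Kronecker products."""
    eyes = [sp.identity(n, format="csr") for n in shape]
    mats = [d1 if a == axis else eyes[a] for a in range(3)]
    return sp.kron(sp.kron(mats[0], mats[1]), mats[2]).tocsr()


def derivative(shape, axis: int, spacing: float, scheme: str = "central") -> sp.csr_matrix:
    """First-derivative operator along ``axis`` for a C-order flattened volume.

    ``scheme`` is either "central" (one-sided at edges) or "forward"
    (Neumann zero row at the trailing edge, suitable for TV penalties).
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3:
        raise ValueError("shape must be 3D")
    if scheme == "central":
        d1 = _d1_central(shape[axis], spacing)
    elif scheme == "forward":
        d1 = _d1_forward(shape[axis], spacing)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return _embed(d1, shape, axis)


def gradient_operators(shape, voxel_size, scheme: str = "forward"):
    """Per-axis derivative operators (list of 3 CSR matrices)."""
    return [derivative(shape, a, float(voxel_size[a]), scheme) for a in range(3)]


def flux_divergence_operator(
    shape, axis: int, spacing: float, cbar: np.ndarray, mask: np.ndarray
) -> sp.csr_matrix:
    """Linear operator u_a -> d(cbar * u_a)/dx_a in conservative flux form.

    Faces carry the centered concentration 0.5*(c_i + c_j) and the centered
    velocity 0.5*(u_i + u_j); faces at the domain boundary or touching an
    out-of-mask voxel are closed (zero flux), matching a zero-flux forward
    model.  Returns an (nvox, nvox) CSR matrix on C-order flattened volumes.
    """
    shape = tuple(int(n) for n in shape)
    nvox = int(np.prod(shape))
    cflat = np.asarray(cbar, dtype=float).reshape(-1)
    mflat = np.asarray(mask, dtype=bool).reshape(-1)

    idx = np.arange(nvox).reshape(shape)
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(0, shape[axis] - 1)
    sl_hi[axis] = slice(1, shape[axis])
    i = idx[tuple(sl_lo)].reshape(-1)  # low-side cell of each interior face
    j = idx[tuple(sl_hi)].reshape(-1)  # high-side cell
    open_face = mflat[i] & mflat[j]
    i, j = i[open_face], j[open_face]
    w = 0.5 * 0.5 * (cflat[i] + cflat[j]) / spacing  # per-face weight on u_i, u_j

    rows = np.concatenate([i, i, j, j])
    cols = np.concatenate([i, j, i, j])
    vals = np.concatenate([w, w, -w, -w])
    return sp.csr_matrix((vals, (rows, cols)), shape=(nvox, nvox))
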