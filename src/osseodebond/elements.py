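"""Eight-node hexahedral elements with 2x2x2 Gauss quadrature.

Total-Lagrangian formulation: internal forces and the consistent tangent are
integrated over the reference configuration with the first Piola-Kirchhoff
stress of the Neo-Hookean model.  All routines are vectorized over an array
of elements.
"""

from __future__ import annotations

import numpy as np

from .materials import ElasticParams, first_pk_stress, material_tangent

__all__ = [
    "HEX_VERTICES",
    "shape_functions",
    "shape_gradients",
    "precompute_quadrature",
    "internal_forces",
    "element_residual_stiffness",
]

# reference vertices in [-1,1]^3, standard trilinear ordering
HEX_VERTICES = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)

_g = 1.0 / np.sqrt(3.0)
GAUSS_POINTS = HEX_VERTICES * _g
GAUSS_WEIGHTS = np.ones(8)


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions at points xi (shape (..., 3)) -> (..., 8)."""
    xi = np.asarray(xi, dtype=float)
    v = HEX_VERTICES
    return 0.125 * np.prod(1.0 + xi[..., None, :] * v, axis=-1)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """Gradients dN_a/dxi_j at points xi -> shape (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    v = HEX_VERTICES
    terms = 1.0 + xi[..., None, :] * v  # (..., 8, 3)
    grad = np.empty(xi.shape[:-1] + (8, 3))
    for j in range(3):
        others = [k for k in range(3) if k != j]
        grad[..., :, j] = 0.125 * v[:, j] * terms[..., :, others[0]] * terms[..., :, others[1]]
    return grad


def precompute_quadrature(coords: np.ndarray):
    """Reference-configuration quadrature data for a batch of elements.

    Parameters
    ----------
    coords : (nel, 8, 3) reference nodal coordinates.

    Returns
    -------
    dNdX : (nel, 8gp, 8node, 3) shape gradients w.r.t. reference coords.
    wdetJ : (nel, 8gp) quadrature weight times reference Jacobian.
    """
    coords = np.asarray(coords, dtype=float)
    dNdxi = shape_gradients(GAUSS_POINTS)  # (8gp, 8, 3)
    # J0[e, g, i, j] = dX_i/dxi_j
    J0 = np.einsum("eai,gaj->egij", coords, dNdxi)
    detJ = np.linalg.det(J0)
    if np.any(detJ <= 0.0):
        raise ValueError("non-positive reference Jacobian in hex mesh")
    J0inv = np.linalg.inv(J0)
    dNdX = np.einsum("gaj,egji->egai", dNdxi, J0inv)
    wdetJ = GAUSS_WEIGHTS[None, :] * detJ
    return dNdX, wdetJ


def _deformation_gradients(disp: np.ndarray, dNdX: np.ndarray) -> np.ndarray:
    """F[e, g] = I + sum_a u_a (x) dN_a/dX at each Gauss point."""
    F = np.einsum("eai,egaj->egij", disp, dNdX)
    F += np.eye(3)
    return F


def internal_forces(disp: np.ndarray, dNdX: np.ndarray, wdetJ: np.ndarray,
                    mat: ElasticParams) -> np.ndarray:
    """Element internal force vectors, shape (nel, 8, 3)."""
    F = _deformation_gradients(np.asarray(disp, dtype=float), dNdX)
    P = first_pk_stress(F, mat)
    return np.einsum("eg,egiJ,egaJ->eai", wdetJ, P, dNdX, optimize=True)


def element_residual_stiffness(disp: np.ndarray, dNdX: np.ndarray, wdetJ: np.ndarray,
                               mat: ElasticParams):
    """Internal forces and consistent tangents for a batch of elements.

    Returns ``(fint, K)`` with shapes (nel, 8, 3) and (nel, 24, 24); the
    24-vector ordering is node-major (node a, component i -> 3a + i).
    """
    disp = np.asarray(disp, dtype=float)
    F = _deformation_gradients(disp, dNdX)
    P = first_pk_stress(F, mat)
    A = material_tangent(F, mat)
    fint = np.einsum("eg,egiJ,egaJ->eai", wdetJ, P, dNdX, optimize=True)
    nel = disp.shape[0]
    # K = sum_g w B_g^T A_g B_g with B[(iJ),(3b+k)] = d_ik dN_b/dX_J (BLAS path)
    K = np.zeros((nel, 24, 24))
    B = np.zeros((nel, 3, 3, 8, 3))
    for g in range(dNdX.shape[1]):
        B[:] = 0.0
        dN = dNdX[:, g]  # (nel, 8, 3)
        for i in range(3):
            B[:, i, :, :, i] = dN.transpose(0, 2, 1)
        B2 = B.reshape(nel, 9, 24)
        A2 = (A[:, g] * wdetJ[:, g, None, None, None, None]).reshape(nel, 9, 9)
        K += B2.transpose(0, 2, 1) @ (A2 @ B2)
    return fint, K
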