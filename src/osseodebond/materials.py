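"""Compressible Neo-Hookean hyperelasticity.

Cauchy stress: sigma = Lambda/J * ln(J) * I + G/J * (b - I), with J = det F
and b = F F^T.  The corresponding stored energy density (per reference
volume) is W = Lambda/2 (ln J)^2 + G/2 (tr b - 3) - G ln J, and the first
Piola-Kirchhoff stress P = G (F - F^-T) + Lambda ln J F^-T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ElasticParams", "neo_hookean_stress", "first_pk_stress", "material_tangent"]


@dataclass(frozen=True)
class ElasticParams:
    """Isotropic elastic constants; Lame parameters derived from (E, nu)."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0.0:
            raise ValueError("E must be positive")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("nu must lie in [0, 0.5)")

    @property
    def G(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def Lambda(self) -> float:
        return 2.0 * self.G * self.nu / (1.0 - 2.0 * self.nu)


def neo_hookean_stress(F: np.ndarray, mat: ElasticParams) -> np.ndarray:
    """Cauchy stress for deformation gradient(s) F (shape (..., 3, 3))."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        raise ValueError("element inversion: det(F) <= 0")
    b = F @ np.swapaxes(F, -1, -2)
    I = np.broadcast_to(np.eye(3), F.shape)
    J = J[..., None, None]
    return mat.Lambda / J * np.log(J) * I + mat.G / J * (b - I)


def first_pk_stress(F: np.ndarray, mat: ElasticParams) -> np.ndarray:
    """First Piola-Kirchhoff stress P = G(F - F^-T) + Lambda ln(J) F^-T."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        raise ValueError("element inversion: det(F) <= 0")
    FinvT = np.swapaxes(np.linalg.inv(F), -1, -2)
    lnJ = np.log(J)[..., None, None]
    return mat.G * (F - FinvT) + mat.Lambda * lnJ * FinvT


def material_tangent(F: np.ndarray, mat: ElasticParams) -> np.ndarray:
    """Full material tangent A_iJkL = dP_iJ / dF_kL, shape (..., 3, 3, 3, 3).

    A = G d_ik d_JL + Lambda Fi_Ji Fi_Lk ... written with Finv = F^-1:
    A_iJkL = G d_ik d_JL + Lambda Finv_Ji Finv_Lk
             - (Lambda ln J - G) Finv_Jk Finv_Li
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    Finv = np.linalg.inv(F)
    lnJ = np.log(J)
    eye = np.eye(3)
    dd = np.einsum("ik,JL->iJkL", eye, eye)
    FF1 = np.einsum("...Ji,...Lk->...iJkL", Finv, Finv)
    FF2 = np.einsum("...Jk,...Li->...iJkL", Finv, Finv)
    coef = (mat.Lambda * lnJ - mat.G)[..., None, None, None, None]
    return mat.G * dd + mat.Lambda * FF1 - coef * FF2
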