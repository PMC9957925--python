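"""Point-wise adhesive-frictional contact constitutive model.

This module is the FE-independent kernel of the bone-implant interface model.
Three laws are supported:

* ``COULOMB`` -- classical Coulomb friction with constant coefficient ``mu_b``
  and no tensile resistance,
* ``MC`` -- modified Coulomb law: the friction coefficient interpolates
  between an unbroken value ``mu_ub`` and a broken value ``mu_b`` through a
  bonding state variable ``phi`` that degrades with accumulated tangential
  interface slip,
* ``EMC`` -- extended modified Coulomb law: adds an exponential cohesive zone
  in the normal direction (peak traction ``phi0*t0`` at gap ``g0``, sharp
  cutoff at ``g_b``) and shifts the sliding limit so that frictional sliding
  remains possible under tensile normal traction.

The bonding state ``phi`` at an interface point is ``phi0 * w(g_d)`` where
``phi0`` is the initial degree of osseointegration and ``w`` is a smooth,
non-increasing window of the accumulated interface deformation ``g_d``.  For
the MC law ``g_d`` is the accumulated irreversible tangential slip ``g_s``;
the EMC additionally accumulates the normal-gap change ``g_sn``.  Both
accumulators are path integrals of absolute increments and therefore never
decrease, even when the loading reverses.

All quantities are SI (m, Pa, N).  Functions accept scalars or numpy arrays
and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum, IntEnum

import numpy as np

__all__ = [
    "ContactLaw",
    "PointStatus",
    "AdhesiveFrictionParams",
    "BondPointState",
    "ContactPointKinematics",
    "state_function",
    "update_damage",
    "friction_coefficient",
    "normal_traction",
    "sliding_limit",
    "slip_update",
    "smooth_penalty",
    "calibrate_t0",
]


class ContactLaw(str, Enum):
    """Selector for the interface constitutive law."""

    COULOMB = "coulomb"
    MC = "mc"
    EMC = "emc"


class PointStatus(IntEnum):
    """Contact status of a quadrature point after the return mapping."""

    STICK = 0
    SLIP = 1
    OPEN = 2


@dataclass(frozen=True)
class AdhesiveFrictionParams:
    """Constant parameters of the interface law.

    Parameters
    ----------
    a_s : float
        Displacement threshold of the state function (m).  Damage below
        ``a_s`` leaves the bond intact.
    b_s : float
        Dimensionless size of the transition zone between the fully bonded
        and fully broken state; the bond is gone at ``g_d = a_s*(1+2*b_s)``.
    mu_ub, mu_b : float
        Friction coefficients of the unbroken and broken interface.
    t0 : float
        Peak adhesive normal traction of the cohesive zone (Pa).
    g0 : float
        Normal gap at which the peak traction occurs (m).
    g_b : float
        Cutoff gap beyond which contact is lost (m).
    eps_n, eps_t : float
        Normal and tangential penalty moduli (Pa/m).
    law : ContactLaw
        Which branch set to use.
    """

    a_s: float
    b_s: float
    mu_ub: float
    mu_b: float
    t0: float = 0.0
    g0: float = 1.0
    g_b: float = 1.0
    eps_n: float = 1.0
    eps_t: float = 1.0
    law: ContactLaw = ContactLaw.MC

    def __post_init__(self) -> None:
        if self.a_s <= 0.0:
            raise ValueError("a_s must be positive")
        if self.b_s <= 0.0:
            raise ValueError("b_s must be positive")
        if not (0.0 <= self.mu_b <= self.mu_ub):
            raise ValueError("need 0 <= mu_b <= mu_ub")
        if self.t0 < 0.0:
            raise ValueError("t0 must be non-negative")
        if not (0.0 < self.g0 <= self.g_b):
            raise ValueError("need 0 < g0 <= g_b")
        if self.eps_n <= 0.0 or self.eps_t <= 0.0:
            raise ValueError("penalty moduli must be positive")
        object.__setattr__(self, "law", ContactLaw(self.law))

    @property
    def g_d_max(self) -> float:
        """Accumulated deformation at which the bond is fully broken."""
        return self.a_s * (1.0 + 2.0 * self.b_s)

    def with_law(self, law: ContactLaw | str) -> "AdhesiveFrictionParams":
        return replace(self, law=ContactLaw(law))


@dataclass
class BondPointState:
    """History of one contact quadrature point.

    ``xi_prev`` holds the parametric location of the previous interacting
    point on the master surface as ``(facet_index, xi, eta)``; ``None`` before
    first contact.
    """

    phi0: float = 0.0
    g_s: float = 0.0
    g_sn: float = 0.0
    phi: float = 0.0
    g_en_prev: float = 0.0
    xi_prev: tuple | None = None
    status: PointStatus = PointStatus.OPEN

    @property
    def g_d(self) -> float:
        return self.g_s + self.g_sn


@dataclass
class ContactPointKinematics:
    """Geometric quantities of a slave point against the master surface.

    ``g_e = x_k - x_l`` is the elastic gap vector from the interacting master
    point to the slave point, ``n`` the outward unit master normal, and
    ``g_n = g_e . n`` the signed normal gap (negative in penetration).
    """

    x_k: np.ndarray
    x_l: np.ndarray
    n: np.ndarray
    xi: tuple | None = None

    def __post_init__(self) -> None:
        self.x_k = np.asarray(self.x_k, dtype=float)
        self.x_l = np.asarray(self.x_l, dtype=float)
        self.n = np.asarray(self.n, dtype=float)

    @property
    def g_e(self) -> np.ndarray:
        return self.x_k - self.x_l

    @property
    def g_n(self) -> float:
        return float(self.g_e @ self.n)

    @property
    def g_en(self) -> float:
        """Scalar normal component of the elastic gap."""
        return self.g_n


def state_function(g_d, phi0, a_s: float, b_s: float):
    """Bonding state phi as a smooth non-increasing window of damage.

    ``phi = phi0`` for ``g_d < a_s``, decays along a half-sine over
    ``a_s <= g_d <= a_s*(1+2*b_s)`` and is zero beyond.  Continuous in value
    at both branch joints.
    """
    g_d = np.asarray(g_d, dtype=float)
    phi0 = np.asarray(phi0, dtype=float)
    if np.any(g_d < 0.0):
        raise ValueError("g_d must be non-negative")
    if np.any(phi0 < 0.0) or np.any(phi0 > 1.0):
        raise ValueError("phi0 must lie in [0, 1]")
    if a_s <= 0.0 or b_s <= 0.0:
        raise ValueError("a_s and b_s must be positive")
    c1 = g_d / a_s
    w = 0.5 - 0.5 * np.sin(np.pi / (2.0 * b_s) * (c1 - b_s - 1.0))
    w = np.where(c1 < 1.0, 1.0, w)
    w = np.where(c1 > 1.0 + 2.0 * b_s, 0.0, w)
    out = phi0 * w
    if out.ndim == 0:
        return float(out)
    return out


def damage_measure(g_s, g_sn, law: ContactLaw):
    """Accumulated deformation driving the state function.

    Tangential slip only for MC/COULOMB; slip plus accumulated normal-gap
    change for EMC.
    """
    if ContactLaw(law) is ContactLaw.EMC:
        return g_s + g_sn
    return np.asarray(g_s, dtype=float) + 0.0


def update_damage(
    state: BondPointState,
    kin_now: ContactPointKinematics,
    kin_prev: ContactPointKinematics,
    params: AdhesiveFrictionParams,
) -> BondPointState:
    """Commit one converged step of damage accumulation at a point.

    The tangential slip increment is the distance between the current
    positions of the current and previous interacting master points; the
    normal increment is the absolute change of the scalar normal gap.  Both
    are accumulated unconditionally (they are path lengths), so reversing the
    loading keeps increasing them.
    """
    ds = float(np.linalg.norm(kin_now.x_l - kin_prev.x_l))
    dgn = abs(kin_now.g_en - kin_prev.g_en)
    g_s = state.g_s + ds
    g_sn = state.g_sn + dgn
    g_d = damage_measure(g_s, g_sn, params.law)
    phi = state_function(g_d, state.phi0, params.a_s, params.b_s)
    return replace(
        state,
        g_s=g_s,
        g_sn=g_sn,
        phi=float(phi),
        g_en_prev=kin_now.g_en,
        xi_prev=kin_now.xi,
    )


def friction_coefficient(phi, mu_ub: float, mu_b: float):
    """Friction coefficient of a partially bonded interface.

    Convex combination ``mu(phi) = phi*mu_ub + (1-phi)*mu_b``.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0.0) or np.any(phi > 1.0):
        raise ValueError("phi must lie in [0, 1]")
    out = phi * mu_ub + (1.0 - phi) * mu_b
    if out.ndim == 0:
        return float(out)
    return out


def normal_traction(g_n, phi, params: AdhesiveFrictionParams, phi0=1.0):
    """Signed scalar normal traction t_n (tension positive).

    Penetration (``g_n < 0``) gives the penalty pressure ``t_n = eps_n*g_n``
    (compressive, hence negative) for every law.  For the EMC a partially
    bonded point (``phi > 0``) carries the cohesive tensile traction
    ``phi0*t0*(g_n/g0)*exp(1 - g_n/g0)`` over ``0 <= g_n < g_b``; the traction
    drops sharply to zero at the cutoff ``g_b`` or once ``phi = 0``.  MC and
    classical Coulomb carry no tension.

    The traction *vector* exerted on the slave surface is ``-t_n * n`` with
    ``n`` the outward master normal.
    """
    g_n = np.asarray(g_n, dtype=float)
    phi = np.asarray(phi, dtype=float)
    phi0 = np.asarray(phi0, dtype=float)
    compress = params.eps_n * np.minimum(g_n, 0.0)
    if params.law is ContactLaw.EMC and params.t0 > 0.0:
        czm = phi0 * params.t0 * (g_n / params.g0) * np.exp(1.0 - g_n / params.g0)
        tensile = np.where((g_n >= 0.0) & (g_n < params.g_b) & (phi > 0.0), czm, 0.0)
    else:
        tensile = np.zeros_like(g_n)
    out = compress + tensile
    if out.ndim == 0:
        return float(out)
    return out


def sliding_limit(t_n, phi, params: AdhesiveFrictionParams, phi0=1.0):
    """Magnitude limit of the tangential traction during sliding.

    EMC: ``mu(phi) * (phi0*t0 - t_n)`` clamped at zero from below -- the
    adhesive offset keeps sliding friction alive under moderate tension and
    vanishes together with the bond amplitude ``phi0*t0``.  MC: ``mu(phi)*p``
    with ``p = -t_n`` the contact pressure (zero under tension).  COULOMB:
    ``mu_b * p``.
    """
    t_n = np.asarray(t_n, dtype=float)
    law = params.law
    if law is ContactLaw.COULOMB:
        mu = np.asarray(params.mu_b, dtype=float)
    else:
        mu = np.asarray(friction_coefficient(phi, params.mu_ub, params.mu_b))
    if law is ContactLaw.EMC:
        out = np.maximum(0.0, mu * (np.asarray(phi0, dtype=float) * params.t0 - t_n))
    else:
        p = np.maximum(0.0, -t_n)
        out = mu * p
    if out.ndim == 0:
        return float(out)
    return out


def slip_update(trial, limit):
    """Radial return of the trial tangential traction onto the slip surface.

    Returns ``(traction, status)``: the trial is kept when its magnitude is
    below the limit (STICK), otherwise scaled back onto the limit circle
    (SLIP).  The slip criterion ``f_s = ||t_t|| - t_slide <= 0`` always holds
    on return; the tie ``f_s = 0`` is classified as SLIP.
    """
    trial = np.asarray(trial, dtype=float)
    single = trial.ndim == 1
    t = np.atleast_2d(trial).astype(float)
    lim = np.broadcast_to(np.asarray(limit, dtype=float), t.shape[:-1]).copy()
    if np.any(lim < 0.0):
        raise ValueError("sliding limit must be non-negative")
    norm = np.linalg.norm(t, axis=-1)
    slip = norm >= lim
    scale = np.ones_like(norm)
    np.divide(lim, norm, out=scale, where=slip & (norm > 0.0))
    scale = np.where(slip & (norm == 0.0), 0.0, scale)
    t_out = t * scale[..., None]
    status = np.where(slip, PointStatus.SLIP, PointStatus.STICK).astype(np.int8)
    if single:
        return t_out[0], PointStatus(int(status[0]))
    return t_out, status


def smooth_penalty(phi0: float, t0: float, g0: float) -> float:
    """Penalty modulus making the normal traction C1 at zero gap.

    Matching the penalty slope to the cohesive-zone slope at ``g_n = 0``
    requires ``eps_n = phi0 * e * t0 / g0``.  Degenerates to zero for
    ``phi0 = 0``; callers must then fall back to a floor penalty.
    """
    if g0 <= 0.0:
        raise ValueError("g0 must be positive")
    return phi0 * np.e * t0 / g0


def calibrate_t0(F_max: float, phi0: float, R: float) -> float:
    """Invert the peak pull-out force of a uniformly separating coin interface.

    For uniform normal separation of a circular bonded interface of radius
    ``R`` the cohesive traction peaks simultaneously everywhere at
    ``phi0*t0``, so the peak force is ``F = phi0 * t0 * pi * R**2``; this
    returns ``t0 = F_max / (phi0 * pi * R**2)``.
    """
    if phi0 <= 0.0:
        raise ValueError("cannot calibrate t0 for phi0 <= 0")
    if R <= 0.0:
        raise ValueError("R must be positive")
    return F_max / (phi0 * np.pi * R**2)
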