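"""Master-slave contact discretization of the adhesive-frictional law.

The slave surface (peri-implant bone, which owns the bonding state) carries a
5x5 Gauss rule per quad facet; every slave quadrature point is projected onto
the master surface (implant) each Newton iteration.  Contact tractions follow
the point-wise law of :mod:`osseodebond.contact_law`; history variables are
held fixed during the Newton loop and committed once per converged load step.

Sign conventions: ``n`` is the outward unit master normal at the projection,
``g_n = (x_k - x_l) . n`` (negative in penetration), the scalar normal
traction ``t_N`` is tension-positive and the traction vector exerted on the
slave surface is ``t = -t_N n + t_t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_law import (
    AdhesiveFrictionParams,
    ContactLaw,
    PointStatus,
    damage_measure,
    friction_coefficient,
    normal_traction,
    state_function,
)

__all__ = ["ContactPair", "ContactEval", "project_points"]


def _quad_gauss(n: int):
    """Tensor Gauss rule on the bilinear reference square [-1,1]^2."""
    x, w = np.polynomial.legendre.leggauss(n)
    XI, ETA = np.meshgrid(x, x, indexing="ij")
    W = np.outer(w, w)
    return np.stack([XI.ravel(), ETA.ravel()], axis=1), W.ravel()


_QV = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)


def _quad_shape(xi: np.ndarray):
    """Bilinear shape functions N (...,4) at points xi (...,2)."""
    xi = np.asarray(xi, dtype=float)
    return 0.25 * (1.0 + xi[..., None, 0] * _QV[:, 0]) * (1.0 + xi[..., None, 1] * _QV[:, 1])


def _quad_shape_grad(xi: np.ndarray):
    """Gradients dN/d(xi,eta), shape (...,4,2)."""
    xi = np.asarray(xi, dtype=float)
    g = np.empty(xi.shape[:-1] + (4, 2))
    g[..., :, 0] = 0.25 * _QV[:, 0] * (1.0 + xi[..., None, 1] * _QV[:, 1])
    g[..., :, 1] = 0.25 * _QV[:, 1] * (1.0 + xi[..., None, 0] * _QV[:, 0])
    return g


def project_points(x_pts: np.ndarray, facets: np.ndarray, coords: np.ndarray,
                   search_radius: float, edge_tol: float):
    """Closest-point projection of points onto a set of bilinear quad facets.

    Gauss-Newton on each candidate facet (broad phase: inflated axis-aligned
    boxes), parametric coordinates clamped to the facet; projections whose
    in-plane (lateral) offset from the clamped point exceeds ``edge_tol`` are
    rejected, so points beyond the master boundary fall out of contact
    instead of being smeared onto the edge.

    Returns ``(facet_idx, xi, x_l, n, g_n)``; ``facet_idx = -1`` flags points
    with no admissible projection.
    """
    npts = x_pts.shape[0]
    best_score = np.full(npts, np.inf)
    facet_idx = np.full(npts, -1, dtype=np.int64)
    xi_out = np.zeros((npts, 2))
    x_l_out = np.zeros((npts, 3))
    n_out = np.zeros((npts, 3))
    g_n_out = np.zeros(npts)
    infl = search_radius + edge_tol
    for f in range(facets.shape[0]):
        xc = coords[facets[f]]  # (4,3)
        lo = xc.min(axis=0) - infl
        hi = xc.max(axis=0) + infl
        mask = np.all((x_pts >= lo) & (x_pts <= hi), axis=1)
        if not np.any(mask):
            continue
        p = x_pts[mask]
        xi = np.zeros((p.shape[0], 2))
        for _ in range(15):
            N = _quad_shape(xi)
            dN = _quad_shape_grad(xi)
            x = N @ xc
            J = np.einsum("paj,ai->pij", dN, xc)  # (p,3,2)
            r = p - x
            grad = -np.einsum("pij,pi->pj", J, r)
            H = np.einsum("pij,pik->pjk", J, J)
            cvec = 0.25 * (_QV[:, 0] * _QV[:, 1]) @ xc  # d2x/dxi deta
            rc = r @ cvec
            H[:, 0, 1] -= rc
            H[:, 1, 0] -= rc
            det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] * H[:, 1, 0]
            det = np.where(np.abs(det) < 1e-30, 1e-30, det)
            dxi = np.empty_like(xi)
            dxi[:, 0] = -(H[:, 1, 1] * grad[:, 0] - H[:, 0, 1] * grad[:, 1]) / det
            dxi[:, 1] = -(-H[:, 1, 0] * grad[:, 0] + H[:, 0, 0] * grad[:, 1]) / det
            xi = np.clip(xi + dxi, -1.0, 1.0)
            if np.max(np.abs(dxi)) < 1e-12:
                break
        N = _quad_shape(xi)
        dN = _quad_shape_grad(xi)
        x_l = N @ xc
        J = np.einsum("paj,ai->pij", dN, xc)
        nrm = np.cross(J[:, :, 0], J[:, :, 1])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        d = p - x_l
        g_n = np.einsum("pi,pi->p", d, nrm)
        lat2 = np.maximum(np.einsum("pi,pi->p", d, d) - g_n**2, 0.0)
        ok = (lat2 <= edge_tol**2) & (g_n <= search_radius)
        score = np.sqrt(lat2) * 1e6 + np.abs(g_n)
        idx = np.where(mask)[0]
        upd = ok & (score < best_score[idx])
        tgt = idx[upd]
        best_score[tgt] = score[upd]
        facet_idx[tgt] = f
        xi_out[tgt] = xi[upd]
        x_l_out[tgt] = x_l[upd]
        n_out[tgt] = nrm[upd]
        g_n_out[tgt] = g_n[upd]
    return facet_idx, xi_out, x_l_out, n_out, g_n_out


@dataclass
class ContactEval:
    """One contact evaluation: tractions, assembly triplets, diagnostics."""

    facet_idx: np.ndarray
    xi: np.ndarray
    x_l: np.ndarray
    n: np.ndarray
    g_n: np.ndarray
    t_N: np.ndarray
    t_t: np.ndarray
    status: np.ndarray
    x_k: np.ndarray
    f_dofs: np.ndarray
    f_vals: np.ndarray
    k_rows: np.ndarray
    k_cols: np.ndarray
    k_vals: np.ndarray


class ContactPair:
    """A slave/master surface pairing with persistent per-point bond state."""

    def __init__(self, mesh, slave_surface: str, master_surface: str,
                 params: AdhesiveFrictionParams, gauss_n: int = 5,
                 search_radius: float | None = None, edge_tol_frac: float = 0.002):
        self.mesh = mesh
        self.params = params
        self.slave_facets = np.asarray(mesh.surfaces[slave_surface], dtype=np.int64)
        self.master_facets = np.asarray(mesh.surfaces[master_surface], dtype=np.int64)
        xi_g, w_g = _quad_gauss(gauss_n)
        self.gauss_xi = xi_g
        self.N_s = _quad_shape(xi_g)  # (ngp, 4)
        # reference-configuration area weights per slave quadrature point
        dN = _quad_shape_grad(xi_g)  # (ngp, 4, 2)
        xc = mesh.nodes[self.slave_facets]  # (nf, 4, 3)
        J = np.einsum("gaj,fai->fgij", dN, xc)
        jac = np.linalg.norm(np.cross(J[..., :, 0], J[..., :, 1]), axis=-1)
        self.weights = (jac * w_g[None, :]).ravel()  # (npts,)
        nf, ngp = self.slave_facets.shape[0], xi_g.shape[0]
        self.n_points = nf * ngp
        self.point_facet = np.repeat(np.arange(nf), ngp)
        # master facet size scales
        xm = mesh.nodes[self.master_facets]
        areas = np.linalg.norm(
            np.cross(xm[:, 1] - xm[:, 0], xm[:, 3] - xm[:, 0]), axis=1)
        size = float(np.sqrt(np.median(areas)))
        self.edge_tol = edge_tol_frac * size
        self.search_radius = search_radius if search_radius is not None else 3.0 * params.g_b
        # vertex incidence for the smoothed (averaged) master normal field:
        # bilinear facets carry crease discontinuities in their normals, so
        # gap and traction directions use normals averaged at the master
        # vertices and interpolated over the facet (continuous across edges)
        self._m_verts, self._m_local = np.unique(self.master_facets,
                                                 return_inverse=True)
        self._m_local = self._m_local.reshape(self.master_facets.shape)
        npts = self.n_points
        # persistent history (committed once per converged step)
        self.phi0 = np.zeros(npts)
        self.g_s = np.zeros(npts)
        self.g_sn = np.zeros(npts)
        self.phi = np.zeros(npts)
        self.g_en_prev = np.zeros(npts)
        self.prev_facet = np.full(npts, -1, dtype=np.int64)
        self.prev_xi = np.zeros((npts, 2))
        self.x_k_comm = np.zeros((npts, 3))
        self.x_l_comm = np.zeros((npts, 3))
        self.t_t_prev = np.zeros((npts, 3))
        self.status = np.full(npts, PointStatus.OPEN, dtype=np.int8)
        self._committed = True

    # ------------------------------------------------------------------
    def slave_positions(self, coords: np.ndarray) -> np.ndarray:
        xc = coords[self.slave_facets]  # (nf,4,3)
        return np.einsum("ga,fai->fgi", self.N_s, xc).reshape(-1, 3)

    def _master_point_positions(self, coords: np.ndarray, facet_idx, xi) -> np.ndarray:
        out = np.zeros((facet_idx.shape[0], 3))
        ok = facet_idx >= 0
        if np.any(ok):
            N = _quad_shape(xi[ok])
            out[ok] = np.einsum("pa,pai->pi", N, coords[self.master_facets[facet_idx[ok]]])
        return out

    @property
    def g_d(self) -> np.ndarray:
        return damage_measure(self.g_s, self.g_sn, self.params.law)

    # ------------------------------------------------------------------
    def evaluate(self, coords: np.ndarray,
                 frozen_status: np.ndarray | None = None) -> ContactEval:
        """Tractions, nodal forces and tangent triplets at configuration ``coords``.

        History variables are those of the last commit; stick/slip/open status
        is re-decided from the current geometry (semi-smooth Newton).  When
        ``frozen_status`` is given the active/stick/slip classification is
        taken from it instead, which removes set-chattering once the Newton
        iteration is close to the solution.
        """
        par = self.params
        x_k = self.slave_positions(coords)
        facet_idx, xi, x_l, n, g_n = project_points(
            x_k, self.master_facets, coords, self.search_radius, self.edge_tol)
        valid = facet_idx >= 0
        # replace facet normals by the smoothed vertex-averaged normal field
        xm = coords[self.master_facets]
        nf = np.cross(xm[:, 2] - xm[:, 0], xm[:, 3] - xm[:, 1])  # 2x oriented area
        nv = np.zeros((self._m_verts.size, 3))
        np.add.at(nv, self._m_local.ravel(), np.repeat(nf, 4, axis=0))
        nv /= np.linalg.norm(nv, axis=1, keepdims=True)
        if np.any(valid):
            iv = valid
            N = _quad_shape(xi[iv])
            ns = np.einsum("pa,pai->pi", N, nv[self._m_local[facet_idx[iv]]])
            ns /= np.linalg.norm(ns, axis=1, keepdims=True)
            n[iv] = ns
            g_n[iv] = np.einsum("pi,pi->p", x_k[iv] - x_l[iv], ns)
        t_N = np.where(valid, normal_traction(g_n, self.phi, par, self.phi0), 0.0)
        if par.law is ContactLaw.EMC:
            open_pt = ~valid | (g_n >= par.g_b) | ((g_n >= 0.0) & (self.phi <= 0.0) & (par.t0 > 0.0))
        else:
            open_pt = ~valid | (g_n >= 0.0)
        active = valid & ~open_pt

        # tangential elastic predictor relative to the last committed state
        t_trial = np.zeros((self.n_points, 3))
        has_prev = self.prev_facet >= 0
        anchored = active & has_prev
        if np.any(anchored):
            x_lm = self._master_point_positions(coords, self.prev_facet, self.prev_xi)
            dg = (x_k - self.x_k_comm) - (x_lm - self.x_l_comm)
            t_prev = self.t_t_prev
            tt = t_prev - par.eps_t * dg
            # project onto the current tangent plane
            tt -= np.einsum("pi,pi->p", tt, n)[:, None] * n
            t_trial[anchored] = tt[anchored]

        mu = np.where(
            par.law is ContactLaw.COULOMB, par.mu_b,
            friction_coefficient(np.clip(self.phi, 0.0, 1.0), par.mu_ub, par.mu_b))
        if par.law is ContactLaw.EMC:
            limit = np.maximum(0.0, mu * (self.phi0 * par.t0 - t_N))
        else:
            limit = mu * np.maximum(0.0, -t_N)
        limit = np.where(active, limit, 0.0)

        norm_tr = np.linalg.norm(t_trial, axis=1)
        if frozen_status is not None:
            active = valid & (frozen_status != PointStatus.OPEN)
            limit = np.where(active, limit, 0.0)
            slip = active & (frozen_status == PointStatus.SLIP)
            stick = active & ~slip
        else:
            slip = active & (norm_tr >= limit)
            stick = active & ~slip
        scale = np.ones(self.n_points)
        np.divide(limit, norm_tr, out=scale, where=slip & (norm_tr > 0.0))
        scale[slip & (norm_tr == 0.0)] = 0.0
        t_t = t_trial * scale[:, None]
        status = np.full(self.n_points, PointStatus.OPEN, dtype=np.int8)
        status[stick] = PointStatus.STICK
        status[slip] = PointStatus.SLIP

        t_vec = -t_N[:, None] * n + t_t

        # --- assemble nodal forces and tangent triplets over active points
        ai = np.where(active)[0]
        f_dofs = np.zeros(0, dtype=np.int64)
        f_vals = np.zeros(0)
        k_rows = np.zeros(0, dtype=np.int64)
        k_cols = np.zeros(0, dtype=np.int64)
        k_vals = np.zeros(0)
        if ai.size:
            w = self.weights[ai]
            sl_nodes = self.slave_facets[self.point_facet[ai]]       # (m,4)
            ms_nodes = self.master_facets[facet_idx[ai]]             # (m,4)
            N_sl = self.N_s[np.tile(np.arange(self.N_s.shape[0]),
                                    self.slave_facets.shape[0])[ai]]  # (m,4)
            N_ms = _quad_shape(xi[ai])                               # (m,4)
            s_fac = np.concatenate([-N_sl, N_ms], axis=1)            # (m,8)
            nodes8 = np.concatenate([sl_nodes, ms_nodes], axis=1)    # (m,8)
            tv = t_vec[ai]
            # residual contribution r_p = w * s_fac * t_vec
            fv = w[:, None, None] * s_fac[:, :, None] * tv[:, None, :]
            f_dofs = (3 * nodes8[:, :, None] + np.arange(3)[None, None, :]).ravel()
            f_vals = fv.ravel()

            # point-wise traction derivative D = dt_vec/dg_e
            nn = n[ai]
            eye = np.eye(3)
            tang = eye[None, :, :] - nn[:, :, None] * nn[:, None, :]
            dtN = self._normal_slope(g_n[ai], ai)
            D = -dtN[:, None, None] * (nn[:, :, None] * nn[:, None, :])
            st = stick[ai]
            sp = slip[ai]
            D[st] += -par.eps_t * tang[st]
            if np.any(sp):
                tr = t_trial[ai][sp]
                nrm = np.linalg.norm(tr, axis=1)
                pos = nrm > 1e-300
                dirv = np.zeros_like(tr)
                dirv[pos] = tr[pos] / nrm[pos, None]
                lim = limit[ai][sp]
                fac = np.zeros_like(nrm)
                fac[pos] = lim[pos] / nrm[pos]
                tang_sp = tang[sp]
                dd = dirv[:, :, None] * dirv[:, None, :]
                Dsp = -par.eps_t * fac[:, None, None] * (tang_sp - dd)
                # limit varies with the normal traction: dlimit/dg_n = -mu * dt_N/dg_n
                dlim = -mu[ai][sp] * dtN[sp]
                Dsp += dirv[:, :, None] * (dlim[:, None] * nn[sp])[:, None, :]
                D[sp] += Dsp
            # K block = -w * (s s^T) x D
            ss = s_fac[:, :, None] * s_fac[:, None, :]
            Kb = -w[:, None, None, None, None] * ss[:, :, :, None, None] * D[:, None, None, :, :]
            Kb = Kb.transpose(0, 1, 3, 2, 4)  # (m, 8,3, 8,3)
            dofs8 = 3 * nodes8[:, :, None] + np.arange(3)[None, None, :]
            dofs8 = dofs8.reshape(-1, 24)
            k_rows = np.repeat(dofs8, 24, axis=1).ravel()
            k_cols = np.tile(dofs8, (1, 24)).ravel()
            k_vals = Kb.reshape(-1, 24 * 24).ravel()

        return ContactEval(facet_idx, xi, x_l, n, g_n, t_N, t_t, status, x_k,
                           f_dofs, f_vals, k_rows, k_cols, k_vals)

    def _normal_slope(self, g_n: np.ndarray, ai: np.ndarray) -> np.ndarray:
        """dt_N/dg_n at the given active points."""
        par = self.params
        out = np.where(g_n < 0.0, par.eps_n, 0.0)
        if par.law is ContactLaw.EMC and par.t0 > 0.0:
            czm = (self.phi0[ai] * par.t0 / par.g0
                   * np.exp(1.0 - g_n / par.g0) * (1.0 - g_n / par.g0))
            tens = (g_n >= 0.0) & (g_n < par.g_b) & (self.phi[ai] > 0.0)
            out = np.where(tens, czm, out)
        return out

    # ------------------------------------------------------------------
    def commit(self, coords: np.ndarray, ev: ContactEval) -> None:
        """Commit damage and stick references after a converged step.

        Damage accumulates wherever a projection exists and the point carries
        traction; a point whose traction has dropped to zero (OPEN) is frozen
        and its anchor cleared, so re-contact restarts accumulation from the
        new projection.
        """
        par = self.params
        active = ev.status != PointStatus.OPEN
        upd = active & (self.prev_facet >= 0)
        if np.any(upd):
            x_lm_prev = self._master_point_positions(coords, self.prev_facet, self.prev_xi)
            ds = np.linalg.norm(ev.x_l - x_lm_prev, axis=1)
            dgn = np.abs(ev.g_n - self.g_en_prev)
            self.g_s[upd] += ds[upd]
            self.g_sn[upd] += dgn[upd]
        g_d = damage_measure(self.g_s, self.g_sn, par.law)
        phi_new = state_function(g_d, self.phi0, par.a_s, par.b_s)
        self.phi = np.minimum(self.phi, phi_new)
        # store the new references where contact persists; clear where lost
        self.prev_facet = np.where(active, ev.facet_idx, -1)
        self.prev_xi = np.where(active[:, None], ev.xi, 0.0)
        self.x_k_comm = np.where(active[:, None], ev.x_k, 0.0)
        self.x_l_comm = np.where(active[:, None], ev.x_l, 0.0)
        self.g_en_prev = np.where(active, ev.g_n, 0.0)
        self.t_t_prev = np.where(active[:, None], ev.t_t, 0.0)
        self.status = ev.status.copy()

    # ------------------------------------------------------------------
    def set_osseointegration(self, phi0: float, coords: np.ndarray) -> None:
        """Assign a homogeneous initial bonding state to the current interface.

        Points currently within cohesive range (projection with
        ``g_n < g_b``) become bonded at ``phi0`` with their accumulated
        damage reset; all other points stay unbonded.  Contact tractions and
        stick references are preserved (bonding does not move the interface).
        """
        x_k = self.slave_positions(coords)
        facet_idx, xi, x_l, n, g_n = project_points(
            x_k, self.master_facets, coords, self.search_radius, self.edge_tol)
        bonded = (facet_idx >= 0) & (g_n < self.params.g_b)
        self.phi0 = np.where(bonded, float(phi0), 0.0)
        self.g_s[:] = 0.0
        self.g_sn[:] = 0.0
        self.phi = self.phi0.copy()

    def mean_bonding(self) -> float:
        """Area-weighted average bonding state over the bonded interface."""
        if self.n_points == 0:
            raise ValueError("empty contact pair")
        mask = self.phi0 > 0.0
        if not np.any(mask):
            return 0.0
        return float(np.sum(self.weights[mask] * self.phi[mask])
                     / np.sum(self.weights[mask]))

    def adhesive_capacity(self) -> float:
        """Upper bound of the total tensile force the interface can carry."""
        if self.params.law is not ContactLaw.EMC:
            return 0.0
        alive = self.phi > 0.0
        return float(np.sum(self.weights[alive] * self.phi0[alive]) * self.params.t0)

    def state_table(self):
        """Per-point state for dumping (positions from last commit)."""
        import pandas as pd

        return pd.DataFrame({
            "x": self.x_k_comm[:, 0], "y": self.x_k_comm[:, 1], "z": self.x_k_comm[:, 2],
            "phi0": self.phi0, "phi": self.phi, "g_s": self.g_s, "g_sn": self.g_sn,
            "g_d": self.g_d, "status": self.status,
        })
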