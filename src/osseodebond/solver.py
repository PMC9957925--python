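"""Global assembly, constraint handling and the quasi-static Newton solver.

Constraints are handled by a sparse reduction ``u = u_p + T q``: Dirichlet
dofs carry prescribed values, force-held groups (e.g. a constant vertical
resultant on the implant top while sliding laterally) are condensed to a
single master unknown that keeps the group displacements equal and receives
the prescribed total force.  Contact history is frozen inside the Newton
loop and committed on convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .contact_fe import ContactPair
from .elements import element_residual_stiffness, precompute_quadrature
from .materials import ElasticParams

__all__ = ["SolverSettings", "StepBC", "Coupling", "FEModel", "NonConvergence"]


class NonConvergence(RuntimeError):
    """Newton iteration failed to converge (after any step bisection)."""


@dataclass(frozen=True)
class SolverSettings:
    tol_rel: float = 1e-6
    tol_abs: float = 1e-4     # N, absolute force residual floor
    max_iter: int = 40
    bisect_depth: int = 5
    line_search: bool = True
    freeze_after: int = 10    # freeze the contact active set after this iteration
    # penalty contact on faceted surfaces leaves a small non-smooth residual
    # floor (points crossing facet/boundary creases); accept a stagnated
    # iteration once the residual is below this fraction of the contact force
    stall_rel: float = 5e-3


@dataclass
class Coupling:
    """Equal-displacement group on one axis carrying a total applied force."""

    dofs: np.ndarray
    force: float


@dataclass
class StepBC:
    """Boundary conditions of one load step (absolute target values)."""

    dirichlet_dofs: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    dirichlet_vals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    couplings: list = field(default_factory=list)

    def interpolated(self, u_prev_vals: np.ndarray, frac: float,
                     coupling_prev: list[float]) -> "StepBC":
        """BC at fraction ``frac`` between the previous state and this step."""
        vals = u_prev_vals + frac * (self.dirichlet_vals - u_prev_vals)
        cps = [Coupling(c.dofs, fp + frac * (c.force - fp))
               for c, fp in zip(self.couplings, coupling_prev)]
        return StepBC(self.dirichlet_dofs, vals, cps)


class FEModel:
    """Finite-strain quasi-static FE model with penalty contact."""

    def __init__(self, mesh, materials: dict[str, ElasticParams],
                 pairs: list[ContactPair] | None = None,
                 settings: SolverSettings | None = None):
        self.mesh = mesh
        self.materials = materials
        self.pairs = pairs or []
        self.settings = settings or SolverSettings()
        self.u = np.zeros((mesh.n_nodes, 3))
        self.ndof = 3 * mesh.n_nodes
        self._groups = []
        for body, mat in materials.items():
            eids = np.where(mesh.body == body)[0]
            if eids.size == 0:
                continue
            conn = mesh.hexes[eids]
            dNdX, wdetJ = precompute_quadrature(mesh.nodes[conn])
            dofs = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
            rows = np.repeat(dofs, 24, axis=1).ravel()
            cols = np.tile(dofs, (1, 24)).ravel()
            self._groups.append((mat, conn, dNdX, wdetJ, dofs, rows, cols))
        self.last_reactions = np.zeros(self.ndof)

    # ------------------------------------------------------------------
    def bulk_residual_stiffness(self, u: np.ndarray):
        fint = np.zeros(self.ndof)
        rows_all, cols_all, vals_all = [], [], []
        for mat, conn, dNdX, wdetJ, dofs, rows, cols in self._groups:
            disp = u.reshape(-1, 3)[conn]
            fe, Ke = element_residual_stiffness(disp, dNdX, wdetJ, mat)
            np.add.at(fint, dofs.ravel(), fe.reshape(-1, 24).ravel())
            rows_all.append(rows)
            cols_all.append(cols)
            vals_all.append(Ke.ravel())
        return fint, rows_all, cols_all, vals_all

    def _residual_system(self, u: np.ndarray, frozen: list | None = None):
        fint, rows, cols, vals = self.bulk_residual_stiffness(u)
        coords = self.mesh.nodes + u
        evals = []
        r = fint.copy()
        for ip, pair in enumerate(self.pairs):
            ev = pair.evaluate(coords, None if frozen is None else frozen[ip])
            evals.append(ev)
            np.add.at(r, ev.f_dofs, ev.f_vals)
            rows.append(ev.k_rows)
            cols.append(ev.k_cols)
            vals.append(ev.k_vals)
        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ndof, self.ndof)).tocsr()
        return r, K, evals

    # ------------------------------------------------------------------
    def _reduction(self, bc: StepBC):
        """Build u_p, T and the reduced external force for the given BC."""
        presc = np.zeros(self.ndof, dtype=bool)
        u_p = np.zeros(self.ndof)
        presc[bc.dirichlet_dofs] = True
        u_p[bc.dirichlet_dofs] = bc.dirichlet_vals
        coupled = np.zeros(self.ndof, dtype=bool)
        for c in bc.couplings:
            if np.any(presc[c.dofs]):
                raise ValueError("dof both prescribed and force-coupled")
            coupled[c.dofs] = True
        free = ~presc & ~coupled
        nfree = int(free.sum())
        ncpl = len(bc.couplings)
        nred = nfree + ncpl
        rows = [np.where(free)[0]]
        cols = [np.arange(nfree)]
        for i, c in enumerate(bc.couplings):
            rows.append(c.dofs)
            cols.append(np.full(c.dofs.shape[0], nfree + i))
        T = sp.csr_matrix(
            (np.ones(sum(len(r) for r in rows)),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ndof, nred))
        F_red = np.zeros(nred)
        for i, c in enumerate(bc.couplings):
            F_red[nfree + i] = c.force
        return u_p, T, F_red, free, nfree

    def _compose(self, bc: StepBC, u_p, T, free, nfree, q, cpl_base):
        u = u_p.copy()
        u[free] = q[:nfree]
        for i, c in enumerate(bc.couplings):
            u[c.dofs] = cpl_base[i] + q[nfree + i]
        return u.reshape(-1, 3)

    # ------------------------------------------------------------------
    def solve_step(self, bc: StepBC, commit: bool = True):
        """Newton-solve one load step; on convergence commit contact history.

        Non-convergence triggers recursive bisection of the BC increment up
        to ``settings.bisect_depth`` before raising :class:`NonConvergence`.
        """
        prev_vals = self.u.reshape(-1)[bc.dirichlet_dofs].copy()
        prev_forces = [self._current_coupling_force(c) for c in bc.couplings]
        self._solve_bisect(bc, prev_vals, prev_forces, depth=0)
        if commit:
            coords = self.mesh.nodes + self.u
            for pair, ev in zip(self.pairs, self._last_evals):
                pair.commit(coords, ev)
        return self

    def _current_coupling_force(self, c: Coupling) -> float:
        # force currently carried by the group = sum of residual entries
        return float(np.sum(self.last_reactions[c.dofs]))

    def _solve_bisect(self, bc: StepBC, prev_vals, prev_forces, depth: int):
        try:
            self._newton(bc)
        except NonConvergence:
            if depth >= self.settings.bisect_depth:
                raise
            u_saved = self.u.copy()
            half = bc.interpolated(prev_vals, 0.5, prev_forces)
            try:
                self._solve_bisect(half, prev_vals, prev_forces, depth + 1)
                half_vals = self.u.reshape(-1)[bc.dirichlet_dofs].copy()
                half_forces = [c.force for c in half.couplings]
                self._solve_bisect(bc, half_vals, half_forces, depth + 1)
            except NonConvergence:
                self.u = u_saved
                raise

    def _newton(self, bc: StepBC):
        st = self.settings
        u_p, T, F_red, free, nfree = self._reduction(bc)
        flat = self.u.reshape(-1)
        q = np.zeros(T.shape[1])
        q[:nfree] = flat[free]
        cpl_base = []
        for i, c in enumerate(bc.couplings):
            base = flat[c.dofs].mean()
            cpl_base.append(base)
        u = self._compose(bc, u_p, T, free, nfree, q, cpl_base)
        frozen = None
        r, K, evals = self._residual_system(u)
        R = T.T @ r - F_red
        res_hist = []
        for it in range(st.max_iter):
            if it == st.freeze_after and self.pairs:
                # near the solution: pin the active/stick/slip sets to kill
                # set-chattering and iterate the remaining smooth problem
                frozen = [ev.status for ev in evals]
                r, K, evals = self._residual_system(u, frozen)
                R = T.T @ r - F_red
            scale = max(float(np.linalg.norm(T.T @ r)), float(np.linalg.norm(F_red)), 1.0)
            resn = float(np.linalg.norm(R))
            res_hist.append(resn)
            converged = resn <= st.tol_rel * scale + st.tol_abs
            if not converged and it > st.freeze_after + 5 and len(res_hist) >= 6:
                fc = np.zeros(self.ndof)
                for ev in evals:
                    np.add.at(fc, ev.f_dofs, ev.f_vals)
                f_scale = max(float(np.linalg.norm(fc)),
                              float(np.linalg.norm(F_red)), 1.0)
                stalled = resn > 0.9 * min(res_hist[:-5])
                converged = stalled and resn <= st.stall_rel * f_scale
            if converged:
                self.u = u
                self.last_reactions = r
                self._last_evals = evals
                self.newton_iters = it
                return
            Kr = (T.T @ K @ T).tocsc()
            try:
                dq = spla.spsolve(Kr, -R)
            except Exception as exc:  # singular factorization
                raise NonConvergence(f"linear solve failed: {exc}") from exc
            if not np.all(np.isfinite(dq)):
                raise NonConvergence("non-finite Newton update")
            step = 1.0
            for _ in range(5):
                q_try = q + step * dq
                u_try = self._compose(bc, u_p, T, free, nfree, q_try, cpl_base)
                try:
                    r_try, K_try, ev_try = self._residual_system(u_try, frozen)
                except ValueError:  # element inversion
                    step *= 0.5
                    continue
                R_try = T.T @ r_try - F_red
                if (not st.line_search) or np.linalg.norm(R_try) < max(2.0 * resn, 10 * st.tol_abs) or step <= 0.126:
                    q, u, r, K, R, evals = q_try, u_try, r_try, K_try, R_try, ev_try
                    break
                step *= 0.5
            else:
                raise NonConvergence("line search failed")
        raise NonConvergence(
            f"no convergence in {st.max_iter} iterations (residual {np.linalg.norm(R):.3e})")

    # ------------------------------------------------------------------
    def reaction_force(self, nodes: np.ndarray) -> np.ndarray:
        """Total constraint reaction (N) on a node set at the last state."""
        dofs = (3 * nodes[:, None] + np.arange(3)[None, :]).ravel()
        return self.last_reactions[dofs].reshape(-1, 3).sum(axis=0)

    def reaction_moment_z(self, nodes: np.ndarray, center: np.ndarray) -> float:
        """Torque about the +z axis through ``center`` from nodal reactions."""
        f = self.last_reactions.reshape(-1, 3)[nodes]
        x = (self.mesh.nodes + self.u)[nodes] - center
        return float(np.sum(x[:, 0] * f[:, 1] - x[:, 1] * f[:, 0]))
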