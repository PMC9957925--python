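"""Structured hexahedral mesh generation.

All meshes the package needs are generated programmatically: rectangular
blocks, mapped-square cylinders (coin implant), and spherical O-grid meshes
built on a cubed-hemisphere parametrization (acetabular cup shell, and the
bone block with a hemispherical cavity).  Meshes carry named surface patch
sets (oriented quad facets) and named node sets for boundary conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HexMesh",
    "block_mesh",
    "cylinder_mesh",
    "cubed_hemisphere_grid",
    "hemisphere_shell_mesh",
    "cavity_block_mesh",
]


@dataclass
class HexMesh:
    """Nodes, 8-node hexahedra, surface patch sets and node sets.

    ``surfaces`` maps a patch name to an (nf, 4) array of node indices whose
    winding gives the outward normal of the owning body via the right-hand
    rule.  ``body`` tags each element with the name of the body it belongs
    to (used to pick the material).
    """

    nodes: np.ndarray
    hexes: np.ndarray
    body: np.ndarray
    surfaces: dict = field(default_factory=dict)
    node_sets: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.hexes.shape[0]

    def nodes_of_surface(self, name: str) -> np.ndarray:
        return np.unique(self.surfaces[name])

    def merge(self, other: "HexMesh") -> "HexMesh":
        """Concatenate two meshes without welding (disjoint bodies)."""
        off = self.n_nodes
        nodes = np.vstack([self.nodes, other.nodes])
        hexes = np.vstack([self.hexes, other.hexes + off])
        body = np.concatenate([self.body, other.body])
        surfaces = dict(self.surfaces)
        for k, v in other.surfaces.items():
            surfaces[k] = v + off
        node_sets = dict(self.node_sets)
        for k, v in other.node_sets.items():
            node_sets[k] = v + off
        return HexMesh(nodes, hexes, body, surfaces, node_sets)

    def translated(self, shift) -> "HexMesh":
        m = HexMesh(self.nodes + np.asarray(shift, float), self.hexes, self.body,
                    dict(self.surfaces), dict(self.node_sets))
        return m


def _grid_hexes(ni: int, nj: int, nk: int) -> np.ndarray:
    """Connectivity of an (ni+1)x(nj+1)x(nk+1) structured node grid."""
    def nid(i, j, k):
        return (i * (nj + 1) + j) * (nk + 1) + k

    hexes = []
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                hexes.append([
                    nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ])
    return np.array(hexes, dtype=np.int64)


def block_mesh(lx: float, ly: float, lz: float, nx: int, ny: int, nz: int,
               origin=(0.0, 0.0, 0.0), body: str = "bone") -> HexMesh:
    """Structured block [0,lx]x[0,ly]x[-lz,0] shifted by ``origin``.

    Surfaces: ``top`` (z = 0, outward +z), ``bottom`` (z = -lz, outward -z).
    Node sets: ``top``, ``bottom``.
    """
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    zs = np.linspace(-lz, 0.0, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1) + np.asarray(origin, float)
    hexes = _grid_hexes(nx, ny, nz)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    top, bot = [], []
    for i in range(nx):
        for j in range(ny):
            # outward +z: counterclockwise seen from above
            top.append([nid(i, j, nz), nid(i + 1, j, nz), nid(i + 1, j + 1, nz), nid(i, j + 1, nz)])
            bot.append([nid(i, j, 0), nid(i, j + 1, 0), nid(i + 1, j + 1, 0), nid(i + 1, j, 0)])
    surfaces = {"top": np.array(top), "bottom": np.array(bot)}
    node_sets = {
        "top": np.array([nid(i, j, nz) for i in range(nx + 1) for j in range(ny + 1)]),
        "bottom": np.array([nid(i, j, 0) for i in range(nx + 1) for j in range(ny + 1)]),
    }
    return HexMesh(nodes, hexes, np.array([body] * hexes.shape[0]), surfaces, node_sets)


def _square_to_disk(u: np.ndarray, v: np.ndarray):
    """Elliptical mapping of [-1,1]^2 onto the unit disk."""
    x = u * np.sqrt(1.0 - 0.5 * v**2)
    y = v * np.sqrt(1.0 - 0.5 * u**2)
    return x, y


def cylinder_mesh(R: float, H: float, n_plan: int, nz: int, body: str = "implant",
                  area_preserving: bool = True) -> HexMesh:
    """Cylinder of radius R, axis +z, base at z = 0, meshed n_plan x n_plan x nz.

    The circular cross-section is a mapped square; the polygonal footprint
    slightly under-covers the disk at coarse resolution, so by default the
    cross-section is scaled to make the footprint area exactly pi R^2 (this
    removes a systematic bias in integrated contact forces).

    Surfaces: ``bottom`` (z = 0, outward -z), ``top``.  Node sets: ``top``,
    ``bottom``.
    """
    s = np.linspace(-1.0, 1.0, n_plan + 1)
    U, V = np.meshgrid(s, s, indexing="ij")
    X, Y = _square_to_disk(U, V)
    if area_preserving:
        # footprint polygon area via boundary vertices (shoelace)
        bx, by = [], []
        for i in range(n_plan):        # edge v=-1
            bx.append(X[i, 0]); by.append(Y[i, 0])
        for j in range(n_plan):        # edge u=+1
            bx.append(X[-1, j]); by.append(Y[-1, j])
        for i in range(n_plan, 0, -1):  # edge v=+1
            bx.append(X[i, -1]); by.append(Y[i, -1])
        for j in range(n_plan, 0, -1):  # edge u=-1
            bx.append(X[0, j]); by.append(Y[0, j])
        bx = np.array(bx); by = np.array(by)
        area = 0.5 * abs(np.sum(bx * np.roll(by, -1) - np.roll(bx, -1) * by))
        scale = np.sqrt(np.pi / area)
        X, Y = X * scale, Y * scale
    zs = np.linspace(0.0, H, nz + 1)
    nn_plan = (n_plan + 1) ** 2
    nodes = np.empty(((nz + 1) * nn_plan, 3))
    for k, z in enumerate(zs):
        nodes[k * nn_plan:(k + 1) * nn_plan, 0] = R * X.ravel()
        nodes[k * nn_plan:(k + 1) * nn_plan, 1] = R * Y.ravel()
        nodes[k * nn_plan:(k + 1) * nn_plan, 2] = z

    def nid(i, j, k):
        return k * nn_plan + i * (n_plan + 1) + j

    hexes = []
    bot, top = [], []
    for i in range(n_plan):
        for j in range(n_plan):
            for k in range(nz):
                hexes.append([
                    nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ])
            bot.append([nid(i, j, 0), nid(i, j + 1, 0), nid(i + 1, j + 1, 0), nid(i + 1, j, 0)])
            top.append([nid(i, j, nz), nid(i + 1, j, nz), nid(i + 1, j + 1, nz), nid(i, j + 1, nz)])
    hexes = np.array(hexes, dtype=np.int64)
    surfaces = {"bottom": np.array(bot), "top": np.array(top)}
    node_sets = {
        "bottom": np.arange(nn_plan),
        "top": np.arange(nz * nn_plan, (nz + 1) * nn_plan),
    }
    return HexMesh(nodes, hexes, np.array([body] * hexes.shape[0]), surfaces, node_sets)


def cubed_hemisphere_grid(n: int):
    """Quad grid of the lower unit hemisphere via cube projection.

    Five cube faces are used: the full bottom face (n x n) and the lower half
    of the four side faces (n x m, m = n//2, requires even n).  Points are
    radially projected onto the unit sphere.  Returns ``(directions, quads,
    pole_patch)`` where ``pole_patch`` indexes the quads of the bottom face
    (used to attach the ancillary shaft).  Quad winding is outward (away from
    the center).
    """
    if n % 2 != 0:
        raise ValueError("cubed_hemisphere_grid requires even n")
    m = n // 2
    pts: list[tuple] = []
    index: dict[tuple, int] = {}

    def add(p):
        key = tuple(np.round(p, 9))
        if key not in index:
            index[key] = len(pts)
            pts.append(key)
        return index[key]

    quads = []
    pole_patch = []
    s = np.linspace(-1.0, 1.0, n + 1)
    t = np.linspace(-1.0, 0.0, m + 1)

    def face_grid(fn, ni, si, sj):
        ids = np.empty((len(si), len(sj)), dtype=np.int64)
        for i, a in enumerate(si):
            for j, b in enumerate(sj):
                ids[i, j] = add(fn(a, b))
        return ids

    # bottom face z=-1
    ids = face_grid(lambda a, b: (a, b, -1.0), n, s, s)
    for i in range(n):
        for j in range(n):
            pole_patch.append(len(quads))
            quads.append([ids[i, j], ids[i + 1, j], ids[i + 1, j + 1], ids[i, j + 1]])
    # side faces, z in [-1, 0]
    faces = [
        lambda a, b: (1.0, a, b),
        lambda a, b: (-1.0, a, b),
        lambda a, b: (a, 1.0, b),
        lambda a, b: (a, -1.0, b),
    ]
    for fn in faces:
        ids = face_grid(fn, n, s, t)
        for i in range(n):
            for j in range(m):
                quads.append([ids[i, j], ids[i + 1, j], ids[i + 1, j + 1], ids[i, j + 1]])

    P = np.array(pts, dtype=float)
    D = P / np.linalg.norm(P, axis=1, keepdims=True)
    quads = np.array(quads, dtype=np.int64)
    # enforce outward winding (normal pointing away from origin)
    for q in quads:
        v0, v1, v2 = D[q[0]], D[q[1]], D[q[2]]
        nrm = np.cross(v1 - v0, v2 - v0)
        c = D[q].mean(axis=0)
        if nrm @ c < 0.0:
            q[:] = q[::-1]
    return D, quads, np.array(pole_patch, dtype=np.int64)


def _shell_hexes(quads: np.ndarray, nn_shell: int, n_layers: int):
    """Hexes between consecutive node shells; layer k nodes at offset k*nn_shell.

    The quad winding is outward; layer k is the inner shell, so the hex base
    (first four nodes) sits on the inner shell with the outward layer on top.
    """
    hexes = []
    for k in range(n_layers):
        lo, hi = k * nn_shell, (k + 1) * nn_shell
        for q in quads:
            hexes.append([q[0] + lo, q[1] + lo, q[2] + lo, q[3] + lo,
                          q[0] + hi, q[1] + hi, q[2] + hi, q[3] + hi])
    return np.array(hexes, dtype=np.int64)


def hemisphere_shell_mesh(R_outer: float, thickness: float, n: int, n_layers: int = 1,
                          body: str = "implant") -> HexMesh:
    """Hemispherical shell (acetabular cup), pole pointing -z, center at origin.

    Surfaces: ``outer`` (spherical outer surface, outward winding), ``inner``.
    Node sets: ``rim`` (equator ring nodes of the outer shell).
    """
    D, quads, pole_patch = cubed_hemisphere_grid(n)
    nn = D.shape[0]
    radii = np.linspace(R_outer - thickness, R_outer, n_layers + 1)
    nodes = np.vstack([D * r for r in radii])
    hexes = _shell_hexes(quads, nn, n_layers)
    outer = quads + n_layers * nn
    inner = quads[:, ::-1].copy()  # inward winding = outward of the body on inner surface
    rim = np.unique(quads) [np.abs(D[np.unique(quads), 2]) < 1e-9] + n_layers * nn
    surfaces = {"outer": outer, "inner": inner}
    node_sets = {"rim": rim, "pole_patch_quads": pole_patch}
    return HexMesh(nodes, hexes, np.array([body] * hexes.shape[0]), surfaces, node_sets)


def cavity_block_mesh(R_cavity: float, R_cyl: float, H: float, n: int,
                      n_layers: int = 4, rim_relief: float = 0.0,
                      grading: float = 1.6, body: str = "bone") -> HexMesh:
    """Cylindrical bone block with a hemispherical cavity (spherical O-grid).

    The block is the cylinder (radius ``R_cyl``, depth ``H``, top plane z=0)
    minus the hemisphere of radius ``R_cavity`` centered at the origin.  Nodes
    lie on rays ``r*d`` for the cubed-hemisphere directions ``d``; the first
    shell is the cavity surface, the last shell the outer boundary (cylinder
    side or bottom, whichever the ray hits first).  ``rim_relief`` adds a
    small outward radial offset to the equator ring of the cavity surface,
    a coarse-mesh stand-in for the rounded rim fillet.  ``grading`` > 1
    concentrates shells near the cavity where contact gradients live.

    Surfaces: ``cavity`` (outward of the bone = toward the cavity center).
    Node sets: ``bottom`` (outer-shell nodes on the cylinder bottom), ``top``
    (equator nodes in the z=0 plane).
    """
    D, quads, _ = cubed_hemisphere_grid(n)
    nn = D.shape[0]
    rho = np.hypot(D[:, 0], D[:, 1])
    with np.errstate(divide="ignore"):
        r_side = np.where(rho > 1e-12, R_cyl / np.maximum(rho, 1e-12), np.inf)
        r_bot = np.where(D[:, 2] < -1e-12, H / np.maximum(-D[:, 2], 1e-12), np.inf)
    r_max = np.minimum(r_side, r_bot)
    r_in = np.full(nn, R_cavity)
    if rim_relief > 0.0:
        eq = np.abs(D[:, 2]) < 1e-9
        r_in[eq] += rim_relief
    # graded radial distribution, finer near the cavity
    s = np.linspace(0.0, 1.0, n_layers + 1) ** grading
    nodes = np.vstack([D * (r_in + sk * (r_max - r_in))[:, None] for sk in s])
    hexes = _shell_hexes(quads, nn, n_layers)
    cavity = quads[:, ::-1].copy()  # outward of bone points toward cavity center
    bottom = np.where(nodes[n_layers * nn:, 2] < -H + 1e-9)[0] + n_layers * nn
    top = np.where(np.abs(nodes[:, 2]) < 1e-9)[0]
    surfaces = {"cavity": cavity}
    node_sets = {"bottom": bottom, "top": top}
    return HexMesh(nodes, hexes, np.array([body] * hexes.shape[0]), surfaces, node_sets)
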