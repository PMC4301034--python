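"""Voxel hexahedral linear-elasticity solver.

Every non-background voxel of a material map becomes one trilinear (8-node)
hexahedral element; shared nodes are deduplicated so the mesh has exactly
3 degrees of freedom per node.  Element stiffness uses 2x2x2 Gauss
quadrature of the isotropic Hooke operator; the global system is assembled
sparse and solved either directly (small meshes) or with Jacobi-
preconditioned conjugate gradients.  Stresses are evaluated at element
centroids and condensed to the von Mises scalar, which the optimization
module consumes both raw (Pa) and scaled so the worst-case maximum maps
to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import MaterialMap
from .phantom import Tissue

GRAVITY = 9.81  # m/s^2

#: local node offsets of a voxel's corners, VTK hexahedron ordering
_CORNERS = np.array(
    [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
     (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)], dtype=np.int64)
#: the same corners in reference coordinates xi, eta, zeta in {-1, +1}
_SIGNS = 2.0 * _CORNERS - 1.0


class SolverError(RuntimeError):
    """Raised when the linear solve fails (non-convergence or singularity)."""


def linear_hex_dof(n_nodes: int) -> int:
    """Degrees of freedom of a linear hexahedral mesh: 3 per node."""
    return 3 * int(n_nodes)


def isotropic_d_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 Hooke matrix, Voigt order (xx, yy, zz, xy, yz, zx)."""
    if E <= 0:
        raise ValueError("E must be > 0")
    if not (-1.0 < nu < 0.5):
        raise ValueError("nu must lie in (-1, 0.5)")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.diag_indices(3)] = lam + 2 * mu
    D[3, 3] = D[4, 4] = D[5, 5] = mu
    return D


def _shape_gradients(xi: np.ndarray, size: tuple[float, float, float]) -> np.ndarray:
    """(3, 8) physical gradients dN_a/dx at reference point xi."""
    hx, hy, hz = size
    s = _SIGNS
    g = np.empty((3, 8))
    for a in range(8):
        sx, sy, sz = s[a]
        g[0, a] = sx * (1 + sy * xi[1]) * (1 + sz * xi[2]) / 8 * (2.0 / hx)
        g[1, a] = sy * (1 + sx * xi[0]) * (1 + sz * xi[2]) / 8 * (2.0 / hy)
        g[2, a] = sz * (1 + sx * xi[0]) * (1 + sy * xi[1]) / 8 * (2.0 / hz)
    return g


def _b_matrix(xi: np.ndarray, size: tuple[float, float, float]) -> np.ndarray:
    """(6, 24) strain-displacement matrix at reference point xi."""
    g = _shape_gradients(xi, size)
    B = np.zeros((6, 24))
    for a in range(8):
        c = 3 * a
        B[0, c] = g[0, a]
        B[1, c + 1] = g[1, a]
        B[2, c + 2] = g[2, a]
        B[3, c] = g[1, a]
        B[3, c + 1] = g[0, a]
        B[4, c + 1] = g[2, a]
        B[4, c + 2] = g[1, a]
        B[5, c] = g[2, a]
        B[5, c + 2] = g[0, a]
    return B


@lru_cache(maxsize=32)
def _unit_stiffness(nu: float, size: tuple[float, float, float]) -> np.ndarray:
    """24x24 stiffness of a box element with E = 1, by 2x2x2 Gauss quadrature."""
    D = isotropic_d_matrix(1.0, nu)
    hx, hy, hz = size
    detJ = hx * hy * hz / 8.0
    gp = 1.0 / np.sqrt(3.0)
    K = np.zeros((24, 24))
    for sx, sy, sz in _SIGNS:
        B = _b_matrix(np.array([sx * gp, sy * gp, sz * gp]), size)
        K += B.T @ D @ B * detJ
    return 0.5 * (K + K.T)


def element_stiffness(E: float, nu: float,
                      voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Stiffness of one trilinear hexahedron (symmetric PSD, 6 rigid modes)."""
    if any(h <= 0 for h in voxel_size):
        raise ValueError("voxel_size components must be > 0")
    if E <= 0:
        raise ValueError("E must be > 0")
    if not (-1.0 < nu < 0.5):
        raise ValueError("nu must lie in (-1, 0.5)")
    return E * _unit_stiffness(float(nu), tuple(float(h) for h in voxel_size))


@dataclass
class VoxelMesh:
    """Hexahedral discretization of the non-background voxels."""

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    shape: tuple[int, int, int]  # voxel grid the elements index into
    elem_voxels: np.ndarray  # (nelem, 3) int voxel indices
    connectivity: np.ndarray  # (nelem, 8) node ids
    nodes_xyz: np.ndarray  # (nnodes, 3) mm
    nodes_ijk: np.ndarray  # (nnodes, 3) structured-grid node indices
    E: np.ndarray  # (nelem,) Pa
    nu: np.ndarray  # (nelem,)
    labels: np.ndarray  # (nelem,) Tissue codes
    nonunion: np.ndarray  # (nelem,) bool
    _coo_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_elements(self) -> int:
        return self.connectivity.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.nodes_xyz.shape[0]

    @property
    def n_dof(self) -> int:
        return linear_hex_dof(self.n_nodes)

    @property
    def implant(self) -> np.ndarray:
        return self.labels == Tissue.IMPLANT

    @property
    def spacing_m(self) -> tuple[float, float, float]:
        """Voxel size in meters (consistent with E in Pa and forces in N)."""
        return tuple(s * 1e-3 for s in self.spacing)  # type: ignore[return-value]

    @property
    def edof(self) -> np.ndarray:
        """(nelem, 24) global dof indices, node-major (ux, uy, uz)."""
        if "edof" not in self._coo_cache:
            e = (3 * self.connectivity[:, :, None]
                 + np.arange(3)[None, None, :]).reshape(-1, 24)
            self._coo_cache["edof"] = e.astype(np.int64)
        return self._coo_cache["edof"]


def build_mesh(materials: MaterialMap) -> VoxelMesh:
    """One hexahedron per non-background voxel, shared nodes deduplicated."""
    lab = materials.labels.labels
    fg = lab != Tissue.BACKGROUND
    if not fg.any():
        raise ValueError("material map has no non-background voxel to mesh")
    if np.any(materials.E[fg] <= 0):
        raise ValueError("every meshed voxel must have E > 0")
    nx, ny, nz = lab.shape
    iv = np.argwhere(fg)  # (nelem, 3)
    grid = (nx + 1, ny + 1, nz + 1)
    corners = iv[:, None, :] + _CORNERS[None, :, :]  # (nelem, 8, 3)
    gids = np.ravel_multi_index(
        (corners[:, :, 0], corners[:, :, 1], corners[:, :, 2]), grid)
    used, conn = np.unique(gids, return_inverse=True)
    conn = conn.reshape(gids.shape).astype(np.int64)
    ii, jj, kk = np.unravel_index(used, grid)
    nodes_ijk = np.stack([ii, jj, kk], axis=1).astype(np.int64)
    sx, sy, sz = materials.spacing
    ox, oy, oz = materials.origin
    nodes_xyz = nodes_ijk * np.array([sx, sy, sz]) + np.array([ox, oy, oz])
    return VoxelMesh(
        spacing=materials.spacing,
        origin=materials.origin,
        shape=lab.shape,
        elem_voxels=iv,
        connectivity=conn,
        nodes_xyz=nodes_xyz,
        nodes_ijk=nodes_ijk,
        E=materials.E[fg].copy(),
        nu=materials.nu[fg].copy(),
        labels=lab[fg].copy(),
        nonunion=materials.labels.nonunion_mask[fg].copy(),
    )


def assemble(mesh: VoxelMesh) -> sp.csr_matrix:
    """Global stiffness in CSR form (unconstrained, symmetric PSD)."""
    nel = mesh.n_elements
    size = mesh.spacing_m
    data = np.empty((nel, 576))
    for nu in np.unique(mesh.nu):
        ke = _unit_stiffness(float(nu), size).ravel()
        sel = mesh.nu == nu
        data[sel] = mesh.E[sel, None] * ke[None, :]
    edof = mesh.edof
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    K = sp.coo_matrix((data.ravel(), (rows, cols)),
                      shape=(mesh.n_dof, mesh.n_dof)).tocsr()
    return K


@dataclass
class LoadCase:
    """Dirichlet-fixed nodes plus a total force spread over loaded nodes.

    By default the total force is split equally over the loaded nodes; an
    explicit per-node force table (e.g. a consistent surface traction) can
    be supplied via :meth:`from_node_forces`.
    """

    fixed_nodes: np.ndarray
    loaded_nodes: np.ndarray
    total_force: np.ndarray  # (3,) N
    node_forces: np.ndarray | None = None  # (nnodes, 3) explicit override

    def __post_init__(self) -> None:
        self.fixed_nodes = np.unique(np.asarray(self.fixed_nodes, dtype=np.int64))
        self.loaded_nodes = np.unique(np.asarray(self.loaded_nodes, dtype=np.int64))
        self.total_force = np.asarray(self.total_force, dtype=np.float64)
        if self.fixed_nodes.size == 0 or self.loaded_nodes.size == 0:
            raise ValueError("fixed and loaded node sets must be nonempty")
        if np.intersect1d(self.fixed_nodes, self.loaded_nodes).size:
            raise ValueError("fixed and loaded node sets must be disjoint")
        if not np.linalg.norm(self.total_force) > 0:
            raise ValueError("total force must be nonzero")

    @classmethod
    def from_node_forces(cls, fixed_nodes: np.ndarray,
                         node_forces: np.ndarray) -> "LoadCase":
        node_forces = np.asarray(node_forces, dtype=np.float64)
        loaded = np.flatnonzero(np.any(node_forces != 0, axis=1))
        return cls(fixed_nodes=fixed_nodes, loaded_nodes=loaded,
                   total_force=node_forces.sum(axis=0), node_forces=node_forces)

    def nodal_forces(self, n_nodes: int) -> np.ndarray:
        """(nnodes, 3) force array; sums exactly to ``total_force``."""
        if self.node_forces is not None:
            if self.node_forces.shape != (n_nodes, 3):
                raise ValueError("node_forces shape does not match mesh")
            return self.node_forces.copy()
        f = np.zeros((n_nodes, 3))
        f[self.loaded_nodes] = self.total_force / self.loaded_nodes.size
        return f


def apply_load_case(mesh: VoxelMesh, body_mass_kg: float = 80.0,
                    direction: tuple[float, float, float] = (0.0, 0.0, -1.0),
                    g: float = GRAVITY) -> LoadCase:
    """Axial body-weight loading: cranio-caudal force on the proximal bone
    face, distal node plane fully fixed.

    The force magnitude is ``body_mass_kg * g`` along ``direction`` (default
    -z), split equally over the top-face nodes of the bone elements in the
    highest bone-occupied slice; all nodes of the lowest occupied node plane
    are fixed in all three components.
    """
    if body_mass_kg <= 0:
        raise ValueError("body mass must be > 0")
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    bone = np.isin(mesh.labels, (Tissue.CANCELLOUS, Tissue.CORTICAL))
    if not bone.any():
        raise ValueError("no bone elements found to load")
    k_elem = mesh.elem_voxels[:, 2]
    k_top = k_elem[bone].max()
    top_elems = bone & (k_elem == k_top)
    # local nodes 4..7 are the +z face of the voxel
    loaded = np.unique(mesh.connectivity[top_elems][:, 4:8])
    k_bottom = mesh.nodes_ijk[:, 2].min()
    fixed = np.flatnonzero(mesh.nodes_ijk[:, 2] == k_bottom)
    loaded = np.setdiff1d(loaded, fixed)
    if loaded.size == 0:
        raise ValueError("proximal bone face coincides with the fixed plane")
    total = body_mass_kg * g * d
    return LoadCase(fixed_nodes=fixed, loaded_nodes=loaded, total_force=total)


@dataclass
class Displacements:
    """Solution of one load case."""

    u: np.ndarray  # (nnodes, 3) displacements in meters (E in Pa, forces in N)
    residual: float
    iterations: int
    method: str
    reactions: np.ndarray  # (nnodes, 3), nonzero only at fixed nodes


def solve(mesh: VoxelMesh, load: LoadCase, tol: float = 1e-8,
          method: str = "auto", maxiter: int = 20000,
          direct_limit: int = 30000) -> Displacements:
    """Assemble and solve ``K u = f`` with the load case's constraints.

    ``method`` is ``"direct"`` (sparse LU), ``"cg"`` (Jacobi-preconditioned
    conjugate gradients) or ``"auto"`` (direct below ``direct_limit`` free
    DOFs, CG above).  Raises :class:`SolverError` with the final residual on
    non-convergence and a singular-system diagnostic when the load path is
    disconnected.
    """
    K = assemble(mesh)
    n_dof = mesh.n_dof
    f = load.nodal_forces(mesh.n_nodes).ravel()
    fixed_dofs = (3 * load.fixed_nodes[:, None] + np.arange(3)).ravel()
    free = np.ones(n_dof, dtype=bool)
    free[fixed_dofs] = False
    Kff = K[free][:, free].tocsr()
    ff = f[free]

    n_free = int(free.sum())
    if method == "auto":
        method = "direct" if n_free <= direct_limit else "cg"

    u = np.zeros(n_dof)
    iters = 0
    if np.linalg.norm(ff) == 0:
        uf = np.zeros(n_free)
    elif method == "direct":
        with np.errstate(all="ignore"):
            uf = spla.spsolve(Kff.tocsc(), ff)
        if not np.all(np.isfinite(uf)):
            raise SolverError(
                "direct solve produced non-finite displacements; the load "
                "path between fixed and loaded nodes is likely disconnected")
    elif method == "cg":
        diag = Kff.diagonal()
        if np.any(diag <= 0):
            raise SolverError(
                "zero diagonal in the constrained stiffness matrix; the mesh "
                "contains elements with no stiffness (singular system)")
        M = spla.LinearOperator(Kff.shape, matvec=lambda x: x / diag)
        count = {"n": 0}

        def _cb(_):
            count["n"] += 1

        uf, info = spla.cg(Kff, ff, rtol=tol, atol=0.0, maxiter=maxiter,
                           M=M, callback=_cb)
        iters = count["n"]
        if info != 0:
            res = np.linalg.norm(Kff @ uf - ff) / np.linalg.norm(ff)
            raise SolverError(
                f"CG did not converge within {maxiter} iterations "
                f"(final relative residual {res:.3e})")
    else:
        raise ValueError(f"unknown solver method {method!r}")

    u[free] = uf
    resid = np.linalg.norm(Kff @ u[free] - ff) / max(np.linalg.norm(ff), 1e-300)
    if not np.isfinite(resid) or resid > max(10 * tol, 1e-6):
        raise SolverError(f"solution residual {resid:.3e} exceeds tolerance")
    r = (K @ u - f).reshape(-1, 3)
    reactions = np.zeros_like(r)
    reactions[load.fixed_nodes] = r[load.fixed_nodes]
    return Displacements(u=u.reshape(-1, 3), residual=float(resid),
                         iterations=iters, method=method, reactions=reactions)


@dataclass
class StressField:
    """Per-element centroid stress state."""

    tensor: np.ndarray  # (nelem, 6) Voigt (xx, yy, zz, xy, yz, zx), Pa
    von_mises: np.ndarray  # (nelem,), Pa
    reference_max: float | None = None  # Pa; the worst-case scaling anchor
    scaled: np.ndarray | None = None  # dimensionless, reference_max -> 100


def von_mises_stress(tensor: np.ndarray) -> np.ndarray:
    """Von Mises scalar from Voigt stress rows (xx, yy, zz, xy, yz, zx)."""
    t = np.asarray(tensor, dtype=np.float64)
    sxx, syy, szz, sxy, syz, szx = (t[..., i] for i in range(6))
    return np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2 + (szz - sxx) ** 2)
                   + 3.0 * (sxy**2 + syz**2 + szx**2))


def element_stress(mesh: VoxelMesh, disp: Displacements | np.ndarray) -> StressField:
    """Centroid stress tensor and von Mises scalar for every element."""
    u = disp.u if isinstance(disp, Displacements) else np.asarray(disp)
    if u.shape != (mesh.n_nodes, 3):
        raise ValueError(
            f"displacement shape {u.shape} does not match mesh nodes {mesh.n_nodes}")
    B0 = _b_matrix(np.zeros(3), mesh.spacing_m)  # constant for the voxel size
    ue = u.ravel()[mesh.edof]  # (nelem, 24)
    strain = ue @ B0.T  # (nelem, 6) engineering strains
    lam = mesh.E * mesh.nu / ((1 + mesh.nu) * (1 - 2 * mesh.nu))
    mu = mesh.E / (2 * (1 + mesh.nu))
    tr = strain[:, 0] + strain[:, 1] + strain[:, 2]
    stress = np.empty_like(strain)
    for i in range(3):
        stress[:, i] = lam * tr + 2 * mu * strain[:, i]
    for i in range(3, 6):
        stress[:, i] = mu * strain[:, i]
    return StressField(tensor=stress, von_mises=von_mises_stress(stress))


def scale_stresses(fieldv: StressField, reference_max: float) -> StressField:
    """Scale so the worst-case reference maximum maps to 100."""
    if not reference_max > 0:
        raise ValueError("reference_max must be > 0")
    return StressField(
        tensor=fieldv.tensor,
        von_mises=fieldv.von_mises,
        reference_max=float(reference_max),
        scaled=100.0 * fieldv.von_mises / reference_max,
    )
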