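"""Static small-strain linear elasticity on 8-node hexahedral meshes.

Trilinear displacement elements with mean-dilatation B-bar treatment of the
volumetric stiffness (selective reduced integration): the deviatoric response
is integrated with full 2x2x2 Gauss quadrature while the dilatation gradient
is replaced by its element average. This removes volumetric locking, which
matters here because brain tissue is nearly incompressible (nu = 0.45).

The global system is assembled in sparse CSR form; Dirichlet constraints are
applied by reduction (condensing constrained dofs into the right-hand side),
keeping the reduced operator symmetric positive definite. Displacements
come back in micrometres, strains are dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import HexMesh
from .materials import Material

__all__ = [
    "element_stiffness",
    "assemble",
    "apply_boundary_conditions",
    "solve",
    "compute_strain_field",
    "von_mises_strain",
    "LinearSystem",
    "StrainField",
]

# Local corner coordinates, VTK hexahedron ordering.
_XI_NODES = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)

_G = 1.0 / np.sqrt(3.0)
_GAUSS = np.array([[sx * _G, sy * _G, sz * _G]
                   for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """d N_a / d xi_i at one local point -> (8, 3)."""
    s = _XI_NODES
    g = np.empty((8, 3))
    g[:, 0] = 0.125 * s[:, 0] * (1 + s[:, 1] * xi[1]) * (1 + s[:, 2] * xi[2])
    g[:, 1] = 0.125 * s[:, 1] * (1 + s[:, 0] * xi[0]) * (1 + s[:, 2] * xi[2])
    g[:, 2] = 0.125 * s[:, 2] * (1 + s[:, 0] * xi[0]) * (1 + s[:, 1] * xi[1])
    return g


_DN_GAUSS = np.stack([_shape_gradients(xi) for xi in _GAUSS])  # (8 gp, 8, 3)
_DN_CENTER = _shape_gradients(np.zeros(3))


def _physical_gradients(coords: np.ndarray, dn: np.ndarray):
    """Physical shape-function gradients for a batch of elements.

    coords: (E, 8, 3); dn: (8, 3) local gradients at one point.
    Returns (grads (E, 8, 3), detJ (E,)). Raises on non-positive Jacobian.
    """
    J = np.einsum("ai,eaj->eij", dn, coords)  # J_ij = d x_j / d xi_i
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        raise ValueError("inverted or degenerate element (non-positive Jacobian)")
    # grad_x N = J^{-1} grad_xi N  (since grad_xi N = J grad_x N)
    grads = np.einsum("eij,aj->eai", np.linalg.inv(J), dn)
    return grads, detJ


def jacobian_determinants(coords: np.ndarray) -> np.ndarray:
    """detJ at the 8 Gauss points for each element -> (E, 8). The sum over
    Gauss points is the exact element volume for trilinear hexes."""
    coords = np.atleast_3d(coords)
    out = np.empty((coords.shape[0], 8))
    for g, dn in enumerate(_DN_GAUSS):
        J = np.einsum("ai,eaj->eij", dn, coords)
        out[:, g] = np.linalg.det(J)
    return out


def _stiffness_batch(coords: np.ndarray, lam: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """B-bar element stiffness matrices for a batch -> (E, 24, 24)."""
    E = coords.shape[0]
    lam = np.broadcast_to(np.asarray(lam, float), (E,))
    mu = np.broadcast_to(np.asarray(mu, float), (E,))

    grads = np.empty((8, E, 8, 3))
    detJ = np.empty((8, E))
    for g, dn in enumerate(_DN_GAUSS):
        grads[g], detJ[g] = _physical_gradients(coords, dn)
    vol = detJ.sum(axis=0)
    # Element-average dilatation gradient (the B-bar substitution).
    gbar = np.einsum("ge,geai->eai", detJ, grads) / vol[:, None, None]
    bbar = gbar.reshape(E, 24)

    kappa3 = 3.0 * lam + 2.0 * mu  # = 3 * bulk modulus
    K = np.zeros((E, 24, 24))
    eye3 = np.eye(3)
    for g in range(8):
        G = grads[g]
        w = detJ[g]
        # Full-integration isotropic kernel:
        # K[ai,bj] = lam g_ai g_bj + mu g_aj g_bi + mu delta_ij (g_a . g_b)
        k = np.einsum("e,eai,ebj->eaibj", lam * w, G, G)
        k += np.einsum("e,eaj,ebi->eaibj", mu * w, G, G)
        k += np.einsum("e,eab,ij->eaibj", mu * w,
                       np.einsum("eak,ebk->eab", G, G), eye3)
        k = k.reshape(E, 24, 24)
        # Volumetric correction: with c = bbar - b(g),
        # Bbar^T D Bbar = B^T D B + (kappa3/3) (b c^T + c b^T + c c^T).
        b = G.reshape(E, 24)
        c = bbar - b
        s = (kappa3 * w / 3.0)[:, None, None]
        k += s * (b[:, :, None] * c[:, None, :]
                  + c[:, :, None] * b[:, None, :]
                  + c[:, :, None] * c[:, None, :])
        K += k
    return K


def element_stiffness(coords: np.ndarray, material: Material) -> np.ndarray:
    """24 x 24 stiffness of a single trilinear hexahedron (B-bar).

    ``coords`` are the 8 corner coordinates in VTK ordering, micrometres;
    entries of the result are in MPa * um (force per displacement scale).
    """
    coords = np.asarray(coords, float)
    if coords.shape != (8, 3):
        raise ValueError("coords must be (8, 3)")
    return _stiffness_batch(coords[None], material.lam, material.mu)[0]


@dataclass
class LinearSystem:
    """Assembled global system with (optionally) applied constraints."""

    K: sp.csr_matrix
    f: np.ndarray
    n_nodes: int
    constrained: np.ndarray | None = None   # bool mask over dofs
    values: np.ndarray | None = None        # prescribed values where constrained

    @property
    def n_dof(self) -> int:
        return self.K.shape[0]

    def symmetry_error(self) -> float:
        d = (self.K - self.K.T).tocoo()
        if d.nnz == 0:
            return 0.0
        scale = np.abs(self.K.data).max()
        return float(np.abs(d.data).max() / scale)

    def rigid_body_residual(self) -> float:
        """max_r ||K r|| / ||K|| over the 6 rigid-body modes (unconstrained
        operator)."""
        xyz_scale = 1.0
        n = self.n_nodes
        modes = []
        for i in range(3):
            m = np.zeros((n, 3))
            m[:, i] = 1.0
            modes.append(m.ravel())
        # Rotations need coordinates; caller passes them via attach_coords.
        coords = getattr(self, "_coords", None)
        if coords is not None:
            xyz_scale = max(np.abs(coords).max(), 1.0)
            for axis in range(3):
                r = np.zeros((n, 3))
                a, b = (axis + 1) % 3, (axis + 2) % 3
                r[:, a] = -coords[:, b] / xyz_scale
                r[:, b] = coords[:, a] / xyz_scale
                modes.append(r.ravel())
        knorm = spla.norm(self.K, np.inf)
        worst = 0.0
        for m in modes:
            worst = max(worst, np.abs(self.K @ m).max() / (knorm * max(np.abs(m).max(), 1e-300)))
        return float(worst)


def assemble(mesh: HexMesh, materials: dict[int, Material],
             chunk: int = 20000) -> LinearSystem:
    """Assemble the global stiffness for a tagged mesh.

    ``materials`` maps region tag (0 = tissue, 1 = probe) to
    :class:`~micromotion_fem.materials.Material`. Every tag present in the
    mesh must be catalogued. Assembly result is independent of element
    ordering (contributions are summed).
    """
    tags = np.unique(mesh.region)
    for t in tags:
        if int(t) not in materials:
            raise KeyError(f"no material supplied for region tag {int(t)}")
    lam = np.empty(mesh.n_elements)
    mu = np.empty(mesh.n_elements)
    for t in tags:
        m = materials[int(t)]
        sel = mesh.region == t
        lam[sel], mu[sel] = m.lam, m.mu

    ndof = 3 * mesh.n_nodes
    K = sp.csr_matrix((ndof, ndof))
    edof_all = (3 * mesh.elements[:, :, None]
                + np.arange(3)[None, None, :]).reshape(-1, 24)
    parts = []
    for lo in range(0, mesh.n_elements, chunk):
        hi = min(lo + chunk, mesh.n_elements)
        ke = _stiffness_batch(mesh.nodes[mesh.elements[lo:hi]],
                              lam[lo:hi], mu[lo:hi])
        edof = edof_all[lo:hi]
        rows = np.repeat(edof, 24, axis=1).ravel()
        cols = np.tile(edof, (1, 24)).ravel()
        parts.append(sp.coo_matrix(
            (ke.ravel(), (rows.astype(np.int64), cols.astype(np.int64))),
            shape=(ndof, ndof)).tocsr())
        if len(parts) >= 8:
            parts = [sum(parts)]
    K = sum(parts) if parts else K
    K.sum_duplicates()
    sys = LinearSystem(K=K.tocsr(), f=np.zeros(ndof), n_nodes=mesh.n_nodes)
    sys._coords = mesh.nodes
    return sys


def constrain(system: LinearSystem, dofs: np.ndarray,
              values: np.ndarray | float) -> LinearSystem:
    """Prescribe individual dofs (``dof = 3 * node + component``) to given
    values, accumulating with any constraints already applied."""
    dofs = np.asarray(dofs, dtype=np.int64)
    if system.constrained is None:
        system.constrained = np.zeros(system.n_dof, dtype=bool)
        system.values = np.zeros(system.n_dof)
    system.constrained[dofs] = True
    system.values[dofs] = values
    return system


#: Micromotion displacement range discussed for cortical implants, um.
MICROMOTION_RANGE = (0.0, 60.0)


def apply_boundary_conditions(system: LinearSystem, fixed: np.ndarray,
                              prescribed: np.ndarray, d: float,
                              direction: int = 0,
                              clamp: bool = True) -> LinearSystem:
    """Pin ``fixed`` nodes in all components and displace ``prescribed``
    nodes by ``d`` (um) along ``direction``.

    With ``clamp=True`` (default) the prescribed patch is welded to the
    moving mount: the full displacement vector is set (``d`` along
    ``direction``, zero in the other components). This models a probe whose
    platform is grounded in the cranium — without it a probe that is rigid
    relative to the tissue is free to rock about its tip, which suppresses
    the tip strain field entirely. ``clamp=False`` prescribes only the
    ``direction`` component and leaves the other two free.

    Emits a warning when ``d`` lies outside the physiological micromotion
    range [0, 60] um. Returns the same system object with constraint masks
    attached.
    """
    fixed = np.asarray(fixed, dtype=np.int64)
    prescribed = np.asarray(prescribed, dtype=np.int64)
    if fixed.size == 0 or prescribed.size == 0:
        raise ValueError("fixed and prescribed node sets must be non-empty")
    if np.intersect1d(fixed, prescribed).size:
        raise ValueError("fixed and prescribed node sets overlap")
    if not MICROMOTION_RANGE[0] <= d <= MICROMOTION_RANGE[1]:
        warnings.warn(
            f"displacement {d} um is outside the micromotion range "
            f"{MICROMOTION_RANGE} um", stacklevel=2)
    for i in range(3):
        constrain(system, 3 * fixed + i, 0.0)
    for i in range(3):
        if i == direction:
            constrain(system, 3 * prescribed + i, d)
        elif clamp:
            constrain(system, 3 * prescribed + i, 0.0)
    return system


@dataclass
class SolveInfo:
    method: str
    residual: float
    iterations: int | None = None


def solve(system: LinearSystem, tol: float = 1e-8,
          method: str = "auto") -> tuple[np.ndarray, SolveInfo]:
    """Solve the constrained system for the nodal displacement field.

    ``method``: ``"direct"`` (sparse LU, deterministic), ``"cg"``
    (conjugate gradients with incomplete-Cholesky preconditioning, see
    :mod:`micromotion_fem.icsolver`), or ``"auto"`` (direct for small
    systems, CG beyond ~60k free dofs where LU fill becomes prohibitive).
    Returns ``(u (n_nodes, 3), SolveInfo)``; the relative residual of the
    reduced system is checked against ``tol``.
    """
    if system.constrained is None:
        raise ValueError("apply boundary conditions before solving")
    free = ~system.constrained
    uc = system.values[system.constrained]
    Kfc = system.K[free][:, system.constrained]
    Kff = system.K[free][:, free].tocsc()
    rhs = system.f[free] - Kfc @ uc

    nfree = Kff.shape[0]
    if method == "auto":
        method = "direct" if nfree <= 60_000 else "cg"

    iterations = None
    if np.abs(rhs).max() == 0.0:
        uf = np.zeros(nfree)
    elif method == "direct":
        uf = spla.splu(Kff).solve(rhs)
    elif method == "cg":
        from .icsolver import ic_cg

        uf, iterations = ic_cg(Kff, rhs, tol=tol * 0.1)
    else:
        raise ValueError(f"unknown solver method {method!r}")

    rnorm = np.linalg.norm(rhs)
    residual = 0.0 if rnorm == 0 else float(
        np.linalg.norm(Kff @ uf - rhs) / rnorm)
    if residual > tol:
        raise RuntimeError(
            f"solver residual {residual:.3e} exceeds tolerance {tol:.1e}")

    u = np.empty(system.n_dof)
    u[free] = uf
    u[system.constrained] = uc
    return u.reshape(-1, 3), SolveInfo(method=method, residual=residual,
                                       iterations=iterations)


@dataclass
class StrainField:
    """Per-element centroid strain state.

    ``tensor``: (E, 6) Voigt components (xx, yy, zz, xy, yz, zx) with
    *tensor* shear (eps_xy, not the engineering gamma). ``von_mises``:
    (E,) equivalent elastic strain. ``region``: (E,) tags copied from the
    mesh.
    """

    tensor: np.ndarray
    von_mises: np.ndarray
    region: np.ndarray


def compute_strain_field(mesh: HexMesh, u: np.ndarray,
                         nu_eff: np.ndarray | float | None = None,
                         materials: dict[int, Material] | None = None) -> StrainField:
    """Small strains eps = sym(grad u) at element centroids, plus the Von
    Mises equivalent strain.

    ``nu_eff`` sets the effective Poisson ratio in the equivalent-strain
    formula; if ``materials`` is given instead, each element uses its own
    material's ratio (tissue elements at 0.45). Defaults to 0 if neither is
    supplied.
    """
    u = np.asarray(u, float).reshape(mesh.n_nodes, 3)
    coords = mesh.nodes[mesh.elements]
    grads, _ = _physical_gradients(coords, _DN_CENTER)
    gradu = np.einsum("eai,eaj->eij", u[mesh.elements], grads)
    eps = 0.5 * (gradu + gradu.transpose(0, 2, 1))
    voigt = np.column_stack([
        eps[:, 0, 0], eps[:, 1, 1], eps[:, 2, 2],
        eps[:, 0, 1], eps[:, 1, 2], eps[:, 2, 0],
    ])
    if materials is not None:
        nu_eff = np.empty(mesh.n_elements)
        for t in np.unique(mesh.region):
            nu_eff[mesh.region == t] = materials[int(t)].nu
    elif nu_eff is None:
        nu_eff = 0.0
    vm = von_mises_strain(voigt, nu_eff)
    return StrainField(tensor=voigt, von_mises=vm, region=mesh.region.copy())


def von_mises_strain(strain, nu_eff=0.0) -> np.ndarray | float:
    """Von Mises (equivalent elastic) strain of symmetric strain tensors.

    eps_eq = 1/(1 + nu_eff) * sqrt(((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2) / 2)

    over principal strains e1..e3, computed here through the equivalent
    deviatoric-norm identity sqrt(3/2) * ||dev eps||. Accepts (..., 3, 3)
    tensors (symmetry enforced to 1e-8 relative) or (..., 6) Voigt vectors
    with tensor shears. ``nu_eff`` may be scalar or per-entry; 0.5 is
    allowed here (postprocessing only).
    """
    a = np.asarray(strain, float)
    if a.shape[-2:] == (3, 3):
        asym = np.abs(a - np.swapaxes(a, -1, -2)).max()
        scale = max(np.abs(a).max(), 1e-300)
        if asym > 1e-8 * scale:
            raise ValueError("strain tensor is not symmetric")
        v = np.stack([a[..., 0, 0], a[..., 1, 1], a[..., 2, 2],
                      a[..., 0, 1], a[..., 1, 2], a[..., 2, 0]], axis=-1)
    elif a.shape[-1] == 6:
        v = a
    else:
        raise ValueError("strain must be (..., 3, 3) or (..., 6)")
    nu = np.asarray(nu_eff, float)
    if np.any(nu < 0) or np.any(nu > 0.5):
        raise ValueError("nu_eff must lie in [0, 0.5]")
    tr = v[..., 0] + v[..., 1] + v[..., 2]
    dev_n = v[..., :3] - tr[..., None] / 3.0
    dev2 = (dev_n ** 2).sum(axis=-1) + 2.0 * (v[..., 3:] ** 2).sum(axis=-1)
    out = np.sqrt(1.5 * dev2) / (1.0 + nu)
    return out if out.ndim else float(out)
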