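"""Analytic verification problems that gate the elasticity solver.

Each fixture is a small synthetic boundary-value problem whose exact
solution is known in closed form: a homogeneous uniaxial block, the classic
patch test on a distorted mesh, a slender cantilever checked against
Timoshenko beam stiffness, and a two-material bar in series (the 1D
archetype of probe–tissue modulus mismatch). The probe cases are only
trusted because these gates pass first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import fem
from .geometry import REGION_PROBE, REGION_TISSUE, HexMesh, box_mesh
from .materials import Material

__all__ = [
    "Fixture",
    "uniaxial_block",
    "patch_test",
    "cantilever",
    "bimaterial_series",
    "solve_fixture",
    "verify_all",
]


@dataclass
class Fixture:
    """A mesh, Dirichlet data, materials, and the exact solution."""

    name: str
    mesh: HexMesh
    materials: dict[int, Material]
    constrained_dofs: np.ndarray          # dof = 3 * node + component
    constrained_values: np.ndarray
    exact_u: Callable[[np.ndarray], np.ndarray] | None = None
    exact_strain: np.ndarray | None = None   # Voigt (xx,yy,zz,xy,yz,zx)
    oracle: dict = field(default_factory=dict)
    tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if self.exact_u is not None:
            # The exact solution must satisfy the fixture's own constraints.
            nodes = self.constrained_dofs // 3
            comps = self.constrained_dofs % 3
            ue = self.exact_u(self.mesh.nodes)
            err = np.abs(ue[nodes, comps] - self.constrained_values)
            if err.size and err.max() > 1e-9 * max(np.abs(ue).max(), 1e-300):
                raise AssertionError(
                    f"{self.name}: exact solution violates its own boundary "
                    f"conditions (max {err.max():.2e})")


def _pin(dofs: list, vals: list, node: int, comp: int, value: float) -> None:
    dofs.append(3 * node + comp)
    vals.append(value)


def _find_node(mesh: HexMesh, point) -> int:
    d2 = ((mesh.nodes - np.asarray(point, float)) ** 2).sum(axis=1)
    k = int(np.argmin(d2))
    if d2[k] > 1e-16:
        raise ValueError(f"no node at {point}")
    return k


def _uniaxial_like(name: str, mesh: HexMesh, mats: dict[int, Material],
                   lx: float, end_strain_u: float,
                   exact_u: Callable, exact_strain: np.ndarray | None,
                   **oracle) -> Fixture:
    """Shared construction: u_x prescribed on both x faces, lateral faces
    free, rigid-body motion pinned at nodes where the exact solution
    vanishes."""
    xyz = mesh.nodes
    tol = 1e-9 * lx
    dofs: list[int] = []
    vals: list[float] = []
    for n in np.flatnonzero(np.abs(xyz[:, 0]) < tol):
        _pin(dofs, vals, n, 0, 0.0)
    for n in np.flatnonzero(np.abs(xyz[:, 0] - lx) < tol):
        _pin(dofs, vals, n, 0, end_strain_u)
    ly, lz = xyz[:, 1].max(), xyz[:, 2].max()
    a = _find_node(mesh, (0, 0, 0))
    b = _find_node(mesh, (0, ly, 0))
    c = _find_node(mesh, (0, 0, lz))
    _pin(dofs, vals, a, 1, 0.0)
    _pin(dofs, vals, a, 2, 0.0)
    _pin(dofs, vals, b, 2, 0.0)
    _pin(dofs, vals, c, 1, 0.0)
    return Fixture(name=name, mesh=mesh, materials=mats,
                   constrained_dofs=np.array(dofs),
                   constrained_values=np.array(vals),
                   exact_u=exact_u, exact_strain=exact_strain, oracle=oracle)


def uniaxial_block(E: float, nu: float, stretch: float = 1e-3,
                   n: int = 4) -> Fixture:
    """Homogeneous uniaxial extension of a unit block.

    End displacements prescribe eps_xx = ``stretch``; lateral faces free.
    Exact solution: u = (s x, -nu s y, -nu s z) relative to the pinned
    corner, i.e. eps_yy = eps_zz = -nu * stretch, no shears.
    """
    mesh = box_mesh(1.0, 1.0, 1.0, n, n, n)
    mat = Material("fixture", E, nu)
    s = stretch

    def exact(x):
        return np.column_stack([s * x[:, 0], -nu * s * x[:, 1],
                                -nu * s * x[:, 2]])

    exact_strain = np.array([s, -nu * s, -nu * s, 0.0, 0.0, 0.0])
    return _uniaxial_like("uniaxial_block", mesh, {REGION_TISSUE: mat},
                          1.0, s, exact, exact_strain)


def patch_test(material: Material, n: int = 3,
               distortion: float = 0.12) -> Fixture:
    """Constant-strain patch test on a smoothly distorted interior mesh.

    A globally linear displacement field is imposed on every boundary node;
    a correct element must reproduce it exactly in the interior together
    with the constant strain tensor it implies. Interior nodes are shifted
    by a deterministic sinusoidal perturbation so the elements are genuinely
    non-rectangular.
    """
    mesh = box_mesh(1.0, 1.0, 1.0, n, n, n)
    xyz = mesh.nodes
    interior = np.all((xyz > 1e-12) & (xyz < 1 - 1e-12), axis=1)
    h = distortion / n
    pert = np.column_stack([
        np.sin(2.1 * np.pi * xyz[:, 0] + 1.0) * np.cos(np.pi * xyz[:, 1]),
        np.sin(1.7 * np.pi * xyz[:, 1] + 2.0) * np.cos(np.pi * xyz[:, 2]),
        np.sin(1.3 * np.pi * xyz[:, 2] + 3.0) * np.cos(np.pi * xyz[:, 0]),
    ])
    mesh.nodes = xyz + h * pert * interior[:, None]

    # u = A x with a full (symmetric + skew) gradient, strain = sym(A).
    A = np.array([[3.0, 1.0, -2.0], [0.5, -1.0, 1.5], [1.0, 2.0, 0.5]]) * 1e-4

    def exact(x):
        return x @ A.T

    boundary = np.flatnonzero(~interior)
    dofs = (3 * boundary[:, None] + np.arange(3)).ravel()
    vals = exact(mesh.nodes)[boundary].ravel()
    sym = 0.5 * (A + A.T)
    exact_strain = np.array([sym[0, 0], sym[1, 1], sym[2, 2],
                             sym[0, 1], sym[1, 2], sym[2, 0]])
    return Fixture(name="patch_test", mesh=mesh,
                   materials={REGION_TISSUE: material},
                   constrained_dofs=dofs, constrained_values=vals,
                   exact_u=exact, exact_strain=exact_strain)


def cantilever(E: float, nu: float, dims: tuple[float, float, float],
               tip_displacement: float, n_thickness: int = 4) -> Fixture:
    """Slender cantilever with a prescribed transverse tip displacement.

    The beam spans ``dims = (L, h, b)`` along x with bending in y. The root
    face is clamped; the tip face is displaced by ``tip_displacement`` in y
    (other components free). The oracle is the Timoshenko tip stiffness
    ``k = [L^3 / 3EI + L / (kappa G A)]^-1`` with the rectangular shear
    factor ``kappa = 10 (1 + nu) / (12 + 11 nu)``; the FEM reaction force
    at the tip should match ``k * tip_displacement`` within a few percent.
    """
    import warnings

    L, h, b = dims
    if L < 10 * h:
        warnings.warn(f"cantilever is not slender (L = {L}, h = {h})",
                      stacklevel=2)
    nx = max(int(round(L / h * n_thickness)), n_thickness)
    mesh = box_mesh(L, h, b, nx, n_thickness,
                    max(2, int(round(n_thickness * b / h))))
    mat = Material("fixture", E, nu)
    xyz = mesh.nodes
    tol = 1e-9 * L
    dofs: list[int] = []
    vals: list[float] = []
    for nnode in np.flatnonzero(np.abs(xyz[:, 0]) < tol):
        for cpt in range(3):
            _pin(dofs, vals, nnode, cpt, 0.0)
    tip_nodes = np.flatnonzero(np.abs(xyz[:, 0] - L) < tol)
    for nnode in tip_nodes:
        _pin(dofs, vals, nnode, 1, tip_displacement)

    I = b * h ** 3 / 12.0
    G = mat.mu
    kappa = 10.0 * (1.0 + nu) / (12.0 + 11.0 * nu)
    k_timoshenko = 1.0 / (L ** 3 / (3.0 * E * I) + L / (kappa * G * b * h))
    return Fixture(name="cantilever", mesh=mesh, materials={REGION_TISSUE: mat},
                   constrained_dofs=np.array(dofs),
                   constrained_values=np.array(vals),
                   oracle={"tip_stiffness": k_timoshenko,
                           "tip_nodes": tip_nodes,
                           "tip_displacement": tip_displacement},
                   tolerance=0.05)


def bimaterial_series(E1: float, E2: float, stretch: float = 1e-3,
                      n: int = 4, nu: float = 0.0) -> Fixture:
    """Two blocks in series (x in [0,1] material 1, [1,2] material 2) under
    end displacement, with nu = 0 so the series-spring partition is exact:
    eps_1 / eps_2 = E2 / E1 and eps_1 + eps_2 = 2 * stretch.
    """
    if nu != 0.0:
        raise ValueError("the series oracle is exact only for nu = 0")
    mesh = box_mesh(2.0, 1.0, 1.0, 2 * n, n, n)
    c = mesh.element_centroids()
    mesh.region[c[:, 0] > 1.0] = REGION_PROBE
    mats = {REGION_TISSUE: Material("block1", E1, 0.0),
            REGION_PROBE: Material("block2", E2, 0.0)}
    # Series springs: common stress sigma = E1 eps1 = E2 eps2.
    eps1 = 2.0 * stretch * E2 / (E1 + E2)
    eps2 = 2.0 * stretch * E1 / (E1 + E2)

    def exact(x):
        ux = np.where(x[:, 0] <= 1.0, eps1 * x[:, 0],
                      eps1 + eps2 * (x[:, 0] - 1.0))
        return np.column_stack([ux, np.zeros(len(x)), np.zeros(len(x))])

    fx = _uniaxial_like("bimaterial_series", mesh, mats, 2.0,
                        2.0 * stretch, exact, None,
                        eps1=eps1, eps2=eps2)
    return fx


def solve_fixture(fixture: Fixture, tol: float = 1e-10,
                  method: str = "direct"):
    """Assemble, constrain, and solve a fixture; returns (u, strain field)."""
    system = fem.assemble(fixture.mesh, fixture.materials)
    fem.constrain(system, fixture.constrained_dofs, fixture.constrained_values)
    u, _ = fem.solve(system, tol=tol, method=method)
    field = fem.compute_strain_field(fixture.mesh, u)
    return u, field


def verify_all(E: float = 10.0, nu: float = 0.3) -> dict[str, dict]:
    """Run every fixture gate; returns per-fixture pass/fail with measured
    errors. Used by the command-line ``verify`` command and the test suite.
    """
    report: dict[str, dict] = {}

    fx = uniaxial_block(E, 0.45)
    u, f = solve_fixture(fx)
    err = np.abs(u - fx.exact_u(fx.mesh.nodes)).max() / np.abs(u).max()
    report["uniaxial_block"] = {"error": float(err), "passed": err < 1e-9}

    fx = patch_test(Material("m", E, nu))
    u, f = solve_fixture(fx)
    err = np.abs(u - fx.exact_u(fx.mesh.nodes)).max() / np.abs(u).max()
    serr = np.abs(f.tensor - fx.exact_strain).max() / np.abs(fx.exact_strain).max()
    report["patch_test"] = {"error": float(max(err, serr)),
                            "passed": max(err, serr) < 1e-8}

    fx = cantilever(E, nu, (10.0, 1.0, 1.0), 1e-3, n_thickness=6)
    u, _ = solve_fixture(fx, tol=1e-10)
    reaction = fixture_tip_reaction(fx, u)
    exact = fx.oracle["tip_stiffness"] * fx.oracle["tip_displacement"]
    err = abs(reaction - exact) / exact
    report["cantilever"] = {"error": float(err), "passed": err < fx.tolerance}

    fx = bimaterial_series(100.0, 1.0)
    u, f = solve_fixture(fx)
    from .geometry import REGION_PROBE as P, REGION_TISSUE as T

    e1 = f.tensor[f.region == T, 0].mean()
    e2 = f.tensor[f.region == P, 0].mean()
    err = max(abs(e1 - fx.oracle["eps1"]), abs(e2 - fx.oracle["eps2"])) \
        / fx.oracle["eps2"]
    report["bimaterial_series"] = {"error": float(err), "passed": err < 1e-8}
    return report


def fixture_tip_reaction(fixture: Fixture, u: np.ndarray) -> float:
    """Total reaction force on the prescribed tip dofs of the cantilever."""
    system = fem.assemble(fixture.mesh, fixture.materials)
    forces = system.K @ u.ravel()
    tip_dofs = 3 * fixture.oracle["tip_nodes"] + 1
    return float(forces[tip_dofs].sum())
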