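"""Parametric probe-in-tissue domain and graded structured hexahedral meshing.

Coordinate convention
---------------------
Origin at the centre of the tissue top surface; ``+y`` points downward along
the probe axis (so the tissue occupies ``0 <= y <= tissue_depth``); ``+x`` is
the tangential displacement direction (across the probe width); ``+z`` is the
probe thickness direction. All lengths in micrometres.

The probe is a rectangular shank embedded from the top surface: its top face
lies in the ``y = 0`` plane and its tip at ``y = embed_depth``. The mesh is a
tensor-product grid over the tissue box whose axis divisions conform exactly
to the probe faces, so probe and tissue elements share interface nodes — the
conforming mesh realises bonded (no-slip, no-separation) contact.

Grading: element edges start at ``near_size`` at the probe interfaces and
grow geometrically by ``grading`` away from the probe, capped at
``far_size``; sizes are then scaled so each segment fits its interval
exactly. Meshing is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DomainSpec",
    "MeshParams",
    "HexMesh",
    "build_domain_spec",
    "generate_hex_mesh",
    "extract_node_sets",
    "hex_volumes",
    "subdivide_to_tets",
]

REGION_TISSUE = 0
REGION_PROBE = 1

_GEOM_TOL = 1e-9


@dataclass(frozen=True)
class DomainSpec:
    """Probe-in-tissue box geometry (micrometres).

    ``embed_depth`` is the axial distance from the tissue top surface to the
    probe tip; the probe top face is flush with the tissue top surface.
    """

    probe_length: float
    probe_width: float
    probe_thickness: float
    tissue_width: float = 1500.0
    tissue_length: float = 1500.0
    tissue_depth: float = 1500.0
    embed_depth: float | None = None

    def __post_init__(self) -> None:
        if self.embed_depth is None:
            object.__setattr__(self, "embed_depth", self.probe_length)
        dims = (
            self.probe_length, self.probe_width, self.probe_thickness,
            self.tissue_width, self.tissue_length, self.tissue_depth,
            self.embed_depth,
        )
        if any(d <= 0 for d in dims):
            raise ValueError(f"all dimensions must be positive, got {self}")
        if self.probe_width >= self.tissue_width:
            raise ValueError(
                f"probe width {self.probe_width} um must be strictly less "
                f"than tissue width {self.tissue_width} um"
            )
        if self.probe_thickness >= self.tissue_length:
            raise ValueError(
                f"probe thickness {self.probe_thickness} um must be strictly "
                f"less than tissue length {self.tissue_length} um"
            )
        if self.embed_depth > self.tissue_depth:
            raise ValueError(
                f"embed depth {self.embed_depth} um exceeds tissue depth "
                f"{self.tissue_depth} um"
            )
        if self.embed_depth != self.probe_length:
            raise ValueError(
                "probe top face must lie on the tissue top surface: "
                f"embed_depth {self.embed_depth} != probe_length "
                f"{self.probe_length}"
            )

    # Probe box extents in the global frame.
    @property
    def probe_x(self) -> tuple[float, float]:
        return (-self.probe_width / 2.0, self.probe_width / 2.0)

    @property
    def probe_z(self) -> tuple[float, float]:
        return (-self.probe_thickness / 2.0, self.probe_thickness / 2.0)

    @property
    def probe_y(self) -> tuple[float, float]:
        return (0.0, self.embed_depth)


@dataclass(frozen=True)
class MeshParams:
    """Structured-mesh grading parameters (micrometres where dimensional).

    ``n_through_thickness`` — element divisions across the probe thickness
    (>= 3). ``near_size`` — target element edge at the probe–tissue
    interface. ``grading`` — geometric growth ratio of edges away from the
    probe (>= 1). ``far_size`` — edge-length cap in the far field.
    ``axial_cap`` — edge-length cap along the probe axis inside the embedded
    region (defaults to ``far_size/2``; the shank is long and smooth so
    coarser axial seeding is safe away from its ends).
    """

    n_through_thickness: int = 4
    near_size: float = 7.0
    grading: float = 1.4
    far_size: float = 130.0
    axial_cap: float | None = None

    def __post_init__(self) -> None:
        if self.n_through_thickness < 3:
            raise ValueError("need at least 3 elements through the probe thickness")
        if not (self.near_size > 0 and math.isfinite(self.grading)):
            raise ValueError("near_size must be positive and grading finite")
        if self.grading < 1.0:
            raise ValueError(f"grading ratio must be >= 1, got {self.grading}")
        if self.far_size < self.near_size:
            raise ValueError("far_size must be >= near_size")
        if self.axial_cap is None:
            object.__setattr__(self, "axial_cap", self.far_size / 2.0)

    def refined(self, factor: float) -> "MeshParams":
        """Return params with all target sizes scaled by ``factor`` (< 1 is
        finer) and through-thickness count scaled inversely."""
        return replace(
            self,
            n_through_thickness=max(3, int(round(self.n_through_thickness / factor))),
            near_size=self.near_size * factor,
            far_size=self.far_size * factor,
            axial_cap=self.axial_cap * factor,
        )


@dataclass
class HexMesh:
    """Structured 8-node hexahedral mesh with material tags and node sets.

    ``nodes``: (N, 3) float64 coordinates in um. ``elements``: (E, 8) int32
    connectivity in VTK hexahedron ordering. ``region``: (E,) int8 tag,
    0 = tissue, 1 = probe. ``node_sets``: named 1-D int arrays.
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    axes: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)


def build_domain_spec(
    probe_length: float,
    probe_width: float,
    probe_thickness: float,
    tissue_width: float = 1500.0,
    tissue_length: float = 1500.0,
    tissue_depth: float = 1500.0,
) -> DomainSpec:
    """Build the domain for one probe geometry.

    Default tissue box 1500 x 1500 um laterally and 1500 um deep; the probe
    is fully embedded with its top face flush with the tissue surface.
    """
    return DomainSpec(
        probe_length=probe_length,
        probe_width=probe_width,
        probe_thickness=probe_thickness,
        tissue_width=tissue_width,
        tissue_length=tissue_length,
        tissue_depth=tissue_depth,
    )


def _graded_sizes(length: float, h0: float, ratio: float, hmax: float) -> np.ndarray:
    """Edge sizes filling ``length`` starting at ``h0``, growing by ``ratio``
    up to ``hmax``, then rescaled to fit exactly."""
    if length <= 0:
        return np.empty(0)
    if length <= h0:
        return np.array([length])
    sizes = []
    h, total = h0, 0.0
    while total < length:
        sizes.append(h)
        total += h
        h = min(h * ratio, hmax)
    out = np.asarray(sizes)
    return out * (length / out.sum())


def _double_graded_sizes(length: float, h0: float, ratio: float, hmax: float) -> np.ndarray:
    """Sizes fine at both ends of ``length``, growing toward the middle."""
    half = _graded_sizes(length / 2.0, h0, ratio, hmax)
    return np.concatenate([half, half[::-1]])


def _uniform_sizes(length: float, n: int) -> np.ndarray:
    return np.full(n, length / n)


def _axis_coords(segments: list[np.ndarray], start: float) -> np.ndarray:
    """Concatenate per-segment divisions into axis coordinates, forcing each
    segment endpoint to land exactly on its breakpoint (probe faces must be
    represented bit-exactly so region tagging and node sets are unambiguous).
    """
    coords = [np.array([start])]
    pos = start
    for sizes, end in segments:
        if not sizes.size:
            pos = end
            continue
        c = pos + np.cumsum(sizes)
        c[-1] = end
        coords.append(c)
        pos = end
    return np.concatenate(coords)


def _lateral_axis(lo: float, hi: float, p_lo: float, p_hi: float,
                  n_inside: int, params: MeshParams) -> np.ndarray:
    """1-D divisions for a lateral axis: [lo, p_lo] graded, [p_lo, p_hi]
    uniform with n_inside divisions, [p_hi, hi] graded."""
    left = _graded_sizes(p_lo - lo, params.near_size, params.grading,
                         params.far_size)[::-1]
    mid = _uniform_sizes(p_hi - p_lo, n_inside)
    right = _graded_sizes(hi - p_hi, params.near_size, params.grading,
                          params.far_size)
    return _axis_coords([(left, p_lo), (mid, p_hi), (right, hi)], lo)


def generate_hex_mesh(spec: DomainSpec, params: MeshParams) -> HexMesh:
    """Generate the graded conforming hex mesh over the tissue box.

    Probe elements are the grid cells inside the probe box (the grid
    conforms to the probe faces exactly, so containment is unambiguous).
    Raises if the requested near-interface size exceeds the probe thickness
    or the grading is degenerate (checked in :class:`MeshParams`).
    """
    if params.near_size > spec.probe_thickness:
        raise ValueError(
            f"near-interface element size {params.near_size} um exceeds "
            f"probe thickness {spec.probe_thickness} um"
        )
    ht = spec.probe_thickness / params.n_through_thickness
    # Across the probe width, seed at roughly the near size but never
    # coarser than a quarter-width and never finer than the thickness seed.
    h_in = max(ht, params.near_size)
    n_w = max(4, int(round(spec.probe_width / h_in)))

    x = _lateral_axis(-spec.tissue_width / 2, spec.tissue_width / 2,
                      *spec.probe_x, n_w, params)
    z = _lateral_axis(-spec.tissue_length / 2, spec.tissue_length / 2,
                      *spec.probe_z, params.n_through_thickness, params)

    # Axial: fine at the probe top and tip, growing toward mid-shank
    # (capped at axial_cap); below the tip, graded from near_size to far.
    embed = _double_graded_sizes(spec.embed_depth, params.near_size,
                                 params.grading, params.axial_cap)
    below = _graded_sizes(spec.tissue_depth - spec.embed_depth,
                          params.near_size, params.grading, params.far_size)
    y = _axis_coords([(embed, spec.embed_depth), (below, spec.tissue_depth)],
                     0.0)

    return _tensor_mesh(x, y, z, spec)


def _tensor_mesh(x: np.ndarray, y: np.ndarray, z: np.ndarray,
                 spec: DomainSpec | None) -> HexMesh:
    nx, ny, nz = len(x) - 1, len(y) - 1, len(z) - 1
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    # VTK hexahedron ordering: bottom face (z) counter-clockwise, then top.
    elements = np.column_stack([
        nid(I, J, K), nid(I + 1, J, K), nid(I + 1, J + 1, K), nid(I, J + 1, K),
        nid(I, J, K + 1), nid(I + 1, J, K + 1), nid(I + 1, J + 1, K + 1),
        nid(I, J + 1, K + 1),
    ]).astype(np.int32)

    mesh = HexMesh(nodes=nodes, elements=elements,
                   region=np.zeros(len(elements), dtype=np.int8),
                   axes=(x, y, z))
    if spec is not None:
        c = mesh.element_centroids()
        (px0, px1), (py0, py1) = spec.probe_x, spec.probe_y
        pz0, pz1 = spec.probe_z
        inside = (
            (c[:, 0] > px0) & (c[:, 0] < px1)
            & (c[:, 1] > py0) & (c[:, 1] < py1)
            & (c[:, 2] > pz0) & (c[:, 2] < pz1)
        )
        mesh.region[inside] = REGION_PROBE
        mesh.node_sets = extract_node_sets(mesh, spec)
    return mesh


def default_monitor_points(spec: DomainSpec, offset: float = 10.0) -> np.ndarray:
    """Four monitoring points in the tissue: two near the probe-tip
    interface (monitor 1, 2) and two near the top probe–tissue interface
    (monitor 3, 4), ``offset`` um off the interface."""
    w2 = spec.probe_width / 2.0
    t2 = spec.probe_thickness / 2.0
    tip = spec.embed_depth
    return np.array([
        [0.0, tip + offset, 0.0],            # below the tip, on axis
        [0.0, tip - offset, t2 + offset],    # beside the shank near the tip
        [0.0, offset, t2 + offset],          # beside the shank near the top
        [w2 + offset, offset, 0.0],          # off the width face near the top
    ])


def extract_node_sets(mesh: HexMesh, spec: DomainSpec,
                      monitor_offset: float = 10.0,
                      tol: float = 1e-6) -> dict[str, np.ndarray]:
    """Named node sets for boundary conditions and monitoring.

    ``bottom_edges`` — nodes on the four perimeter edges of the tissue
    bottom face (the fixed support). ``probe_top_face`` — probe nodes on the
    tissue top plane (the loaded patch). ``interface`` — nodes shared by
    probe and tissue elements. ``monitor_1..4`` — nearest tissue node to
    each default monitoring point.
    """
    xyz = mesh.nodes
    w2, l2 = spec.tissue_width / 2.0, spec.tissue_length / 2.0
    bottom = np.abs(xyz[:, 1] - spec.tissue_depth) < tol
    on_rim = (np.abs(np.abs(xyz[:, 0]) - w2) < tol) | \
             (np.abs(np.abs(xyz[:, 2]) - l2) < tol)
    bottom_edges = np.flatnonzero(bottom & on_rim)

    pw2, pt2 = spec.probe_width / 2.0, spec.probe_thickness / 2.0
    top_face = np.flatnonzero(
        (np.abs(xyz[:, 1]) < tol)
        & (np.abs(xyz[:, 0]) <= pw2 + tol)
        & (np.abs(xyz[:, 2]) <= pt2 + tol)
    )

    probe_nodes = np.unique(mesh.elements[mesh.region == REGION_PROBE])
    tissue_nodes = np.unique(mesh.elements[mesh.region == REGION_TISSUE])
    interface = np.intersect1d(probe_nodes, tissue_nodes)

    sets = {
        "bottom_edges": bottom_edges,
        "probe_top_face": top_face,
        "interface": interface,
    }
    pts = default_monitor_points(spec, monitor_offset)
    for i, p in enumerate(pts, start=1):
        d2 = np.sum((xyz[tissue_nodes] - p) ** 2, axis=1)
        sets[f"monitor_{i}"] = np.array([tissue_nodes[int(np.argmin(d2))]])

    for name, s in sets.items():
        if s.size == 0:
            raise ValueError(f"node set '{name}' is empty: mesh/spec mismatch")
        if s.min() < 0 or s.max() >= mesh.n_nodes:
            raise ValueError(f"node set '{name}' references invalid nodes")
    return sets


def hex_volumes(mesh: HexMesh) -> np.ndarray:
    """Exact volumes of the (axis-aligned or mildly distorted) hexahedra via
    2x2x2 Gauss integration of the Jacobian determinant."""
    from .fem import jacobian_determinants

    return jacobian_determinants(mesh.nodes[mesh.elements]).sum(axis=1)


def unit_cube_mesh(n: int) -> HexMesh:
    """Uniform n x n x n mesh of the unit cube (no probe region) — used by
    verification fixtures and tests."""
    ax = np.linspace(0.0, 1.0, n + 1)
    return _tensor_mesh(ax, ax.copy(), ax.copy(), None)


def box_mesh(lx: float, ly: float, lz: float, nx: int, ny: int, nz: int) -> HexMesh:
    """Uniform structured mesh of an axis-aligned box with one corner at the
    origin."""
    return _tensor_mesh(np.linspace(0, lx, nx + 1), np.linspace(0, ly, ny + 1),
                        np.linspace(0, lz, nz + 1), None)


# Corner split of a hexahedron into 6 tetrahedra (consistent across shared
# faces for a structured grid).
_HEX_TO_TETS = np.array([
    [0, 1, 3, 4], [1, 2, 3, 6], [1, 3, 4, 6],
    [3, 4, 6, 7], [1, 4, 5, 6], [4, 5, 6, 7],
])


def subdivide_to_tets(mesh: HexMesh) -> tuple[np.ndarray, np.ndarray]:
    """Split every hexahedron into 6 tetrahedra (sensitivity checks and
    export only — the solver operates on hexahedra).

    Returns ``(tet_connectivity (6E, 4), tet_region (6E,))``.
    """
    tets = mesh.elements[:, _HEX_TO_TETS].reshape(-1, 4)
    region = np.repeat(mesh.region, len(_HEX_TO_TETS))
    return tets, region
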