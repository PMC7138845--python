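"""Reference-surface generation for the normal colon and pouch models.

The normal colon midsurface is a quarter cylinder (radius ``Rm``, axis z,
symmetry planes x = 0 and z = 0).  A diverticulum-like pouch is the
intersection of a sphere of diameter ``D`` with the cylinder such that the
cap apex sits a height ``H`` above the midsurface; the crease where the two
surfaces meet is rounded by a rolling-ball fillet of radius ``r_f``
realized on signed distance fields.

Meshes are structured grids in the (circumferential arc, axial) parameter
plane, split into flat triangles.  Nodes inside the pouch footprint are
lifted onto the spherical cap and every node near the pouch is projected
onto the implicit blended surface, so the discrete surface converges to the
implicit one under refinement.

The module also computes the four pouch descriptors used for the
stress-geometry correlations: the neck widths ``Dx`` (along x) and ``Dz``
(along z), the neck base area ``Ab`` on the cylinder, and the lumen-side
pouch surface area ``Sp``.  These are measured on the pre-fillet
sphere/cylinder intersection curve; the fillet is treated purely as a
smoothing device.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .analytic_tube import TubeGeometry
from .constitutive import DomainError

__all__ = [
    "PouchSpec",
    "PouchMetrics",
    "SurfaceMesh",
    "build_normal_mesh",
    "build_pouch_mesh",
    "pouch_geometry_metrics",
    "assign_fiber_frame",
    "reflect_mesh_z",
    "write_vtk",
    "STUDY_GRID",
]

#: the (H, D) grid of the pouch study, mm
STUDY_GRID = tuple(
    (h, d) for h in (2.0, 4.0, 6.0) for d in (8.0, 10.0, 12.0)
)


@dataclass(frozen=True)
class PouchSpec:
    """Pouch construction parameters, mm."""

    diameter_sphere: float
    height: float
    fillet_radius: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.height < self.diameter_sphere:
            raise DomainError(
                f"need 0 < H < D for a proper spherical cap, got "
                f"H={self.height}, D={self.diameter_sphere}"
            )
        if self.fillet_radius < 0:
            raise DomainError("fillet radius must be non-negative")

    @property
    def label(self) -> str:
        return f"D{self.diameter_sphere:g}_H{self.height:g}"


@dataclass(frozen=True)
class PouchMetrics:
    """Pouch geometry descriptors (mm, mm^2)."""

    d_x: float
    d_z: float
    a_b: float
    s_p: float


@dataclass
class SurfaceMesh:
    """Triangulated reference midsurface with per-element fiber frame.

    Coordinates are in mm.  ``node_tags`` holds boolean masks:
    ``sym_yz`` (x = 0 plane), ``sym_xy`` (z = 0 plane), ``far_end``
    (z = +/- L/2) and ``pouch_region``.  ``cell_ij`` stores for every
    triangle the (circumferential, axial) index of its parent grid cell so
    post-processing can walk structured paths.
    """

    nodes: np.ndarray
    tris: np.ndarray
    thickness: np.ndarray
    node_tags: dict = field(default_factory=dict)
    cell_ij: np.ndarray | None = None
    node_ij: np.ndarray | None = None
    mesh_size: float = 0.0
    fiber_long: np.ndarray | None = None
    fiber_circ: np.ndarray | None = None
    normals: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_cells(self) -> int:
        return self.tris.shape[0]

    def areas(self) -> np.ndarray:
        p = self.nodes[self.tris]
        cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tris].mean(axis=1)


# ---------------------------------------------------------------------------
# implicit blended surface
# ---------------------------------------------------------------------------


def _pouch_frame(geom: TubeGeometry, pouch: PouchSpec):
    """Sphere radius and center height for the cap construction."""
    rs = 0.5 * pouch.diameter_sphere
    yc = geom.r_mid + pouch.height - rs
    return rs, yc


def _sdf_and_grad(xyz: np.ndarray, geom: TubeGeometry, pouch: PouchSpec):
    """Signed distance (negative inside) of the filleted cylinder+sphere
    union, and its gradient.

    The rounded union of two signed distance fields a, b with fillet radius
    r is  F = max(r, min(a, b)) - hypot(max(r-a, 0), max(r-b, 0)),
    which reproduces an exact rolling-ball fillet where the two surfaces
    meet at a crease.
    """
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    rs, yc = _pouch_frame(geom, pouch)
    r = pouch.fillet_radius

    rho_c = np.sqrt(x * x + y * y)
    a = rho_c - geom.r_mid
    ga = np.stack([x, y, np.zeros_like(z)], axis=-1) / np.maximum(rho_c, 1e-12)[..., None]

    dy = y - yc
    rho_s = np.sqrt(x * x + dy * dy + z * z)
    b = rho_s - rs
    gb = np.stack([x, dy, z], axis=-1) / np.maximum(rho_s, 1e-12)[..., None]

    m = np.minimum(a, b)
    gm = np.where((a <= b)[..., None], ga, gb)
    if r == 0.0:
        return m, gm

    qa = np.maximum(r - a, 0.0)
    qb = np.maximum(r - b, 0.0)
    L = np.sqrt(qa * qa + qb * qb)
    F = np.maximum(r, m) - L
    with np.errstate(invalid="ignore", divide="ignore"):
        gL = (qa[..., None] * -ga + qb[..., None] * -gb) / np.maximum(L, 1e-12)[..., None]
    gF = np.where((m > r)[..., None], gm, 0.0) - np.where((L > 0)[..., None], gL, 0.0)
    # normalize to keep projection steps well-scaled
    nrm = np.linalg.norm(gF, axis=-1)
    gF = gF / np.maximum(nrm, 1e-12)[..., None]
    return F, gF


def _project_to_surface(xyz, geom, pouch, iters: int = 8):
    p = xyz.copy()
    for _ in range(iters):
        phi, grad = _sdf_and_grad(p, geom, pouch)
        p = p - phi[..., None] * grad
    return p


# ---------------------------------------------------------------------------
# intersection curve of the pre-fillet sphere and cylinder
# ---------------------------------------------------------------------------


def _neck_curve(geom: TubeGeometry, pouch: PouchSpec, n: int = 400):
    """Sampled sphere/cylinder intersection curve on the quarter domain.

    Returns arrays (theta, z, points) with theta the cylinder azimuth from
    the pouch meridian (+y axis), z >= 0, plus the azimuthal extent
    theta_b.  On the curve  z^2 = Rs^2 - yc^2 - Rm^2 + 2 yc Rm cos(theta).
    """
    rm = geom.r_mid
    rs, yc = _pouch_frame(geom, pouch)
    cos_tb = (yc * yc + rm * rm - rs * rs) / (2.0 * yc * rm)
    if cos_tb >= 1.0:
        raise DomainError("sphere does not intersect the cylinder (degenerate pouch)")
    if cos_tb <= -1.0:
        raise DomainError("sphere swallows the cylinder")
    theta_b = math.acos(cos_tb)
    theta = np.linspace(0.0, theta_b, n)
    z2 = rs * rs - yc * yc - rm * rm + 2.0 * yc * rm * np.cos(theta)
    z = np.sqrt(np.maximum(z2, 0.0))
    pts = np.stack([rm * np.sin(theta), rm * np.cos(theta), z], axis=1)
    return theta, z, pts, theta_b


# ---------------------------------------------------------------------------
# structured grids
# ---------------------------------------------------------------------------


def _graded_axis(total, h_fine, fine_extent, h_coarse, growth=1.2):
    """1-D node coordinates on [0, total]: uniform ``h_fine`` spacing up to
    ``fine_extent`` then geometric growth capped at ``h_coarse``; the coarse
    tail is rescaled so the last node lands exactly on ``total``."""
    if h_fine > total:
        raise DomainError(f"mesh size {h_fine} exceeds the domain extent {total}")
    if fine_extent >= total or h_fine >= h_coarse:
        n = max(1, math.ceil(total / h_fine))
        return np.linspace(0.0, total, n + 1)
    n_f = max(1, math.ceil(fine_extent / h_fine))
    fine_len = n_f * h_fine
    if fine_len >= total:
        n = max(1, math.ceil(total / h_fine))
        return np.linspace(0.0, total, n + 1)
    spac = [h_fine] * n_f
    tail = []
    h = h_fine
    x = fine_len
    while x < total - 1e-12:
        h = min(h * growth, h_coarse)
        tail.append(h)
        x += h
    factor = (total - fine_len) / sum(tail)
    spac += [s * factor for s in tail]
    return np.concatenate([[0.0], np.cumsum(spac)])


def _grid_to_tris(n_i: int, n_j: int):
    """Triangulate an (n_i+1) x (n_j+1) node grid; returns (tris, cell_ij).

    Node id = i * (n_j + 1) + j.  Orientation is chosen so that, on the
    cylinder, triangle normals point outward (away from the axis).
    """
    ii, jj = np.meshgrid(np.arange(n_i), np.arange(n_j), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    n00 = ii * (n_j + 1) + jj
    n10 = (ii + 1) * (n_j + 1) + jj
    n01 = n00 + 1
    n11 = n10 + 1
    t1 = np.stack([n00, n11, n10], axis=1)
    t2 = np.stack([n00, n01, n11], axis=1)
    tris = np.concatenate([t1, t2], axis=0)
    cell_ij = np.concatenate(
        [np.stack([ii, jj], axis=1), np.stack([ii, jj], axis=1)], axis=0
    )
    return tris, cell_ij


def _finalize(mesh: SurfaceMesh, outward_ref):
    """Fix triangle orientation to outward normals and attach fiber frames."""
    p = mesh.nodes[mesh.tris]
    cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = np.einsum("ij,ij->i", cr, outward_ref) < 0.0
    mesh.tris[flip] = mesh.tris[flip][:, ::-1]
    assign_fiber_frame(mesh)
    return mesh


def pouch_fine_extent(geom: TubeGeometry, pouch: PouchSpec) -> float:
    """Parametric radius (mm) of the refined region around a pouch."""
    rm = geom.r_mid
    _, _, pts, theta_b = _neck_curve(geom, pouch)
    rho_max = max(rm * theta_b, pts[:, 2].max())
    return rho_max + pouch.fillet_radius + 2.0


def build_normal_mesh(
    geom: TubeGeometry,
    mesh_size: float,
    fine_extent: float | None = None,
    refine_factor: float = 0.5,
) -> SurfaceMesh:
    """Quarter-cylinder midsurface mesh (x >= 0, z >= 0), axis along z.

    With ``fine_extent`` set, the grid is graded exactly like a pouch mesh
    of that footprint; a study's normal reference uses the same grading as
    its diseased meshes so discretization bias cancels in every ratio.
    """
    rm = geom.r_mid
    half_len = 0.5 * geom.length_axial
    arc = math.pi * rm
    if mesh_size <= 0:
        raise DomainError("mesh size must be positive")
    if mesh_size > min(arc, half_len):
        raise DomainError("mesh size exceeds the quarter-domain extent")
    if fine_extent is None:
        u = np.linspace(0.0, arc, max(2, math.ceil(arc / mesh_size)) + 1)
        v = np.linspace(0.0, half_len, max(2, math.ceil(half_len / mesh_size)) + 1)
    else:
        h_fine = mesh_size * refine_factor
        u = _graded_axis(arc, h_fine, fine_extent, mesh_size)
        v = _graded_axis(half_len, h_fine, fine_extent, mesh_size)
    return _structured_cylinder_mesh(geom, u, v, pouch=None, mesh_size=mesh_size)


def build_pouch_mesh(
    geom: TubeGeometry,
    pouch: PouchSpec,
    mesh_size: float,
    refine_factor: float = 0.5,
    fine_extent: float | None = None,
) -> SurfaceMesh:
    """Midsurface mesh of the colon with one pouch at (theta=0, z=0).

    ``mesh_size`` is the far-field target element size; near the pouch the
    grid is refined by ``refine_factor``.  Nodes whose parametric position
    falls inside the pre-fillet neck footprint are lifted onto the
    spherical cap, and every node near the pouch is then projected onto
    the implicit filleted surface.  ``fine_extent`` overrides the refined
    footprint radius (a study passes the grid-wide maximum so all its
    meshes share one grading).
    """
    rm = geom.r_mid
    half_len = 0.5 * geom.length_axial
    arc = math.pi * rm
    extent = pouch_fine_extent(geom, pouch)
    if fine_extent is not None:
        extent = max(extent, fine_extent)
    if extent > min(arc, half_len):
        raise DomainError("pouch does not fit in the quarter domain")
    h_fine = mesh_size * refine_factor
    u = _graded_axis(arc, h_fine, extent, mesh_size)
    v = _graded_axis(half_len, h_fine, extent, mesh_size)
    return _structured_cylinder_mesh(geom, u, v, pouch=pouch, mesh_size=mesh_size)


def _structured_cylinder_mesh(geom, u, v, pouch, mesh_size):
    rm = geom.r_mid
    n_i, n_j = len(u) - 1, len(v) - 1
    uu, vv = np.meshgrid(u, v, indexing="ij")
    uu, vv = uu.ravel(), vv.ravel()
    theta = uu / rm
    nodes = np.stack([rm * np.sin(theta), rm * np.cos(theta), vv], axis=1)
    pouch_mask = np.zeros(nodes.shape[0], dtype=bool)

    if pouch is not None:
        rs, yc = _pouch_frame(geom, pouch)
        th_c, z_c, pts_c, theta_b = _neck_curve(geom, pouch)
        # curve in the parameter plane and on the sphere, indexed by the
        # polar angle beta of the (u, v) plane
        beta_c = np.arctan2(z_c, rm * th_c)
        beta_c[0] = 0.5 * math.pi  # theta=0 endpoint
        rho_c = np.hypot(rm * th_c, z_c)
        dirs = (pts_c - np.array([0.0, yc, 0.0])) / rs
        alpha_c = np.arccos(np.clip(dirs[:, 1], -1.0, 1.0))
        zeta_c = np.arctan2(dirs[:, 2], np.maximum(dirs[:, 0], 0.0))
        zeta_c[0] = 0.5 * math.pi
        order = np.argsort(beta_c)
        beta_s, rho_s_, alpha_s, zeta_s = (
            beta_c[order], rho_c[order], alpha_c[order], zeta_c[order]
        )

        beta = np.arctan2(vv, uu)
        rho = np.hypot(uu, vv)
        rho_n = np.interp(beta, beta_s, rho_s_)
        in_cap = rho < rho_n
        if np.any(in_cap):
            s = rho[in_cap] / rho_n[in_cap]
            a_n = np.interp(beta[in_cap], beta_s, alpha_s)
            z_n = np.interp(beta[in_cap], beta_s, zeta_s)
            # radial map: near-unit arc-length metric at the apex, exact
            # match to the neck curve at s = 1
            slope = np.clip(np.interp(beta[in_cap], beta_s, rho_s_) / (rs * a_n), 0.0, 1.0)
            phi_p = a_n * (slope * s + (1.0 - slope) * s * s)
            nodes[in_cap] = np.stack(
                [
                    rs * np.sin(phi_p) * np.cos(z_n),
                    yc + rs * np.cos(phi_p),
                    rs * np.sin(phi_p) * np.sin(z_n),
                ],
                axis=1,
            )
        near = rho < rho_n + 3.0 * pouch.fillet_radius + 1.0
        nodes[near] = _project_to_surface(nodes[near], geom, pouch)
        # keep symmetry-plane nodes exactly on their planes
        nodes[np.isclose(uu, 0.0), 0] = 0.0
        nodes[np.isclose(uu, u[-1]), 0] = 0.0
        nodes[np.isclose(vv, 0.0), 2] = 0.0
        pouch_mask = rho < rho_n + 2.0 * pouch.fillet_radius

    tris, cell_ij = _grid_to_tris(n_i, n_j)
    node_ij = np.stack(
        np.meshgrid(np.arange(n_i + 1), np.arange(n_j + 1), indexing="ij"), axis=-1
    ).reshape(-1, 2)
    tags = {
        "sym_yz": np.isclose(uu, 0.0) | np.isclose(uu, u[-1]),
        "sym_xy": np.isclose(vv, 0.0),
        "far_end": np.isclose(vv, v[-1]),
        "pouch_region": pouch_mask,
    }
    mesh = SurfaceMesh(
        nodes=nodes,
        tris=tris,
        thickness=np.full(tris.shape[0], geom.thickness),
        node_tags=tags,
        cell_ij=cell_ij,
        node_ij=node_ij,
        mesh_size=mesh_size,
        meta={
            "geom": geom,
            "pouch": pouch,
            "apex": np.array([0.0, rm + (pouch.height if pouch else 0.0), 0.0]),
            "axis_u": u,
            "axis_v": v,
        },
    )
    # outward direction: implicit-surface gradient (radial for the plain tube)
    cent = mesh.centroids()
    if pouch is not None:
        _, outward = _sdf_and_grad(cent, geom, pouch)
    else:
        outward = cent.copy()
        outward[:, 2] = 0.0
    return _finalize(mesh, outward)


def assign_fiber_frame(mesh: SurfaceMesh) -> SurfaceMesh:
    """Per-element orthonormal fiber frame tangent to the surface.

    Longitudinal = unit projection of the global z axis onto the element
    plane; circumferential = normal x longitudinal.
    """
    p = mesh.nodes[mesh.tris]
    cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    nrm = np.linalg.norm(cr, axis=1)
    if np.any(nrm <= 0):
        raise DomainError("degenerate (zero-area) element")
    n = cr / nrm[:, None]
    ez = np.array([0.0, 0.0, 1.0])
    l_raw = ez - n * n[:, 2][:, None]
    l_len = np.linalg.norm(l_raw, axis=1)
    bad = l_len < 1e-8
    if np.any(bad):
        raise DomainError(
            f"element normal parallel to z, cannot project the longitudinal "
            f"direction (elements {np.nonzero(bad)[0][:5]})"
        )
    long_ = l_raw / l_len[:, None]
    circ = np.cross(n, long_)
    mesh.normals = n
    mesh.fiber_long = long_
    mesh.fiber_circ = circ
    return mesh


def reflect_mesh_z(mesh: SurfaceMesh) -> SurfaceMesh:
    """Mirror a quarter mesh through the z = 0 plane into a half model.

    Nodes on z = 0 are shared; mirrored triangles are rewound so normals
    stay outward.  Used for symmetry verification of the solver.
    """
    on_plane = mesh.node_tags["sym_xy"]
    n_nodes = mesh.n_nodes
    idx_map = np.empty(n_nodes, dtype=int)
    idx_map[on_plane] = np.nonzero(on_plane)[0]
    new_ids = np.arange(np.count_nonzero(~on_plane)) + n_nodes
    idx_map[~on_plane] = new_ids
    mirrored = mesh.nodes[~on_plane].copy()
    mirrored[:, 2] *= -1.0
    nodes = np.concatenate([mesh.nodes, mirrored], axis=0)
    tris_m = idx_map[mesh.tris][:, ::-1]
    tris = np.concatenate([mesh.tris, tris_m], axis=0)
    tags = {
        "sym_yz": np.concatenate(
            [mesh.node_tags["sym_yz"], mesh.node_tags["sym_yz"][~on_plane]]
        ),
        "sym_xy": np.zeros(nodes.shape[0], dtype=bool),
        "far_end": np.concatenate(
            [mesh.node_tags["far_end"], mesh.node_tags["far_end"][~on_plane]]
        ),
        "pouch_region": np.concatenate(
            [mesh.node_tags["pouch_region"], mesh.node_tags["pouch_region"][~on_plane]]
        ),
    }
    cell_ij = None
    if mesh.cell_ij is not None:
        cm = mesh.cell_ij.copy()
        cm[:, 1] = -1 - cm[:, 1]
        cell_ij = np.concatenate([mesh.cell_ij, cm], axis=0)
    out = SurfaceMesh(
        nodes=nodes,
        tris=tris,
        thickness=np.concatenate([mesh.thickness, mesh.thickness]),
        node_tags=tags,
        cell_ij=cell_ij,
        node_ij=None,
        mesh_size=mesh.mesh_size,
        meta=dict(mesh.meta, mirrored_z=True),
    )
    return assign_fiber_frame(out)


# ---------------------------------------------------------------------------
# pouch geometry descriptors
# ---------------------------------------------------------------------------


def pouch_geometry_metrics(geom: TubeGeometry, pouch: PouchSpec) -> PouchMetrics:
    """Neck widths, neck base area and lumen-side pouch surface area.

    All quantities are measured on the pre-fillet sphere/cylinder
    intersection:  ``Dz`` is the z-extent of the intersection curve
    (closed form 2 sqrt(H (D - H)), exact because the cylinder is straight
    along z), ``Dx`` its straight-line x-extent, ``Ab`` the cylinder-surface
    area enclosed by the curve, and ``Sp`` the sphere-surface area outside
    the cylinder.
    """
    rm = geom.r_mid
    rs, yc = _pouch_frame(geom, pouch)
    h, d = pouch.height, pouch.diameter_sphere
    cos_tb = (yc * yc + rm * rm - rs * rs) / (2.0 * yc * rm)
    if cos_tb >= 1.0:
        warnings.warn("degenerate (tangent) pouch: all metrics zero")
        return PouchMetrics(0.0, 0.0, 0.0, 0.0)
    if cos_tb <= -1.0:
        raise DomainError("sphere swallows the cylinder")
    theta_b = math.acos(cos_tb)

    d_z = 2.0 * math.sqrt(h * (d - h))
    d_x = 2.0 * rm * (math.sin(theta_b) if theta_b <= 0.5 * math.pi else 1.0)

    def half_width(theta):
        z2 = rs * rs - yc * yc - rm * rm + 2.0 * yc * rm * np.cos(theta)
        return np.sqrt(np.maximum(z2, 0.0))

    a_b, _ = integrate.quad(lambda t: 4.0 * rm * half_width(t), 0.0, theta_b,
                            epsabs=1e-10, epsrel=1e-10)

    def azimuthal_measure(phi):
        # measure of sphere azimuths outside the cylinder at polar angle phi
        y = yc + rs * math.cos(phi)
        s2 = rs * rs * math.sin(phi) ** 2
        if s2 <= 0.0:
            return 2.0 * math.pi if y * y >= rm * rm else 0.0
        t = (rm * rm - y * y) / s2
        if t <= 0.0:
            return 2.0 * math.pi
        if t >= 1.0:
            return 0.0
        return 2.0 * math.pi - 4.0 * math.asin(math.sqrt(t))

    s_p, _ = integrate.quad(
        lambda f: rs * rs * math.sin(f) * azimuthal_measure(f),
        0.0, math.pi, epsabs=1e-10, epsrel=1e-9, limit=200,
    )
    return PouchMetrics(d_x=d_x, d_z=d_z, a_b=a_b, s_p=s_p)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_vtk(mesh: SurfaceMesh, path, cell_data=None, point_data=None) -> None:
    """Write the mesh as a legacy ASCII VTK unstructured grid.

    ``cell_data`` / ``point_data`` map names to scalar (n,) or vector
    (n, 3) arrays.  The fiber frame is always included as cell vectors.
    """
    cell_data = dict(cell_data or {})
    if mesh.fiber_long is not None:
        cell_data.setdefault("fiber_long", mesh.fiber_long)
        cell_data.setdefault("fiber_circ", mesh.fiber_circ)
    point_data = dict(point_data or {})
    for name, mask in mesh.node_tags.items():
        point_data.setdefault("tag_" + name, mask.astype(float))

    def fmt_block(arr):
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            return "\n".join(f"{x:.9g}" for x in arr)
        return "\n".join(" ".join(f"{x:.9g}" for x in row) for row in arr)

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncolomech surface mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        fh.write(fmt_block(mesh.nodes) + "\n")
        m = mesh.n_cells
        fh.write(f"CELLS {m} {4 * m}\n")
        for t in mesh.tris:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_TYPES {m}\n" + "\n".join(["5"] * m) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                fh.write(fmt_block(arr) + "\n")
        if cell_data:
            fh.write(f"CELL_DATA {m}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                fh.write(fmt_block(arr) + "\n")
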