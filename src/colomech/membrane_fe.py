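"""Nonlinear incompressible fiber-reinforced membrane finite elements.

Quasi-static inflation of the colon midsurface: a two-stage load program
(axial prestretch by prescribed far-end displacement, then luminal follower
pressure ramped in fixed increments) solved with damped Newton iteration on
the total-Lagrangian virtual-work residual.

Element technology: flat 3-node constant-strain membrane triangles.  Per
element the surface deformation gradient ``F`` (3x2, from the reference
fiber frame to 3-space) gives the right Cauchy-Green tensor ``C = F^T F``;
the thickness stretch follows from incompressibility and the plane-stress
condensed stress comes from :mod:`colomech.constitutive`.  The follower
pressure acts along the current element normal and its load stiffness
(unsymmetric) is kept in the Newton matrix.

The formulation replaces a solid-element model on the strength of the
thin-wall geometry (diameter-to-thickness ratio near 20); it carries no
bending stiffness, so fillet boundary layers are resolved only in a
membrane sense.  A small compression-modulus floor (default 1e-3 C10,
flag-controlled) keeps wrinkling-prone regions from losing rank.

The solver is fully deterministic: assembly order is fixed and no source
of randomness exists anywhere in the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .constitutive import DomainError, MaterialParams, membrane_stress_tangent
from .geometry_factory import SurfaceMesh

__all__ = [
    "LoadSchedule",
    "StressField",
    "PressureSweep",
    "SweepFailure",
    "solve_sweep",
    "solve_sweep_robust",
    "export_sweep_fields",
    "rigid_body_check",
    "mesh_convergence_study",
]


class SweepFailure(RuntimeError):
    """Non-convergence after the maximum number of step bisections."""

    def __init__(self, msg, sweep=None):
        super().__init__(msg)
        self.sweep = sweep


@dataclass(frozen=True)
class LoadSchedule:
    """Two-stage load program: axial prestretch, then luminal pressure.

    Pressure is in kPa at this boundary (converted to Pa internally); the
    outer wall pressure is identically zero.
    """

    axial_prestretch: float = 1.10
    pressure_max_kpa: float = 5.0
    pressure_step_kpa: float = 0.25

    def __post_init__(self) -> None:
        if self.pressure_step_kpa <= 0:
            raise DomainError("pressure step must be positive")
        n = self.pressure_max_kpa / self.pressure_step_kpa
        if abs(n - round(n)) > 1e-9:
            raise DomainError("pressure_max must be a multiple of pressure_step")
        if self.axial_prestretch <= 0:
            raise DomainError("axial prestretch must be positive")

    @property
    def levels_kpa(self) -> np.ndarray:
        n = int(round(self.pressure_max_kpa / self.pressure_step_kpa))
        return np.linspace(0.0, self.pressure_max_kpa, n + 1)


@dataclass
class StressField:
    """Per-element membrane state at one load level.

    ``stress`` holds the in-plane Cauchy components in the (deformed)
    fiber frame as columns [sigma_circ, sigma_long, sigma_shear] in Pa.
    ``sigma_mps`` is the max principal stress including the zero
    through-thickness principal value; ``von_mises`` the plane-stress
    equivalent stress.  Centroids are in mm.
    """

    level_kpa: float
    stress: np.ndarray
    sigma_mps: np.ndarray
    von_mises: np.ndarray
    stretches: np.ndarray
    centroid_ref: np.ndarray
    centroid_def: np.ndarray


@dataclass
class PressureSweep:
    """Fields and diagnostics of one quasi-static inflation history."""

    mesh: SurfaceMesh
    params: MaterialParams
    loads: LoadSchedule
    levels_kpa: list = field(default_factory=list)
    fields: list = field(default_factory=list)
    displacements: list = field(default_factory=list)
    diagnostics: pd.DataFrame | None = None
    converged: bool = True
    failed_level: float | None = None
    #: levels dropped with a reason (the unloaded pouch membrane state is
    #: degenerate: wrinkling modes carry no stiffness at exactly P = 0)
    skipped_levels: list = field(default_factory=list)

    def field_at(self, level_kpa: float):
        for lv, f in zip(self.levels_kpa, self.fields):
            if abs(lv - level_kpa) < 1e-9:
                return f
        raise KeyError(f"level {level_kpa} kPa not recorded")

    def max_sigma_mps(self) -> np.ndarray:
        """Peak max-principal stress (Pa) per recorded pressure level."""
        return np.array([f.sigma_mps.max() for f in self.fields])


# ---------------------------------------------------------------------------


class _Assembler:
    """Precomputed element data and vectorized residual/stiffness."""

    def __init__(self, mesh: SurfaceMesh, p: MaterialParams,
                 stabilization: bool = True, stab_factor: float = 1e-3,
                 tension_only: bool = False):
        if mesh.fiber_long is None:
            raise DomainError("mesh needs fiber frames (assign_fiber_frame)")
        self.mesh = mesh
        self.p = p
        self.tension_only = tension_only
        self.k_stab = stab_factor * p.c10 if stabilization else 0.0

        self.X = mesh.nodes * 1e-3  # mm -> m
        self.tris = mesh.tris
        m = mesh.n_cells
        e1 = self.X[self.tris[:, 1]] - self.X[self.tris[:, 0]]
        e2 = self.X[self.tris[:, 2]] - self.X[self.tris[:, 0]]
        cr = np.cross(e1, e2)
        area = 0.5 * np.linalg.norm(cr, axis=1)
        if np.any(area <= 0):
            raise DomainError("degenerate reference element")
        self.area = area
        self.w = area * mesh.thickness * 1e-3  # reference volume per element

        c = mesh.fiber_circ
        l = mesh.fiber_long
        A = np.empty((m, 2, 2))
        A[:, 0, 0] = np.einsum("ij,ij->i", e1, c)
        A[:, 0, 1] = np.einsum("ij,ij->i", e2, c)
        A[:, 1, 0] = np.einsum("ij,ij->i", e1, l)
        A[:, 1, 1] = np.einsum("ij,ij->i", e2, l)
        det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
        B = np.empty_like(A)
        B[:, 0, 0] = A[:, 1, 1] / det
        B[:, 0, 1] = -A[:, 0, 1] / det
        B[:, 1, 0] = -A[:, 1, 0] / det
        B[:, 1, 1] = A[:, 0, 0] / det
        self.B = B
        G = np.empty((m, 3, 2))
        G[:, 1, :] = B[:, 0, :]
        G[:, 2, :] = B[:, 1, :]
        G[:, 0, :] = -(G[:, 1, :] + G[:, 2, :])
        self.G = G

        # global dof bookkeeping (dof = 3*node + comp)
        edofs = (3 * self.tris[:, :, None] + np.arange(3)[None, None, :])
        self.edofs = edofs.reshape(m, 9)
        self.rows = np.repeat(self.edofs, 9, axis=1).ravel()
        self.cols = np.tile(self.edofs, (1, 9)).ravel()
        self.ndof = 3 * mesh.n_nodes

    # -- kinematics ---------------------------------------------------------

    def deformation(self, x: np.ndarray):
        d1 = x[self.tris[:, 1]] - x[self.tris[:, 0]]
        d2 = x[self.tris[:, 2]] - x[self.tris[:, 0]]
        d = np.stack([d1, d2], axis=2)  # (m, 3, 2)
        F = np.einsum("eiK,eKJ->eiJ", d, self.B)
        C = np.einsum("eiP,eiQ->ePQ", F, F)
        return d, F, C

    def _stress(self, C, with_tangent):
        S, dSdC = membrane_stress_tangent(
            self.p, C, tension_only=self.tension_only, with_tangent=with_tangent
        )
        if self.k_stab:
            eye = np.zeros_like(C)
            eye[:, 0, 0] = eye[:, 1, 1] = 1.0
            S = S + self.k_stab * (C - eye)
            if with_tangent:
                I_sym = 0.5 * (
                    np.einsum("pr,qs->pqrs", np.eye(2), np.eye(2))
                    + np.einsum("ps,qr->pqrs", np.eye(2), np.eye(2))
                )
                dSdC = dSdC + self.k_stab * I_sym[None]
        return S, dSdC

    def energy(self, x: np.ndarray) -> float:
        """Total elastic energy (J) of a deformed configuration (m)."""
        _, _, C = self.deformation(x)
        p = self.p
        detC = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
        i1 = C[:, 0, 0] + C[:, 1, 1] + 1.0 / detC
        g = math.radians(p.gamma_s)
        i4l = C[:, 1, 1]
        i4s = math.cos(g) ** 2 * C[:, 0, 0] + math.sin(g) ** 2 * C[:, 1, 1]

        def fib(k1, k2, i4):
            if k1 == 0.0:
                return 0.0
            return k1 / k2 * np.expm1(k2 * (i4 - 1.0) ** 2)

        w = p.c10 * (i1 - 3.0) + fib(p.k1_l, p.k2_l, i4l) + fib(p.k1_s, p.k2_s, i4s)
        if self.k_stab:
            eye = np.zeros_like(C)
            eye[:, 0, 0] = eye[:, 1, 1] = 1.0
            w = w + 0.25 * self.k_stab * np.sum((C - eye) ** 2, axis=(1, 2))
        return float(np.sum(self.w * w))

    # -- residual and stiffness --------------------------------------------

    def internal_forces(self, F, S):
        f_el = np.einsum("e,eiP,ePQ,eaQ->eai", self.w, F, S, self.G,
                         optimize=True)
        f = np.zeros(self.ndof)
        np.add.at(f, self.edofs.ravel(), f_el.reshape(-1))
        return f

    def external_forces(self, d, pressure_pa):
        if pressure_pa == 0.0:
            return np.zeros(self.ndof)
        cr = 0.5 * np.cross(d[:, :, 0], d[:, :, 1], axis=1)  # outward area vector
        f_node = (pressure_pa / 3.0) * cr  # same on each of the 3 nodes
        f = np.zeros(self.ndof)
        f_el = np.repeat(f_node[:, None, :], 3, axis=1)  # (m, a, i)
        np.add.at(f, self.edofs.ravel(), f_el.reshape(-1))
        return f

    #: trial states with any in-plane stretch beyond this are rejected as
    #: unphysical (the exponential fiber terms make them meaningless anyway)
    stretch_cap = 4.0

    def residual(self, x, pressure_pa, with_K=True):
        d, F, C = self.deformation(x)
        if C[:, 0, 0].max() > self.stretch_cap**2 or C[:, 1, 1].max() > self.stretch_cap**2:
            return None
        S, dSdC = self._stress(C, with_tangent=with_K)
        if not np.all(np.isfinite(S)):
            return None
        with np.errstate(over="ignore", invalid="ignore"):
            f_int = self.internal_forces(F, S)
            f_ext = self.external_forces(d, pressure_pa)
            R = f_int - f_ext
            scale = max(np.linalg.norm(f_int), np.linalg.norm(f_ext), 1e-12)
        if not with_K:
            return R, scale, None
        if not np.all(np.isfinite(dSdC)):
            return None

        G, w = self.G, self.w
        geo = np.einsum("e,eaP,ePQ,ebQ->eab", w, G, S, G, optimize=True)
        tmp = np.einsum("ePQRS,eiP->eiQRS", dSdC, F, optimize=True)
        tmp = np.einsum("eiQRS,ejR->eiQjS", tmp, F, optimize=True)
        K_el = 2.0 * np.einsum("e,eiQjS,eaQ,ebS->eaibj", w, tmp, G, G,
                               optimize=True)
        K_el += geo[:, :, None, :, None] * np.eye(3)[None, None, :, None, :]

        if pressure_pa != 0.0:
            # follower-load stiffness of f_a = (P/6) (e1 x e2), e1 = x2-x1
            def skew(v):
                m = np.zeros(v.shape[:-1] + (3, 3))
                m[..., 0, 1] = -v[..., 2]
                m[..., 0, 2] = v[..., 1]
                m[..., 1, 0] = v[..., 2]
                m[..., 1, 2] = -v[..., 0]
                m[..., 2, 0] = -v[..., 1]
                m[..., 2, 1] = v[..., 0]
                return m

            s1 = skew(d[:, :, 0])  # e1
            s2 = skew(d[:, :, 1])  # e2
            dfdx = np.stack([s2 - s1, -s2, s1], axis=1)  # (m, b, 3, 3)
            K_ext = (pressure_pa / 6.0) * dfdx[:, None, :, :, :]  # same for all a
            K_el = K_el - np.transpose(K_ext, (0, 1, 3, 2, 4))
        # K_el[e, a, i, b, j]: row dof edofs[e, 3a+i], col dof edofs[e, 3b+j]
        data = K_el.reshape(-1)
        K = sparse.coo_matrix(
            (data, (self.rows, self.cols)), shape=(self.ndof, self.ndof)
        ).tocsr()
        return R, scale, K


# ---------------------------------------------------------------------------


class _Constraints:
    """Dirichlet bookkeeping plus removal of the neutral y-translation.

    The quarter model fixes x on the x = 0 symmetry plane, z on the z = 0
    plane and prescribes z at the far end(s); a rigid translation along y
    remains an exact zero-energy, zero-load mode (net follower force along
    y vanishes identically on this geometry).  It is removed by pinning
    u_y of one far-end node on the theta = pi meridian: the constraint is
    consistent with a y-translated equilibrium, so its reaction is zero
    and no stress artifact is introduced (only the rigid representative
    of the solution is selected).
    """

    def __init__(self, mesh: SurfaceMesh, loads: LoadSchedule):
        n = mesh.n_nodes
        ndof = 3 * n
        self.fixed = np.zeros(ndof, dtype=bool)
        tags = mesh.node_tags
        self.fixed[3 * np.nonzero(tags["sym_yz"])[0] + 0] = True
        if tags["sym_xy"].any():
            self.fixed[3 * np.nonzero(tags["sym_xy"])[0] + 2] = True
        far = np.nonzero(tags["far_end"])[0]
        self.fixed[3 * far + 2] = True
        self.far_nodes = far
        # pin the y null mode at the far-end node with the lowest y
        pin = far[np.argmin(mesh.nodes[far, 1])]
        self.fixed[3 * pin + 1] = True
        self.pin_node = int(pin)
        self.free = ~self.fixed
        self.loads = loads
        self.mesh = mesh

    def displacement_template(self, stretch_factor: float) -> np.ndarray:
        """Full displacement vector (m) with prescribed entries filled for
        an axial stretch factor lambda; free entries zero."""
        u = np.zeros(3 * self.mesh.n_nodes)
        z_ref = self.mesh.nodes[self.far_nodes, 2] * 1e-3
        u[3 * self.far_nodes + 2] = (stretch_factor - 1.0) * z_ref
        return u


def _newton(asm: _Assembler, con: _Constraints, u: np.ndarray, pressure_pa: float,
            rtol: float = 1e-8, max_iter: int = 60):
    """Damped Newton with Levenberg fallback on the free dofs.

    Wrinkling-prone states make the tangent indefinite; when the line
    search collapses, a diagonal regularization mu * diag(K) is blended in
    and adapted, which lets the iteration walk through indefinite regions
    to the equilibrium point.  Returns (u, iters, residual) or None.
    """
    free = con.free
    X = asm.X.reshape(-1)
    mu = 0.0
    for it in range(max_iter):
        out = asm.residual((X + u).reshape(-1, 3), pressure_pa, with_K=True)
        if out is None:
            return None
        R, scale, K = out
        with np.errstate(over="ignore", invalid="ignore"):
            rnorm = float(np.linalg.norm(R[free]))
        if not (np.isfinite(rnorm) and np.isfinite(scale)):
            return None
        if rnorm <= rtol * scale + 1e-14:
            return u, it, rnorm / scale
        K_ff = K[free][:, free].tocsc()
        dia = np.abs(K_ff.diagonal())
        dia_floor = np.maximum(dia, dia.mean() * 1e-6)
        accepted = False
        for _ in range(8):
            K_try = K_ff if mu == 0.0 else K_ff + sparse.diags(mu * dia_floor)
            with np.errstate(invalid="ignore"):
                du = spsolve(K_try, -R[free])
            if np.all(np.isfinite(du)):
                # backtracking line search on the residual norm
                alpha = 1.0
                for _ in range(10):
                    u_try = u.copy()
                    u_try[free] += alpha * du
                    out2 = asm.residual(
                        (X + u_try).reshape(-1, 3), pressure_pa, with_K=False
                    )
                    if out2 is not None:
                        with np.errstate(over="ignore", invalid="ignore"):
                            r2 = float(np.linalg.norm(out2[0][free]))
                        if np.isfinite(r2) and np.isfinite(out2[1]) and (
                            r2 < rnorm * (1.0 - 1e-4 * alpha)
                            or r2 <= rtol * out2[1]
                        ):
                            accepted = True
                            break
                    alpha *= 0.5
            if accepted:
                break
            mu = 1e-4 if mu == 0.0 else mu * 10.0
            if mu > 1e6:
                return None
        if not accepted:
            return None
        u = u_try
        if alpha == 1.0:
            mu = 0.0 if mu < 1e-3 else mu / 30.0
    return None


def _minimize_prestretch(asm: _Assembler, con: _Constraints, u: np.ndarray):
    """Energy minimization of the pressure-free prestretch state.

    The P = 0 problem is conservative, so the wrinkly (indefinite) pouch
    states are handled far more robustly by quasi-Newton descent on the
    elastic energy than by root finding; the result seeds the Newton polish.
    """
    from scipy.optimize import minimize

    free = con.free
    X = asm.X.reshape(-1)
    u0 = u.copy()

    def fun(v):
        uu = u0.copy()
        uu[free] = v
        x = (X + uu).reshape(-1, 3)
        _, F, C = asm.deformation(x)
        if C[:, 0, 0].max() > asm.stretch_cap**2 or C[:, 1, 1].max() > asm.stretch_cap**2:
            return 1e30, np.zeros_like(v)
        try:
            e = asm.energy(x)
        except FloatingPointError:
            return 1e30, np.zeros_like(v)
        if not np.isfinite(e):
            return 1e30, np.zeros_like(v)
        S, _ = asm._stress(C, with_tangent=False)
        if not np.all(np.isfinite(S)):
            return 1e30, np.zeros_like(v)
        g = asm.internal_forces(F, S)
        return e, g[free]

    res = minimize(fun, u0[free], jac=True, method="L-BFGS-B",
                   options=dict(maxiter=2000, ftol=1e-16, gtol=1e-12))
    out = u0.copy()
    out[free] = res.x
    return out


def solve_sweep(
    mesh: SurfaceMesh,
    p: MaterialParams,
    loads: LoadSchedule = LoadSchedule(),
    stabilization: bool = True,
    stab_factor: float = 1e-3,
    tension_only: bool = False,
    rtol: float = 1e-8,
    max_bisect: int = 7,
    store_displacements: bool = False,
) -> PressureSweep:
    """Run the two-stage quasi-static inflation of one model.

    Stage 1 ramps the far-end axial displacement to the prescribed
    prestretch; stage 2 ramps the follower luminal pressure through the
    0.25 kPa grid of ``loads``.  Every grid level is solved to a relative
    residual of ``rtol``; a failing increment is bisected up to
    ``max_bisect`` times before the sweep is marked failed at the last
    converged level.
    """
    asm = _Assembler(mesh, p, stabilization=stabilization,
                     stab_factor=stab_factor, tension_only=tension_only)
    con = _Constraints(mesh, loads)
    sweep = PressureSweep(mesh=mesh, params=p, loads=loads)
    diag_rows = []

    free = con.free
    u = np.zeros(asm.ndof)
    lam = loads.axial_prestretch

    def attempt(u_start, stretch_frac, pressure_pa, affine_z=False,
                max_iter=60):
        factor = 1.0 + (lam - 1.0) * stretch_frac
        uu = con.displacement_template(factor)
        uu[free] = u_start[free]
        if affine_z:
            # homogeneous-stretch predictor for the axial component: avoids
            # overstretching the far-end element row on boundary jumps
            z_dofs = 3 * np.arange(mesh.n_nodes) + 2
            z_free = free[z_dofs]
            uu[z_dofs[z_free]] = (factor - 1.0) * asm.X[z_free, 2]
        return _newton(asm, con, uu, pressure_pa, rtol=rtol, max_iter=max_iter)

    def advance(u0, s0, p0, s1, p1, depth=0, affine_z=False,
                bisect_budget=None, max_iter=60):
        """Move from converged (s0, p0) to (s1, p1), bisecting on failure."""
        budget = max_bisect if bisect_budget is None else bisect_budget
        res = attempt(u0, s1, p1, affine_z=affine_z, max_iter=max_iter)
        if res is None:
            if depth >= budget:
                return None
            sm, pm = 0.5 * (s0 + s1), 0.5 * (p0 + p1)
            mid = advance(u0, s0, p0, sm, pm, depth + 1, affine_z,
                          bisect_budget, max_iter)
            if mid is None:
                return None
            u_mid, _, _ = mid
            return advance(u_mid, sm, pm, s1, p1, depth + 1, affine_z,
                           bisect_budget, max_iter)
        return res

    levels = loads.levels_kpa
    records: dict[float, tuple] = {}

    def record(level, u_state, its, rres):
        records[level] = (_extract_field(asm, u_state, level),
                          1e3 * u_state.reshape(-1, 3), its, rres)

    if levels[-1] == 0.0:
        # pure prestretch program
        s_prev, iters_pre = 0.0, 0
        for s in ([0.5, 1.0] if lam != 1.0 else [1.0]):
            res = advance(u, s_prev, 0.0, s, 0.0, affine_z=True)
            if res is None:
                # wrinkling-prone meshes: minimize the elastic energy from
                # the affine guess, then polish the minimizer by Newton
                factor = 1.0 + (lam - 1.0) * s
                uu = con.displacement_template(factor)
                uu[free] = u[free]
                z_dofs = 3 * np.arange(mesh.n_nodes) + 2
                z_free = free[z_dofs]
                uu[z_dofs[z_free]] = (factor - 1.0) * asm.X[z_free, 2]
                u_min = _minimize_prestretch(asm, con, uu)
                res = _newton(asm, con, u_min, 0.0, rtol=rtol)
            if res is None:
                sweep.converged = False
                sweep.failed_level = 0.0
                raise SweepFailure("prestretch stage failed to converge", sweep)
            u, its, rres = res
            iters_pre += its
            s_prev = s
        record(0.0, u, iters_pre, rres)
    else:
        # stage 1: joint prestretch/first-pressure continuation.  Loading a
        # hyperelastic model is path independent, so the solver may pick
        # any continuation that converges; keeping pressure on while
        # stretching keeps the pouch membrane tensioned (the P = 0 pouch
        # state has inextensional wrinkling modes).  Anchor candidates:
        # the first pressure level; then, for severely wrinkling cases,
        # the strongly tensioned final level, from which the grid is
        # walked downward.
        anchors = [levels[1]]
        if levels[-1] != levels[1]:
            anchors.append(levels[-1])
        u_anchor = None
        for anchor in anchors:
            Pa = anchor * 1e3
            res = advance(u, 0.0, 0.0, 1.0, Pa, affine_z=True)
            if res is None and anchor == levels[1]:
                # inflate at lambda_z = 1 first, then stretch under pressure
                res_a = advance(u, 0.0, 0.0, 0.0, Pa)
                if res_a is not None:
                    res = advance(res_a[0], 0.0, Pa, 1.0, Pa, affine_z=True)
            if res is not None:
                u_anchor, its, rres = res
                break
        if u_anchor is None:
            sweep.converged = False
            sweep.failed_level = levels[1]
            raise SweepFailure("prestretch stage failed to converge", sweep)
        record(anchor, u_anchor, its, rres)

        def walk(start_u, start_level, level_seq):
            """March the grid from a converged anchor state with a secant
            predictor, recording every converged level."""
            uu = start_u
            P_prev = start_level * 1e3
            hist = [(P_prev, uu.copy())]
            for level in level_seq:
                P = level * 1e3
                u_guess = uu
                if len(hist) >= 2 and hist[-1][0] != hist[-2][0]:
                    (pa_, ua), (pb_, ub) = hist[-2], hist[-1]
                    fac = (P - pb_) / (pb_ - pa_)
                    u_guess = ub.copy()
                    u_guess[free] = ub[free] + fac * (ub[free] - ua[free])
                res = advance(u_guess, 1.0, P_prev, 1.0, P)
                if res is None and u_guess is not uu:
                    res = advance(uu, 1.0, P_prev, 1.0, P)
                if res is None:
                    sweep.converged = False
                    sweep.failed_level = level
                    return None
                uu, its_, rres_ = res
                hist.append((P, uu.copy()))
                if len(hist) > 2:
                    hist.pop(0)
                record(level, uu, its_, rres_)
                P_prev = P
            return uu

        pos = [lv for lv in levels if lv > 0]
        idx = pos.index(anchor)
        u_low = walk(u_anchor, anchor, list(reversed(pos[:idx])))
        if sweep.converged:
            walk(u_anchor, anchor, pos[idx + 1:])

        # the pressure-free state: downward continuation from the lowest
        # positive level; a pouch membrane is degenerate at exactly P = 0
        # (wrinkling modes), in which case the level is skipped, not faked
        if sweep.converged and u_low is not None:
            res0 = advance(u_low, 1.0, pos[0] * 1e3, 1.0, 0.0,
                           bisect_budget=0, max_iter=20)
            if res0 is None:
                sweep.skipped_levels.append(
                    (0.0, "degenerate unloaded membrane state")
                )
            else:
                record(0.0, res0[0], res0[1], res0[2])

    for level in levels:
        if level not in records:
            continue
        fld, disp, its, rres = records[level]
        sweep.levels_kpa.append(level)
        sweep.fields.append(fld)
        if store_displacements:
            sweep.displacements.append(disp)
        diag_rows.append(dict(pressure_kPa=level, newton_iters=its,
                              rel_residual=rres))

    sweep.diagnostics = pd.DataFrame(diag_rows)
    return sweep


def _extract_field(asm: _Assembler, u: np.ndarray, level_kpa: float) -> StressField:
    x = (asm.X.reshape(-1) + u).reshape(-1, 3)
    d, F, C = asm.deformation(x)
    S, _ = asm._stress(C, with_tangent=False)

    # in-plane Cauchy stress in the deformed co-rotated fiber frame:
    # sigma = F2 S F2^T with F2 the 2x2 components of F in an orthonormal
    # basis of the deformed tangent plane (J = 1 by incompressibility)
    f1 = F[:, :, 0]
    f2 = F[:, :, 1]
    t1 = f1 / np.linalg.norm(f1, axis=1)[:, None]
    nrm = np.cross(f1, f2)
    n = nrm / np.linalg.norm(nrm, axis=1)[:, None]
    t2 = np.cross(n, t1)
    F2 = np.empty((F.shape[0], 2, 2))
    F2[:, 0, 0] = np.einsum("ij,ij->i", t1, f1)
    F2[:, 0, 1] = np.einsum("ij,ij->i", t1, f2)
    F2[:, 1, 0] = 0.0
    F2[:, 1, 1] = np.einsum("ij,ij->i", t2, f2)
    sig = np.einsum("eiP,ePQ,ejQ->eij", F2, S, F2)

    s11, s22, s12 = sig[:, 0, 0], sig[:, 1, 1], sig[:, 0, 1]
    mean = 0.5 * (s11 + s22)
    rad = np.sqrt(0.25 * (s11 - s22) ** 2 + s12**2)
    p1, p2 = mean + rad, mean - rad
    sigma_mps = np.maximum(p1, 0.0)
    von_mises = np.sqrt(p1**2 - p1 * p2 + p2**2)
    stretches = np.sqrt(np.stack([C[:, 0, 0], C[:, 1, 1]], axis=1))

    cent_ref = 1e3 * asm.X[asm.tris].mean(axis=1)
    cent_def = 1e3 * x[asm.tris].mean(axis=1)
    return StressField(
        level_kpa=level_kpa,
        stress=np.stack([s11, s22, s12], axis=1),
        sigma_mps=sigma_mps,
        von_mises=von_mises,
        stretches=stretches,
        centroid_ref=cent_ref,
        centroid_def=cent_def,
    )


def solve_sweep_robust(
    mesh: SurfaceMesh,
    p: MaterialParams,
    loads: LoadSchedule = LoadSchedule(),
    stab_ladder: tuple = (1e-3, 3e-3, 1e-2),
    **kwargs,
) -> PressureSweep:
    """Run a sweep, escalating the wrinkling-stabilization floor on failure.

    Materials whose fiber walls force a strong circumferential contraction
    under axial prestretch develop broad wrinkled zones on the pouch cap;
    a pure membrane then needs a slightly larger compression floor for the
    static solve to close.  The smallest floor that converges is used and
    reported on the sweep (``sweep.stab_factor``); the floor stress stays
    orders of magnitude below the reported peak stresses.
    """
    err = None
    for stab in stab_ladder:
        try:
            sweep = solve_sweep(mesh, p, loads, stab_factor=stab, **kwargs)
        except SweepFailure as exc:
            err = exc
            continue
        if sweep.converged:
            sweep.stab_factor = stab
            return sweep
        err = SweepFailure(f"failed at level {sweep.failed_level}", sweep)
    raise err


def rigid_body_check(mesh: SurfaceMesh, p: MaterialParams) -> bool:
    """Verify frame indifference of the discrete elastic energy.

    Rigid translations and rotations of the reference configuration must
    leave the energy at zero (relative to the energy of a genuine 10%
    axial stretch) to within 1e-10.
    """
    asm = _Assembler(mesh, p, stabilization=False)
    X = asm.X
    ang = math.radians(30.0)
    Q = np.array(
        [
            [math.cos(ang), -math.sin(ang), 0.0],
            [math.sin(ang), math.cos(ang), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    b = np.array([0.01, -0.02, 0.005])
    stretched = X.copy()
    stretched[:, 2] *= 1.1
    e_ref = asm.energy(stretched)
    motions = [X + b, X @ Q.T, (X @ Q.T) + b]
    return all(abs(asm.energy(x)) <= 1e-10 * e_ref for x in motions)


def mesh_convergence_study(
    model_builder,
    p: MaterialParams,
    loads: LoadSchedule = LoadSchedule(),
    tol_percent: float = 10.0,
    start_size: float = 1.3,
    size_floor: float = 0.1,
    **solve_kwargs,
):
    """Successive-halving mesh refinement until the peak stress settles.

    ``model_builder(mesh_size)`` must return a ready mesh.  Halving stops
    when the change of max sigma_MPS at the final load level between two
    successive meshes falls below ``tol_percent``; the chosen size is the
    coarser mesh of that converged pair.

    Returns ``(chosen_size, table)`` with the per-size peak stresses.
    """
    rows = []
    size = start_size
    prev_val = None
    while True:
        mesh = model_builder(size)
        sweep = solve_sweep(mesh, p, loads, **solve_kwargs)
        if not sweep.converged:
            raise SweepFailure(f"sweep failed at mesh size {size}", sweep)
        val = float(sweep.fields[-1].sigma_mps.max())
        var = np.nan if prev_val is None else abs(val - prev_val) / prev_val * 100.0
        rows.append(dict(mesh_size_mm=size, max_sigma_mps_Pa=val,
                         variation_percent=var))
        if prev_val is not None and var < tol_percent:
            chosen = 2.0 * size  # the coarser member of the converged pair
            return chosen, pd.DataFrame(rows)
        if size / 2.0 < size_floor:
            raise SweepFailure(
                "mesh convergence not reached before the size floor; table: "
                + pd.DataFrame(rows).to_string(),
            )
        prev_val = val
        size /= 2.0


def export_sweep_fields(sweep: PressureSweep, out_dir) -> list:
    """Write per-level VTK field files and a sweep summary table.

    Each recorded pressure level becomes ``fields_p<kPa>.vtk`` with
    sigma_MPS, von Mises and the local stress components as cell data
    (plus displacement as point data when the sweep stored it); the
    summary table ``sweep_summary.csv`` lists the peak stress and Newton
    iteration count per level.  Returns the written paths.
    """
    from pathlib import Path

    from .geometry_factory import write_vtk

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    disps = sweep.displacements if sweep.displacements else [None] * len(sweep.fields)
    for level, fld, disp in zip(sweep.levels_kpa, sweep.fields, disps):
        path = out / f"fields_p{level:g}.vtk"
        cell_data = dict(
            sigma_mps=fld.sigma_mps,
            von_mises=fld.von_mises,
            sigma_circ=fld.stress[:, 0],
            sigma_long=fld.stress[:, 1],
            sigma_shear=fld.stress[:, 2],
        )
        point_data = {"displacement_mm": disp} if disp is not None else None
        write_vtk(sweep.mesh, path, cell_data=cell_data, point_data=point_data)
        paths.append(path)
    summary = pd.DataFrame(
        dict(
            pressure_kPa=sweep.levels_kpa,
            max_sigma_mps_Pa=sweep.max_sigma_mps(),
            newton_iters=sweep.diagnostics.newton_iters.values,
        )
    )
    spath = out / "sweep_summary.csv"
    summary.to_csv(spath, index=False)
    paths.append(spath)
    return paths
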