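"""Anisotropic hyperelastic model of colon tissue.

The tissue is treated as an incompressible, fiber-reinforced hyperelastic
solid.  The strain-energy density combines a Neo-Hookean ground matrix with
two exponential collagen-fiber contributions::

    W = C10 (I1 - 3)
      + k1l/k2l [exp(k2l (I4l - 1)^2) - 1]
      + k1s/k2s [exp(k2s (I4s - 1)^2) - 1]

where ``I1`` is the first invariant of the (isochoric) deformation,
``I4l = lambda_z**2`` is the squared stretch along the longitudinal fiber
family and ``I4s = lambda_theta**2 cos^2(gamma) + lambda_z**2 sin^2(gamma)``
collapses the two symmetric fiber families inclined at ``+/- gamma`` from
the circumferential direction.  Incompressibility eliminates the radial
stretch, ``lambda_r = 1 / (lambda_theta lambda_z)``.

Under the thin-wall (plane-stress) condition the in-plane Cauchy stresses
follow from stretch derivatives of W:

    sigma_theta = lambda_theta dW/dlambda_theta
    sigma_z     = lambda_z     dW/dlambda_z

All stresses are in Pa; stretches are dimensionless; gamma is in degrees at
the API boundary and converted internally.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DomainError",
    "RangeOverflowError",
    "MaterialParams",
    "StretchState",
    "InvariantSet",
    "EnergyDerivatives",
    "load_material_params",
    "invariants",
    "strain_energy",
    "energy_derivatives",
    "isochoric_stresses",
    "membrane_cauchy",
    "membrane_stress_tangent",
]

# exp() overflows IEEE doubles just above exp(709); we refuse earlier so the
# failure is a clean range error instead of a silent inf propagating.
_EXP_ARG_MAX = 700.0


class DomainError(ValueError):
    """Input outside the physical domain (non-positive stretch, bad tensor)."""


class RangeOverflowError(OverflowError):
    """Fiber exponential overflowed at an extreme stretch."""


@dataclass(frozen=True)
class MaterialParams:
    """One set of constitutive constants.

    Parameters
    ----------
    c10 : float
        Ground-matrix (Neo-Hookean) modulus, Pa.
    k1_l, k2_l : float
        Stiffness (Pa) and dimensionless exponent of the longitudinal
        fiber family.
    k1_s, k2_s : float
        Stiffness (Pa) and exponent of the symmetric fiber families.
    gamma_s : float
        Fiber angle of the symmetric families from the circumferential
        direction, degrees, in [0, 90].
    label : str
        Free-text identifier, e.g. ``"#1"``.
    """

    c10: float
    k1_l: float
    k2_l: float
    k1_s: float
    k2_s: float
    gamma_s: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.c10 > 0:
            raise DomainError(f"c10 must be positive, got {self.c10}")
        if self.k1_l < 0 or self.k1_s < 0:
            raise DomainError("fiber stiffness k1 must be non-negative")
        if not (self.k2_l > 0 and self.k2_s > 0):
            raise DomainError("fiber exponents k2 must be positive")
        if not 0.0 <= self.gamma_s <= 90.0:
            raise DomainError(f"gamma_s must be in [0, 90] deg, got {self.gamma_s}")


@dataclass(frozen=True)
class StretchState:
    """Circumferential/axial stretch pair; the radial stretch is derived."""

    lambda_theta: float
    lambda_z: float

    def __post_init__(self) -> None:
        if not (self.lambda_theta > 0 and self.lambda_z > 0):
            raise DomainError(
                f"stretches must be positive, got "
                f"({self.lambda_theta}, {self.lambda_z})"
            )

    @property
    def lambda_r(self) -> float:
        """Radial stretch from incompressibility."""
        return 1.0 / (self.lambda_theta * self.lambda_z)


@dataclass(frozen=True)
class InvariantSet:
    i1: float
    i4_l: float
    i4_s: float


@dataclass(frozen=True)
class EnergyDerivatives:
    """First/second partials of W with respect to (I1, I4l, I4s).

    ``first`` is the length-3 gradient; ``second`` the symmetric 3x3 Hessian
    (the energy is additively separable, so it is diagonal).
    """

    first: np.ndarray
    second: np.ndarray


def load_material_params(path=None) -> list[MaterialParams]:
    """Load constitutive parameter sets from a key/value text file.

    Without ``path`` the five packaged swine descending-colon sets are
    returned, in order #1..#5.
    """
    if path is None:
        ref = importlib.resources.files("colomech.data") / "material_params.txt"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()

    blocks: list[dict] = []
    current: dict = {}
    for raw in text.splitlines():
        if raw.lstrip().startswith("#"):
            continue
        line = raw.strip()
        if not line:
            if current:
                blocks.append(current)
                current = {}
            continue
        key, _, value = line.partition("=")
        current[key.strip()] = value.strip()
    if current:
        blocks.append(current)

    out = []
    for b in blocks:
        out.append(
            MaterialParams(
                c10=float(b["C10_Pa"]),
                k1_l=float(b["k1l_Pa"]),
                k2_l=float(b["k2l"]),
                k1_s=float(b["k1s_Pa"]),
                k2_s=float(b["k2s"]),
                gamma_s=float(b["gamma_deg"]),
                label=b.get("label", ""),
            )
        )
    return out


def invariants(state: StretchState, gamma_s: float) -> InvariantSet:
    """Deformation invariants (I1, I4l, I4s) of a biaxial stretch state.

    ``gamma_s`` is the symmetric-family fiber angle in degrees.
    """
    lt2 = state.lambda_theta**2
    lz2 = state.lambda_z**2
    g = math.radians(gamma_s)
    i1 = lt2 + lz2 + 1.0 / (lt2 * lz2)
    i4s = lt2 * math.cos(g) ** 2 + lz2 * math.sin(g) ** 2
    return InvariantSet(i1=i1, i4_l=lz2, i4_s=i4s)


def _fiber_energy(k1: float, k2: float, i4: float) -> float:
    # k1 = 0 evaluates the term as exactly 0 regardless of k2 (limit convention)
    if k1 == 0.0:
        return 0.0
    arg = k2 * (i4 - 1.0) ** 2
    if arg > _EXP_ARG_MAX:
        raise RangeOverflowError(
            f"fiber exponential overflow: k2 (I4-1)^2 = {arg:.3g}"
        )
    return k1 / k2 * math.expm1(arg)


def _fiber_psi(k1: float, k2: float, i4: float) -> float:
    """dW/dI4 of one fiber term."""
    if k1 == 0.0:
        return 0.0
    x = i4 - 1.0
    arg = k2 * x * x
    if arg > _EXP_ARG_MAX:
        raise RangeOverflowError(
            f"fiber exponential overflow: k2 (I4-1)^2 = {arg:.3g}"
        )
    return 2.0 * k1 * x * math.exp(arg)


def _fiber_psi_prime(k1: float, k2: float, i4: float) -> float:
    """d2W/dI4^2 of one fiber term."""
    if k1 == 0.0:
        return 0.0
    x = i4 - 1.0
    arg = k2 * x * x
    if arg > _EXP_ARG_MAX:
        raise RangeOverflowError(
            f"fiber exponential overflow: k2 (I4-1)^2 = {arg:.3g}"
        )
    return 2.0 * k1 * math.exp(arg) * (1.0 + 2.0 * k2 * x * x)


def strain_energy(p: MaterialParams, state: StretchState) -> float:
    """Strain-energy density W (Pa) at a biaxial stretch state."""
    inv = invariants(state, p.gamma_s)
    w = (
        p.c10 * (inv.i1 - 3.0)
        + _fiber_energy(p.k1_l, p.k2_l, inv.i4_l)
        + _fiber_energy(p.k1_s, p.k2_s, inv.i4_s)
    )
    if not math.isfinite(w):
        raise RangeOverflowError("strain energy overflowed")
    return w


def energy_derivatives(p: MaterialParams, inv: InvariantSet) -> EnergyDerivatives:
    """First and second partials of W w.r.t. (I1, I4l, I4s).

    dW/dI1 is the constant C10; the fiber first derivatives vanish at
    I4 = 1; the Hessian is diagonal because the energy is additively
    separable in the invariants.
    """
    first = np.array(
        [
            p.c10,
            _fiber_psi(p.k1_l, p.k2_l, inv.i4_l),
            _fiber_psi(p.k1_s, p.k2_s, inv.i4_s),
        ]
    )
    second = np.diag(
        [
            0.0,
            _fiber_psi_prime(p.k1_l, p.k2_l, inv.i4_l),
            _fiber_psi_prime(p.k1_s, p.k2_s, inv.i4_s),
        ]
    )
    return EnergyDerivatives(first=first, second=second)


def isochoric_stresses(p: MaterialParams, state: StretchState) -> tuple[float, float]:
    """In-plane Cauchy stresses (sigma_theta, sigma_z) in Pa.

    Computed as lambda dW/dlambda by the chain rule through the invariants;
    with the radial stretch eliminated by incompressibility this equals the
    physical in-plane Cauchy stress under the thin-wall condition
    sigma_r = 0.
    """
    inv = invariants(state, p.gamma_s)
    d = energy_derivatives(p, inv)
    lt2 = state.lambda_theta**2
    lz2 = state.lambda_z**2
    lr2 = state.lambda_r**2
    g = math.radians(p.gamma_s)
    cg2, sg2 = math.cos(g) ** 2, math.sin(g) ** 2
    # lambda_theta * dI1/dlambda_theta = 2 (lt^2 - lr^2), etc.
    sig_t = 2.0 * d.first[0] * (lt2 - lr2) + 2.0 * d.first[2] * lt2 * cg2
    sig_z = (
        2.0 * d.first[0] * (lz2 - lr2)
        + 2.0 * d.first[1] * lz2
        + 2.0 * d.first[2] * lz2 * sg2
    )
    return sig_t, sig_z


# ---------------------------------------------------------------------------
# Plane-stress membrane condensation
#
# The membrane solver works with the 2x2 right Cauchy-Green tensor C of the
# midsurface expressed in the local fiber frame (index 0 = circumferential,
# index 1 = longitudinal).  Incompressibility fixes the thickness stretch,
# lambda_t^2 = 1/det(C), and the through-thickness Cauchy stress is zero by
# the plane-stress condensation, which eliminates the hydrostatic pressure.
# The resulting 2nd Piola-Kirchhoff stress is
#
#   S = 2 C10 (I - C^-1/det C) + 2 psi_l Hl + 2 psi_s Hs
#
# with structure tensors Hl = diag(0, 1) and
# Hs = diag(cos^2 gamma, sin^2 gamma).
# ---------------------------------------------------------------------------


def membrane_stress_tangent(
    p: MaterialParams,
    C: np.ndarray,
    tension_only: bool = False,
    with_tangent: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Vectorized plane-stress 2nd PK stress and tangent in the fiber frame.

    Parameters
    ----------
    C : (..., 2, 2) array
        Right Cauchy-Green tensor(s) of the midsurface in the local frame
        (circumferential, longitudinal).
    tension_only : bool
        If True, fiber terms are disabled where I4 < 1.
    with_tangent : bool
        Also return dS/dC as a (..., 2, 2, 2, 2) array.

    Returns
    -------
    S : (..., 2, 2)
    dSdC : (..., 2, 2, 2, 2) or None

    Notes
    -----
    This is the batch evaluation path used by the finite-element solver; it
    does not raise on overflow but lets non-finite values propagate so the
    solver can reject the trial state.  Scalar user-facing evaluation with
    error reporting goes through :func:`membrane_cauchy`.
    """
    C = np.asarray(C, dtype=float)
    detC = C[..., 0, 0] * C[..., 1, 1] - C[..., 0, 1] * C[..., 1, 0]
    inv_det = 1.0 / detC
    Ci = np.empty_like(C)
    Ci[..., 0, 0] = C[..., 1, 1] * inv_det
    Ci[..., 1, 1] = C[..., 0, 0] * inv_det
    Ci[..., 0, 1] = -C[..., 0, 1] * inv_det
    Ci[..., 1, 0] = -C[..., 1, 0] * inv_det

    g = math.radians(p.gamma_s)
    cg2, sg2 = math.cos(g) ** 2, math.sin(g) ** 2
    i4l = C[..., 1, 1]
    i4s = cg2 * C[..., 0, 0] + sg2 * C[..., 1, 1]

    with np.errstate(over="ignore", invalid="ignore"):
        xl = i4l - 1.0
        xs = i4s - 1.0
        el = np.exp(np.minimum(p.k2_l * xl * xl, _EXP_ARG_MAX + 10.0))
        es = np.exp(np.minimum(p.k2_s * xs * xs, _EXP_ARG_MAX + 10.0))
        psi_l = 2.0 * p.k1_l * xl * el
        psi_s = 2.0 * p.k1_s * xs * es
        dpsi_l = 2.0 * p.k1_l * el * (1.0 + 2.0 * p.k2_l * xl * xl)
        dpsi_s = 2.0 * p.k1_s * es * (1.0 + 2.0 * p.k2_s * xs * xs)
    if tension_only:
        off_l = xl < 0.0
        off_s = xs < 0.0
        psi_l = np.where(off_l, 0.0, psi_l)
        dpsi_l = np.where(off_l, 0.0, dpsi_l)
        psi_s = np.where(off_s, 0.0, psi_s)
        dpsi_s = np.where(off_s, 0.0, dpsi_s)

    eye = np.zeros_like(C)
    eye[..., 0, 0] = 1.0
    eye[..., 1, 1] = 1.0
    with np.errstate(over="ignore", invalid="ignore"):
        S = 2.0 * p.c10 * (eye - Ci * inv_det[..., None, None])
        S[..., 0, 0] += 2.0 * psi_s * cg2
        S[..., 1, 1] += 2.0 * psi_l + 2.0 * psi_s * sg2

    if not with_tangent:
        return S, None

    # dS/dC, symmetric in (PQ), (RS) and under major exchange:
    #   2 C10 / detC [ Ci_PQ Ci_RS + (Ci_PR Ci_QS + Ci_PS Ci_QR)/2 ]
    # + 2 dpsi_l Hl x Hl + 2 dpsi_s Hs x Hs
    with np.errstate(over="ignore", invalid="ignore"):
        CiCi = np.einsum("...pq,...rs->...pqrs", Ci, Ci)
        CiCi_sym = 0.5 * (
            np.einsum("...pr,...qs->...pqrs", Ci, Ci)
            + np.einsum("...ps,...qr->...pqrs", Ci, Ci)
        )
        dSdC = (2.0 * p.c10 * inv_det)[..., None, None, None, None] * (
            CiCi + CiCi_sym
        )
        Hl = np.array([[0.0, 0.0], [0.0, 1.0]])
        Hs = np.array([[cg2, 0.0], [0.0, sg2]])
        dSdC = dSdC + 2.0 * dpsi_l[..., None, None, None, None] * np.einsum(
            "pq,rs->pqrs", Hl, Hl
        )
        dSdC = dSdC + 2.0 * dpsi_s[..., None, None, None, None] * np.einsum(
            "pq,rs->pqrs", Hs, Hs
        )
    return S, dSdC


def membrane_cauchy(
    p: MaterialParams,
    surface_stretch: np.ndarray,
    fiber_axes: np.ndarray | None = None,
    tension_only: bool = False,
) -> np.ndarray:
    """In-plane Cauchy stress of a membrane surface stretch state.

    Parameters
    ----------
    surface_stretch : (2, 2) array
        Symmetric positive-definite right stretch tensor of the midsurface.
        Its components are interpreted in a working frame; by default that
        frame IS the fiber frame (axis 0 circumferential, axis 1
        longitudinal).
    fiber_axes : (2, 2) array, optional
        Columns give the circumferential and longitudinal fiber directions
        in the working frame, for evaluating a rotated state.

    Returns
    -------
    (2, 2) Cauchy stress in the working frame.  The through-thickness
    stress is identically zero by construction (plane-stress condensation
    with the thickness stretch fixed by incompressibility).
    """
    U = np.asarray(surface_stretch, dtype=float)
    if U.shape != (2, 2):
        raise DomainError(f"surface stretch must be 2x2, got {U.shape}")
    if not np.allclose(U, U.T, rtol=0.0, atol=1e-10 * max(1.0, abs(U).max())):
        raise DomainError("surface stretch must be symmetric")
    w = np.linalg.eigvalsh(U)
    if w.min() <= 0.0:
        raise DomainError("surface stretch must be positive-definite")

    Q = np.eye(2) if fiber_axes is None else np.asarray(fiber_axes, dtype=float)
    C_work = U @ U
    C_fib = Q.T @ C_work @ Q
    S_fib, _ = membrane_stress_tangent(
        p, C_fib, tension_only=tension_only, with_tangent=False
    )
    if not np.all(np.isfinite(S_fib)):
        raise RangeOverflowError("fiber exponential overflow in membrane stress")
    S_work = Q @ S_fib @ Q.T
    # incompressible: J = 1, so sigma = F S F^T with F = U (pure stretch)
    return U @ S_work @ U
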