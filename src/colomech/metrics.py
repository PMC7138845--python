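"""Derived stress metrics of the pouch study.

Aggregation of peak max-principal stresses over models and material
parameter sets, normalization against the normal colon, the pressure
factor (percent luminal-pressure reduction needed to bring a diseased
model's peak stress back to the normal level), the zone of influence of a
pouch along the longitudinal and circumferential lumen paths, and Pearson
correlations of stress/zone metrics with the pouch geometry descriptors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constitutive import DomainError
from .geometry_factory import PouchMetrics, SurfaceMesh

__all__ = [
    "StudySummary",
    "PressureFactorResult",
    "ZoneOfInfluence",
    "CorrelationResult",
    "max_principal",
    "von_mises",
    "aggregate_study",
    "pressure_factor",
    "path_profiles",
    "influence_distance",
    "zone_of_influence",
    "correlate_geometry",
]


def max_principal(sigma: np.ndarray) -> float:
    """Max principal stress of a 2x2 symmetric membrane stress tensor.

    The zero through-thickness principal value of the plane-stress state
    participates: the result is max(in-plane eigenvalues, 0).
    """
    s = np.asarray(sigma, dtype=float)
    if s.shape != (2, 2):
        raise DomainError(f"expected a 2x2 tensor, got {s.shape}")
    scale = max(abs(s).max(), 1.0)
    if abs(s[0, 1] - s[1, 0]) > 1e-9 * scale:
        raise DomainError("stress tensor must be symmetric")
    ev = np.linalg.eigvalsh(0.5 * (s + s.T))
    return float(max(ev.max(), 0.0))


def von_mises(sigma: np.ndarray) -> float:
    """Plane-stress von Mises stress sqrt(s1^2 - s1 s2 + s2^2)."""
    s = np.asarray(sigma, dtype=float)
    if s.shape != (2, 2):
        raise DomainError(f"expected a 2x2 tensor, got {s.shape}")
    scale = max(abs(s).max(), 1.0)
    if abs(s[0, 1] - s[1, 0]) > 1e-9 * scale:
        raise DomainError("stress tensor must be symmetric")
    s1, s2 = np.linalg.eigvalsh(0.5 * (s + s.T))
    return float(math.sqrt(s1 * s1 - s1 * s2 + s2 * s2))


# ---------------------------------------------------------------------------


@dataclass
class StudySummary:
    """Aggregated peak stresses of the full study.

    ``sigma_max``: peak sigma_MPS (Pa) per (model, parameter set) and
    pressure; ``sigma_avg``: its mean over the parameter sets;
    ``normalized``: diseased sigma_avg divided by the normal model's value
    at the same pressure.
    """

    pressures_kpa: np.ndarray
    sigma_max: pd.DataFrame
    sigma_avg: pd.DataFrame
    normalized: pd.DataFrame
    normal_label: str = "normal"


def aggregate_study(
    curves: dict[tuple[str, str], np.ndarray],
    pressures_kpa: np.ndarray,
    normal_label: str = "normal",
) -> StudySummary:
    """Aggregate per-case peak-stress curves into the study summary.

    ``curves`` maps (model label, parameter-set label) to the peak
    sigma_MPS curve sampled on ``pressures_kpa``.
    """
    models = sorted({m for m, _ in curves}, key=lambda m: (m == normal_label, m))
    if normal_label not in {m for m, _ in curves}:
        raise DomainError("missing normal-model reference curves")
    sigma_max = pd.DataFrame(
        {key: np.asarray(val, dtype=float) for key, val in sorted(curves.items())},
        index=pd.Index(pressures_kpa, name="pressure_kPa"),
    )
    sigma_max.columns = pd.MultiIndex.from_tuples(
        sigma_max.columns, names=["model", "set"]
    )
    sigma_avg = sigma_max.T.groupby(level="model").mean().T
    diseased = [m for m in models if m != normal_label]
    normal = sigma_avg[normal_label]
    normalized = sigma_avg[diseased].div(normal, axis=0)
    return StudySummary(
        pressures_kpa=np.asarray(pressures_kpa, dtype=float),
        sigma_max=sigma_max,
        sigma_avg=sigma_avg,
        normalized=normalized,
        normal_label=normal_label,
    )


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PressureFactorResult:
    p_n: float
    p_d: float
    factor_percent: float


def pressure_factor(
    diseased_curve: np.ndarray,
    normal_curve: np.ndarray,
    p_n: float,
    pressures_kpa: np.ndarray,
) -> PressureFactorResult:
    """Pressure reduction restoring normal peak stress.

    ``P_d`` is the largest grid pressure <= ``p_n`` with
    diseased(P_d) <= normal(p_n) (the grid search decrements by one grid
    step at a time); the factor is (P_n - P_d)/P_n * 100.  Ties resolve
    toward the larger ``P_d`` (smallest factor satisfying the bound).
    """
    pr = np.asarray(pressures_kpa, dtype=float)
    d = np.asarray(diseased_curve, dtype=float)
    n = np.asarray(normal_curve, dtype=float)
    if d.shape != pr.shape or n.shape != pr.shape:
        raise DomainError("curves must share the pressure grid")
    i_n = np.nonzero(np.isclose(pr, p_n))[0]
    if i_n.size == 0:
        raise DomainError(f"P_n = {p_n} kPa is not on the pressure grid")
    target = n[i_n[0]]
    if np.isnan(target):
        raise DomainError("normal curve undefined at P_n")
    for i in range(i_n[0], -1, -1):
        if not np.isnan(d[i]) and d[i] <= target:
            p_d = pr[i]
            return PressureFactorResult(
                p_n=p_n, p_d=p_d, factor_percent=(p_n - p_d) / p_n * 100.0
            )
    raise DomainError(
        f"no grid pressure satisfies the bound at P_n = {p_n} kPa "
        "(factor would exceed 100%)"
    )


# ---------------------------------------------------------------------------


@dataclass
class ZoneOfInfluence:
    """Zone-of-influence distances (mm) of one diseased case at one level."""

    d_l_inf: float
    d_c_inf: float
    profile_l: pd.DataFrame = field(repr=False, default=None)
    profile_c: pd.DataFrame = field(repr=False, default=None)


def path_profiles(mesh: SurfaceMesh, sigma_mps: np.ndarray):
    """Max-principal-stress profiles along the two lumen paths.

    Longitudinal path: grid-cell column adjacent to the x = 0 meridian
    through the pouch center; circumferential path: cell row adjacent to
    the z = 0 hoop.  Distances are reference arc lengths from the pouch
    center, accumulated along the path centroids.  One sample per grid
    cell (the two triangles of a quad are averaged).
    """
    if mesh.cell_ij is None:
        raise DomainError("mesh lacks structured cell indices")
    cent = mesh.nodes[mesh.tris].mean(axis=1)
    apex = mesh.meta.get("apex")

    def profile(axis: int):
        sel = mesh.cell_ij[:, 1 - axis] == 0
        if not np.any(sel):
            raise DomainError("empty path")
        cells = mesh.cell_ij[sel, axis]
        vals = sigma_mps[sel]
        pts = cent[sel]
        order = np.unique(cells)
        sig, xyz = [], []
        for c in order:
            m = cells == c
            sig.append(vals[m].mean())
            xyz.append(pts[m].mean(axis=0))
        xyz = np.array(xyz)
        seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        d0 = np.linalg.norm(xyz[0] - apex)
        d = np.concatenate([[d0], d0 + np.cumsum(seg)])
        return pd.DataFrame({"distance_mm": d, "sigma_mps_Pa": np.array(sig)})

    # axis 1 = axial cell index varies -> longitudinal path (theta column 0)
    return profile(1), profile(0)


def influence_distance(d, sig, sig_ref, threshold=0.10, two_sided=True):
    """Farthest path distance at which ``sig`` deviates from ``sig_ref``
    by more than ``threshold`` (relative), interpolated between samples.

    ``two_sided=False`` counts only elevation above the reference.
    Returns 0 when the whole profile stays inside the band.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        if two_sided:
            out = np.abs(sig - sig_ref) > threshold * sig_ref
        else:
            out = sig - sig_ref > threshold * sig_ref
    if not np.any(out):
        return 0.0
    i = np.max(np.nonzero(out)[0])
    if i == len(d) - 1:
        return float(d[i])
    # linear interpolation of the band crossing between samples i and i+1
    def excess(j):
        dev = abs(sig[j] - sig_ref[j]) if two_sided else sig[j] - sig_ref[j]
        return dev - threshold * sig_ref[j]

    g0, g1 = excess(i), excess(i + 1)
    t = g0 / (g0 - g1) if g0 != g1 else 0.0
    return float(d[i] + t * (d[i + 1] - d[i]))


def zone_of_influence(
    field_mesh: SurfaceMesh,
    sigma_mps: np.ndarray,
    normal_mesh: SurfaceMesh,
    normal_sigma_mps: np.ndarray,
    threshold: float = 0.10,
    two_sided: bool = True,
) -> ZoneOfInfluence:
    """Farthest distance from the pouch center at which stress still
    deviates from the normal model by more than ``threshold``.

    The normal model's profile along the same path (position-wise, linearly
    interpolated at the diseased path's distances) is the reference; the
    band crossing is located by linear interpolation between adjacent
    samples.  Returns 0 where the whole profile stays inside the band.
    """
    prof_l, prof_c = path_profiles(field_mesh, sigma_mps)
    ref_l, ref_c = path_profiles(normal_mesh, normal_sigma_mps)

    out = []
    for prof, ref in ((prof_l, ref_l), (prof_c, ref_c)):
        sig_ref = np.interp(
            prof.distance_mm.values, ref.distance_mm.values, ref.sigma_mps_Pa.values
        )
        prof["sigma_normal_Pa"] = sig_ref
        out.append(
            influence_distance(
                prof.distance_mm.values,
                prof.sigma_mps_Pa.values,
                sig_ref,
                threshold,
                two_sided,
            )
        )
    return ZoneOfInfluence(
        d_l_inf=out[0], d_c_inf=out[1], profile_l=prof_l, profile_c=prof_c
    )


# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    predictor: str
    r2_per_pressure: pd.Series
    r2_average: float
    p_max: float


def correlate_geometry(
    responses: pd.DataFrame,
    pouch_metrics: dict[str, PouchMetrics],
) -> dict[str, CorrelationResult]:
    """Pearson correlation of a per-model response against pouch geometry.

    ``responses``: rows = pressure levels, columns = diseased model labels.
    For each of the four descriptors (d_x, d_z, a_b, s_p) the squared
    Pearson coefficient is computed at every pressure, averaged over
    pressures, and the largest two-tailed p-value (exact t transform,
    n - 2 degrees of freedom) is reported.
    """
    models = list(responses.columns)
    out = {}
    for name in ("d_x", "d_z", "a_b", "s_p"):
        x = np.array([getattr(pouch_metrics[m], name) for m in models])
        if np.allclose(x, x[0]):
            raise DomainError(f"zero variance in predictor {name}")
        r2s, ps = [], []
        for _, row in responses.iterrows():
            y = row.values.astype(float)
            if np.allclose(y, y[0]):
                raise DomainError("zero variance in response")
            r, pval = stats.pearsonr(x, y)
            r2s.append(r * r)
            ps.append(pval)
        r2_series = pd.Series(r2s, index=responses.index)
        out[name] = CorrelationResult(
            predictor=name,
            r2_per_pressure=r2_series,
            r2_average=float(r2_series.mean()),
            p_max=float(max(ps)),
        )
    return out
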