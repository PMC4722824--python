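"""Reflectance-spectrum processing and the avian tetrahedral color space.

Spectra are smoothed with LOESS (local quadratic regression, tricube
weights, default span 0.25).  Hue is extracted as the wavelength of peak
reflectance independently in a UV/blue window (300-500 nm) and a long-wave
window (beyond 600 nm).  Relative quantum catches of an idealized
tetrachromat place each spectrum in the tetrahedral color space whose
achromatic center sits at the origin and whose four unit-stimulation
vertices are 0.75 from it; color volumes are 3-D convex hulls and their
overlap is an exact half-space intersection (Monte-Carlo fallback).

Quantum catches integrate reflectance over 300-700 nm only: reflectance
beyond 700 nm contributes to hue extraction but lies outside the visual
integration range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

logger = logging.getLogger(__name__)

__all__ = [
    "ReflectanceSpectrum",
    "VisualModel",
    "ColorPoint",
    "VolumeOverlapResult",
    "smooth_spectrum",
    "hue_peaks",
    "quantum_catches",
    "tetra_point",
    "color_volume_overlap",
    "default_visual_model",
    "TETRA_VERTICES",
]

#: vertex coordinates of the u, s, m, l unit-stimulation points (rows), at
#: distance 0.75 from the achromatic origin
TETRA_VERTICES = np.array(
    [
        [0.0, 0.0, 0.75],  # u
        [-0.5 * np.sqrt(1.5), -1.0 / (2.0 * np.sqrt(2.0)), -0.25],  # s
        [0.0, np.sqrt(2.0) / 2.0, -0.25],  # m
        [0.5 * np.sqrt(1.5), -1.0 / (2.0 * np.sqrt(2.0)), -0.25],  # l
    ]
)


@dataclass
class ReflectanceSpectrum:
    """A reflectance spectrum on a strictly ascending wavelength grid (nm)."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelengths and reflectance must be equal-length 1-D")
        if not (np.diff(self.wavelengths) > 0).all():
            raise ValueError("wavelength grid must be strictly ascending")
        if not np.isfinite(self.reflectance).all():
            raise ValueError("reflectance must be finite")


@dataclass
class VisualModel:
    """Four cone sensitivity curves plus an illuminant on a common grid.

    Sensitivities are normalized to integrate to 1 over the grid.
    """

    wavelengths: np.ndarray
    sensitivities: np.ndarray  # (4, n) rows u, s, m, l
    illuminant: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        self.illuminant = np.asarray(self.illuminant, dtype=float)
        if self.sensitivities.shape != (4, self.wavelengths.size):
            raise ValueError("need 4 sensitivity rows on the wavelength grid")
        if (self.sensitivities < 0).any():
            raise ValueError("cone sensitivities must be nonnegative")
        areas = np.trapezoid(self.sensitivities, self.wavelengths, axis=1)
        if (areas <= 0).any():
            raise ValueError("each sensitivity curve must have positive area")
        self.sensitivities = self.sensitivities / areas[:, None]


def default_visual_model(
    lo: float = 300.0, hi: float = 700.0, step: float = 1.0
) -> VisualModel:
    """Idealized tetrachromat: Gaussian cones peaking at 372, 456, 544 and
    609 nm (SD 40 nm) under a flat illuminant."""
    wl = np.arange(lo, hi + step / 2, step)
    peaks = [372.0, 456.0, 544.0, 609.0]
    sens = np.array([np.exp(-0.5 * ((wl - p) / 40.0) ** 2) for p in peaks])
    return VisualModel(wl, sens, np.ones_like(wl))


@dataclass
class ColorPoint:
    usml: np.ndarray
    xyz: np.ndarray
    h_theta: float
    h_phi: float
    r_vec: float
    r_max: float
    r_achieved: float
    label: str = ""


@dataclass
class VolumeOverlapResult:
    vol_a: float
    vol_b: float
    vol_intersection: float
    overlap_vs_smaller: float
    overlap_vs_union: float
    method: str = "exact"


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def smooth_spectrum(spec: ReflectanceSpectrum, span: float = 0.25,
                    clip_negative: bool = True) -> ReflectanceSpectrum:
    """LOESS smoothing (local quadratic, tricube weights) evaluated on the
    input grid.

    ``span`` is the fraction of points in each local window; windows of
    fewer than 5 points cannot support a quadratic fit and raise.  Negative
    smoothed reflectance is clipped to 0 with a logged count.
    """
    x = spec.wavelengths
    y = spec.reflectance
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 points to smooth")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    k = max(int(np.ceil(span * n)), 2)
    if k < 5:
        raise ValueError(
            f"span {span} gives windows of {k} points; minimum span is "
            f"{5.0 / n:.3f} for a local quadratic fit"
        )
    out = np.empty(n)
    half = k // 2
    for i in range(n):
        loidx = max(0, min(i - half, n - k))
        idx = slice(loidx, loidx + k)
        xi = x[idx]
        yi = y[idx]
        d = np.abs(xi - x[i])
        dmax = d.max()
        if dmax == 0:
            out[i] = yi.mean()
            continue
        w = (1.0 - np.minimum(d / dmax, 1.0) ** 3) ** 3
        w = np.maximum(w, 1e-12)
        X = np.vstack([np.ones_like(xi), xi - x[i], (xi - x[i]) ** 2]).T
        WX = X * w[:, None]
        coef, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ yi, rcond=None)
        out[i] = coef[0]
    if clip_negative:
        neg = int((out < 0).sum())
        if neg:
            logger.info("clipped %d negative smoothed reflectance values", neg)
        out = np.maximum(out, 0.0)
    return ReflectanceSpectrum(x.copy(), out, label=spec.label)


# ---------------------------------------------------------------------------
# hue
# ---------------------------------------------------------------------------


def hue_peaks(
    spec: ReflectanceSpectrum,
    windows: tuple[tuple[float, float], ...] = ((300.0, 500.0), (600.0, None)),
) -> list[dict]:
    """Wavelength of maximum reflectance inside each window.

    ``None`` as an upper bound means the end of the grid.  A maximum landing
    on a window boundary is flagged ``boundary=True`` (not a genuine peak).
    Windows outside the grid raise.
    """
    x = spec.wavelengths
    y = spec.reflectance
    results = []
    for lo, hi in windows:
        hi_eff = x[-1] if hi is None else hi
        if lo < x[0] - 1e-9 or hi_eff > x[-1] + 1e-9 or lo >= hi_eff:
            raise ValueError(f"window ({lo}, {hi}) outside the grid "
                             f"[{x[0]}, {x[-1]}]")
        mask = (x >= lo) & (x <= hi_eff)
        xi = x[mask]
        yi = y[mask]
        j = int(np.argmax(yi))
        results.append({
            "window": (float(lo), float(hi_eff)),
            "peak_nm": float(xi[j]),
            "reflectance": float(yi[j]),
            "boundary": bool(j == 0 or j == xi.size - 1),
        })
    return results


# ---------------------------------------------------------------------------
# tetrahedral color space
# ---------------------------------------------------------------------------


def quantum_catches(spec: ReflectanceSpectrum, vm: VisualModel) -> np.ndarray:
    """Relative quantum catches: ``Q_i = integral R(l) I(l) S_i(l) dl``
    (trapezoid) over the visual model's grid, normalized to sum 1."""
    r = np.interp(vm.wavelengths, spec.wavelengths, spec.reflectance)
    q = np.trapezoid(r * vm.illuminant * vm.sensitivities, vm.wavelengths, axis=1)
    total = q.sum()
    if total <= 0:
        raise ValueError("zero total quantum catch (black spectrum)")
    return q / total


def usml_to_xyz(usml: np.ndarray) -> np.ndarray:
    """Linear map from the catch simplex to tetrahedral coordinates."""
    return usml @ TETRA_VERTICES


def xyz_to_usml(xyz: np.ndarray) -> np.ndarray:
    """Inverse of :func:`usml_to_xyz` (barycentric coordinates)."""
    A = np.vstack([TETRA_VERTICES.T, np.ones(4)])
    b = np.concatenate([np.atleast_1d(np.asarray(xyz, dtype=float)), [1.0]])
    return np.linalg.solve(A, b)


def _r_max(direction: np.ndarray) -> float:
    """Distance from the origin to the tetrahedron boundary along a unit
    direction (exact ray-face intersection)."""
    # faces: each omits one vertex; plane through the other three
    t_best = np.inf
    for omit in range(4):
        tri = TETRA_VERTICES[[i for i in range(4) if i != omit]]
        normal = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        denom = normal @ direction
        if abs(denom) < 1e-14:
            continue
        t = (normal @ tri[0]) / denom
        if t > 1e-12:
            point = t * direction
            if _inside_tetra(point, tol=1e-9):
                t_best = min(t_best, t)
    if not np.isfinite(t_best):  # pragma: no cover - degenerate direction
        raise RuntimeError("ray-face intersection failed")
    return float(t_best)


def _inside_tetra(p: np.ndarray, tol: float = 1e-9) -> bool:
    bary = xyz_to_usml(p)
    return bool((bary >= -tol).all())


def tetra_point(usml, label: str = "") -> ColorPoint:
    """Locate relative quantum catches in the tetrahedral color space.

    Returns Cartesian coordinates, hue angles (azimuth theta, elevation
    phi), chroma ``r_vec``, the maximum chroma ``r_max`` achievable along
    the same hue direction, and ``r_achieved = r_vec/r_max``.
    """
    usml = np.asarray(usml, dtype=float)
    if usml.shape != (4,):
        raise ValueError("usml must have 4 entries")
    if abs(usml.sum() - 1.0) > 1e-9 or (usml < -1e-9).any():
        raise ValueError("usml must lie on the probability simplex")
    xyz = usml_to_xyz(usml)
    r_vec = float(np.linalg.norm(xyz))
    if r_vec < 1e-12:  # achromatic: snap rounding dust to the exact origin
        return ColorPoint(usml=usml, xyz=np.zeros(3), h_theta=0.0, h_phi=0.0,
                          r_vec=0.0, r_max=_r_max(np.array([0.0, 0.0, 1.0])),
                          r_achieved=0.0, label=label)
    direction = xyz / r_vec
    h_theta = float(np.arctan2(xyz[1], xyz[0]))
    h_phi = float(np.arcsin(np.clip(xyz[2] / r_vec, -1.0, 1.0)))
    r_max = _r_max(direction)
    return ColorPoint(usml=usml, xyz=xyz, h_theta=h_theta, h_phi=h_phi,
                      r_vec=r_vec, r_max=r_max,
                      r_achieved=float(r_vec / r_max), label=label)


# ---------------------------------------------------------------------------
# color volumes
# ---------------------------------------------------------------------------


def _hull_volume(points: np.ndarray) -> tuple[float, ConvexHull | None]:
    try:
        hull = ConvexHull(points)
        return float(hull.volume), hull
    except QhullError:
        logger.info("degenerate (coplanar) point set: volume 0")
        return 0.0, None


def _intersection_volume_exact(hull_a: ConvexHull, hull_b: ConvexHull) -> float:
    halfspaces = np.vstack([hull_a.equations, hull_b.equations])
    # Chebyshev center LP for a strictly interior point
    norms = np.linalg.norm(halfspaces[:, :3], axis=1, keepdims=True)
    c = np.zeros(4)
    c[3] = -1.0
    A_ub = np.hstack([halfspaces[:, :3], norms])
    b_ub = -halfspaces[:, 3]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None)] * 3 + [(0, None)],
                  method="highs")
    if not res.success or res.x[3] < 1e-12:
        return 0.0
    interior = res.x[:3]
    hs = HalfspaceIntersection(halfspaces, interior)
    vol, _ = _hull_volume(hs.intersections)
    return vol


def _intersection_volume_mc(points_a, points_b, hull_a, hull_b,
                            n_mc: int, rng_seed: int) -> float:
    rng = np.random.default_rng(rng_seed)
    lo = np.maximum(points_a.min(axis=0), points_b.min(axis=0))
    hi = np.minimum(points_a.max(axis=0), points_b.max(axis=0))
    if (hi <= lo).any():
        return 0.0
    box = rng.uniform(lo, hi, size=(n_mc, 3))

    def inside(hull, pts):
        eq = hull.equations
        return ((pts @ eq[:, :3].T + eq[:, 3]) <= 1e-12).all(axis=1)

    frac = (inside(hull_a, box) & inside(hull_b, box)).mean()
    return float(frac * np.prod(hi - lo))


def color_volume_overlap(points_a, points_b, method: str = "exact",
                         n_mc: int = 1_000_000, rng_seed: int = 0) -> VolumeOverlapResult:
    """Convex-hull color volumes of two point sets and their overlap.

    ``method='exact'`` intersects the two hulls' half-space systems (with a
    Chebyshev-center feasibility LP); ``'mc'`` uses seeded Monte-Carlo
    (documented tolerance ~1%).  Degenerate (coplanar) sets yield volume 0.
    """
    points_a = np.asarray(points_a, dtype=float)
    points_b = np.asarray(points_b, dtype=float)
    for name, pts in (("A", points_a), ("B", points_b)):
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
            raise ValueError(f"set {name}: need >= 4 points in 3-D")
    vol_a, hull_a = _hull_volume(points_a)
    vol_b, hull_b = _hull_volume(points_b)
    if hull_a is None or hull_b is None or vol_a == 0 or vol_b == 0:
        return VolumeOverlapResult(vol_a, vol_b, 0.0, 0.0, 0.0, method="degenerate")
    if method == "exact":
        inter = _intersection_volume_exact(hull_a, hull_b)
        used = "exact"
    elif method == "mc":
        inter = _intersection_volume_mc(points_a, points_b, hull_a, hull_b,
                                        n_mc, rng_seed)
        used = "mc"
    else:
        raise ValueError("method must be 'exact' or 'mc'")
    inter = min(inter, vol_a, vol_b)
    union = vol_a + vol_b - inter
    return VolumeOverlapResult(
        vol_a=vol_a, vol_b=vol_b, vol_intersection=inter,
        overlap_vs_smaller=inter / min(vol_a, vol_b),
        overlap_vs_union=inter / union,
        method=used,
    )
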