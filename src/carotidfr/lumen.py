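"""FWHM-based lumen contouring and effective-diameter extraction.

The bright carotid lumen in an axial slice is delineated semi-
automatically: from a seed point inside the vessel, rays are cast
outward; along each ray, the boundary is placed at the outermost
linearly interpolated crossing of half the signal range (the FWHM
criterion).  The resulting polygon is triangulated to an area ``A`` and
converted to an effective diameter ``D = 2 sqrt(A / pi)``.  Per-phase
diameters over the cardiac cycle give the systolic (maximum) and
diastolic (minimum) diameters, averaged over a few adjacent slices.

Coordinates: voxel centers at integer 0-based indices; physical
millimetres are ``index * voxel_mm``.  Intensity profiles along rays are
sampled by bilinear interpolation at 0.1-voxel steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .recon import Image4D

__all__ = [
    "LumenContour",
    "DiameterSeries",
    "fwhm_crossings",
    "extract_contour",
    "polygon_area",
    "effective_diameter",
    "diameter_series",
]


@dataclass
class LumenContour:
    """Closed lumen-boundary polygon in in-slice mm coordinates."""

    vertices_mm: np.ndarray  # (n_rays, 2)
    center_mm: np.ndarray  # (2,) centroid used for the rays
    phase: int | None = None
    slice_index: int | None = None

    def __post_init__(self) -> None:
        if self.vertices_mm.shape[0] < 8:
            raise ValueError("contour needs at least 8 vertices")


@dataclass
class DiameterSeries:
    """Per-phase effective diameters for one vessel, with extrema."""

    diameters_mm: np.ndarray  # per phase, averaged across slices
    d_s: float
    d_d: float
    vessel: str = ""
    slices: tuple = ()

    @property
    def rdc_percent(self) -> float:
        return (self.d_s - self.d_d) / self.d_d * 100.0


def fwhm_crossings(profile: np.ndarray, positions: np.ndarray) -> tuple[float, float]:
    """Outermost half-range crossings bracketing the profile's peak.

    The half level is ``min + 0.5 * (max - min)`` over the profile.
    Scanning outward from each end toward the peak, the first linearly
    interpolated crossing of the half level is returned, so interior
    dips below the half level between the outermost crossings are
    ignored.
    """
    profile = np.asarray(profile, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if profile.size < 5:
        raise ValueError("profile needs at least 5 samples")
    lo, hi = profile.min(), profile.max()
    if hi == lo:
        raise ValueError("flat profile: signal range is zero")
    half = lo + 0.5 * (hi - lo)
    peak = int(np.argmax(profile))

    def cross(i0: int, i1: int) -> float:
        f = (half - profile[i0]) / (profile[i1] - profile[i0])
        return positions[i0] + f * (positions[i1] - positions[i0])

    left = None
    for i in range(peak):
        if profile[i] < half <= profile[i + 1]:
            left = cross(i, i + 1)
            break
    right = None
    for i in range(len(profile) - 1, peak, -1):
        if profile[i] < half <= profile[i - 1]:
            right = cross(i, i - 1)
            break
    if left is None or right is None:
        side = "left" if left is None else "right"
        raise ValueError(f"no half-range crossing found on the {side} side of the peak")
    return float(left), float(right)


def _ray_half_crossing(profile: np.ndarray, radii: np.ndarray) -> float:
    """Outermost half-range crossing along an outward (center->edge) ray."""
    lo, hi = profile.min(), profile.max()
    if hi == lo:
        raise ValueError("flat ray profile")
    half = lo + 0.5 * (hi - lo)
    below = profile < half
    if not below.any() or below[0]:
        raise ValueError("ray does not start inside the bright lumen")
    # first sample below half, scanning outward: boundary crossing
    i = int(np.argmax(below))
    f = (half - profile[i - 1]) / (profile[i] - profile[i - 1])
    return float(radii[i - 1] + f * (radii[i] - radii[i - 1]))


def extract_contour(
    slice_image: np.ndarray,
    roi_center_mm,
    voxel_mm: float = 0.6,
    n_rays: int = 64,
    max_radius_mm: float = 6.0,
    step_voxel: float = 0.1,
    max_center_iters: int = 10,
    center_tol_voxel: float = 0.1,
) -> LumenContour:
    """Cast FWHM rays from an iteratively re-centered lumen centroid.

    The seed only needs to lie inside the bright lumen; the ray-cast
    polygon's centroid replaces the seed until it moves by less than
    ``center_tol_voxel`` voxels (at most ``max_center_iters`` rounds).
    """
    center = np.asarray(roi_center_mm, dtype=float)
    angles = 2 * np.pi * np.arange(n_rays) / n_rays
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    radii = np.arange(0.0, max_radius_mm + 1e-9, step_voxel * voxel_mm)

    vertices = None
    for _ in range(max_center_iters + 1):
        pts = center[None, None, :] + radii[None, :, None] * dirs[:, None, :]  # (R, S, 2)
        coords = (pts / voxel_mm).reshape(-1, 2).T  # index units
        prof = map_coordinates(slice_image, coords, order=1, mode="nearest").reshape(
            n_rays, len(radii)
        )
        ray_r = np.empty(n_rays)
        failed = []
        for i in range(n_rays):
            try:
                ray_r[i] = _ray_half_crossing(prof[i], radii)
            except ValueError:
                failed.append(i)
        if failed:
            degs = ", ".join(f"{np.degrees(angles[i]):.0f}" for i in failed[:8])
            raise ValueError(f"FWHM failed on {len(failed)} ray(s) at angles [{degs}] deg")
        vertices = center[None, :] + ray_r[:, None] * dirs
        new_center = vertices.mean(axis=0)
        shift = np.linalg.norm(new_center - center) / voxel_mm
        if shift < center_tol_voxel:
            center = new_center
            break
        center = new_center
    else:  # pragma: no cover - loop always breaks or exhausts
        pass
    return LumenContour(vertices_mm=vertices, center_mm=center)


def polygon_area(contour: LumenContour | np.ndarray) -> float:
    """Polygon area by fan triangulation from the vertex centroid (mm^2).

    For the star-shaped FWHM contours this equals the shoelace value.
    """
    v = contour.vertices_mm if isinstance(contour, LumenContour) else np.asarray(contour)
    if v.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    c = v.mean(axis=0)
    a = v - c
    b = np.roll(v, -1, axis=0) - c
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return float(abs(0.5 * np.sum(cross)))


def effective_diameter(area_mm2: float) -> float:
    """Diameter of the circle with the given area: ``2 sqrt(A / pi)``."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return float(2.0 * np.sqrt(area_mm2 / np.pi))


def diameter_series(
    image4d: Image4D,
    roi_center_mm,
    slice_indices=(30, 32, 34),
    vessel: str = "",
    n_rays: int = 64,
    max_radius_mm: float = 6.0,
    extrema_then_average: bool = True,
) -> DiameterSeries:
    """Per-phase effective diameters for one vessel over several slices.

    Per slice and phase, a contour is extracted, triangulated and
    converted to a diameter.  By default the systolic/diastolic extrema
    are taken per slice and then averaged across slices (the alternative
    - average the per-phase curves first, then take extrema - is behind
    the flag).  The reported per-phase series is always the across-slice
    mean.
    """
    mag = image4d.magnitude()
    n_phases = image4d.n_phases
    slice_indices = tuple(slice_indices)
    if len(slice_indices) < 1:
        raise ValueError("need at least one slice")
    diam = np.empty((len(slice_indices), n_phases))
    for si, z in enumerate(slice_indices):
        for p in range(n_phases):
            try:
                c = extract_contour(
                    mag[:, :, z, p],
                    roi_center_mm,
                    voxel_mm=image4d.voxel_mm,
                    n_rays=n_rays,
                    max_radius_mm=max_radius_mm,
                )
            except ValueError as exc:
                raise ValueError(
                    f"contour failed at slice {z}, phase {p}: {exc}"
                ) from exc
            diam[si, p] = effective_diameter(polygon_area(c))
    if extrema_then_average:
        d_s = float(np.mean(diam.max(axis=1)))
        d_d = float(np.mean(diam.min(axis=1)))
    else:
        mean_curve = diam.mean(axis=0)
        d_s, d_d = float(mean_curve.max()), float(mean_curve.min())
    return DiameterSeries(
        diameters_mm=diam.mean(axis=0),
        d_s=d_s,
        d_d=d_d,
        vessel=vessel,
        slices=slice_indices,
    )
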