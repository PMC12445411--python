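"""Endocardial/epicardial layer decomposition of contoured perfusion maps.

A short-axis myocardial blood-flow (MBF) map is split into an inner
(subendocardial) and an outer (subepicardial) layer by a midventricular line
positioned equidistantly between the endocardial and epicardial contours:
rays are cast from the centre of the LV blood pool at uniform angular
increments, each ray's crossing with the two contours is found, and the
midline vertex on that ray is the midpoint of the two crossings.  Pixels are
then classified by point-in-polygon tests against the epicardial, endocardial
and midline polygons.

Coordinate convention
---------------------
All geometry lives in continuous millimetre coordinates with the origin at
the grid corner.  ``x`` runs along columns, ``y`` along rows; the centre of
pixel ``(row, col)`` is ``((col + 0.5) * spacing_col, (row + 0.5) *
spacing_row)``.  Angles increase counterclockwise in the (x, y) frame.
Background (non-myocardial) pixels carry NaN so that masking mistakes
propagate loudly instead of silently biasing means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import shapely.affinity
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import LineString, Point, Polygon

BACKGROUND = np.nan

SLICE_LABELS = ("basal", "mid", "apical")
STATES = ("stress", "rest")


class GeometryError(ValueError):
    """Raised when contours or rays violate the geometric preconditions."""


@dataclass
class PerfusionMap:
    """One short-axis slice of a pixel-wise MBF map.

    Parameters
    ----------
    values
        2-D array of MBF in mL/min/g; background pixels are NaN.
    pixel_spacing
        (row, col) spacing in mm.
    slice_label
        One of ``basal``, ``mid``, ``apical``.
    state
        ``stress`` or ``rest``.
    """

    values: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_label: str
    state: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("perfusion map must be a non-empty 2-D grid")
        sp = self.pixel_spacing
        if np.isscalar(sp):
            sp = (float(sp), float(sp))
        self.pixel_spacing = (float(sp[0]), float(sp[1]))
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.slice_label not in SLICE_LABELS:
            raise ValueError(f"unknown slice_label {self.slice_label!r}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("MBF values must be non-negative")

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Physical (height, width) of the grid in mm."""
        return (
            self.values.shape[0] * self.pixel_spacing[0],
            self.values.shape[1] * self.pixel_spacing[1],
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of pixel-centre coordinates in mm."""
        rows, cols = self.values.shape
        y = (np.arange(rows) + 0.5) * self.pixel_spacing[0]
        x = (np.arange(cols) + 0.5) * self.pixel_spacing[1]
        return np.meshgrid(x, y)


@dataclass
class ContourSet:
    """Endocardial/epicardial contours plus the RV-insertion landmark.

    Polygons are simple closed rings in mm coordinates; the endocardial
    contour must lie strictly inside the epicardial one.
    """

    endo: Polygon
    epi: Polygon
    rv_insertion: tuple[float, float]
    _center: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.endo, Polygon):
            self.endo = Polygon(np.asarray(self.endo, dtype=float))
        if not isinstance(self.epi, Polygon):
            self.epi = Polygon(np.asarray(self.epi, dtype=float))
        for name, poly in (("endo", self.endo), ("epi", self.epi)):
            if not poly.is_valid or not poly.is_simple:
                raise GeometryError(f"{name} contour is not a simple polygon")
        if not self.epi.contains(self.endo):
            raise GeometryError("endo contour must lie strictly inside epi contour")
        self.rv_insertion = tuple(float(v) for v in self.rv_insertion)

    @property
    def blood_pool_center(self) -> np.ndarray:
        if self._center is None:
            self._center = compute_blood_pool_center(self)
        return self._center

    def translated(self, dx: float, dy: float) -> "ContourSet":
        return ContourSet(
            shapely.affinity.translate(self.endo, dx, dy),
            shapely.affinity.translate(self.epi, dx, dy),
            (self.rv_insertion[0] + dx, self.rv_insertion[1] + dy),
        )


@dataclass
class LayerMasks:
    """Boolean layer masks on a pixel grid plus the separating midline."""

    myocardium: np.ndarray
    endo_layer: np.ndarray
    epi_layer: np.ndarray
    midline: np.ndarray  # (n_rays, 2) closed polyline, mm
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        if (self.endo_layer & self.epi_layer).any():
            raise GeometryError("endo and epi layers overlap")
        if not np.array_equal(self.endo_layer | self.epi_layer, self.myocardium):
            raise GeometryError("layers do not partition the myocardium")


def compute_blood_pool_center(contours: ContourSet) -> np.ndarray:
    """Centre of the LV blood pool: area centroid of the endocardial polygon."""
    if contours.endo.area <= 0:
        raise GeometryError("degenerate endocardial polygon (zero area)")
    c = contours.endo.centroid
    return np.array([c.x, c.y])


def cast_rays(n_rays: int = 360, reference_angle_deg: float = 0.0) -> np.ndarray:
    """Unit ray directions at uniform angular increments.

    Returns an ``(n_rays, 2)`` array ordered counterclockwise starting from
    ``reference_angle_deg`` (degrees from the +x axis).  360 rays give the
    1-degree increment used for midline construction.
    """
    if n_rays < 8:
        raise ValueError("n_rays must be at least 8")
    ang = np.deg2rad(reference_angle_deg) + 2 * np.pi * np.arange(n_rays) / n_rays
    return np.column_stack([np.cos(ang), np.sin(ang)])


def _ray_crossing(ring, center: np.ndarray, direction: np.ndarray, reach: float,
                  angle_deg: float, name: str) -> np.ndarray:
    """Unique intersection of a ray from `center` with a contour ring."""
    seg = LineString([center, center + direction * reach])
    inter = seg.intersection(ring)
    if inter.is_empty:
        raise GeometryError(f"ray at {angle_deg:.1f} deg misses the {name} contour")
    if isinstance(inter, Point):
        return np.array([inter.x, inter.y])
    pts = getattr(inter, "geoms", None)
    if pts is None or any(not isinstance(g, Point) for g in pts):
        raise GeometryError(
            f"ray at {angle_deg:.1f} deg overlaps the {name} contour")
    raise GeometryError(
        f"ray at {angle_deg:.1f} deg crosses the {name} contour "
        f"{len(list(pts))} times (non-star-shaped contour)")


def compute_midline(contours: ContourSet, rays: np.ndarray | None = None,
                    n_rays: int = 360) -> np.ndarray:
    """Midventricular polyline equidistant between the two contours.

    Per ray from the blood-pool centre, the midline vertex is the midpoint of
    the ray's crossings with the endocardial and epicardial contours.  Returns
    one vertex per ray (the polyline closes implicitly).
    """
    if rays is None:
        rays = cast_rays(n_rays)
    center = contours.blood_pool_center
    endo_ring = contours.endo.exterior
    epi_ring = contours.epi.exterior
    minx, miny, maxx, maxy = contours.epi.bounds
    reach = 2.0 * max(maxx - minx, maxy - miny) + 1.0
    mid = np.empty((len(rays), 2))
    for i, d in enumerate(rays):
        ang = np.degrees(np.arctan2(d[1], d[0])) % 360.0
        p_endo = _ray_crossing(endo_ring, center, d, reach, ang, "endo")
        p_epi = _ray_crossing(epi_ring, center, d, reach, ang, "epi")
        mid[i] = 0.5 * (p_endo + p_epi)
    return mid


def interpolate_map(pmap: PerfusionMap, target_spacing: float = 1.0) -> PerfusionMap:
    """Resample a map to ``target_spacing`` mm with bilinear interpolation.

    Background pixels are excluded from the interpolation support (filled by
    nearest valid neighbour before interpolation) so the NaN sentinel does not
    bleed into myocardial values; pixels whose interpolated validity falls
    below one half are set back to background.  The physical extent is
    preserved.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    h_mm, w_mm = pmap.extent_mm
    if target_spacing > min(h_mm, w_mm):
        raise ValueError(
            f"target_spacing {target_spacing} mm exceeds map extent "
            f"({h_mm:.1f} x {w_mm:.1f} mm)")

    values = pmap.values
    valid = np.isfinite(values)
    filled = values
    if not valid.all():
        # index of nearest valid pixel, used only to pad the support
        _, (ri, ci) = ndimage.distance_transform_edt(
            ~valid, return_indices=True, sampling=pmap.pixel_spacing)
        filled = values[ri, ci]

    rows, cols = values.shape
    y_src = (np.arange(rows) + 0.5) * pmap.pixel_spacing[0]
    x_src = (np.arange(cols) + 0.5) * pmap.pixel_spacing[1]
    interp_v = RegularGridInterpolator(
        (y_src, x_src), filled, method="linear", bounds_error=False, fill_value=None)
    interp_m = RegularGridInterpolator(
        (y_src, x_src), valid.astype(float), method="linear",
        bounds_error=False, fill_value=None)

    new_rows = max(int(round(h_mm / target_spacing)), 1)
    new_cols = max(int(round(w_mm / target_spacing)), 1)
    y_new = (np.arange(new_rows) + 0.5) * target_spacing
    x_new = (np.arange(new_cols) + 0.5) * target_spacing
    yy, xx = np.meshgrid(y_new, x_new, indexing="ij")
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    out = interp_v(pts).reshape(new_rows, new_cols)
    support = interp_m(pts).reshape(new_rows, new_cols)
    out[support < 0.5] = BACKGROUND
    out[np.isfinite(out) & (out < 0)] = 0.0  # clip tiny interpolation undershoot
    return PerfusionMap(out, (target_spacing, target_spacing),
                        pmap.slice_label, pmap.state)


def assign_layers(pmap: PerfusionMap, contours: ContourSet,
                  midline: np.ndarray | None = None,
                  n_rays: int = 360) -> LayerMasks:
    """Split the myocardium into endo and epi layers via the midline polygon.

    A pixel belongs to the myocardium when its centre lies inside the
    epicardial contour (boundary inclusive) and not strictly inside the
    endocardial one.  Myocardial pixels inside or on the midline polygon are
    endocardial (ties on the midline break toward endo), the rest epicardial.
    """
    if midline is None:
        midline = compute_midline(contours, n_rays=n_rays)
    X, Y = pmap.pixel_centers()
    x, y = X.ravel(), Y.ravel()
    inside_epi = shapely.intersects_xy(contours.epi, x, y)
    inside_endo = shapely.contains_xy(contours.endo, x, y)
    myo = (inside_epi & ~inside_endo).reshape(pmap.values.shape)
    if not myo.any():
        raise GeometryError("empty myocardium mask")
    mid_poly = Polygon(midline)
    in_mid = shapely.intersects_xy(mid_poly, x, y).reshape(pmap.values.shape)
    endo_layer = myo & in_mid
    epi_layer = myo & ~in_mid
    return LayerMasks(myo, endo_layer, epi_layer, midline, pmap.pixel_spacing)
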