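"""Planar-polygon geometry: the DICOM contour convention, PTV union,
overlap volumes, and ROI-to-PTV surface-distance summaries.

Contours are stored slice-wise (one z per planar contour).  Within a slice
the DICOM convention is order-dependent: a ring lying inside the
cumulatively built region subtracts area (a hole, e.g. a ring structure),
while a ring outside it adds area (an island, e.g. both lungs delineated
as one ROI).  Shapely performs the 2-D boolean arithmetic; volumes are
slice areas times local slice thickness.

Internally everything is millimetres; overlap volumes are returned in
cm^3 and distances in cm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from dvhdb.ingest import RoiContours

log = logging.getLogger(__name__)

_Z_SNAP = 1e-3  # mm; z keys snapped to a micron before dictionary lookup
MAX_DISTANCE_PAIRS = 10**7


@dataclass
class SlicePolygonSet:
    """Per-slice planar regions of one (or a union of) ROI(s).

    ``slices`` maps snapped z (mm) to a shapely (Multi)Polygon carrying
    hole/island structure.  z keys are kept sorted on access.
    """

    slices: dict[float, BaseGeometry] = field(default_factory=dict)
    source: str = ""

    def z_values(self) -> list[float]:
        return sorted(self.slices)

    def slice_thicknesses(self) -> dict[float, float]:
        """Thickness per slice from the gap to the adjacent (next) slice.

        The last slice reuses the previous gap; a single-slice set has no
        defined thickness and returns an empty mapping.
        """
        zs = self.z_values()
        if len(zs) < 2:
            return {}
        gaps = np.diff(zs)
        thick = {z: float(g) for z, g in zip(zs[:-1], gaps)}
        thick[zs[-1]] = float(gaps[-1])
        return thick

    def volume(self) -> float:
        """Slice-summed volume in cm^3 (area x local thickness)."""
        thick = self.slice_thicknesses()
        if not thick:
            raise ValueError("cannot compute a volume from fewer than 2 slices")
        return sum(self.slices[z].area * thick[z] for z in self.slices) / 1000.0

    def boundary_points(self, densify_mm: Optional[float] = None) -> np.ndarray:
        """All boundary vertices as an (n, 3) array of (x, y, z) mm.

        With ``densify_mm`` set, extra points are interpolated along each
        boundary so consecutive points are at most that far apart.
        """
        pts = []
        for z in self.z_values():
            geom = self.slices[z]
            boundary = geom.boundary
            if densify_mm is not None:
                boundary = boundary.segmentize(densify_mm)
            for line in getattr(boundary, "geoms", [boundary]):
                xy = np.asarray(line.coords, dtype=float)
                if len(xy) > 1 and np.allclose(xy[0], xy[-1]):
                    xy = xy[:-1]  # drop closing duplicate
                pts.append(np.column_stack([xy[:, 0], xy[:, 1], np.full(len(xy), z)]))
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)


def _snap(z: float) -> float:
    return round(float(z) / _Z_SNAP) * _Z_SNAP


def _clean(poly: Polygon) -> Optional[BaseGeometry]:
    if poly.is_valid:
        return poly
    repaired = poly.buffer(0)
    if repaired.is_valid and not repaired.is_empty:
        return repaired
    return None


def build_slice_polygons(roi: RoiContours) -> SlicePolygonSet:
    """Fold each slice's rings into a planar region with holes/islands.

    Rings are processed in stored order: a ring inside the cumulative
    region subtracts (hole); one outside adds (island).  Self-intersecting
    rings are repaired by zero-buffer cleaning; irreparable rings are
    dropped with a warning.
    """
    out: dict[float, BaseGeometry] = {}
    for z, rings in roi.slices:
        region: Optional[BaseGeometry] = None
        for ring in rings:
            poly = _clean(Polygon(np.asarray(ring, dtype=float)))
            if poly is None or poly.is_empty or poly.area <= 0:
                log.warning("ROI %s z=%s: dropping invalid ring", roi.roi_name, z)
                continue
            if region is None or region.is_empty:
                region = poly
            elif region.contains(poly):
                region = region.difference(poly)
            else:
                region = region.union(poly)
        if region is not None and not region.is_empty:
            out[_snap(z)] = region
    return SlicePolygonSet(slices=out, source=roi.roi_name)


def union_ptvs(ptvs: Sequence[SlicePolygonSet]) -> SlicePolygonSet:
    """Per-slice union of all planning target volumes.

    The result is keyed on the merged set of z values and is usable
    anywhere a single ROI region is.
    """
    if not ptvs:
        raise ValueError("no PTV found")
    merged: dict[float, list[BaseGeometry]] = {}
    for p in ptvs:
        for z, geom in p.slices.items():
            merged.setdefault(_snap(z), []).append(geom)
    out = {z: unary_union(geoms) for z, geoms in merged.items()}
    return SlicePolygonSet(slices=out, source=" + ".join(p.source for p in ptvs))


def overlap_volume(ptv: SlicePolygonSet, roi: SlicePolygonSet) -> float:
    """PTV-overlap volume in cm^3: sum of per-slice intersection areas
    times the local slice thickness.

    Thickness comes from the gap between a slice and its adjacent slice in
    the ROI; a single-slice ROI falls back to the PTV's median spacing.
    """
    if not ptv.slices or not roi.slices:
        raise ValueError("both inputs must be non-empty")
    thick = roi.slice_thicknesses()
    if not thick:
        zs = ptv.z_values()
        fallback = float(np.median(np.diff(zs))) if len(zs) > 1 else 0.0
        log.warning(
            "single-slice ROI %s: falling back to PTV median spacing %.3f mm",
            roi.source,
            fallback,
        )
        thick = {z: fallback for z in roi.slices}
    total_mm3 = 0.0
    for z, geom in roi.slices.items():
        other = ptv.slices.get(z)
        if other is None:
            continue
        total_mm3 += geom.intersection(other).area * thick[z]
    return total_mm3 / 1000.0


@dataclass
class GeometrySummary:
    """Distance summaries (cm) between ROI and combined-PTV boundary points,
    plus the PTV-overlap volume (cm^3)."""

    dist_min: float
    dist_mean: float
    dist_median: float
    dist_max: float
    ptv_overlap: float = 0.0


def surface_distances(
    ptv: SlicePolygonSet,
    roi: SlicePolygonSet,
    force: bool = False,
    densify_mm: Optional[float] = None,
) -> GeometrySummary:
    """Brute-force 3-D distances between all ROI and PTV boundary points.

    Returns the min / mean / median / max of the full pairwise distance
    multiset, in cm.  Surfaces whose pair count exceeds
    ``MAX_DISTANCE_PAIRS`` are refused unless ``force`` is set (memory
    guard: external/skin contours can be enormous).
    """
    a = ptv.boundary_points(densify_mm)
    b = roi.boundary_points(densify_mm)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty boundary point set")
    if len(a) * len(b) > MAX_DISTANCE_PAIRS and not force:
        raise MemoryError(
            f"{len(a)} x {len(b)} point pairs exceeds guard of {MAX_DISTANCE_PAIRS}; "
            "pass force=True to compute anyway"
        )
    d = cdist(a, b)
    return GeometrySummary(
        dist_min=float(d.min()) / 10.0,
        dist_mean=float(d.mean()) / 10.0,
        dist_median=float(np.median(d)) / 10.0,
        dist_max=float(d.max()) / 10.0,
    )


def roi_geometry_summary(
    ptv: SlicePolygonSet,
    roi: SlicePolygonSet,
    compute_distances: bool = True,
    force: bool = False,
) -> GeometrySummary:
    """Overlap plus (optionally) surface distances for one ROI against the
    combined PTV."""
    overlap = overlap_volume(ptv, roi)
    if compute_distances:
        summary = surface_distances(ptv, roi, force=force)
        summary.ptv_overlap = overlap
        return summary
    return GeometrySummary(
        dist_min=float("nan"),
        dist_mean=float("nan"),
        dist_median=float("nan"),
        dist_max=float("nan"),
        ptv_overlap=overlap,
    )
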