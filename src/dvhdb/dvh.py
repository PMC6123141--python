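"""Cumulative DVH computation from contours and a dose grid, plus
D_x / V_x endpoint evaluation.

A structure is rasterized onto the dose grid by voxel-centre membership:
a voxel belongs to the ROI iff its centre lies inside the ROI's slice
region (even-odd rule, honouring holes and islands) on the grid plane
nearest that slice's z.  No partial-volume weighting is applied, so the
computed volume depends on the dose-grid resolution and converges to the
true volume as the grid is refined.

The differential DVH bins voxel volumes at a fixed bin width (default
0.01 Gy); the cumulative DVH at bin b is the volume receiving at least
that bin's dose.  Endpoints are evaluated by linear interpolation along
the cumulative curve.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import shapely

from dvhdb.geometry import SlicePolygonSet, build_slice_polygons
from dvhdb.ingest import DoseGrid, RoiContours

log = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.01  # Gy


@dataclass
class VoxelMask:
    """Voxel indices of a rasterized ROI on a specific dose grid."""

    grid_shape: tuple[int, int, int]
    indices: np.ndarray  # (n, 3) int array of (k, j, i) = (plane, row, col)
    voxel_volumes: np.ndarray  # cm^3 per masked voxel (plane thickness varies)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def volume(self) -> float:
        """Masked volume in cm^3."""
        return float(self.voxel_volumes.sum())


@dataclass
class DoseVolumeHistogram:
    bin_width: float  # Gy
    diff_counts: np.ndarray  # per-bin voxel volume, cm^3
    cumulative: np.ndarray  # per-bin volume receiving >= bin dose, cm^3
    volume: float  # cm^3
    min_dose: float
    mean_dose: float
    max_dose: float
    rx_dose: Optional[float] = None  # Gy, for relative-dose scaling

    @property
    def dose_edges(self) -> np.ndarray:
        """Lower dose edge of each bin (the dose the cumulative bin refers to)."""
        return np.arange(len(self.cumulative)) * self.bin_width

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(len(self.diff_counts)) + 0.5) * self.bin_width


@dataclass
class EndpointSpec:
    """A D_x or V_x endpoint.

    kind 'D': minimum dose to the hottest ``value`` % (value_units '%') or
    cm^3 (value_units 'cc') of the structure.  kind 'V': volume receiving at
    least ``value`` Gy (value_units 'Gy') or % of the prescription dose
    (value_units '%').  output_units 'absolute' reports Gy / cc; 'relative'
    reports % of the prescription dose / % of the structure volume.
    """

    kind: str  # 'D' or 'V'
    value: float
    value_units: str  # '%' or 'cc' for D; '%' or 'Gy' for V
    output_units: str = "absolute"  # or 'relative'

    def __post_init__(self) -> None:
        if self.kind not in ("D", "V"):
            raise ValueError(f"endpoint kind must be 'D' or 'V', got {self.kind!r}")
        if self.value <= 0:
            raise ValueError("endpoint value must be positive")
        valid = {"D": {"%", "cc"}, "V": {"%", "Gy"}}[self.kind]
        if self.value_units not in valid:
            raise ValueError(
                f"{self.kind} endpoint units must be one of {valid}, got {self.value_units!r}"
            )
        if self.output_units not in ("absolute", "relative"):
            raise ValueError("output_units must be 'absolute' or 'relative'")

    @property
    def label(self) -> str:
        unit = self.value_units
        return f"{self.kind}_{self.value:g}{unit}"

    @classmethod
    def parse(cls, text: str, output_units: str = "absolute") -> "EndpointSpec":
        """Parse e.g. ``D_95%``, ``D_2cc``, ``V_20Gy``, ``V_100%``."""
        m = re.fullmatch(r"\s*([DV])_?([0-9.]+)\s*(%|cc|Gy)\s*", text)
        if not m:
            raise ValueError(f"cannot parse endpoint {text!r}")
        return cls(kind=m.group(1), value=float(m.group(2)), value_units=m.group(3),
                   output_units=output_units)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def rasterize_structure(
    roi: RoiContours | SlicePolygonSet, grid: DoseGrid
) -> VoxelMask:
    """Rasterize an ROI onto the dose grid by voxel-centre membership.

    Each ROI slice is matched to the nearest grid plane; slices farther
    than half the local plane spacing from any plane are skipped.  An ROI
    entirely outside the grid yields an empty mask with a warning.
    """
    region = roi if isinstance(roi, SlicePolygonSet) else build_slice_polygons(roi)
    xs, ys, zs = grid.x_coords, grid.y_coords, grid.z_coords
    thickness = grid.plane_thickness()
    dx, dy = grid.pixel_spacing
    xx, yy = np.meshgrid(xs, ys)  # (ny, nx)
    flat_x, flat_y = xx.ravel(), yy.ravel()

    plane_regions: dict[int, list] = {}
    for z, geom in region.slices.items():
        k = int(np.argmin(np.abs(zs - z)))
        if abs(zs[k] - z) > thickness[k] / 2 + 1e-9:
            continue
        plane_regions.setdefault(k, []).append(geom)

    idx_list = []
    vol_list = []
    for k, geoms in plane_regions.items():
        geom = geoms[0]
        for extra in geoms[1:]:
            geom = geom.union(extra)
        inside = shapely.contains_xy(geom, flat_x, flat_y)
        jj, ii = np.divmod(np.nonzero(inside)[0], len(xs))
        if len(jj) == 0:
            continue
        idx_list.append(np.column_stack([np.full(len(jj), k), jj, ii]))
        vol_list.append(np.full(len(jj), dx * dy * thickness[k] / 1000.0))

    if not idx_list:
        log.warning("ROI %s: no voxel centres inside the grid", region.source)
        return VoxelMask(
            grid_shape=grid.values.shape,
            indices=np.empty((0, 3), dtype=int),
            voxel_volumes=np.empty(0),
        )
    return VoxelMask(
        grid_shape=grid.values.shape,
        indices=np.vstack(idx_list).astype(int),
        voxel_volumes=np.concatenate(vol_list),
    )


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------


def compute_dvh(
    mask: VoxelMask,
    grid: DoseGrid,
    bin_width: float = DEFAULT_BIN_WIDTH,
    rx_dose: Optional[float] = None,
) -> DoseVolumeHistogram:
    """Differential + cumulative DVH of the masked voxel doses.

    Voxel volumes are binned at ``bin_width``; the cumulative histogram at
    bin b is the total volume with dose >= b*bin_width.  Mean dose is
    volume-weighted.
    """
    if len(mask) == 0:
        raise ValueError("zero-volume ROI: cannot compute a DVH")
    dose = grid.dose_gy
    k, j, i = mask.indices.T
    doses = dose[k, j, i]
    vols = mask.voxel_volumes
    bins = np.floor(doses / bin_width + 1e-9).astype(int)
    diff = np.bincount(bins, weights=vols, minlength=bins.max() + 2)
    cumulative = np.cumsum(diff[::-1])[::-1]
    volume = float(vols.sum())
    return DoseVolumeHistogram(
        bin_width=bin_width,
        diff_counts=diff,
        cumulative=cumulative,
        volume=volume,
        min_dose=float(doses.min()),
        mean_dose=float(np.average(doses, weights=vols)),
        max_dose=float(doses.max()),
        rx_dose=rx_dose,
    )


def _dose_at_abs_volume(dvh: DoseVolumeHistogram, target_cc: float) -> float:
    """Dose (Gy) at which the cumulative curve crosses ``target_cc``,
    linearly interpolated; ties on flat segments break toward higher dose."""
    cum = dvh.cumulative
    doses = dvh.dose_edges
    if target_cc > dvh.volume + 1e-12:
        raise ValueError(
            f"requested volume {target_cc:g} cc exceeds structure volume {dvh.volume:g} cc"
        )
    at_least = np.nonzero(cum >= target_cc - 1e-12)[0]
    if len(at_least) == 0:
        return 0.0
    hi = at_least[-1]  # highest dose still covering the target volume
    if hi == len(cum) - 1 or cum[hi] <= target_cc + 1e-12:
        return float(doses[hi])
    d1, d2 = doses[hi], doses[hi + 1]
    v1, v2 = cum[hi], cum[hi + 1]
    if v1 == v2:
        return float(d2)
    return float(d1 + (d2 - d1) * (v1 - target_cc) / (v1 - v2))


def dose_at_volume(dvh: DoseVolumeHistogram, spec: EndpointSpec) -> float:
    """Evaluate a D_x endpoint (minimum dose to the hottest x% / x cc)."""
    if spec.kind != "D":
        raise ValueError("dose_at_volume requires a D endpoint")
    if spec.value_units == "%":
        if not 0 < spec.value <= 100:
            raise ValueError("percent volume must be in (0, 100]")
        target = dvh.volume * spec.value / 100.0
    else:
        target = spec.value
    d = _dose_at_abs_volume(dvh, target)
    if spec.output_units == "relative":
        if not dvh.rx_dose:
            raise ValueError("relative dose output requires a prescription dose")
        return 100.0 * d / dvh.rx_dose
    return d


def volume_at_dose(dvh: DoseVolumeHistogram, spec: EndpointSpec) -> float:
    """Evaluate a V_x endpoint (volume receiving at least x Gy / x% of rx)."""
    if spec.kind != "V":
        raise ValueError("volume_at_dose requires a V endpoint")
    if spec.value_units == "%":
        if not dvh.rx_dose:
            raise ValueError("percent-dose endpoint requires a prescription dose")
        dose = dvh.rx_dose * spec.value / 100.0
    else:
        dose = spec.value
    edges = dvh.dose_edges
    cum = dvh.cumulative
    if dose <= edges[0]:
        v = float(cum[0])
    elif dose >= edges[-1]:
        v = float(cum[-1]) if dose == edges[-1] else 0.0
    else:
        v = float(np.interp(dose, edges, cum))
    if spec.output_units == "relative":
        return 100.0 * v / dvh.volume
    return v


def evaluate_endpoint(dvh: DoseVolumeHistogram, spec: EndpointSpec) -> float:
    return dose_at_volume(dvh, spec) if spec.kind == "D" else volume_at_dose(dvh, spec)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_dvhs_csv(
    path,
    rows: Sequence[dict],
) -> None:
    """Write one CSV row per ROI: identifiers, volume, dose summaries, then
    the cumulative bin values.

    Each entry of ``rows`` must carry mrn, study_uid, roi_name and a
    :class:`DoseVolumeHistogram` under key 'dvh'.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["mrn", "study_uid", "roi_name", "volume_cc", "min_dose_gy",
             "mean_dose_gy", "max_dose_gy", "bin_width_gy", "cumulative_cc"]
        )
        for row in rows:
            dvh = row["dvh"]
            writer.writerow(
                [row["mrn"], row["study_uid"], row["roi_name"],
                 f"{dvh.volume:.6g}", f"{dvh.min_dose:.6g}", f"{dvh.mean_dose:.6g}",
                 f"{dvh.max_dose:.6g}", f"{dvh.bin_width:g}",
                 ";".join(f"{v:.6g}" for v in dvh.cumulative)]
            )
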