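"""Synthetic, standards-valid DICOM-RT filesets and in-memory phantoms
with analytic ground truth.

Phantoms pair a 3-D dose grid (uniform, axial-gradient, or spherical
fall-off dose models) with geometric structures (spheres, boxes,
cylinders, ring cylinders, two-island pairs) contoured as dense planar
polygons — vertex spacing at most 1 mm along each ring — exactly the way
an RT Structure Set stores them.  Each phantom carries closed-form truth
(volumes, dose summaries where the dose model admits them, concentric
surface gaps) computed symbolically from the spec, never from the
pipeline under test.

``write_dicom_rt`` serializes a phantom to an RT Plan / RT Structure Set
/ RT Dose trio sharing one study-instance UID, with the dose grid scaled
to 16-bit integers, so the full ingest pipeline can be exercised without
patient data.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.sequence import Sequence as DcmSequence
from pydicom.uid import ExplicitVRLittleEndian

from dvhdb.ingest import DoseGrid, RoiContours

_UID_ROOT = "1.2.826.0.1.3680043.10.1098"

SOP_CLASS = {
    "RTPLAN": "1.2.840.10008.5.1.4.1.1.481.5",
    "RTSTRUCT": "1.2.840.10008.5.1.4.1.1.481.3",
    "RTDOSE": "1.2.840.10008.5.1.4.1.1.481.2",
}


# ---------------------------------------------------------------------------
# Shapes and dose models
# ---------------------------------------------------------------------------


@dataclass
class Sphere:
    r: float  # mm

    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.r**3

    def half_height(self) -> float:
        return self.r

    def rings_at(self, dz: float) -> list[tuple[str, float | tuple]]:
        if abs(dz) >= self.r:
            return []
        return [("circle", math.sqrt(self.r**2 - dz**2))]


@dataclass
class Box:
    a: float  # x extent, mm
    b: float  # y extent, mm
    c: float  # z extent, mm

    def volume_mm3(self) -> float:
        return self.a * self.b * self.c

    def half_height(self) -> float:
        return self.c / 2.0

    def rings_at(self, dz: float) -> list:
        if abs(dz) >= self.c / 2.0:
            return []
        return [("rect", (self.a, self.b))]


@dataclass
class Cylinder:
    r: float
    h: float

    def volume_mm3(self) -> float:
        return math.pi * self.r**2 * self.h

    def half_height(self) -> float:
        return self.h / 2.0

    def rings_at(self, dz: float) -> list:
        if abs(dz) >= self.h / 2.0:
            return []
        return [("circle", self.r)]


@dataclass
class RingCylinder:
    """Annular cylinder: outer ring then inner ring on every slice, pinning
    the hole-subtraction contour convention."""

    r_out: float
    r_in: float
    h: float

    def volume_mm3(self) -> float:
        return math.pi * (self.r_out**2 - self.r_in**2) * self.h

    def half_height(self) -> float:
        return self.h / 2.0

    def rings_at(self, dz: float) -> list:
        if abs(dz) >= self.h / 2.0:
            return []
        return [("circle", self.r_out), ("circle", self.r_in)]


@dataclass
class TwoIslands:
    """Two disjoint square prisms delineated as one ROI (island convention)."""

    side: float
    gap: float  # centre-to-centre x offset between the squares
    h: float

    def volume_mm3(self) -> float:
        return 2.0 * self.side**2 * self.h

    def half_height(self) -> float:
        return self.h / 2.0

    def rings_at(self, dz: float) -> list:
        if abs(dz) >= self.h / 2.0:
            return []
        return [
            ("rect_off", (self.side, self.side, -self.gap / 2.0)),
            ("rect_off", (self.side, self.side, +self.gap / 2.0)),
        ]


Shape = Sphere | Box | Cylinder | RingCylinder | TwoIslands


@dataclass
class StructureSpec:
    name: str
    roi_type: str
    shape: Shape
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm


@dataclass
class UniformDose:
    dose: float  # Gy

    def evaluate(self, x, y, z):
        return np.full(np.broadcast(x, y, z).shape, self.dose)


@dataclass
class ZGradientDose:
    """dose(z) = offset + slope * z (Gy, z in mm), clipped at 0."""

    slope: float
    offset: float = 0.0

    def evaluate(self, x, y, z):
        return np.maximum(self.offset + self.slope * np.asarray(z, dtype=float), 0.0) + 0.0 * (
            np.asarray(x) + np.asarray(y)
        )


@dataclass
class SphericalFalloffDose:
    """dose(r) = d0 * 2^(-r / r50): halves every r50 mm from the centre."""

    center: tuple[float, float, float]
    d0: float
    r50: float

    def evaluate(self, x, y, z):
        r = np.sqrt(
            (np.asarray(x) - self.center[0]) ** 2
            + (np.asarray(y) - self.center[1]) ** 2
            + (np.asarray(z) - self.center[2]) ** 2
        )
        return self.d0 * np.exp2(-r / self.r50)


DoseModel = UniformDose | ZGradientDose | SphericalFalloffDose


@dataclass
class RxGroupSpec:
    """One fraction group: ``fxs`` fractions of ``fx_dose`` Gy split over
    ``n_beams`` beams."""

    fxs: int
    fx_dose: float
    n_beams: int = 2
    arc: bool = False


@dataclass
class PlanMeta:
    mrn: str = "PH000001"
    physician: str = "ABC"
    tx_site: Optional[str] = "Phantom"  # written as a "tx:" POI when set
    rx_groups: list[RxGroupSpec] = field(default_factory=lambda: [RxGroupSpec(30, 2.0)])
    sim_date: date = date(2017, 6, 1)
    birthdate: date = date(1950, 1, 15)
    sex: str = "F"
    machine: str = "Linac1"
    plan_label: str = "PhantomPlan"
    brachy: bool = False
    tx_time: float = 300.0  # s, brachytherapy only


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (16, 32, 32)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # (dx, dy, dz) mm
    dose_model: DoseModel = field(default_factory=lambda: UniformDose(60.0))
    structures: list[StructureSpec] = field(default_factory=list)
    plan_meta: PlanMeta = field(default_factory=PlanMeta)
    seed: int = 0


@dataclass
class PhantomTruth:
    """Closed-form ground truth, computed from the spec alone."""

    volumes_cc: dict[str, float] = field(default_factory=dict)
    dose_min: dict[str, float] = field(default_factory=dict)
    dose_mean: dict[str, float] = field(default_factory=dict)
    dose_max: dict[str, float] = field(default_factory=dict)
    surface_gaps_mm: dict[tuple[str, str], float] = field(default_factory=dict)
    rx_dose: float = 0.0


# ---------------------------------------------------------------------------
# Contour generation
# ---------------------------------------------------------------------------


def _circle_points(cx: float, cy: float, r: float, max_spacing: float = 1.0) -> np.ndarray:
    n = max(16, int(math.ceil(2.0 * math.pi * r / max_spacing)))
    t = np.arange(n) * (2.0 * math.pi / n)
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


def _rect_points(cx: float, cy: float, a: float, b: float, max_spacing: float = 1.0) -> np.ndarray:
    """Rectangle boundary densified to ``max_spacing`` between vertices."""
    x0, x1 = cx - a / 2.0, cx + a / 2.0
    y0, y1 = cy - b / 2.0, cy + b / 2.0
    nx = max(1, int(math.ceil(a / max_spacing)))
    ny = max(1, int(math.ceil(b / max_spacing)))
    xs = np.linspace(x0, x1, nx + 1)
    ys = np.linspace(y0, y1, ny + 1)
    pts = (
        [(x, y0) for x in xs[:-1]]
        + [(x1, y) for y in ys[:-1]]
        + [(x, y1) for x in xs[::-1][:-1]]
        + [(x0, y) for y in ys[::-1][:-1]]
    )
    return np.asarray(pts, dtype=float)


def _rings_for(shape: Shape, center, z: float) -> list[np.ndarray]:
    cx, cy, cz = center
    out = []
    for kind, param in shape.rings_at(z - cz):
        if kind == "circle":
            out.append(_circle_points(cx, cy, param))
        elif kind == "rect":
            out.append(_rect_points(cx, cy, param[0], param[1]))
        elif kind == "rect_off":
            a, b, xoff = param
            out.append(_rect_points(cx + xoff, cy, a, b))
    return out


def _grid_geometry(spec: PhantomSpec) -> tuple[tuple[float, float, float], np.ndarray]:
    nz, ny, nx = spec.grid_shape
    dx, dy, dz = spec.spacing
    # centre the grid on the origin of patient space
    origin = (-(nx - 1) * dx / 2.0, -(ny - 1) * dy / 2.0, -(nz - 1) * dz / 2.0)
    z_offsets = np.arange(nz) * dz
    return origin, z_offsets


def _check_inside_grid(spec: PhantomSpec) -> None:
    nz, ny, nx = spec.grid_shape
    dx, dy, dz = spec.spacing
    half = ((nx - 1) * dx / 2.0, (ny - 1) * dy / 2.0, (nz - 1) * dz / 2.0)
    for s in spec.structures:
        shape = s.shape
        if isinstance(shape, Sphere):
            ext = (shape.r, shape.r, shape.r)
        elif isinstance(shape, Box):
            ext = (shape.a / 2, shape.b / 2, shape.c / 2)
        elif isinstance(shape, Cylinder):
            ext = (shape.r, shape.r, shape.h / 2)
        elif isinstance(shape, RingCylinder):
            ext = (shape.r_out, shape.r_out, shape.h / 2)
        else:
            ext = (shape.gap / 2 + shape.side / 2, shape.side / 2, shape.h / 2)
        for axis in range(3):
            if abs(s.center[axis]) + ext[axis] > half[axis] + 1e-9:
                raise ValueError(f"structure {s.name!r} extends outside the dose grid")


def _analytic_dose_summary(model: DoseModel, s: StructureSpec):
    """min/mean/max dose where closed-form: uniform and z-gradient models."""
    if isinstance(model, UniformDose):
        return model.dose, model.dose, model.dose
    if isinstance(model, ZGradientDose):
        hz = s.shape.half_height()
        z0, z1 = s.center[2] - hz, s.center[2] + hz
        d0 = model.offset + model.slope * z0
        d1 = model.offset + model.slope * z1
        lo, hi = min(d0, d1), max(d0, d1)
        if lo < 0:  # clipping breaks the closed form
            return None
        # z-symmetric shapes: volume-weighted mean dose is the dose at centre
        return lo, model.offset + model.slope * s.center[2], hi
    return None


def make_phantom(spec: PhantomSpec) -> tuple[DoseGrid, list[RoiContours], PhantomTruth]:
    """Build the dose grid, densely contoured structures, and analytic truth."""
    _check_inside_grid(spec)
    origin, z_offsets = _grid_geometry(spec)
    nz, ny, nx = spec.grid_shape
    dx, dy, dz = spec.spacing
    xs = origin[0] + np.arange(nx) * dx
    ys = origin[1] + np.arange(ny) * dy
    zs = origin[2] + z_offsets
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    dose = np.asarray(spec.dose_model.evaluate(xx, yy, zz), dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose model produced negative dose")
    max_dose = float(dose.max())
    scaling = max(max_dose, 1e-6) / 65000.0
    values = np.round(dose / scaling).astype(np.uint16)
    grid = DoseGrid(
        origin=origin,
        pixel_spacing=(dx, dy),
        z_offsets=z_offsets,
        values=values.astype(np.float64),
        dose_scaling=scaling,
    )

    rois: list[RoiContours] = []
    truth = PhantomTruth()
    for s in spec.structures:
        slices: list[tuple[float, list[np.ndarray]]] = []
        for z in zs:
            rings = _rings_for(s.shape, s.center, float(z))
            if rings:
                slices.append((round(float(z), 3), rings))
        if not slices:
            raise ValueError(f"structure {s.name!r} intersects no grid plane")
        rois.append(RoiContours(roi_name=s.name, roi_type=s.roi_type, slices=slices))
        truth.volumes_cc[s.name] = s.shape.volume_mm3() / 1000.0
        summary = _analytic_dose_summary(spec.dose_model, s)
        if summary is not None:
            truth.dose_min[s.name], truth.dose_mean[s.name], truth.dose_max[s.name] = summary

    # concentric-shape surface gaps (same centre, both radial shapes)
    for i, a in enumerate(spec.structures):
        for b in spec.structures[i + 1 :]:
            if a.center == b.center:
                ra = getattr(a.shape, "r", None)
                rb = getattr(b.shape, "r", None)
                if ra is not None and rb is not None:
                    truth.surface_gaps_mm[(a.name, b.name)] = abs(ra - rb)

    truth.rx_dose = sum(g.fxs * g.fx_dose for g in spec.plan_meta.rx_groups)
    return grid, rois, truth


# ---------------------------------------------------------------------------
# DICOM writing
# ---------------------------------------------------------------------------


def _uid(rng: random.Random) -> str:
    return f"{_UID_ROOT}.{rng.randrange(10**8)}.{rng.randrange(10**8)}"


def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _base_dataset(
    modality: str,
    meta: PlanMeta,
    study_uid: str,
    series_uid: str,
    sop_instance: str,
    when: datetime,
) -> Dataset:
    ds = Dataset()
    ds.file_meta = _file_meta(SOP_CLASS[modality], sop_instance)
    ds.SOPClassUID = SOP_CLASS[modality]
    ds.SOPInstanceUID = sop_instance
    ds.Modality = modality
    ds.PatientID = meta.mrn
    ds.PatientName = f"Phantom^{meta.mrn}"
    ds.PatientBirthDate = meta.birthdate.strftime("%Y%m%d")
    ds.PatientSex = meta.sex
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.StudyDate = meta.sim_date.strftime("%Y%m%d")
    ds.StudyTime = "120000"
    ds.InstanceCreationDate = when.strftime("%Y%m%d")
    ds.InstanceCreationTime = when.strftime("%H%M%S")
    ds.Manufacturer = "dvhdb"
    ds.ManufacturerModelName = "dvhdb-fixtures"
    ds.SoftwareVersions = "0.1.0"
    return ds


def _write_structure_set(
    path: Path,
    meta: PlanMeta,
    rois: Sequence[RoiContours],
    study_uid: str,
    rng: random.Random,
    when: datetime,
    frame_uid: str,
) -> None:
    ds = _base_dataset("RTSTRUCT", meta, study_uid, _uid(rng), _uid(rng), when)
    ds.StructureSetLabel = "PhantomSS"
    ds.StructureSetDate = ds.InstanceCreationDate
    ds.StructureSetTime = ds.InstanceCreationTime
    ds.FrameOfReferenceUID = frame_uid

    roi_seq, contour_seq, obs_seq = DcmSequence(), DcmSequence(), DcmSequence()

    def _add_roi(number: int, name: str, roi_type: str, contours: list[Dataset]) -> None:
        item = Dataset()
        item.ROINumber = number
        item.ROIName = name
        item.ReferencedFrameOfReferenceUID = frame_uid
        item.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(item)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = DcmSequence(contours)
        contour_seq.append(rc)
        obs = Dataset()
        obs.ObservationNumber = number
        obs.ReferencedROINumber = number
        obs.RTROIInterpretedType = roi_type
        obs.ROIInterpreter = ""
        obs_seq.append(obs)

    number = 1
    for roi in rois:
        contours = []
        for z, rings in roi.slices:
            for ring in rings:
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = len(ring)
                flat = []
                for x, y in np.asarray(ring, dtype=float):
                    flat.extend([float(x), float(y), float(z)])
                c.ContourData = flat
                contours.append(c)
        _add_roi(number, roi.roi_name, roi.roi_type, contours)
        number += 1

    # "tx:"-prefixed treatment-site point of interest
    if meta.tx_site is not None:
        poi = Dataset()
        poi.ContourGeometricType = "POINT"
        poi.NumberOfContourPoints = 1
        poi.ContourData = [0.0, 0.0, 0.0]
        _add_roi(number, f"tx: {meta.tx_site}", "MARKER", [poi])

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.RTROIObservationsSequence = obs_seq
    ds.save_as(path, enforce_file_format=True)


def _control_points(rng: random.Random, arc: bool, iso) -> DcmSequence:
    cps = DcmSequence()
    if arc:
        angles = np.linspace(181.0, 179.0 + 360.0, 8) % 360.0
    else:
        angles = [float(rng.choice([0, 90, 180, 270]))] * 2
    for i, ang in enumerate(angles):
        cp = Dataset()
        cp.ControlPointIndex = i
        cp.GantryAngle = round(float(ang), 2)
        cp.BeamLimitingDeviceAngle = 0.0
        cp.PatientSupportAngle = 0.0
        cp.NominalBeamEnergy = 6.0
        cp.SourceToSurfaceDistance = 900.0 + rng.uniform(-50, 50)
        if i == 0:
            cp.IsocenterPosition = list(iso)
        cps.append(cp)
    return cps


def _write_plan(
    path: Path,
    meta: PlanMeta,
    study_uid: str,
    rng: random.Random,
    when: datetime,
    frame_uid: str,
) -> None:
    ds = _base_dataset("RTPLAN", meta, study_uid, _uid(rng), _uid(rng), when)
    ds.RTPlanLabel = meta.plan_label
    ds.RTPlanDate = ds.InstanceCreationDate
    ds.RTPlanTime = ds.InstanceCreationTime
    ds.RTPlanGeometry = "TREATMENT_DEVICE"
    ds.FrameOfReferenceUID = frame_uid
    ds.PhysiciansOfRecord = meta.physician

    setup = Dataset()
    setup.PatientSetupNumber = 1
    setup.PatientPosition = "HFS"
    ds.PatientSetupSequence = DcmSequence([setup])

    if meta.brachy:
        ds.BrachyTreatmentType = "HDR"
        ds.BrachyTreatmentTechnique = "INTRALUMENARY"
        aps = Dataset()
        aps.ApplicationSetupNumber = 1
        ch = Dataset()
        ch.ChannelNumber = 1
        ch.ChannelTotalTime = meta.tx_time
        ch.NumberOfControlPoints = 2
        aps.ChannelSequence = DcmSequence([ch])
        ds.ApplicationSetupSequence = DcmSequence([aps])

    fg_seq = DcmSequence()
    beam_seq = DcmSequence()
    dr_seq = DcmSequence()
    beam_number = 1
    for gi, group in enumerate(meta.rx_groups, start=1):
        fg = Dataset()
        fg.FractionGroupNumber = gi
        fg.NumberOfFractionsPlanned = group.fxs
        refs = DcmSequence()
        n_beams = 0 if meta.brachy else group.n_beams
        for _ in range(n_beams):
            beam = Dataset()
            beam.BeamNumber = beam_number
            beam.BeamName = f"Beam{beam_number}"
            beam.BeamType = "DYNAMIC" if group.arc else "STATIC"
            beam.RadiationType = "PHOTON"
            beam.TreatmentMachineName = meta.machine
            beam.ControlPointSequence = _control_points(rng, group.arc, (0.0, 0.0, 0.0))
            beam.NumberOfControlPoints = len(beam.ControlPointSequence)
            beam_seq.append(beam)
            ref = Dataset()
            ref.ReferencedBeamNumber = beam_number
            ref.BeamDose = group.fx_dose / group.n_beams
            ref.BeamMeterset = round(100.0 * group.fx_dose / group.n_beams, 1)
            refs.append(ref)
            beam_number += 1
        fg.NumberOfBeams = n_beams
        fg.ReferencedBeamSequence = refs
        fg_seq.append(fg)

        dr = Dataset()
        dr.DoseReferenceNumber = gi
        dr.DoseReferenceStructureType = "SITE"
        dr.DoseReferenceDescription = f"Group{gi}"
        dr.TargetPrescriptionDose = group.fxs * group.fx_dose
        dr_seq.append(dr)

    ds.FractionGroupSequence = fg_seq
    if not meta.brachy:
        ds.BeamSequence = beam_seq
    ds.DoseReferenceSequence = dr_seq
    ds.save_as(path, enforce_file_format=True)


def _write_dose(
    path: Path,
    meta: PlanMeta,
    grid: DoseGrid,
    study_uid: str,
    rng: random.Random,
    when: datetime,
    frame_uid: str,
) -> None:
    ds = _base_dataset("RTDOSE", meta, study_uid, _uid(rng), _uid(rng), when)
    nz, ny, nx = grid.values.shape
    ds.FrameOfReferenceUID = frame_uid
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.ImagePositionPatient = [grid.origin[0], grid.origin[1], grid.origin[2]]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [grid.pixel_spacing[1], grid.pixel_spacing[0]]  # [dy, dx]
    ds.GridFrameOffsetVector = [float(v) for v in grid.z_offsets]
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = grid.dose_scaling
    ds.TissueHeterogeneityCorrection = "IMAGE"
    ds.PixelData = grid.values.astype(np.uint16).tobytes()
    ds.save_as(path, enforce_file_format=True)


def write_dicom_rt(
    phantom: tuple[DoseGrid, Sequence[RoiContours]] | PhantomSpec,
    plan_meta: Optional[PlanMeta] = None,
    out_dir: Path | str = ".",
    seed: Optional[int] = None,
    study_uid: Optional[str] = None,
) -> tuple[Path, Path, Path]:
    """Write a phantom as an RT Plan / Structure Set / Dose trio.

    Accepts either a built ``(DoseGrid, rois)`` pair or a
    :class:`PhantomSpec` (built on the fly).  Returns the three file
    paths.  UIDs are drawn from a seeded generator so a fixed seed gives
    a byte-stable fileset; pass ``study_uid`` to pin the study identity
    explicitly.
    """
    if isinstance(phantom, PhantomSpec):
        grid, rois, _ = make_phantom(phantom)
        plan_meta = plan_meta or phantom.plan_meta
        seed = phantom.seed if seed is None else seed
    else:
        grid, rois = phantom
        plan_meta = plan_meta or PlanMeta()
        seed = 0 if seed is None else seed

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    study = study_uid or _uid(rng)
    frame_uid = _uid(rng)
    when = datetime.combine(plan_meta.sim_date, datetime.min.time()).replace(hour=13)

    tag = f"{plan_meta.mrn}_{study.rsplit('.', 1)[-1]}"
    plan_path = out_dir / f"RP_{tag}.dcm"
    struct_path = out_dir / f"RS_{tag}.dcm"
    dose_path = out_dir / f"RD_{tag}.dcm"
    _write_plan(plan_path, plan_meta, study, rng, when, frame_uid)
    _write_structure_set(struct_path, plan_meta, rois, study, rng, when, frame_uid)
    _write_dose(dose_path, plan_meta, grid, study, rng, when, frame_uid)
    return plan_path, struct_path, dose_path
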