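"""Discover, group, and parse DICOM-RT filesets.

A treatment course is represented by one composite plan: a single RT Plan,
RT Structure Set, and RT Dose object sharing one study-instance UID.  This
module walks a directory of loose DICOM files, groups them by study UID,
picks the latest-timestamp instance of each required modality, and parses
the winning trio into flat domain records (plan / prescription / beam rows)
plus the geometric inputs (contours, dose grid) consumed by the DVH and
geometry stages.

Conventions applied during extraction:

* the treatment site defaults to the plan label, but a point-of-interest
  named ``tx: <site>`` in the structure set overrides it;
* any ROI whose name begins with ``ITV`` is typed ITV regardless of the
  interpreted type stored in the file (several planning systems never
  export that type);
* brachytherapy plans produce no beam rows, but every other record is
  still populated.

All patient-space coordinates stay in millimetres here; unit conversions
(cm^3, cm) happen in the computation modules.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError

log = logging.getLogger(__name__)

_RT_MODALITIES = {"RTPLAN": "plan", "RTSTRUCT": "structure", "RTDOSE": "dose"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PlanFileSet:
    """One complete composite plan: the latest plan/structure/dose trio of a study."""

    mrn: str
    study_uid: str
    plan_file: Path
    structure_file: Path
    dose_file: Path
    extra_files: list[Path] = field(default_factory=list)


@dataclass
class PlanRecord:
    mrn: str
    study_uid: str
    import_timestamp: Optional[str] = None
    age_at_study: Optional[int] = None
    baseline: bool = False
    birthdate: Optional[date] = None
    dose_grid_resolution: Optional[str] = None
    dose_timestamp: Optional[datetime] = None
    fractions: Optional[int] = None
    heterogeneity_correction: Optional[str] = None
    total_mu: Optional[float] = None
    patient_sex: Optional[str] = None
    patient_orientation: Optional[str] = None
    physician: Optional[str] = None
    plan_timestamp: Optional[datetime] = None
    rx_dose: Optional[float] = None
    sim_study_date: Optional[date] = None
    structure_timestamp: Optional[datetime] = None
    tps_manufacturer: Optional[str] = None
    tps_name: Optional[str] = None
    tps_version: Optional[str] = None
    tx_modality: Optional[str] = None
    tx_site: Optional[str] = None
    tx_time: Optional[float] = None  # seconds, brachytherapy only


@dataclass
class RxRecord:
    mrn: str
    study_uid: str
    import_timestamp: Optional[str] = None
    fxs: Optional[int] = None
    fx_dose: Optional[float] = None
    fx_group_name: Optional[str] = None
    fx_group_number: Optional[int] = None
    fx_group_count: Optional[int] = None
    norm_method: Optional[str] = None
    norm_object: Optional[str] = None
    rx_dose: Optional[float] = None
    rx_percent: Optional[float] = None


@dataclass
class AngleInfo:
    """Start/end/min/max/range summary of a rotational axis over control points."""

    start: float = 0.0
    end: float = 0.0
    min: float = 0.0
    max: float = 0.0
    range: float = 0.0


@dataclass
class BeamRecord:
    mrn: str
    study_uid: str
    import_timestamp: Optional[str] = None
    beam_name: Optional[str] = None
    beam_number: Optional[int] = None
    beam_dose: Optional[float] = None
    beam_mu: Optional[float] = None
    mu_per_degree: Optional[float] = None
    mu_per_control_point: Optional[float] = None
    control_point_count: Optional[int] = None
    energy_min: Optional[float] = None
    energy_max: Optional[float] = None
    radiation_type: Optional[str] = None
    beam_type: Optional[str] = None
    fx_count: Optional[int] = None
    fx_group_beam_count: Optional[int] = None
    fx_group_number: Optional[int] = None
    gantry: AngleInfo = field(default_factory=AngleInfo)
    collimator: AngleInfo = field(default_factory=AngleInfo)
    couch: AngleInfo = field(default_factory=AngleInfo)
    isocenter: Optional[tuple[float, float, float]] = None
    scan_spot_count: Optional[int] = None
    scan_mode: Optional[str] = None
    ssd: Optional[float] = None  # mm; mean over control points for arcs
    treatment_machine: Optional[str] = None


@dataclass
class RoiContours:
    """Planar contours of one ROI in patient coordinates (mm).

    ``slices`` is a z-sorted list of ``(z, rings)`` where each ring is an
    ordered ``(n, 2)`` array of in-plane (x, y) vertices.  Ring order within
    a slice is preserved from the file: the DICOM convention folds later
    rings into the earlier ones as holes or islands.
    """

    roi_name: str
    roi_type: str
    slices: list[tuple[float, list[np.ndarray]]] = field(default_factory=list)

    def z_values(self) -> list[float]:
        return [z for z, _ in self.slices]


@dataclass
class DoseGrid:
    """A 3-D dose grid: ``values[k, j, i]`` is plane k, row j (y), column i (x)."""

    origin: tuple[float, float, float]  # x, y, z of the first voxel centre, mm
    pixel_spacing: tuple[float, float]  # dx, dy, mm
    z_offsets: np.ndarray  # mm offsets of each plane from origin z
    values: np.ndarray  # raw stored values, shape (nz, ny, nx)
    dose_scaling: float  # Gy per stored unit
    units: str = "GY"

    def __post_init__(self) -> None:
        self.z_offsets = np.asarray(self.z_offsets, dtype=float)
        if len(self.z_offsets) != self.values.shape[0]:
            raise ValueError("z_offsets length must match number of dose planes")
        dz = np.diff(self.z_offsets)
        if len(dz) and not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z_offsets must be strictly monotone")

    @property
    def dose_gy(self) -> np.ndarray:
        return self.values * self.dose_scaling

    @property
    def x_coords(self) -> np.ndarray:
        nx = self.values.shape[2]
        return self.origin[0] + np.arange(nx) * self.pixel_spacing[0]

    @property
    def y_coords(self) -> np.ndarray:
        ny = self.values.shape[1]
        return self.origin[1] + np.arange(ny) * self.pixel_spacing[1]

    @property
    def z_coords(self) -> np.ndarray:
        return self.origin[2] + self.z_offsets

    def plane_thickness(self) -> np.ndarray:
        """Per-plane z thickness (mm); edge planes reuse their single gap."""
        z = self.z_coords
        if len(z) == 1:
            return np.array([abs(self.pixel_spacing[0])])  # degenerate single plane
        gaps = np.abs(np.diff(z))
        thick = np.empty(len(z))
        thick[:-1] = gaps
        thick[-1] = gaps[-1]
        return thick


# ---------------------------------------------------------------------------
# Discovery
# ---------------------------------------------------------------------------


def _instance_timestamp(ds: pydicom.Dataset, path: Path) -> datetime:
    """DICOM instance creation date+time, falling back to file mtime."""
    d = getattr(ds, "InstanceCreationDate", None)
    t = getattr(ds, "InstanceCreationTime", None) or "000000"
    if d:
        try:
            return datetime.strptime(str(d) + str(t)[:6].ljust(6, "0"), "%Y%m%d%H%M%S")
        except ValueError:
            pass
    return datetime.fromtimestamp(os.path.getmtime(path))


def discover_filesets(
    directory: os.PathLike | str,
) -> tuple[list[PlanFileSet], list[dict]]:
    """Group DICOM files under ``directory`` into complete RT filesets.

    Files are grouped by study-instance UID.  Within a group, the instance
    of each required modality (RT Plan / Structure / Dose) with the latest
    timestamp wins; superseded and unrelated files of the same study are
    kept in ``extra_files``.  Groups missing any required modality are
    reported in the second return value, not returned as filesets.
    Unreadable or non-DICOM files are skipped with a logged warning.
    """
    groups: dict[str, dict] = {}
    for root, _dirs, names in os.walk(directory):
        for name in sorted(names):
            path = Path(root) / name
            try:
                ds = pydicom.dcmread(path, stop_before_pixels=True, force=False)
            except (InvalidDicomError, Exception) as exc:  # noqa: BLE001
                log.warning("skipping unreadable file %s: %s", path, exc)
                continue
            modality = _RT_MODALITIES.get(str(getattr(ds, "Modality", "")))
            uid = str(getattr(ds, "StudyInstanceUID", "") or "")
            if not uid:
                log.warning("skipping %s: no study-instance UID", path)
                continue
            g = groups.setdefault(
                uid, {"mrn": None, "files": {"plan": [], "structure": [], "dose": []}, "other": []}
            )
            if g["mrn"] is None:
                g["mrn"] = str(getattr(ds, "PatientID", "") or "")
            if modality is None:
                g["other"].append(path)
            else:
                g["files"][modality].append((_instance_timestamp(ds, path), path))

    filesets: list[PlanFileSet] = []
    incomplete: list[dict] = []
    for uid in sorted(groups):
        g = groups[uid]
        missing = [m for m in ("plan", "structure", "dose") if not g["files"][m]]
        if missing:
            incomplete.append({"study_uid": uid, "missing": missing})
            log.warning("study %s incomplete, missing: %s", uid, ", ".join(missing))
            continue
        chosen = {}
        extras = list(g["other"])
        for m in ("plan", "structure", "dose"):
            # sort by (timestamp, path) so ties break deterministically
            ranked = sorted(g["files"][m], key=lambda tp: (tp[0], str(tp[1])))
            chosen[m] = ranked[-1][1]
            extras.extend(p for _, p in ranked[:-1])
        filesets.append(
            PlanFileSet(
                mrn=g["mrn"] or "",
                study_uid=uid,
                plan_file=chosen["plan"],
                structure_file=chosen["structure"],
                dose_file=chosen["dose"],
                extra_files=sorted(extras),
            )
        )
    return filesets, incomplete


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------


def _dcm_date(value) -> Optional[date]:
    if not value:
        return None
    try:
        return datetime.strptime(str(value)[:8], "%Y%m%d").date()
    except ValueError:
        return None


def _dcm_datetime(d, t) -> Optional[datetime]:
    if not d:
        return None
    try:
        return datetime.strptime(str(d) + (str(t)[:6] if t else "000000").ljust(6, "0"), "%Y%m%d%H%M%S")
    except ValueError:
        return None


def _floor_years(start: date, end: date) -> int:
    years = end.year - start.year
    if (end.month, end.day) < (start.month, start.day):
        years -= 1
    return years


def _angle_info(angles: Sequence[float]) -> AngleInfo:
    """Summarize an axis over control points; range is the accumulated sweep."""
    a = np.asarray([float(x) for x in angles], dtype=float)
    if a.size == 0:
        return AngleInfo()
    # accumulate the shortest-arc deltas so a 358->2 degree step counts as 4
    deltas = np.diff(a)
    deltas = (deltas + 180.0) % 360.0 - 180.0
    sweep = float(abs(np.sum(np.abs(deltas))))
    return AngleInfo(
        start=float(a[0]),
        end=float(a[-1]),
        min=float(a.min()),
        max=float(a.max()),
        range=sweep,
    )


def _find_tx_site_poi(struct_ds: pydicom.Dataset) -> Optional[str]:
    """Return the site text of a ``tx:``-prefixed point of interest, if any."""
    for roi in struct_ds.get("StructureSetROISequence", []):
        name = str(getattr(roi, "ROIName", "") or "")
        if name.lower().lstrip().startswith("tx:"):
            return name.split(":", 1)[1].strip()
    return None


def _is_brachy(plan_ds: pydicom.Dataset) -> bool:
    return bool(getattr(plan_ds, "BrachyTreatmentType", None)) or (
        "ApplicationSetupSequence" in plan_ds
    )


def _tx_modality(plan_ds: pydicom.Dataset, beams: list[BeamRecord]) -> str:
    if _is_brachy(plan_ds):
        return "Brachytherapy"
    rad_types = {b.radiation_type for b in beams if b.radiation_type}
    if "PROTON" in rad_types:
        return "Protons"
    if "ELECTRON" in rad_types:
        return "Electrons"
    if any(b.gantry.range > 0 for b in beams):
        return "Photon arc"
    return "Photon 3D" if beams else "Unknown"


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def parse_plan(fs: PlanFileSet) -> tuple[PlanRecord, list[RxRecord], list[BeamRecord]]:
    """Parse one fileset into plan, prescription, and beam records.

    The composite prescription dose is the sum of the fraction-group
    prescriptions; one :class:`RxRecord` is emitted per fraction group.
    Brachytherapy plans yield no beam records.
    """
    plan_ds = pydicom.dcmread(fs.plan_file)
    struct_ds = pydicom.dcmread(fs.structure_file, stop_before_pixels=True)
    dose_ds = pydicom.dcmread(fs.dose_file, stop_before_pixels=True)

    mrn = str(getattr(plan_ds, "PatientID", "") or "")
    study_uid = str(getattr(plan_ds, "StudyInstanceUID", "") or "")
    if not mrn or not study_uid:
        raise ValueError(f"{fs.plan_file}: missing Patient ID or study-instance UID")

    brachy = _is_brachy(plan_ds)
    plan_label = str(getattr(plan_ds, "RTPlanLabel", "") or getattr(plan_ds, "RTPlanName", "") or "")

    # --- prescriptions: one per fraction group -----------------------------
    fx_groups = list(plan_ds.get("FractionGroupSequence", []))
    beam_dose_by_number: dict[int, dict] = {}
    rxs: list[RxRecord] = []
    dose_refs = list(plan_ds.get("DoseReferenceSequence", []))
    for i, fg in enumerate(fx_groups):
        fxs = int(getattr(fg, "NumberOfFractionsPlanned", 0) or 0)
        ref_beams = list(fg.get("ReferencedBeamSequence", []))
        fx_dose = 0.0
        for rb in ref_beams:
            bd = float(getattr(rb, "BeamDose", 0.0) or 0.0)
            fx_dose += bd
            num = getattr(rb, "ReferencedBeamNumber", None)
            if num is not None:
                beam_dose_by_number[int(num)] = {
                    "dose": bd,
                    "mu": float(getattr(rb, "BeamMeterset", 0.0) or 0.0),
                    "fx_group_number": int(getattr(fg, "FractionGroupNumber", i + 1) or i + 1),
                    "fxs": fxs,
                    "group_beam_count": len(ref_beams),
                }
        norm_method = norm_object = None
        rx_percent = 100.0
        if i < len(dose_refs):
            dr = dose_refs[i]
            norm_method = str(getattr(dr, "DoseReferenceStructureType", "") or "") or None
            norm_object = str(getattr(dr, "DoseReferenceDescription", "") or "") or None
        rxs.append(
            RxRecord(
                mrn=mrn,
                study_uid=study_uid,
                fxs=fxs,
                fx_dose=fx_dose,
                fx_group_name=plan_label or f"FxGroup{i + 1}",
                fx_group_number=int(getattr(fg, "FractionGroupNumber", i + 1) or i + 1),
                fx_group_count=len(fx_groups),
                norm_method=norm_method,
                norm_object=norm_object,
                rx_dose=fxs * fx_dose,
                rx_percent=rx_percent,
            )
        )

    # --- beams --------------------------------------------------------------
    beams: list[BeamRecord] = []
    if not brachy:
        for b in plan_ds.get("BeamSequence", []):
            cps = list(b.get("ControlPointSequence", []))
            gantry = _angle_info([cp.GantryAngle for cp in cps if "GantryAngle" in cp])
            coll = _angle_info(
                [cp.BeamLimitingDeviceAngle for cp in cps if "BeamLimitingDeviceAngle" in cp]
            )
            couch = _angle_info(
                [cp.PatientSupportAngle for cp in cps if "PatientSupportAngle" in cp]
            )
            energies = [float(cp.NominalBeamEnergy) for cp in cps if "NominalBeamEnergy" in cp]
            ssds = [float(cp.SourceToSurfaceDistance) for cp in cps if "SourceToSurfaceDistance" in cp]
            iso = None
            for cp in cps:
                if "IsocenterPosition" in cp:
                    iso = tuple(float(v) for v in cp.IsocenterPosition)
                    break
            num = int(getattr(b, "BeamNumber", 0) or 0)
            ref = beam_dose_by_number.get(num, {})
            mu = ref.get("mu")
            rec = BeamRecord(
                mrn=mrn,
                study_uid=study_uid,
                beam_name=str(getattr(b, "BeamName", "") or "") or None,
                beam_number=num,
                beam_dose=ref.get("dose"),
                beam_mu=mu,
                mu_per_degree=(mu / gantry.range) if mu and gantry.range > 0 else None,
                mu_per_control_point=(mu / len(cps)) if mu and cps else None,
                control_point_count=len(cps),
                energy_min=min(energies) if energies else None,
                energy_max=max(energies) if energies else None,
                radiation_type=str(getattr(b, "RadiationType", "") or "") or None,
                beam_type=str(getattr(b, "BeamType", "") or "") or None,
                fx_count=ref.get("fxs"),
                fx_group_beam_count=ref.get("group_beam_count"),
                fx_group_number=ref.get("fx_group_number"),
                gantry=gantry,
                collimator=coll,
                couch=couch,
                isocenter=iso,
                scan_spot_count=int(getattr(b, "NumberOfScanSpotPositions", 0) or 0) or None,
                scan_mode=str(getattr(b, "ScanMode", "") or "") or None,
                ssd=float(np.mean(ssds)) if ssds else None,
                treatment_machine=str(getattr(b, "TreatmentMachineName", "") or "") or None,
            )
            beams.append(rec)

    # --- plan ---------------------------------------------------------------
    tx_site = _find_tx_site_poi(struct_ds) or plan_label
    birthdate = _dcm_date(getattr(plan_ds, "PatientBirthDate", None))
    sim_date = _dcm_date(
        getattr(struct_ds, "StudyDate", None) or getattr(plan_ds, "StudyDate", None)
    )
    age = (
        _floor_years(birthdate, sim_date) if (birthdate is not None and sim_date is not None) else None
    )
    spacing = getattr(dose_ds, "PixelSpacing", None)
    gfov = getattr(dose_ds, "GridFrameOffsetVector", None)
    dz = abs(float(gfov[1]) - float(gfov[0])) if gfov is not None and len(gfov) > 1 else None
    resolution = None
    if spacing is not None:
        dx, dy = float(spacing[1]), float(spacing[0])
        resolution = f"{dx:g},{dy:g}" + (f",{dz:g}" if dz is not None else "")

    orientation = None
    for ps in plan_ds.get("PatientSetupSequence", []):
        orientation = str(getattr(ps, "PatientPosition", "") or "") or None
        break

    tx_time = None
    if brachy:
        total = 0.0
        for aps in plan_ds.get("ApplicationSetupSequence", []):
            for ch in aps.get("ChannelSequence", []):
                total += float(getattr(ch, "ChannelTotalTime", 0.0) or 0.0)
        tx_time = total or None

    total_mu = sum(b.beam_mu or 0.0 for b in beams) or None

    plan = PlanRecord(
        mrn=mrn,
        study_uid=study_uid,
        age_at_study=age,
        baseline=False,
        birthdate=birthdate,
        dose_grid_resolution=resolution,
        dose_timestamp=_dcm_datetime(
            getattr(dose_ds, "InstanceCreationDate", None),
            getattr(dose_ds, "InstanceCreationTime", None),
        ),
        fractions=sum(r.fxs or 0 for r in rxs) or None,
        heterogeneity_correction=str(
            getattr(dose_ds, "TissueHeterogeneityCorrection", "") or ""
        )
        or None,
        total_mu=total_mu,
        patient_sex=str(getattr(plan_ds, "PatientSex", "") or "") or None,
        patient_orientation=orientation,
        physician=str(getattr(plan_ds, "PhysiciansOfRecord", "") or "") or None,
        plan_timestamp=_dcm_datetime(
            getattr(plan_ds, "RTPlanDate", None), getattr(plan_ds, "RTPlanTime", None)
        )
        or _dcm_datetime(
            getattr(plan_ds, "InstanceCreationDate", None),
            getattr(plan_ds, "InstanceCreationTime", None),
        ),
        rx_dose=sum(r.rx_dose or 0.0 for r in rxs) or None,
        sim_study_date=sim_date,
        structure_timestamp=_dcm_datetime(
            getattr(struct_ds, "InstanceCreationDate", None),
            getattr(struct_ds, "InstanceCreationTime", None),
        ),
        tps_manufacturer=str(getattr(plan_ds, "Manufacturer", "") or "") or None,
        tps_name=str(getattr(plan_ds, "ManufacturerModelName", "") or "") or None,
        tps_version=str(getattr(plan_ds, "SoftwareVersions", "") or "") or None,
        tx_modality=_tx_modality(plan_ds, beams),
        tx_site=tx_site,
        tx_time=tx_time,
    )
    return plan, rxs, beams


def parse_structures(fs: PlanFileSet) -> list[RoiContours]:
    """Extract planar contours for every geometric ROI in the structure set.

    Point-only ROIs (POIs) are excluded; rings with fewer than 3 points are
    dropped with a warning.  Any ROI whose name begins with ``ITV``
    (case-insensitive) is forced to type ITV.
    """
    ds = pydicom.dcmread(fs.structure_file)
    names: dict[int, str] = {}
    for roi in ds.get("StructureSetROISequence", []):
        names[int(roi.ROINumber)] = str(getattr(roi, "ROIName", "") or "")
    types: dict[int, str] = {}
    for obs in ds.get("RTROIObservationsSequence", []):
        types[int(obs.ReferencedROINumber)] = str(
            getattr(obs, "RTROIInterpretedType", "") or ""
        )

    out: list[RoiContours] = []
    for rc in ds.get("ROIContourSequence", []):
        number = int(rc.ReferencedROINumber)
        name = names.get(number, f"ROI{number}")
        slices: dict[float, list[np.ndarray]] = {}
        geometric = False
        for c in rc.get("ContourSequence", []):
            gtype = str(getattr(c, "ContourGeometricType", "") or "").upper()
            data = np.asarray([float(v) for v in c.ContourData], dtype=float).reshape(-1, 3)
            if gtype == "POINT" or len(data) == 1:
                continue
            if len(data) < 3:
                log.warning("ROI %s: dropping %d-point ring", name, len(data))
                continue
            if not np.all(np.isfinite(data)):
                log.warning("ROI %s: dropping ring with non-finite coordinates", name)
                continue
            geometric = True
            z = round(float(data[0, 2]), 3)
            slices.setdefault(z, []).append(data[:, :2].copy())
        if not geometric:
            continue
        roi_type = types.get(number, "ORGAN")
        if name.lower().lstrip().startswith("itv"):
            roi_type = "ITV"
        out.append(
            RoiContours(
                roi_name=name,
                roi_type=roi_type,
                slices=[(z, slices[z]) for z in sorted(slices)],
            )
        )
    return out


def parse_dose(fs: PlanFileSet) -> DoseGrid:
    """Load the RT Dose grid: raw values plus scaling and geometry."""
    ds = pydicom.dcmread(fs.dose_file)
    units = str(getattr(ds, "DoseUnits", "") or "").upper()
    if units != "GY":
        raise ValueError(f"{fs.dose_file}: unsupported dose units {units!r} (need GY)")
    scaling = float(getattr(ds, "DoseGridScaling", 1.0) or 1.0)
    ipp = [float(v) for v in ds.ImagePositionPatient]
    spacing = [float(v) for v in ds.PixelSpacing]  # [row (dy), col (dx)]
    gfov = np.asarray([float(v) for v in ds.GridFrameOffsetVector], dtype=float)
    values = ds.pixel_array.astype(np.float64)
    if values.ndim == 2:
        values = values[None, :, :]
    return DoseGrid(
        origin=(ipp[0], ipp[1], ipp[2]),
        pixel_spacing=(spacing[1], spacing[0]),
        z_offsets=gfov,
        values=values,
        dose_scaling=scaling,
        units="GY",
    )


def organize_fileset(fs: PlanFileSet, import_root: os.PathLike | str) -> tuple[PlanFileSet, Path]:
    """Move all files of a fileset under ``<import_root>/<mrn>/<study_uid>/``.

    Returns the relocated fileset and its new folder.
    """
    folder = Path(import_root) / fs.mrn / fs.study_uid
    folder.mkdir(parents=True, exist_ok=True)

    def _move(p: Path) -> Path:
        dest = folder / p.name
        if p.resolve() != dest.resolve():
            p.replace(dest)
        return dest

    moved = PlanFileSet(
        mrn=fs.mrn,
        study_uid=fs.study_uid,
        plan_file=_move(fs.plan_file),
        structure_file=_move(fs.structure_file),
        dose_file=_move(fs.dose_file),
        extra_files=[_move(p) for p in fs.extra_files],
    )
    return moved, folder
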