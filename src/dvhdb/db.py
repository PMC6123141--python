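"""Five-table relational store for plans, prescriptions, beams, DVHs, and
the imported-file catalog, linked by MRN + study-instance UID.

The test/default engine is SQLite (file-backed or in-memory); the DDL is
portable ANSI SQL, so a server RDBMS can host the same schema.  DVH
curves are serialized as comma-separated cumulative volumes (cm^3) at a
fixed stored bin width, and ROI contours as per-slice ``z: x,y;x,y;...``
text blocks — plain text keeps every column engine-portable and
round-trips numerics losslessly at repr precision.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field, fields as dc_fields
from datetime import date, datetime
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from dvhdb.dvh import DoseVolumeHistogram
from dvhdb.geometry import GeometrySummary
from dvhdb.ingest import BeamRecord, PlanRecord, RoiContours, RxRecord

log = logging.getLogger(__name__)


@dataclass
class DvhRecord:
    mrn: str
    study_uid: str
    roi_name: str
    roi_type: str
    institutional_roi: str = "uncategorized"
    physician_roi: str = "uncategorized"
    roi_volume: float = 0.0  # cm^3
    min_dose: float = 0.0
    mean_dose: float = 0.0
    max_dose: float = 0.0
    dist_min: Optional[float] = None  # cm
    dist_mean: Optional[float] = None
    dist_median: Optional[float] = None
    dist_max: Optional[float] = None
    ptv_overlap: Optional[float] = None  # cm^3
    dvh_bin_width: float = 0.01
    dvh: str = ""  # comma-separated cumulative volumes, cm^3
    roi_coordinates: str = ""
    import_timestamp: Optional[str] = None

    @classmethod
    def from_dvh(
        cls,
        mrn: str,
        study_uid: str,
        roi_name: str,
        roi_type: str,
        dvh: DoseVolumeHistogram,
        geometry: Optional[GeometrySummary] = None,
        institutional_roi: str = "uncategorized",
        physician_roi: str = "uncategorized",
        contours: Optional[RoiContours] = None,
    ) -> "DvhRecord":
        rec = cls(
            mrn=mrn,
            study_uid=study_uid,
            roi_name=roi_name,
            roi_type=roi_type,
            institutional_roi=institutional_roi,
            physician_roi=physician_roi,
            roi_volume=dvh.volume,
            min_dose=dvh.min_dose,
            mean_dose=dvh.mean_dose,
            max_dose=dvh.max_dose,
            dvh_bin_width=dvh.bin_width,
            dvh=serialize_dvh(dvh),
        )
        if geometry is not None:
            rec.dist_min = geometry.dist_min
            rec.dist_mean = geometry.dist_mean
            rec.dist_median = geometry.dist_median
            rec.dist_max = geometry.dist_max
            rec.ptv_overlap = geometry.ptv_overlap
        if contours is not None:
            rec.roi_coordinates = serialize_contours(contours)
        return rec


@dataclass
class FileCatalogEntry:
    mrn: str
    study_uid: str
    folder: str
    plan_file: str
    structure_file: str
    dose_file: str


@dataclass
class ImportBundle:
    plan: PlanRecord
    rxs: list[RxRecord]
    beams: list[BeamRecord]
    dvhs: list[DvhRecord]
    catalog: FileCatalogEntry


@dataclass
class ImportResult:
    imported: bool
    study_uid: str
    reason: str = ""
    counts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def serialize_dvh(dvh: DoseVolumeHistogram) -> str:
    return ",".join(repr(float(v)) for v in dvh.cumulative)


def deserialize_dvh(text: str, bin_width: float, **summary) -> DoseVolumeHistogram:
    cumulative = np.array([float(v) for v in text.split(",")]) if text else np.zeros(1)
    diff = cumulative - np.append(cumulative[1:], 0.0)
    return DoseVolumeHistogram(
        bin_width=bin_width,
        diff_counts=diff,
        cumulative=cumulative,
        volume=summary.get("volume", float(cumulative[0])),
        min_dose=summary.get("min_dose", 0.0),
        mean_dose=summary.get("mean_dose", 0.0),
        max_dose=summary.get("max_dose", 0.0),
        rx_dose=summary.get("rx_dose"),
    )


def serialize_contours(roi: RoiContours) -> str:
    blocks = []
    for z, rings in roi.slices:
        ring_txt = "|".join(
            ";".join(f"{float(x)!r},{float(y)!r}" for x, y in np.asarray(ring, dtype=float))
            for ring in rings
        )
        blocks.append(f"{float(z)!r}: {ring_txt}")
    return "\n".join(blocks)


def deserialize_contours(text: str, roi_name: str = "", roi_type: str = "") -> RoiContours:
    slices = []
    for line in text.splitlines():
        if not line.strip():
            continue
        z_txt, rings_txt = line.split(":", 1)
        rings = []
        for ring_txt in rings_txt.strip().split("|"):
            pts = [tuple(float(v) for v in pair.split(",")) for pair in ring_txt.split(";") if pair]
            rings.append(np.asarray(pts, dtype=float))
        slices.append((float(z_txt), rings))
    return RoiContours(roi_name=roi_name, roi_type=roi_type, slices=slices)


def _to_sql_value(v):
    if isinstance(v, bool):
        return int(v)
    if isinstance(v, (date, datetime)):
        return v.isoformat()
    if isinstance(v, tuple):
        return ",".join(repr(float(x)) for x in v)
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

_SCHEMA: dict[str, dict[str, str]] = {
    "Plans": {
        "mrn": "TEXT NOT NULL",
        "study_uid": "TEXT NOT NULL",
        "import_timestamp": "TEXT",
        "age_at_study": "INTEGER",
        "baseline": "INTEGER DEFAULT 0",
        "birthdate": "TEXT",
        "dose_grid_resolution": "TEXT",
        "dose_timestamp": "TEXT",
        "fractions": "INTEGER",
        "heterogeneity_correction": "TEXT",
        "total_mu": "REAL",
        "patient_sex": "TEXT",
        "patient_orientation": "TEXT",
        "physician": "TEXT",
        "plan_timestamp": "TEXT",
        "rx_dose": "REAL",
        "sim_study_date": "TEXT",
        "structure_timestamp": "TEXT",
        "tps_manufacturer": "TEXT",
        "tps_name": "TEXT",
        "tps_version": "TEXT",
        "tx_modality": "TEXT",
        "tx_site": "TEXT",
        "tx_time": "REAL",
    },
    "DVHs": {
        "mrn": "TEXT NOT NULL",
        "study_uid": "TEXT NOT NULL",
        "import_timestamp": "TEXT",
        "roi_name": "TEXT NOT NULL",
        "roi_type": "TEXT",
        "institutional_roi": "TEXT",
        "physician_roi": "TEXT",
        "roi_volume": "REAL",
        "min_dose": "REAL",
        "mean_dose": "REAL",
        "max_dose": "REAL",
        "dist_min": "REAL",
        "dist_mean": "REAL",
        "dist_median": "REAL",
        "dist_max": "REAL",
        "ptv_overlap": "REAL",
        "dvh_bin_width": "REAL",
        "dvh": "TEXT",
        "roi_coordinates": "TEXT",
    },
    "Rxs": {
        "mrn": "TEXT NOT NULL",
        "study_uid": "TEXT NOT NULL",
        "import_timestamp": "TEXT",
        "fxs": "INTEGER",
        "fx_dose": "REAL",
        "fx_group_name": "TEXT",
        "fx_group_number": "INTEGER",
        "fx_group_count": "INTEGER",
        "norm_method": "TEXT",
        "norm_object": "TEXT",
        "rx_dose": "REAL",
        "rx_percent": "REAL",
    },
    "Beams": {
        "mrn": "TEXT NOT NULL",
        "study_uid": "TEXT NOT NULL",
        "import_timestamp": "TEXT",
        "beam_name": "TEXT",
        "beam_number": "INTEGER",
        "beam_dose": "REAL",
        "beam_mu": "REAL",
        "mu_per_degree": "REAL",
        "mu_per_control_point": "REAL",
        "control_point_count": "INTEGER",
        "energy_min": "REAL",
        "energy_max": "REAL",
        "radiation_type": "TEXT",
        "beam_type": "TEXT",
        "fx_count": "INTEGER",
        "fx_group_beam_count": "INTEGER",
        "fx_group_number": "INTEGER",
        "gantry_start": "REAL",
        "gantry_end": "REAL",
        "gantry_min": "REAL",
        "gantry_max": "REAL",
        "gantry_range": "REAL",
        "collimator_start": "REAL",
        "collimator_end": "REAL",
        "collimator_min": "REAL",
        "collimator_max": "REAL",
        "collimator_range": "REAL",
        "couch_start": "REAL",
        "couch_end": "REAL",
        "couch_min": "REAL",
        "couch_max": "REAL",
        "couch_range": "REAL",
        "isocenter": "TEXT",
        "scan_spot_count": "INTEGER",
        "scan_mode": "TEXT",
        "ssd": "REAL",
        "treatment_machine": "TEXT",
    },
    "DICOM_Files": {
        "mrn": "TEXT NOT NULL",
        "study_uid": "TEXT NOT NULL",
        "folder": "TEXT",
        "plan_file": "TEXT",
        "structure_file": "TEXT",
        "dose_file": "TEXT",
    },
}

_CONSTRAINTS = {
    "Plans": "PRIMARY KEY (mrn, study_uid)",
    "DVHs": "UNIQUE (mrn, study_uid, roi_name)",
    "DICOM_Files": "UNIQUE (study_uid)",
}


def ddl_statements() -> list[str]:
    stmts = []
    for table, cols in _SCHEMA.items():
        body = ",\n  ".join(f"{c} {t}" for c, t in cols.items())
        constraint = _CONSTRAINTS.get(table)
        if constraint:
            body += f",\n  {constraint}"
        stmts.append(f"CREATE TABLE IF NOT EXISTS {table} (\n  {body}\n);")
    return stmts


class DvhDatabase:
    """Handle to the five-table store (SQLite connection spec or path)."""

    def __init__(self, connection_spec: str | Path = ":memory:"):
        self.spec = str(connection_spec)
        self.conn = sqlite3.connect(self.spec)
        self.conn.execute("PRAGMA foreign_keys = ON")

    # -- schema -------------------------------------------------------------

    def initialize_schema(self) -> "DvhDatabase":
        """Create the five tables; idempotent.  An existing table with a
        different column set is an error — no silent migration."""
        existing = {
            r[0]
            for r in self.conn.execute(
                "SELECT name FROM sqlite_master WHERE type='table'"
            ).fetchall()
        }
        for table, cols in _SCHEMA.items():
            if table in existing:
                have = [r[1] for r in self.conn.execute(f"PRAGMA table_info({table})")]
                if list(cols) != have:
                    raise ValueError(
                        f"table {table} exists with incompatible columns "
                        f"(found {have}, expected {list(cols)})"
                    )
        for stmt in ddl_statements():
            self.conn.execute(stmt)
        self.conn.commit()
        return self

    def tables(self) -> list[str]:
        return [
            r[0]
            for r in self.conn.execute(
                "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
            )
        ]

    # -- import -------------------------------------------------------------

    def _insert(self, table: str, row: dict) -> None:
        cols = list(_SCHEMA[table])
        values = [_to_sql_value(row.get(c)) for c in cols]
        placeholders = ",".join("?" for _ in cols)
        self.conn.execute(
            f"INSERT INTO {table} ({','.join(cols)}) VALUES ({placeholders})", values
        )

    @staticmethod
    def _record_row(rec) -> dict:
        row = {}
        for f in dc_fields(rec):
            v = getattr(rec, f.name)
            if f.name in ("gantry", "collimator", "couch"):
                for part in ("start", "end", "min", "max", "range"):
                    row[f"{f.name}_{part}"] = getattr(v, part)
            else:
                row[f.name] = v
        return row

    def import_fileset(self, bundle: ImportBundle) -> ImportResult:
        """All-or-nothing import of one composite plan.

        A second plan for an existing study UID is refused outright — the
        guard against accidental data duplication.  Every row of one
        import shares one import timestamp.
        """
        uid = bundle.plan.study_uid
        dup = self.conn.execute(
            "SELECT 1 FROM Plans WHERE study_uid = ?", (uid,)
        ).fetchone()
        if dup:
            log.warning("refusing duplicate import for study %s", uid)
            return ImportResult(imported=False, study_uid=uid, reason="duplicate study_uid")

        stamp = datetime.now().isoformat(timespec="seconds")
        try:
            with self.conn:  # transaction: rollback on any failure
                row = self._record_row(bundle.plan)
                row["import_timestamp"] = stamp
                self._insert("Plans", row)
                for rx in bundle.rxs:
                    row = self._record_row(rx)
                    row["import_timestamp"] = stamp
                    self._insert("Rxs", row)
                for beam in bundle.beams:
                    row = self._record_row(beam)
                    row["import_timestamp"] = stamp
                    self._insert("Beams", row)
                for dvh in bundle.dvhs:
                    if dvh.roi_volume <= 0:
                        raise ValueError(f"ROI {dvh.roi_name!r} has non-positive volume")
                    row = self._record_row(dvh)
                    row["import_timestamp"] = stamp
                    self._insert("DVHs", row)
                self._insert("DICOM_Files", self._record_row(bundle.catalog))
        except Exception as exc:  # noqa: BLE001
            log.error("import of study %s failed and was rolled back: %s", uid, exc)
            return ImportResult(imported=False, study_uid=uid, reason=str(exc))
        return ImportResult(
            imported=True,
            study_uid=uid,
            counts={
                "plans": 1,
                "rxs": len(bundle.rxs),
                "beams": len(bundle.beams),
                "dvhs": len(bundle.dvhs),
            },
        )

    # -- query --------------------------------------------------------------

    def table_df(self, table: str) -> pd.DataFrame:
        if table not in _SCHEMA:
            raise ValueError(f"unknown table {table!r}")
        return pd.read_sql_query(f"SELECT * FROM {table}", self.conn)

    def update_record(self, table: str, study_uid: str, mrn: str, column: str, value) -> None:
        """Single-cell edit with an audit log line."""
        if table not in _SCHEMA:
            raise ValueError(f"unknown table {table!r}")
        if column not in _SCHEMA[table]:
            raise ValueError(f"unknown column {column!r} in {table}")
        cur = self.conn.execute(
            f"UPDATE {table} SET {column} = ? WHERE study_uid = ? AND mrn = ?",
            (_to_sql_value(value), study_uid, mrn),
        )
        if cur.rowcount == 0:
            self.conn.rollback()
            raise ValueError(f"no {table} row for mrn={mrn!r} study_uid={study_uid!r}")
        self.conn.commit()
        log.info(
            "AUDIT %s update %s.%s = %r for mrn=%s study=%s",
            datetime.now().isoformat(timespec="seconds"),
            table,
            column,
            value,
            mrn,
            study_uid,
        )

    def close(self) -> None:
        self.conn.close()


# ---------------------------------------------------------------------------
# Query layer
# ---------------------------------------------------------------------------

# Table 2 searchable categories -> (table, column).  Selection categories
# filter on discrete equality; range categories on inclusive min/max.
SELECTION_CATEGORIES: dict[str, tuple[str, str]] = {
    "baseline": ("Plans", "baseline"),
    "beam_type": ("Beams", "beam_type"),
    "collimator_rotation": ("Beams", "collimator_range"),
    "couch_rotation": ("Beams", "couch_range"),
    "dose_grid_resolution": ("Plans", "dose_grid_resolution"),
    "gantry_rotation": ("Beams", "gantry_range"),
    "heterogeneity_correction": ("Plans", "heterogeneity_correction"),
    "mrn": ("Plans", "mrn"),
    "norm_method": ("Rxs", "norm_method"),
    "patient_orientation": ("Plans", "patient_orientation"),
    "patient_sex": ("Plans", "patient_sex"),
    "physician": ("Plans", "physician"),
    "institutional_roi": ("DVHs", "institutional_roi"),
    "physician_roi": ("DVHs", "physician_roi"),
    "roi_type": ("DVHs", "roi_type"),
    "radiation_type": ("Beams", "radiation_type"),
    "scan_mode": ("Beams", "scan_mode"),
    "treatment_machine": ("Beams", "treatment_machine"),
    "tx_modality": ("Plans", "tx_modality"),
    "tx_site": ("Plans", "tx_site"),
}

RANGE_CATEGORIES: dict[str, tuple[str, str]] = {
    "age_at_study": ("Plans", "age_at_study"),
    "beam_dose": ("Beams", "beam_dose"),
    "beam_energy_min": ("Beams", "energy_min"),
    "beam_energy_max": ("Beams", "energy_max"),
    "beam_mu": ("Beams", "beam_mu"),
    "birthdate": ("Plans", "birthdate"),
    "collimator_angle": ("Beams", "collimator_max"),
    "couch_angle": ("Beams", "couch_max"),
    "dist_min": ("DVHs", "dist_min"),
    "fx_dose": ("Rxs", "fx_dose"),
    "gantry_angle": ("Beams", "gantry_max"),
    "fractions": ("Plans", "fractions"),
    "min_dose": ("DVHs", "min_dose"),
    "mean_dose": ("DVHs", "mean_dose"),
    "max_dose": ("DVHs", "max_dose"),
    "roi_volume": ("DVHs", "roi_volume"),
    "rx_dose": ("Plans", "rx_dose"),
    "rx_percent": ("Rxs", "rx_percent"),
    "scan_spot_count": ("Beams", "scan_spot_count"),
    "sim_study_date": ("Plans", "sim_study_date"),
    "ssd": ("Beams", "ssd"),
    "total_mu": ("Plans", "total_mu"),
    "tx_time": ("Plans", "tx_time"),
    "ptv_overlap": ("DVHs", "ptv_overlap"),
}


@dataclass
class QueryFilter:
    """Declarative sample definition.

    ``selection`` pairs repeat a category to OR values together; distinct
    categories AND.  ``range_filters`` are inclusive [min, max] bounds.
    At most eight endpoint specs may ride along for downstream tables.
    """

    selection: list[tuple[str, object]] = field(default_factory=list)
    range_filters: list[tuple[str, float, float]] = field(default_factory=list)
    endpoints: list = field(default_factory=list)
    group: int = 1

    def __post_init__(self) -> None:
        if len(self.endpoints) > 8:
            raise ValueError("at most 8 endpoints per query")
        for cat, _ in self.selection:
            if cat not in SELECTION_CATEGORIES:
                raise ValueError(
                    f"unknown selection category {cat!r}; options: "
                    + ", ".join(sorted(SELECTION_CATEGORIES))
                )
        for cat, _, _ in self.range_filters:
            if cat not in RANGE_CATEGORIES:
                raise ValueError(
                    f"unknown range category {cat!r}; options: "
                    + ", ".join(sorted(RANGE_CATEGORIES))
                )


@dataclass
class RecordSample:
    """Joined query result: DVH rows with plan context, plus the matching
    plan/rx/beam frames."""

    dvhs: pd.DataFrame
    plans: pd.DataFrame
    rxs: pd.DataFrame
    beams: pd.DataFrame

    @property
    def study_uids(self) -> list[str]:
        return sorted(self.plans["study_uid"].unique())


def execute_query(db: DvhDatabase, f: QueryFilter) -> RecordSample:
    """Run a declarative filter against the store.

    Repeated selection categories OR; distinct categories AND; range
    bounds are inclusive.  Conditions on plan/rx/beam columns constrain
    the set of matching (mrn, study_uid) pairs; DVH-level conditions also
    filter individual DVH rows.  Results are insertion-order independent.
    """
    frames = {t: db.table_df(t) for t in ("Plans", "DVHs", "Rxs", "Beams")}

    def _keys(df: pd.DataFrame) -> pd.Index:
        return pd.MultiIndex.from_frame(df[["mrn", "study_uid"]])

    allowed = set(_keys(frames["Plans"]))
    dvh_mask = pd.Series(True, index=frames["DVHs"].index)

    # selection: OR within a repeated category, AND across categories
    by_cat: dict[str, list] = {}
    for cat, value in f.selection:
        by_cat.setdefault(cat, []).append(value)
    for cat, values in by_cat.items():
        table, column = SELECTION_CATEGORIES[cat]
        df = frames[table]
        norm = [int(v) if isinstance(v, bool) else v for v in values]
        hit = df[df[column].isin(norm)]
        if table == "DVHs":
            dvh_mask &= frames["DVHs"][column].isin(norm)
        allowed &= set(_keys(hit))

    for cat, lo, hi in f.range_filters:
        table, column = RANGE_CATEGORIES[cat]
        df = frames[table]
        col = df[column]
        in_range = (col >= lo) & (col <= hi)
        if table == "DVHs":
            dvh_mask &= in_range.reindex(frames["DVHs"].index, fill_value=False)
        allowed &= set(_keys(df[in_range]))

    def _restrict(df: pd.DataFrame) -> pd.DataFrame:
        keys = _keys(df)
        return df[[k in allowed for k in keys]].reset_index(drop=True)

    dvhs = frames["DVHs"][dvh_mask]
    dvhs = _restrict(dvhs)
    plans = _restrict(frames["Plans"])
    dvhs = dvhs.merge(
        plans[["mrn", "study_uid", "rx_dose", "physician", "tx_site", "sim_study_date"]],
        on=["mrn", "study_uid"],
        how="left",
        suffixes=("", "_plan"),
    ).sort_values(["mrn", "study_uid", "roi_name"]).reset_index(drop=True)
    return RecordSample(
        dvhs=dvhs,
        plans=plans.sort_values(["mrn", "study_uid"]).reset_index(drop=True),
        rxs=_restrict(frames["Rxs"]),
        beams=_restrict(frames["Beams"]),
    )


def export_query_csv(sample: RecordSample, out_dir: Path | str, prefix: str = "query") -> list[Path]:
    """Write one CSV per table view of a query result."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (
        ("dvhs", sample.dvhs),
        ("plans", sample.plans),
        ("rxs", sample.rxs),
        ("beams", sample.beams),
    ):
        p = out_dir / f"{prefix}_{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return paths
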