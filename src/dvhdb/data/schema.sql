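-- Five-table schema: plans, prescriptions, beams, DVHs, file catalog.
-- Portable ANSI DDL; generated from dvhdb.db.ddl_statements().

CREATE TABLE IF NOT EXISTS Plans (
  mrn TEXT NOT NULL,
  study_uid TEXT NOT NULL,
  import_timestamp TEXT,
  age_at_study INTEGER,
  baseline INTEGER DEFAULT 0,
  birthdate TEXT,
  dose_grid_resolution TEXT,
  dose_timestamp TEXT,
  fractions INTEGER,
  heterogeneity_correction TEXT,
  total_mu REAL,
  patient_sex TEXT,
  patient_orientation TEXT,
  physician TEXT,
  plan_timestamp TEXT,
  rx_dose REAL,
  sim_study_date TEXT,
  structure_timestamp TEXT,
  tps_manufacturer TEXT,
  tps_name TEXT,
  tps_version TEXT,
  tx_modality TEXT,
  tx_site TEXT,
  tx_time REAL,
  PRIMARY KEY (mrn, study_uid)
);

CREATE TABLE IF NOT EXISTS DVHs (
  mrn TEXT NOT NULL,
  study_uid TEXT NOT NULL,
  import_timestamp TEXT,
  roi_name TEXT NOT NULL,
  roi_type TEXT,
  institutional_roi TEXT,
  physician_roi TEXT,
  roi_volume REAL,
  min_dose REAL,
  mean_dose REAL,
  max_dose REAL,
  dist_min REAL,
  dist_mean REAL,
  dist_median REAL,
  dist_max REAL,
  ptv_overlap REAL,
  dvh_bin_width REAL,
  dvh TEXT,
  roi_coordinates TEXT,
  UNIQUE (mrn, study_uid, roi_name)
);

CREATE TABLE IF NOT EXISTS Rxs (
  mrn TEXT NOT NULL,
  study_uid TEXT NOT NULL,
  import_timestamp TEXT,
  fxs INTEGER,
  fx_dose REAL,
  fx_group_name TEXT,
  fx_group_number INTEGER,
  fx_group_count INTEGER,
  norm_method TEXT,
  norm_object TEXT,
  rx_dose REAL,
  rx_percent REAL
);

CREATE TABLE IF NOT EXISTS Beams (
  mrn TEXT NOT NULL,
  study_uid TEXT NOT NULL,
  import_timestamp TEXT,
  beam_name TEXT,
  beam_number INTEGER,
  beam_dose REAL,
  beam_mu REAL,
  mu_per_degree REAL,
  mu_per_control_point REAL,
  control_point_count INTEGER,
  energy_min REAL,
  energy_max REAL,
  radiation_type TEXT,
  beam_type TEXT,
  fx_count INTEGER,
  fx_group_beam_count INTEGER,
  fx_group_number INTEGER,
  gantry_start REAL,
  gantry_end REAL,
  gantry_min REAL,
  gantry_max REAL,
  gantry_range REAL,
  collimator_start REAL,
  collimator_end REAL,
  collimator_min REAL,
  collimator_max REAL,
  collimator_range REAL,
  couch_start REAL,
  couch_end REAL,
  couch_min REAL,
  couch_max REAL,
  couch_range REAL,
  isocenter TEXT,
  scan_spot_count INTEGER,
  scan_mode TEXT,
  ssd REAL,
  treatment_machine TEXT
);

CREATE TABLE IF NOT EXISTS DICOM_Files (
  mrn TEXT NOT NULL,
  study_uid TEXT NOT NULL,
  folder TEXT,
  plan_file TEXT,
  structure_file TEXT,
  dose_file TEXT,
  UNIQUE (study_uid)
);
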