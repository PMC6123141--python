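# Methods

This note documents the models, conventions, and numerical choices
behind `dvhdb`, and what the synthetic phantoms do and do not establish
about behaviour on clinical data.

## Data model and assumptions

One treatment course is represented by one *composite* plan: a single
RT Plan / RT Structure Set / RT Dose trio sharing a study-instance UID,
covering all boosts. When a directory holds several instances of one
modality for a study, the instance with the latest timestamp wins
(DICOM instance-creation date+time, falling back to file modification
time when the tag is absent; ties break on file path so discovery is
order-independent). Groups missing any of the three modalities are
reported, never silently imported. A second plan arriving for an
already-imported study UID is refused outright — the duplicate guard
exists to flag probable data-duplication accidents, and re-import after
deliberate deletion is the supported path.

Three pieces of information commonly missing from DICOM exports are
handled by convention: the treatment site comes from a point of
interest named `tx: <site>` when present (case-insensitive,
whitespace-tolerant), otherwise the plan label; any structure whose
name begins with `ITV` is typed ITV regardless of the file's
interpreted type; and free-text ROI names are resolved through
per-physician mapping files (below).

## DVH computation

Structures are rasterized by **voxel-centre membership**: a voxel
belongs to a structure iff its centre lies inside the structure's
planar region on the dose-grid plane nearest the contour's z (slices
farther than half the local plane spacing from every plane are
skipped). Within a slice, rings are folded in stored order — a ring
inside the cumulative region subtracts (a hole), a ring outside adds
(an island) — which reproduces the DICOM contour convention for ring
and paired-organ structures. No partial-volume weighting is applied, so
computed volumes carry an O(h) boundary error in the grid spacing h and
converge to the true volume as the grid is refined; at 2 mm a 25 mm
sphere is recovered to well under 3 %.

The differential DVH bins voxel volumes at a fixed width (default
**0.01 Gy**, configurable; the choice trades memory against endpoint
resolution and is far below clinically meaningful dose differences).
The cumulative DVH at bin b is the volume at dose ≥ b·Δ. Endpoints are
evaluated by linear interpolation along the cumulative curve, with ties
on flat segments broken toward the higher dose; a D-endpoint on a
perfectly uniform structure therefore reads within one bin width of the
exact dose. Mean dose is volume-weighted over voxels.

## Geometry

All PTV-typed structures are merged per slice by polygon union into a
combined PTV. Overlap volume is Σ slice-intersection-area × slice
thickness; thickness is the forward gap to the adjacent slice, with the
last slice reusing the previous gap (the adjacent-slice side is
otherwise arbitrary and irrelevant on the uniform spacings produced by
CT simulation). A single-slice structure falls back to the PTV's median
spacing with a warning. Surface distances are the brute-force pairwise
3-D distances between the two boundary vertex sets, summarized by min /
mean / median / max and reported in cm. Boundary points are the contour
vertices as stored (an optional `densify_mm` re-samples segments); the
resolution of `dist_min` is therefore one vertex spacing — phantom
contours are generated at ≤ 1 mm spacing for this reason. A guard
refuses more than 10⁷ point pairs unless forced, because external/skin
contours can exhaust memory; those ROI types are skipped by default and
computed only on request.

Self-intersecting rings are repaired by zero-buffer cleaning;
irreparable rings are dropped with a warning. z keys are snapped to
10⁻³ mm before slice matching. All geometry is internal-mm; overlap is
stored in cm³ and distances in cm.

## Radiobiology

gEUD is the power mean of the differential DVH with bin-centre doses,
evaluated in log space so exponents of ±1000 remain stable. a = 1 gives
the (binned) mean dose exactly; a → ±∞ approach max/min dose at the
n^(−1/a) rate inherent to finite power means. NTCP/TCP use the logistic
dose–response 1/(1+(D₅₀/EUD)^(4γ₅₀)), which is exactly 0.5 at the
midpoint dose and strictly increasing in EUD. No fractionation (EQD)
correction is applied by default — composite-plan doses are used as
summed; `eqd_correction` is an explicit opt-in hook for users whose
tolerance parameters assume 2-Gy fractions. The shipped preset table
(`data/organ_presets.txt`) holds representative literature-derived
organ parameters and is deliberately a plain editable text file: users
are expected to substitute their own values.

## ROI name management

Names are normalized (lowercase; runs of non-alphanumerics collapsed to
one space; trimmed) before lookup, which absorbs the common "L Eye /
Orbit left / eye l" style of variation without any fuzzy matching —
unknown names stay uncategorized rather than being guessed. Variations
map to a physician ROI, which rolls up to an institutional ROI; an
ignore list removes optimization shells and the like from the
uncategorized listing. Mappings persist as per-physician TSV files so
they diff cleanly, and re-categorization touches only database rows,
never DICOM files. Multiple PTVs are labelled PTV1..PTVn by
**descending** D₉₅% (the highest-dose target first; the sort key is a
convention, the direction a design choice), with ties broken by larger
volume then name.

## Database and query semantics

The five tables (Plans, Rxs, Beams, DVHs, file catalog) are linked by
MRN + study UID. The default engine is SQLite with portable ANSI DDL
(also shipped as `data/schema.sql`); a server RDBMS can host the same
schema. DVH curves are serialized as comma-separated cumulative volumes
at the stored bin width and contours as per-slice `z: x,y;x,y;…` text —
`repr` precision makes both round-trips bit-identical. Imports are
all-or-nothing transactions sharing one import timestamp. Query
filters: repeated selection categories OR their values, distinct
categories AND, range bounds are inclusive; results are independent of
insertion order.

## Analytics

Cohort DVH bands resample every curve onto a common dose axis (0 to the
sample's largest maximum; volume beyond a curve's own maximum is zero)
and take per-bin mean / median / percentiles; relative mode divides
each curve by its own volume first. The time-series moving average at a
point is the mean of all non-excluded values whose date lies in a
look-back window counted in **distinct simulation dates**, not calendar
days; excluded indices drop out of the moving average, percentile band,
and sample mean. Group comparison uses the Welch (unequal-variance)
two-sample t-test — the safer default when variances are unknown — the
Wilcoxon rank-sum test (exact enumeration for groups of ≤ 8, otherwise
tie-corrected normal approximation), and Shapiro–Wilk normality per
group (undefined for constant samples). Correlations are Pearson R with
pairwise-complete deletion (≥ 3 cases per pair); regressions are OLS
with listwise deletion, reporting slope/intercept/R²/p/SE/n for the
univariable case and per-coefficient p, R², and the F-probability for
the multivariable case. No multiple-testing correction is applied: the
matrices are exploratory screens, not confirmatory inference.

## Synthetic phantoms: what they show and what they do not

The fixtures module emulates what matters to this pipeline: valid RT
Plan / Structure Set / Dose objects with scaled 16-bit dose grids,
frame-offset vectors, multi-fraction-group prescriptions, arcs with
control points, brachytherapy metadata, `tx:` POIs, and densely
contoured analytic shapes (vertex spacing ≤ 1 mm) including ring and
island structures that pin the contour convention. Default study
conditions — 2 mm cubic grids, 60 Gy in 30 fractions, head-and-neck
style structure sizes — are typical of clinical practice. All
randomness is seeded; a fixed seed gives byte-stable files.

The phantoms do **not** model CT image series, irregular slice
spacings, TPS-specific private tags, contour digitization noise, or
anatomically realistic dose falloff. Passing tests therefore establish
the correctness of the computations and conventions, and the
grid-resolution behaviour of the rasterizer — not robustness to every
vendor's DICOM dialect.

Problem sizes in the test-suite and acceptance script (grids up to
64×72×72 voxels, ten seeded phantoms per oracle check, n = 500
regressions) were chosen so the full suite completes in well under a
minute while leaving every check's verdict unambiguous.

## Known limitations

* Volumes inherit the dose grid's resolution; no contour supersampling
  or partial-volume weighting.
* Surface distances measure stored vertices; a coarse contour bounds
  the achievable precision (densification is available but off by
  default to match the stored-surface semantics).
* `dist_min` between interleaved slice stacks reflects slice
  discretization in z, like any contour-based measure.
* No DICOM networking: files must already be on disk.
* The query layer loads matching tables into pandas; it targets
  clinic-scale (10³–10⁵ plan) databases, not population registries.
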