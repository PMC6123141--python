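"""Sample-level analytics: DVH band aggregation, endpoint tables,
time-series with moving averages, two-group tests, correlation matrices,
and linear regressions.

These operate on query results (lists of DVHs plus per-plan scalars) and
mirror what a clinic would look at: interquartile DVH bands for a cohort,
endpoint tables (D_x / V_x per structure), temporal trends across
simulation dates with a look-back moving average, and exploratory
statistics (Welch t-test, Wilcoxon rank-sum, Shapiro-Wilk normality,
Pearson correlation matrices, univariable and multivariable OLS).

No multiple-testing correction is applied: matrix p-values are raw and
meant for exploratory screening, not confirmatory inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from dvhdb.dvh import DoseVolumeHistogram, EndpointSpec, evaluate_endpoint

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# DVH bands
# ---------------------------------------------------------------------------


@dataclass
class DvhBands:
    dose_axis: np.ndarray  # Gy
    mean: np.ndarray
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    relative: bool = False  # per-bin % of each ROI volume instead of cm^3


def _resample(dvh: DoseVolumeHistogram, axis: np.ndarray) -> np.ndarray:
    """Cumulative volume of one DVH on a common dose axis, zero beyond max."""
    edges = dvh.dose_edges
    out = np.interp(axis, edges, dvh.cumulative, right=0.0)
    out[axis > edges[-1]] = 0.0
    return out


def aggregate_dvhs(
    sample: Sequence[DoseVolumeHistogram],
    percentiles: tuple[float, float] = (25.0, 75.0),
    relative: bool = False,
    bin_width: Optional[float] = None,
) -> DvhBands:
    """Per-bin mean / median / percentile bands across a DVH sample.

    Curves are resampled onto a common dose axis from 0 to the largest
    maximum dose in the sample; beyond a curve's own maximum its volume is
    zero.  In relative mode each curve is first divided by its own volume
    (per-bin values in %).
    """
    if not sample:
        raise ValueError("empty DVH sample")
    bw = bin_width or min(d.bin_width for d in sample)
    top = max(d.dose_edges[-1] for d in sample)
    axis = np.arange(0.0, top + bw, bw)
    curves = np.vstack([_resample(d, axis) for d in sample])
    if relative:
        curves = 100.0 * curves / np.array([d.volume for d in sample])[:, None]
    lo, hi = percentiles
    return DvhBands(
        dose_axis=axis,
        mean=curves.mean(axis=0),
        median=np.median(curves, axis=0),
        q1=np.percentile(curves, lo, axis=0),
        q3=np.percentile(curves, hi, axis=0),
        relative=relative,
    )


# ---------------------------------------------------------------------------
# Endpoint table
# ---------------------------------------------------------------------------


def endpoint_table(
    sample: Sequence[dict],
    specs: Sequence[EndpointSpec],
) -> pd.DataFrame:
    """One row per ROI with identifying columns and one column per endpoint.

    ``sample`` entries are dicts carrying at least ``mrn``, ``roi_name``
    and a :class:`DoseVolumeHistogram` under ``dvh``; optional context
    (rx_dose, dist_min, ptv_overlap, roi names) is passed through.
    """
    if len(specs) > 8:
        raise ValueError("at most 8 endpoints per query")
    rows = []
    for entry in sample:
        dvh: DoseVolumeHistogram = entry["dvh"]
        row = {
            "mrn": entry.get("mrn"),
            "roi_name": entry.get("roi_name"),
            "institutional_roi": entry.get("institutional_roi"),
            "physician_roi": entry.get("physician_roi"),
            "rx_dose": entry.get("rx_dose", dvh.rx_dose),
            "volume": dvh.volume,
            "min_dose": dvh.min_dose,
            "mean_dose": dvh.mean_dose,
            "max_dose": dvh.max_dose,
            "dist_min": entry.get("dist_min"),
            "ptv_overlap": entry.get("ptv_overlap"),
        }
        for spec in specs:
            row[spec.label] = evaluate_endpoint(dvh, spec)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesResult:
    dates: np.ndarray
    values: np.ndarray
    moving_average: np.ndarray
    band_low: float
    band_high: float
    sample_mean: float
    excluded: set = field(default_factory=set)


def time_series(
    dates: Sequence,
    values: Sequence[float],
    lookback_window: int = 6,
    bounds: tuple[float, float] = (5.0, 95.0),
    excluded: Optional[set[int]] = None,
) -> TimeSeriesResult:
    """Trend of a variable over simulation dates.

    The moving average at a point is the mean of all non-excluded values
    whose date falls within the look-back window ending at that point's
    date — the window is counted in *distinct simulation dates*, not
    calendar days.  ``excluded`` indexes are removed from the moving
    average, the percentile band, and the sample mean.
    """
    excluded = excluded or set()
    dates = np.asarray(dates)
    values = np.asarray(values, dtype=float)
    order = np.argsort(dates, kind="stable")
    dates, values = dates[order], values[order]
    excluded_sorted = {int(np.nonzero(order == i)[0][0]) for i in excluded}
    keep = np.array([i not in excluded_sorted for i in range(len(values))])
    if not keep.any():
        raise ValueError("no data left after exclusion")

    distinct = np.unique(dates)
    date_rank = {d: r for r, d in enumerate(distinct)}
    ranks = np.array([date_rank[d] for d in dates])

    ma = np.full(len(values), np.nan)
    for i in range(len(values)):
        lo_rank = ranks[i] - lookback_window + 1
        in_win = (ranks >= lo_rank) & (ranks <= ranks[i]) & keep
        if in_win.any():
            ma[i] = values[in_win].mean()

    kept = values[keep]
    lo, hi = bounds
    return TimeSeriesResult(
        dates=dates,
        values=values,
        moving_average=ma,
        band_low=float(np.percentile(kept, lo)),
        band_high=float(np.percentile(kept, hi)),
        sample_mean=float(kept.mean()),
        excluded=excluded_sorted,
    )


# ---------------------------------------------------------------------------
# Two-group tests
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    p_ttest: float
    p_wilcoxon: float
    p_normality_g1: Optional[float]
    p_normality_g2: Optional[float]


def _shapiro_p(x: np.ndarray) -> Optional[float]:
    if np.ptp(x) == 0:
        return None  # constant sample: normality undefined
    return float(stats.shapiro(x).pvalue)


def compare_groups(g1: Sequence[float], g2: Sequence[float]) -> GroupComparison:
    """Welch two-sample t-test, Wilcoxon rank-sum, and per-group
    Shapiro-Wilk normality p-values.

    The rank-sum test uses exact enumeration for groups of at most 8
    values each, otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        p_t = 1.0
    else:
        p_t = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    method = "exact" if (len(a) <= 8 and len(b) <= 8) else "asymptotic"
    p_w = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    return GroupComparison(
        p_ttest=p_t,
        p_wilcoxon=p_w,
        p_normality_g1=_shapiro_p(a),
        p_normality_g2=_shapiro_p(b),
    )


# ---------------------------------------------------------------------------
# Correlation matrix
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: np.ndarray
    p: np.ndarray


def correlation_matrix(data: pd.DataFrame, variables: Sequence[str]) -> CorrelationMatrix:
    """Pairwise Pearson R and two-sided p over pairwise-complete cases.

    Pairs with fewer than 3 complete cases get NaN in both matrices.
    """
    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, k):
            x = pd.to_numeric(data[variables[i]], errors="coerce")
            y = pd.to_numeric(data[variables[j]], errors="coerce")
            ok = x.notna() & y.notna()
            if ok.sum() < 3:
                continue
            res = stats.pearsonr(x[ok], y[ok])
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    return CorrelationMatrix(variables=list(variables), r=r, p=p)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------


@dataclass
class UnivariableFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    std_err: float
    n: int


@dataclass
class MultivariableFit:
    coefficients: dict[str, float]
    p_values: dict[str, float]
    intercept: float
    intercept_p: float
    r_squared: float
    f_prob: float
    n: int


def fit_univariable(x: Sequence[float], y: Sequence[float]) -> UnivariableFit:
    """Ordinary least squares of y on a single predictor."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("univariable regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    res = stats.linregress(x, y)
    return UnivariableFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        std_err=float(res.stderr),
        n=len(x),
    )


def fit_multivariable(X: pd.DataFrame, y: Sequence[float]) -> MultivariableFit:
    """OLS with intercept on tagged predictors; listwise deletion.

    Reports per-coefficient p-values, R^2, and the F-statistic
    probability.  Exactly collinear designs are refused, naming the
    dependent columns.
    """
    X = pd.DataFrame(X).apply(pd.to_numeric, errors="coerce")
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    ok = X.notna().all(axis=1) & y.notna()
    X, y = X[ok], y[ok]
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"need more than {k + 1} observations for {k} predictors")
    design = sm.add_constant(X.to_numpy(), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # identify which columns are linearly dependent on the rest
        bad = []
        for j, name in enumerate(X.columns):
            others = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(design):
                bad.append(str(name))
        raise ValueError(f"collinear design; dependent columns: {', '.join(bad) or 'constant'}")
    model = sm.OLS(y.to_numpy(), design).fit()
    names = list(X.columns)
    return MultivariableFit(
        coefficients={name: float(model.params[i + 1]) for i, name in enumerate(names)},
        p_values={name: float(model.pvalues[i + 1]) for i, name in enumerate(names)},
        intercept=float(model.params[0]),
        intercept_p=float(model.pvalues[0]),
        r_squared=float(model.rsquared),
        f_prob=float(model.f_pvalue),
        n=int(model.nobs),
    )
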