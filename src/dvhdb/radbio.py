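"""Radiobiological metrics: generalized equivalent uniform dose (gEUD),
tumor control probability (TCP), and normal-tissue complication
probability (NTCP).

The gEUD is the power mean of the differential DVH,

    EUD = ( sum_i v_i * D_i^a )^(1/a)

with v_i the fractional volume of bin i (sum v_i = 1), D_i the bin-centre
dose, and ``a`` a tissue-specific exponent: a = 1 gives the mean dose,
large positive ``a`` approaches the maximum dose (serial organs), large
negative ``a`` the minimum dose (targets, parallel organs).

Response probabilities use the logistic dose-response on EUD:

    NTCP = 1 / (1 + (TD50 / EUD)^(4*gamma50))
    TCP  = 1 / (1 + (TCD50 / EUD)^(4*gamma50))

where TD50 / TCD50 is the dose producing 50% response and gamma50 the
normalized slope at that point.  A small table of published organ
tolerance parameters ships as an editable plain-text preset file; users
are expected to supply their own values where appropriate.

No fractionation (EQD) correction is applied by default: doses are used
as summed in the composite plan.  ``eqd_correction`` is available as an
explicit pre-processing hook for users who want per-fraction scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from dvhdb.dvh import DoseVolumeHistogram

log = logging.getLogger(__name__)


@dataclass
class RadBioParams:
    a: float  # gEUD exponent
    td50_or_tcd50: float  # Gy
    gamma50: float  # normalized slope
    preset_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("gEUD exponent a must be nonzero")
        if self.td50_or_tcd50 <= 0:
            raise ValueError("TD50/TCD50 must be positive")
        if self.gamma50 <= 0:
            raise ValueError("gamma50 must be positive")


@dataclass
class RadBioResult:
    eud: float
    tcp: Optional[float] = None
    ntcp: Optional[float] = None


def compute_eud(dvh: DoseVolumeHistogram, a: float) -> float:
    """Generalized EUD of a DVH: power mean of bin-centre doses with
    fractional-volume weights."""
    if a == 0:
        raise ValueError("gEUD exponent a must be nonzero")
    if dvh.volume <= 0:
        raise ValueError("DVH has zero volume")
    v = dvh.diff_counts / dvh.volume
    d = dvh.bin_centers
    nz = v > 0
    v, d = v[nz], d[nz]
    # compute in log space for numerical stability at large |a|
    with np.errstate(divide="ignore"):
        logd = np.log(np.where(d > 0, d, 1.0))
    if np.any(d <= 0):
        if a < 0:
            return 0.0  # any zero-dose volume pins the negative-exponent mean at 0
        v = v[d > 0]
        logd = logd[d > 0]
    m = np.max(a * logd)
    eud = np.exp((m + np.log(np.sum(v * np.exp(a * logd - m)))) / a)
    return float(eud)


def _logistic(eud: float, d50: float, gamma50: float) -> float:
    if eud <= 0:
        log.warning("non-positive EUD %.3g: response probability set to 0", eud)
        return 0.0
    return float(1.0 / (1.0 + (d50 / eud) ** (4.0 * gamma50)))


def compute_ntcp(eud: float, p: RadBioParams) -> float:
    """Normal-tissue complication probability at the given EUD."""
    return _logistic(eud, p.td50_or_tcd50, p.gamma50)


def compute_tcp(eud: float, p: RadBioParams) -> float:
    """Tumor control probability at the given EUD (TCD50 midpoint)."""
    return _logistic(eud, p.td50_or_tcd50, p.gamma50)


def compute_radbio(dvh: DoseVolumeHistogram, p: RadBioParams, target: bool = False) -> RadBioResult:
    eud = compute_eud(dvh, p.a)
    if target:
        return RadBioResult(eud=eud, tcp=compute_tcp(eud, p))
    return RadBioResult(eud=eud, ntcp=compute_ntcp(eud, p))


def eqd_correction(dvh: DoseVolumeHistogram, n_fractions: int, alpha_beta: float) -> DoseVolumeHistogram:
    """Optional per-fraction equivalent-dose (EQD2-style) rescaling hook.

    Rescales each bin-centre dose D to D * (alpha_beta + D/n) / (alpha_beta + 2)
    before radiobiological evaluation.  Off by default everywhere; provided
    for users whose tolerance parameters assume 2-Gy fractions.
    """
    d = dvh.bin_centers
    scale = (alpha_beta + d / n_fractions) / (alpha_beta + 2.0)
    d_eq = d * scale
    # rebin onto the original bin width
    bins = np.floor(d_eq / dvh.bin_width + 1e-9).astype(int)
    diff = np.bincount(bins, weights=dvh.diff_counts, minlength=int(bins.max()) + 2)
    cumulative = np.cumsum(diff[::-1])[::-1]
    return DoseVolumeHistogram(
        bin_width=dvh.bin_width,
        diff_counts=diff,
        cumulative=cumulative,
        volume=dvh.volume,
        min_dose=float(dvh.min_dose * scale[np.searchsorted(d, dvh.min_dose)] if len(d) else 0.0),
        mean_dose=float(np.sum(diff * ((np.arange(len(diff)) + 0.5) * dvh.bin_width)) / dvh.volume),
        max_dose=float(d_eq.max() if len(d_eq) else 0.0),
        rx_dose=dvh.rx_dose,
    )


def load_presets(path: Optional[Path] = None) -> dict[str, RadBioParams]:
    """Load organ tolerance presets from a plain-text table.

    Format: one organ per line, whitespace-separated columns
    ``organ  a  td50_gy  gamma50``; ``#`` starts a comment.  Defaults to
    the table shipped with the package.
    """
    if path is None:
        text = resources.files("dvhdb").joinpath("data/organ_presets.txt").read_text()
    else:
        text = Path(path).read_text()
    presets: dict[str, RadBioParams] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"bad preset line: {line!r}")
        organ, a, td50, g50 = parts
        presets[organ] = RadBioParams(
            a=float(a), td50_or_tcd50=float(td50), gamma50=float(g50), preset_name=organ
        )
    return presets
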