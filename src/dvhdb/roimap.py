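"""ROI name management: mapping free-text structure names onto curated
categories.

Clinics rarely name structures consistently ("L Eye", "Orbit left",
"eye l" ...).  Each physician gets a mapping from normalized name
variations to a *physician ROI*, and each physician ROI rolls up to an
*institutional ROI* (or stays uncategorized).  Names can also be ignored
outright (optimization shells etc.) so they stop appearing in the
uncategorized listing.  Mappings persist as per-physician tab-separated
text files so they diff cleanly under version control.

Multiple planning target volumes in one plan are relabelled PTV1..PTVn
ordered by their D_95% (highest first).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from dvhdb.dvh import DoseVolumeHistogram, EndpointSpec, dose_at_volume

UNCATEGORIZED = "uncategorized"
IGNORED = "ignored"

_NORM_RE = re.compile(r"[^a-z0-9]+")


def normalize(name: str) -> str:
    """Lowercase, collapse every non-alphanumeric run to one space, trim."""
    return _NORM_RE.sub(" ", name.lower()).strip()


@dataclass
class RoiMapping:
    physician: str
    entries: dict[str, str] = field(default_factory=dict)  # variation -> physician_roi
    rollup: dict[str, str] = field(default_factory=dict)  # physician_roi -> institutional_roi
    ignored: set[str] = field(default_factory=set)


def categorize_roi(m: RoiMapping, raw_name: str) -> tuple[str, str]:
    """Resolve a raw structure name to (institutional_roi, physician_roi).

    Unknown names come back as (uncategorized, uncategorized); ignored
    names as (ignored, ignored).  Unknown is a valid outcome — names are
    never guessed.
    """
    key = normalize(raw_name)
    if key in m.ignored:
        return (IGNORED, IGNORED)
    phys = m.entries.get(key)
    if phys is None:
        return (UNCATEGORIZED, UNCATEGORIZED)
    return (m.rollup.get(phys, UNCATEGORIZED), phys)


def manage_variation(
    m: RoiMapping,
    action: str,
    variation: str,
    physician_roi: Optional[str] = None,
    institutional_roi: Optional[str] = None,
) -> RoiMapping:
    """Add, ignore, or unignore a name variation (in place; returns ``m``).

    ``add`` requires a target physician ROI; adding a variation already
    mapped to a *different* physician ROI is a conflict and raises.
    """
    key = normalize(variation)
    if action == "add":
        if physician_roi is None:
            raise ValueError("add requires a physician_roi")
        existing = m.entries.get(key)
        if existing is not None and existing != physician_roi:
            raise ValueError(
                f"variation {variation!r} already maps to {existing!r}, not {physician_roi!r}"
            )
        m.entries[key] = physician_roi
        m.ignored.discard(key)
        if physician_roi not in m.rollup:
            m.rollup[physician_roi] = institutional_roi or UNCATEGORIZED
        elif institutional_roi is not None:
            m.rollup[physician_roi] = institutional_roi
    elif action == "ignore":
        if key in m.entries:
            raise ValueError(f"variation {variation!r} is mapped; remove the mapping first")
        m.ignored.add(key)
    elif action == "unignore":
        m.ignored.discard(key)
    else:
        raise ValueError(f"unknown action {action!r}")
    return m


def order_ptvs(
    ptv_dvhs: Sequence[tuple[str, DoseVolumeHistogram]],
) -> dict[str, str]:
    """Label PTVs PTV1..PTVn by descending D_95%.

    Ties break by larger volume, then lexicographic name, so the labels
    are always a bijection onto PTV1..PTVn.
    """
    if not ptv_dvhs:
        raise ValueError("no PTV provided")
    spec = EndpointSpec(kind="D", value=95, value_units="%")
    keyed = [
        (-dose_at_volume(dvh, spec), -dvh.volume, name) for name, dvh in ptv_dvhs
    ]
    return {name: f"PTV{rank + 1}" for rank, (_, _, name) in enumerate(sorted(keyed))}


# ---------------------------------------------------------------------------
# Persistence: per-physician TSV files
# ---------------------------------------------------------------------------


def save_mapping(m: RoiMapping, directory: Path | str) -> Path:
    """Write ``<directory>/<physician>.roimap.tsv``: one line per variation
    (variation TAB physician_roi TAB institutional_roi) plus ``!ignore``
    lines for the ignore list."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{m.physician}.roimap.tsv"
    lines = []
    for variation in sorted(m.entries):
        phys = m.entries[variation]
        inst = m.rollup.get(phys, UNCATEGORIZED)
        lines.append(f"{variation}\t{phys}\t{inst}")
    for variation in sorted(m.ignored):
        lines.append(f"!ignore\t{variation}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def load_mapping(physician: str, directory: Path | str) -> RoiMapping:
    """Load a physician's mapping; a missing file yields an empty mapping."""
    path = Path(directory) / f"{physician}.roimap.tsv"
    m = RoiMapping(physician=physician)
    if not path.exists():
        return m
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if parts[0] == "!ignore":
            m.ignored.add(normalize(parts[1]))
        else:
            variation, phys, inst = parts[0], parts[1], parts[2]
            m.entries[normalize(variation)] = phys
            m.rollup[phys] = inst
    return m
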