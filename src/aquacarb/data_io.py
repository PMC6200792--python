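"""Dataset schema, validation, grouping, and result serialization.

The unit of data is a single literature-derived measurement of modern
organic-carbon accumulation rate (g C m⁻² y⁻¹) in an aquatic ecosystem,
with an optional reported standard deviation and categorical labels
(ecosystem category, salinity class, inundation class).  Raw ecosystem
names from the literature are mapped onto seven hydrologically relevant
categories through a user-supplied grouping config, because sparse raw
types (e.g. fjords) are folded into a larger category before analysis.

CSV conventions: UTF-8, comma-separated, header row required, ``""`` or
``"NA"`` (case-insensitive, also ``NaN``/``None``/``null``) denote
missing values.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

ECOSYSTEM_CATEGORIES: tuple[str, ...] = (
    "lake",
    "reservoir",
    "inland_wetland",
    "coastal_wetland",
    "lagoon",
    "mangrove",
    "continental_shelf",
)
SALINITY_CLASSES: tuple[str, ...] = ("fresh", "brackish", "saline")
INUNDATION_CLASSES: tuple[str, ...] = ("permanent", "seasonal", "tidal")
GROUPING_VARIABLES: tuple[str, ...] = (
    "ecosystem_category",
    "salinity_class",
    "inundation_class",
)
SD_SOURCES: tuple[str, ...] = ("reported", "imputed", "missing")

#: Tokens interpreted as missing in CSV cells (after strip + lower-case).
MISSING_TOKENS = frozenset({"", "na", "nan", "none", "null"})

REQUIRED_COLUMNS = ("study_id", "site_id", "rate")
OPTIONAL_COLUMNS = (
    "sd",
    "sd_source",
    "ecosystem_raw",
    "ecosystem_category",
    "salinity_class",
    "inundation_class",
    "latitude",
    "longitude",
    "restored",
    "record_span_years",
)
ALL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS


class SchemaError(ValueError):
    """The input table is missing a required column."""


class EmptyGroupingError(ValueError):
    """No measurement carries the requested grouping label."""


@dataclass(frozen=True)
class RateMeasurement:
    """One literature-derived accumulation-rate observation.

    ``rate`` is the study's reported mean accumulation rate and ``sd``
    its reported (or later imputed) standard deviation, both in
    g C m⁻² y⁻¹.  ``sd_source`` records whether ``sd`` came from the
    study itself, from CV-based imputation, or is still missing.
    """

    study_id: str
    site_id: str
    rate: float
    sd: float | None = None
    sd_source: str = "missing"
    ecosystem_raw: str | None = None
    ecosystem_category: str | None = None
    salinity_class: str | None = None
    inundation_class: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    restored: bool = False
    record_span_years: float | None = None

    def __post_init__(self) -> None:
        if not (self.rate > 0) or not math.isfinite(self.rate):
            raise ValueError(f"rate must be a positive finite number, got {self.rate}")
        if self.sd is not None and (self.sd < 0 or not math.isfinite(self.sd)):
            raise ValueError(f"sd must be non-negative and finite, got {self.sd}")
        if self.sd_source not in SD_SOURCES:
            raise ValueError(f"unknown sd_source {self.sd_source!r}")
        if self.sd is None and self.sd_source != "missing":
            raise ValueError("sd_source must be 'missing' when sd is absent")
        if self.sd is not None and self.sd_source == "missing":
            raise ValueError("sd present but sd_source says 'missing'")
        if self.ecosystem_category is not None and self.ecosystem_category not in ECOSYSTEM_CATEGORIES:
            raise ValueError(f"unknown ecosystem_category {self.ecosystem_category!r}")
        if self.salinity_class is not None and self.salinity_class not in SALINITY_CLASSES:
            raise ValueError(f"unknown salinity_class {self.salinity_class!r}")
        if self.inundation_class is not None and self.inundation_class not in INUNDATION_CLASSES:
            raise ValueError(f"unknown inundation_class {self.inundation_class!r}")
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise ValueError(f"longitude out of range: {self.longitude}")

    def group_label(self, variable: str) -> str | None:
        if variable not in GROUPING_VARIABLES:
            raise ValueError(f"unknown grouping variable {variable!r}")
        return getattr(self, variable)


@dataclass
class LoadReport:
    """Row-level accounting for one dataset load."""

    n_total: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    n_sd_reported: int = 0
    rejections: list[tuple[int, str]] = field(default_factory=list)

    def reject(self, row: int, reason: str) -> None:
        self.n_rejected += 1
        self.rejections.append((row, reason))


@dataclass
class GroupStats:
    n: int
    minimum: float
    maximum: float


@dataclass
class GroupedDataset:
    """Measurements partitioned by one grouping variable.

    Measurements missing the grouping label are excluded from the
    partition (but not from the dataset) and counted in ``n_excluded``.
    """

    grouping_variable: str
    groups: dict[str, list[RateMeasurement]]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for label, rows in self.groups.items():
            if not rows:
                raise ValueError(f"group {label!r} is empty")

    @property
    def n_grouped(self) -> int:
        return sum(len(rows) for rows in self.groups.values())

    def stats(self) -> dict[str, GroupStats]:
        """Per-group n / min / max of the reported rates."""
        return {
            label: GroupStats(
                n=len(rows),
                minimum=min(m.rate for m in rows),
                maximum=max(m.rate for m in rows),
            )
            for label, rows in self.groups.items()
        }

    def stats_frame(self) -> pd.DataFrame:
        rows = [
            {"group": label, "n": s.n, "min": s.minimum, "max": s.maximum}
            for label, s in self.stats().items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Grouping config

def example_grouping() -> dict[str, str]:
    """An illustrative raw-name → category mapping.

    Covers all seven categories plus a handful of raw literature names
    folded into larger hydrologically similar categories (e.g. fjords
    into the continental shelf).  Real analyses should supply their own
    mapping; this one is a documented guess for examples and tests.
    """
    mapping = {c: c for c in ECOSYSTEM_CATEGORIES}
    mapping.update(
        {
            "freshwater lake": "lake",
            "pond": "lake",
            "impoundment": "reservoir",
            "farm pond": "reservoir",
            "freshwater marsh": "inland_wetland",
            "salt marsh": "coastal_wetland",
            "tidal marsh": "coastal_wetland",
            "seagrass meadow": "coastal_wetland",
            "coastal lagoon": "lagoon",
            "mangrove forest": "mangrove",
            "fjord": "continental_shelf",
            "inland sea": "continental_shelf",
            "shelf sea": "continental_shelf",
        }
    )
    return mapping


def load_grouping_config(source: str | Path | Mapping[str, str]) -> dict[str, str]:
    """Load and validate a raw-name → category mapping (YAML file or dict)."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, Mapping) or not raw:
        raise SchemaError("grouping config must be a non-empty mapping")
    mapping: dict[str, str] = {}
    for key, value in raw.items():
        cat = str(value).strip().lower()
        if cat not in ECOSYSTEM_CATEGORIES:
            raise SchemaError(
                f"grouping config maps {key!r} to unknown category {value!r}"
            )
        mapping[str(key).strip().lower()] = cat
    return mapping


# ---------------------------------------------------------------------------
# Reading

def _parse_cell(value: object) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text.lower() in MISSING_TOKENS:
        return None
    return text


def _parse_float(text: str | None, column: str) -> float | None:
    if text is None:
        return None
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"non-numeric {column}: {text!r}") from None


def _parse_bool(text: str | None) -> bool:
    if text is None:
        return False
    return text.strip().lower() in {"1", "true", "yes", "y"}


def read_dataset(
    path: str | Path,
    grouping_config: str | Path | Mapping[str, str] | None = None,
) -> tuple[list[RateMeasurement], LoadReport]:
    """Read and validate a rate-measurement CSV.

    Raw ecosystem names are mapped to the seven categories through
    ``grouping_config``; rows whose raw name has no mapping (and no
    valid ``ecosystem_category`` column) are rejected with a row-level
    diagnostic rather than aborting the whole load.

    Returns the accepted measurements and a :class:`LoadReport` with
    total / accepted / rejected / SD-reported counts.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for column in REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise SchemaError(f"missing required column: {column!r}")
    if "ecosystem_raw" not in frame.columns and "ecosystem_category" not in frame.columns:
        raise SchemaError("missing required column: 'ecosystem_raw' or 'ecosystem_category'")

    mapping = load_grouping_config(grouping_config) if grouping_config is not None else None

    report = LoadReport(n_total=len(frame))
    measurements: list[RateMeasurement] = []
    for idx, row in enumerate(frame.to_dict(orient="records")):
        cells = {col: _parse_cell(row.get(col)) for col in frame.columns}
        try:
            measurement = _row_to_measurement(cells, mapping)
        except ValueError as exc:
            report.reject(idx, str(exc))
            continue
        measurements.append(measurement)
        report.n_accepted += 1
        if measurement.sd_source == "reported":
            report.n_sd_reported += 1
    return measurements, report


def _row_to_measurement(
    cells: Mapping[str, str | None], mapping: Mapping[str, str] | None
) -> RateMeasurement:
    rate = _parse_float(cells.get("rate"), "rate")
    if rate is None:
        raise ValueError("missing rate")

    category = cells.get("ecosystem_category")
    raw = cells.get("ecosystem_raw")
    if category is not None:
        category = category.strip().lower()
        if category not in ECOSYSTEM_CATEGORIES:
            raise ValueError(f"unknown ecosystem_category {category!r}")
    elif raw is not None:
        key = raw.strip().lower()
        if mapping is not None and key in mapping:
            category = mapping[key]
        elif key in ECOSYSTEM_CATEGORIES:
            category = key
        else:
            raise ValueError(f"unmapped ecosystem name {raw!r}")
    else:
        raise ValueError("missing ecosystem_raw / ecosystem_category")

    sd = _parse_float(cells.get("sd"), "sd")
    sd_source = cells.get("sd_source")
    if sd_source is None:
        sd_source = "reported" if sd is not None else "missing"

    return RateMeasurement(
        study_id=cells.get("study_id") or "",
        site_id=cells.get("site_id") or "",
        rate=rate,
        sd=sd,
        sd_source=sd_source,
        ecosystem_raw=raw,
        ecosystem_category=category,
        salinity_class=cells.get("salinity_class"),
        inundation_class=cells.get("inundation_class"),
        latitude=_parse_float(cells.get("latitude"), "latitude"),
        longitude=_parse_float(cells.get("longitude"), "longitude"),
        restored=_parse_bool(cells.get("restored")),
        record_span_years=_parse_float(cells.get("record_span_years"), "record_span_years"),
    )


# ---------------------------------------------------------------------------
# Grouping

def group_by(
    measurements: Sequence[RateMeasurement], variable: str
) -> GroupedDataset:
    """Partition measurements by one grouping variable.

    Rows missing the label are excluded from the partition and counted,
    so that each characteristic (salinity, inundation) is analysed on
    its labeled subset without dropping rows from the dataset at large.
    """
    if variable not in GROUPING_VARIABLES:
        raise ValueError(f"unknown grouping variable {variable!r}")
    groups: dict[str, list[RateMeasurement]] = {}
    n_excluded = 0
    for m in measurements:
        label = m.group_label(variable)
        if label is None:
            n_excluded += 1
            continue
        groups.setdefault(label, []).append(m)
    if not groups:
        raise EmptyGroupingError(
            f"no measurement carries a {variable!r} label ({n_excluded} rows missing it)"
        )
    return GroupedDataset(grouping_variable=variable, groups=groups, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# Writing

def _fmt(value: object) -> object:
    """CSV cell formatting: explicit NA marker instead of silent blanks."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return value


def write_measurements(measurements: Iterable[RateMeasurement], path: str | Path) -> None:
    """Write measurements as schema CSV; ``read_dataset`` round-trips it."""
    rows = []
    for m in measurements:
        record = dataclasses.asdict(m)
        record["restored"] = "true" if m.restored else "false"
        rows.append({col: _fmt(record[col]) for col in ALL_COLUMNS})
    pd.DataFrame(rows, columns=list(ALL_COLUMNS)).to_csv(path, index=False)


def write_results(result, path: str | Path) -> None:
    """Write a posterior or upscaling result to CSV (``.csv``) or JSON.

    CSV carries the summary table (one data row per group) with ``NA``
    marking any diagnostic that could not be computed; JSON carries the
    full metadata at machine precision.
    """
    path = Path(path)
    frame = result.summary_frame()
    if path.suffix.lower() == ".csv":
        frame.map(_fmt).to_csv(path, index=False)
    else:
        payload = result.to_dict()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, allow_nan=True)


def read_summary(path: str | Path) -> pd.DataFrame:
    """Read back a summary CSV written by :func:`write_results`."""
    return pd.read_csv(path, na_values=["NA"], keep_default_na=False)
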