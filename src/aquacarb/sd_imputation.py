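"""Impute missing measurement SDs from ecosystem-specific coefficients of variation.

Roughly half of literature rate measurements come without a reported
standard deviation.  The imputation rule is deliberately simple: within
each ecosystem category, average the per-measurement coefficient of
variation (CV_i = s_i / y_i) over the rows that do report an SD, then
fill each missing SD as that mean CV times the row's own rate.  A group
with no reported SDs at all falls back to the dataset-wide mean CV and
is flagged as such.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .data_io import GroupedDataset, RateMeasurement, group_by


class ImputationError(ValueError):
    """Imputation cannot proceed (no reported SDs anywhere, or a group
    is missing from the CV table)."""


@dataclass
class CvTable:
    """Per-group mean coefficient of variation from SD-reporting rows."""

    grouping_variable: str
    group_cv: dict[str, float]
    n_reported: dict[str, int]
    global_cv: float
    fallback_groups: set[str] = field(default_factory=set)

    def cv_for(self, label: str) -> float:
        if label not in self.group_cv:
            raise ImputationError(f"group {label!r} absent from CV table")
        return self.group_cv[label]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": label,
                "mean_cv": cv,
                "n_reported": self.n_reported[label],
                "fallback": label in self.fallback_groups,
            }
            for label, cv in self.group_cv.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_cv_table(grouped: GroupedDataset) -> CvTable:
    """Mean per-measurement CV within each group, from reported rows only.

    Raises :class:`ImputationError` when the whole dataset has zero
    reported SDs, since then there is no information to impute from.
    """
    all_cvs: list[float] = []
    group_cv: dict[str, float] = {}
    n_reported: dict[str, int] = {}
    fallback: set[str] = set()

    per_group_cvs: dict[str, list[float]] = {}
    for label, rows in grouped.groups.items():
        cvs = [m.sd / m.rate for m in rows if m.sd_source == "reported" and m.sd is not None]
        per_group_cvs[label] = cvs
        all_cvs.extend(cvs)

    if not all_cvs:
        raise ImputationError("no reported SDs anywhere in the dataset; cannot impute")
    global_cv = sum(all_cvs) / len(all_cvs)

    for label, cvs in per_group_cvs.items():
        n_reported[label] = len(cvs)
        if cvs:
            group_cv[label] = sum(cvs) / len(cvs)
        else:
            group_cv[label] = global_cv
            fallback.add(label)

    return CvTable(
        grouping_variable=grouped.grouping_variable,
        group_cv=group_cv,
        n_reported=n_reported,
        global_cv=global_cv,
        fallback_groups=fallback,
    )


def impute_sd(
    measurements: Sequence[RateMeasurement],
    cv: CvTable,
    sd_floor_fraction: float = 1e-6,
) -> list[RateMeasurement]:
    """Fill missing SDs as mean-group-CV × rate; reported rows untouched.

    The operation is idempotent: rows already carrying an SD (reported
    or previously imputed) pass through unchanged.  An imputed SD of
    exactly zero (possible only when the group's mean CV is zero) is
    replaced by ``sd_floor_fraction × rate`` so downstream likelihoods
    stay proper.
    """
    out: list[RateMeasurement] = []
    for m in measurements:
        if m.sd is not None:
            out.append(m)
            continue
        label = m.group_label(cv.grouping_variable)
        if label is None:
            raise ImputationError(
                f"measurement {m.site_id!r} lacks a {cv.grouping_variable!r} label"
            )
        sd = cv.cv_for(label) * m.rate
        if sd <= 0:
            sd = sd_floor_fraction * m.rate
        out.append(dataclasses.replace(m, sd=sd, sd_source="imputed"))
    return out


def impute_dataset(
    measurements: Sequence[RateMeasurement],
    grouping_variable: str = "ecosystem_category",
) -> tuple[list[RateMeasurement], CvTable]:
    """Convenience wrapper: group, build the CV table, impute."""
    grouped = group_by(measurements, grouping_variable)
    table = compute_cv_table(grouped)
    return impute_sd(measurements, table), table
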