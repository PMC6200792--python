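"""Group comparisons and global upscaling of posterior rate estimates.

Three kinds of downstream quantities:

* pairwise overlap of the reported rate ranges between groups, under a
  caller-chosen interval-overlap metric (the metric is recorded in the
  output, never silently defaulted in reports);
* ratios of posterior group means, either as the ratio of medians or as
  the full distribution of paired posterior-draw ratios;
* upscaling of an areal rate posterior (g C m⁻² y⁻¹) by a global
  ecosystem extent (m²) to an annual flux in Tg C y⁻¹
  (1 Tg = 10¹² g), with the credible bounds carried through and also
  expressed as percent of the median flux.

Global extents are user-supplied inputs with citation fields; this
module never bundles them as facts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes_model import GroupPosterior

OVERLAP_METRICS = ("jaccard", "smaller_fraction", "mean_directed")

GRAMS_PER_TG = 1e12


@dataclass
class RangeSummary:
    """Per-group (min, max) of reported accumulation rates."""

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for label, (lo, hi) in self.ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for {label!r}: ({lo}, {hi})")

    @classmethod
    def from_grouped(cls, grouped) -> "RangeSummary":
        return cls(
            {
                label: (s.minimum, s.maximum)
                for label, s in grouped.stats().items()
            }
        )


@dataclass
class OverlapResult:
    metric: str
    matrix: pd.DataFrame  # symmetric, unit diagonal
    average: float  # mean over unordered pairs
    degenerate_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class RatioResult:
    mode: str
    ratio: float
    q2_5: float | None = None
    q97_5: float | None = None
    resample_seed: int | None = None

    def display(self) -> str:
        return f"{round(self.ratio, 1)}x"


@dataclass
class UpscaleResult:
    """Global annual flux for one group: median and credible bounds."""

    label: str
    area_m2: float
    flux_median: float  # Tg C y⁻¹
    flux_lower: float
    flux_upper: float
    percent_lower: float  # 100 × lower / median
    percent_upper: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])

    def to_dict(self) -> dict:
        return {
            "group": self.label,
            "area_m2": self.area_m2,
            "flux_median_Tg_y": self.flux_median,
            "flux_lower_Tg_y": self.flux_lower,
            "flux_upper_Tg_y": self.flux_upper,
            "percent_of_mean_lower": self.percent_lower,
            "percent_of_mean_upper": self.percent_upper,
        }


@dataclass
class UpscaleTable:
    """Upscaling results for several groups (one data row per group)."""

    results: list[UpscaleResult]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])

    def to_dict(self) -> dict:
        return {"groups": [r.to_dict() for r in self.results]}


# ---------------------------------------------------------------------------
# Range overlap

def interval_overlap(
    a: tuple[float, float], b: tuple[float, float], metric: str
) -> tuple[float, bool]:
    """Overlap of two closed intervals under the chosen metric.

    Returns (value, degenerate_flag).  A zero-width interval is treated
    as a point: overlap is 1 if the point lies inside the other
    interval, else 0, and the pair is flagged as degenerate.
    """
    if metric not in OVERLAP_METRICS:
        raise ValueError(f"unknown overlap metric {metric!r}")
    (a_lo, a_hi), (b_lo, b_hi) = a, b
    inter = max(0.0, min(a_hi, b_hi) - max(a_lo, b_lo))
    len_a, len_b = a_hi - a_lo, b_hi - b_lo
    if len_a == 0 or len_b == 0:
        if len_a == 0 and len_b == 0:
            return (1.0 if a_lo == b_lo else 0.0), True
        point, (lo, hi) = (a_lo, b) if len_a == 0 else (b_lo, a)
        return (1.0 if lo <= point <= hi else 0.0), True
    if metric == "jaccard":
        union = max(a_hi, b_hi) - min(a_lo, b_lo)
        return inter / union, False
    if metric == "smaller_fraction":
        return inter / min(len_a, len_b), False
    return (inter / len_a + inter / len_b) / 2.0, False


def range_overlap_matrix(ranges: RangeSummary, metric: str) -> OverlapResult:
    """Pairwise overlap matrix over all groups plus the average over
    unordered pairs; the metric used is recorded in the result."""
    labels = list(ranges.ranges)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for an overlap matrix")
    k = len(labels)
    mat = np.ones((k, k))
    degenerate: list[tuple[str, str]] = []
    values = []
    for i in range(k):
        for j in range(i + 1, k):
            value, flag = interval_overlap(
                ranges.ranges[labels[i]], ranges.ranges[labels[j]], metric
            )
            mat[i, j] = mat[j, i] = value
            values.append(value)
            if flag:
                degenerate.append((labels[i], labels[j]))
    return OverlapResult(
        metric=metric,
        matrix=pd.DataFrame(mat, index=labels, columns=labels),
        average=float(np.mean(values)),
        degenerate_pairs=degenerate,
    )


# ---------------------------------------------------------------------------
# Posterior ratios

def posterior_ratio(
    result_a: GroupPosterior,
    result_b: GroupPosterior,
    mode: str = "median_ratio",
    seed: int | None = None,
) -> RatioResult:
    """Ratio of group mean rates, a / b.

    ``median_ratio`` divides the posterior medians (the convention used
    for headline fold-changes); ``sample_ratio`` forms the distribution
    of paired posterior-draw ratios and reports its median with a 95%
    interval.  Unequal draw counts in sample mode are resampled down to
    the smaller count with a recorded seed.
    """
    if mode == "median_ratio":
        return RatioResult(mode=mode, ratio=result_a.q50 / result_b.q50)
    if mode != "sample_ratio":
        raise ValueError(f"unknown ratio mode {mode!r}")
    a = result_a.mu_samples
    b = result_b.mu_samples
    used_seed = None
    if a.size != b.size:
        used_seed = 0 if seed is None else seed
        rng = np.random.default_rng(used_seed)
        n = min(a.size, b.size)
        if a.size > n:
            a = rng.choice(a, size=n, replace=False)
        if b.size > n:
            b = rng.choice(b, size=n, replace=False)
    ratios = a / b
    q = np.quantile(ratios, [0.025, 0.5, 0.975])
    return RatioResult(
        mode=mode,
        ratio=float(q[1]),
        q2_5=float(q[0]),
        q97_5=float(q[2]),
        resample_seed=used_seed,
    )


# ---------------------------------------------------------------------------
# Upscaling

def _quantiles_of(result) -> tuple[float, float, float]:
    if isinstance(result, GroupPosterior):
        return result.q2_5, result.q50, result.q97_5
    q2_5, q50, q97_5 = result
    return float(q2_5), float(q50), float(q97_5)


def upscale(result, area_m2: float, label: str | None = None) -> UpscaleResult:
    """Scale a rate posterior to a global annual flux in Tg C y⁻¹.

    ``result`` is either a fitted :class:`GroupPosterior` or a bare
    (q2.5, q50, q97.5) triple in g C m⁻² y⁻¹; ``area_m2`` is the global
    extent of the ecosystem category.  Full precision is retained;
    rounding happens only at display.
    """
    if not area_m2 > 0:
        raise ValueError(f"area must be > 0 m², got {area_m2}")
    q2_5, q50, q97_5 = _quantiles_of(result)
    if label is None:
        label = result.label if isinstance(result, GroupPosterior) else "group"
    flux = tuple(q * area_m2 / GRAMS_PER_TG for q in (q2_5, q50, q97_5))
    return UpscaleResult(
        label=label,
        area_m2=float(area_m2),
        flux_lower=flux[0],
        flux_median=flux[1],
        flux_upper=flux[2],
        percent_lower=percent_of_mean(flux[0], flux[1]),
        percent_upper=percent_of_mean(flux[2], flux[1]),
    )


def percent_of_mean(bound: float, mean: float) -> float:
    """Credible bound as a percentage of the median flux (full precision)."""
    if not mean > 0:
        raise ValueError(f"mean flux must be > 0, got {mean}")
    return 100.0 * bound / mean


def display_percent(value: float) -> int:
    """Round a percent to the integer shown in reports (banker's rounding)."""
    return int(round(value))


# ---------------------------------------------------------------------------
# Plotting (optional convenience; requires matplotlib)

def plot_forest(result, path=None):
    """Simple forest plot of per-group posterior medians with 95% CIs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = result.summary_frame()
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(frame) + 1.5))
    ypos = np.arange(len(frame))[::-1]
    ax.errorbar(
        frame["q50"],
        ypos,
        xerr=[frame["q50"] - frame["q2.5"], frame["q97.5"] - frame["q50"]],
        fmt="o",
        color="k",
        capsize=3,
    )
    ax.set_yticks(ypos)
    ax.set_yticklabels(frame["group"])
    ax.set_xlabel("mean accumulation rate (g C m$^{-2}$ y$^{-1}$)")
    ax.set_xscale("log")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
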