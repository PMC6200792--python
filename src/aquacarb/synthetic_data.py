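"""Synthetic literature-synthesis datasets with known ground truth.

The generator mirrors the structure the estimation pipeline assumes:
per group, latent true study rates θ_i ~ Normal(μ_g, τ_g²) truncated to
positive values (by redraw, so the positive support carries no point
mass), per-row measurement SDs s_i drawn log-normally around a
CV-proportional location (s_i ≈ CV_i · θ_i with CV_i spanning a
configurable range), and observed rates y_i ~ Normal(θ_i, s_i²)
truncated above the method detection floor.  A configurable fraction of
SDs is then masked to missing, emulating the roughly 58% of literature
rows that report no uncertainty.

Truncated-normal generation intentionally differs from the untruncated
fitting model; a ``truncate=False`` flag exists for exact model-match
experiments.  Ground truth (μ_g, τ_g, every θ_i, the masking pattern)
is returned alongside the rows so recovery can be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import (
    ECOSYSTEM_CATEGORIES,
    RateMeasurement,
)


class GenerationError(RuntimeError):
    """Truncation rejected essentially every draw; reparameterize."""


@dataclass(frozen=True)
class GroupSpec:
    """True parameters and size for one simulated group."""

    label: str
    mu: float  # true group mean, g C m⁻² y⁻¹
    tau: float  # true between-study SD, g C m⁻² y⁻¹
    n: int
    ecosystem_category: str | None = None
    salinity_class: str | None = None
    inundation_class: str | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class SimulationConfig:
    groups: list[GroupSpec]
    cv_range: tuple[float, float] = (0.1, 0.6)
    sd_missing_prob: float = 0.58
    rate_floor: float = 0.1  # detection floor; observed rates are redrawn above it
    n_studies: int | None = None
    seed: int = 0
    truncate: bool = True
    #: "cv_of_latent": s_i = CV_i · θ_i (uncertainty grows with the true
    #: rate, as in real literature compilations — note this makes s_i
    #: informative about θ_i, which the fitting model ignores by design);
    #: "exogenous": s_i = CV_i · μ_g, independent of θ_i, for exact
    #: model-match calibration experiments.
    sd_model: str = "cv_of_latent"

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("need at least one group")
        lo, hi = self.cv_range
        if not (0 < lo <= hi):
            raise ValueError("cv_range must satisfy 0 < lo <= hi")
        if not 0 <= self.sd_missing_prob <= 1:
            raise ValueError("sd_missing_prob must be in [0, 1]")
        if self.sd_model not in ("cv_of_latent", "exogenous"):
            raise ValueError(f"unknown sd_model {self.sd_model!r}")

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)


@dataclass
class GroundTruth:
    """Everything the generator knew: parameters, latents, masking."""

    seed: int
    group_params: dict[str, dict]  # label -> {mu, tau, n}
    theta: dict[str, list[float]]  # label -> latent true rates, row order
    sd_true: dict[str, list[float]]
    masked: dict[str, list[bool]]  # True where the SD was hidden

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "group_params": self.group_params,
            "theta": self.theta,
            "sd_true": self.sd_true,
            "masked": self.masked,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


# Synthetic defaults: seven groups whose true means and spreads echo the
# magnitudes typical of published syntheses (lakes tight and low, blue
# carbon and reservoirs high and diffuse).  These are simulation inputs,
# not measured facts.
_DEFAULT_GROUPS: tuple[tuple[str, float, float, int, str, str], ...] = (
    ("lake", 15.6, 8.0, 202, "fresh", "permanent"),
    ("reservoir", 69.9, 50.0, 13, "fresh", "permanent"),
    ("inland_wetland", 66.2, 45.0, 17, "fresh", "seasonal"),
    ("coastal_wetland", 62.9, 40.0, 53, "brackish", "tidal"),
    ("lagoon", 41.4, 25.0, 8, "brackish", "permanent"),
    ("mangrove", 73.2, 45.0, 45, "saline", "tidal"),
    ("continental_shelf", 19.6, 12.0, 126, "saline", "permanent"),
)


def default_config(seed: int = 0) -> SimulationConfig:
    """Default 7-category configuration, 464 rows across 103 studies."""
    groups = [
        GroupSpec(
            label=label,
            mu=mu,
            tau=tau,
            n=n,
            ecosystem_category=label,
            salinity_class=sal,
            inundation_class=inund,
        )
        for label, mu, tau, n, sal, inund in _DEFAULT_GROUPS
    ]
    return SimulationConfig(groups=groups, n_studies=103, seed=seed)


def _draw_truncated(
    rng: np.random.Generator,
    loc: np.ndarray | float,
    scale: np.ndarray | float,
    floor: float,
    what: str,
    size: int | None = None,
) -> np.ndarray:
    """Normal draws redrawn until > floor; errors out if the acceptance
    rate is below 1%."""
    loc = np.atleast_1d(np.asarray(loc, dtype=float))
    scale = np.atleast_1d(np.asarray(scale, dtype=float))
    shape = np.broadcast_shapes(loc.shape, scale.shape, (size,) if size else ())
    loc = np.broadcast_to(loc, shape).copy()
    scale = np.broadcast_to(scale, shape).copy()
    out = loc + scale * rng.standard_normal(loc.shape)
    bad = out <= floor
    n_draws = out.size
    n_rejected = int(bad.sum())
    tries = 0
    while bad.any():
        k = int(bad.sum())
        out[bad] = loc[bad] + scale[bad] * rng.standard_normal(k)
        bad = out <= floor
        n_draws += k
        n_rejected += int(bad.sum())
        tries += 1
        if tries > 1000 or (n_draws > 100 * out.size and n_rejected / n_draws > 0.99):
            raise GenerationError(
                f"{what}: truncation rejects >99% of draws; "
                "reparameterize (mu too close to the floor relative to the spread)"
            )
    return out


def generate_dataset(
    config: SimulationConfig,
) -> tuple[list[RateMeasurement], GroundTruth]:
    """Generate one synthetic dataset plus its ground-truth record.

    Fully deterministic in ``config.seed``.  When ``config.truncate`` is
    off, latent rates and observations are plain (untruncated) normal
    draws, exactly matching the fitting model's likelihood.
    """
    rng = np.random.default_rng(config.seed)
    cv_lo, cv_hi = config.cv_range
    log_cv_mid = 0.5 * (math.log(cv_lo) + math.log(cv_hi))
    # ±2 sdlog spans the configured CV range
    sdlog = (math.log(cv_hi) - math.log(cv_lo)) / 4.0

    measurements: list[RateMeasurement] = []
    truth = GroundTruth(
        seed=config.seed, group_params={}, theta={}, sd_true={}, masked={}
    )

    for spec in config.groups:
        n = spec.n
        if config.truncate and spec.tau > 0:
            # true rates below the method detection floor would never be
            # reported, so θ is truncated at the floor, not merely at 0
            theta = _draw_truncated(
                rng, spec.mu, spec.tau, config.rate_floor,
                f"group {spec.label}: theta", size=n,
            )
        elif spec.tau > 0:
            theta = spec.mu + spec.tau * rng.standard_normal(n)
        else:
            theta = np.full(n, spec.mu)
        theta = np.atleast_1d(theta)

        cv = np.exp(rng.normal(log_cv_mid, sdlog, size=n))
        if config.sd_model == "cv_of_latent":
            s = cv * np.abs(theta)
        else:
            s = cv * spec.mu
        s = np.maximum(s, 1e-9)

        if config.truncate:
            y = _draw_truncated(rng, theta, s, config.rate_floor, f"group {spec.label}: y")
        else:
            y = theta + s * rng.standard_normal(n)
        y = np.atleast_1d(y)

        masked = rng.random(n) < config.sd_missing_prob

        truth.group_params[spec.label] = {"mu": spec.mu, "tau": spec.tau, "n": n}
        truth.theta[spec.label] = [float(v) for v in theta]
        truth.sd_true[spec.label] = [float(v) for v in s]
        truth.masked[spec.label] = [bool(v) for v in masked]

        category = spec.ecosystem_category
        if category is None and spec.label in ECOSYSTEM_CATEGORIES:
            category = spec.label
        if category is not None and category not in ECOSYSTEM_CATEGORIES:
            raise ValueError(f"unknown ecosystem_category {category!r}")
        for i in range(n):
            measurements.append(
                RateMeasurement(
                    study_id="",  # assigned globally below
                    site_id=f"{spec.label}_{i:04d}",
                    rate=float(y[i]),
                    sd=None if masked[i] else float(s[i]),
                    sd_source="missing" if masked[i] else "reported",
                    ecosystem_raw=category,
                    ecosystem_category=category,
                    salinity_class=spec.salinity_class,
                    inundation_class=spec.inundation_class,
                    latitude=float(rng.uniform(-60.0, 70.0)),
                    longitude=float(rng.uniform(-180.0, 180.0)),
                    record_span_years=float(rng.uniform(50.0, 200.0)),
                )
            )

    measurements = _assign_studies(measurements, config, rng)
    return measurements, truth


def _assign_studies(
    measurements: list[RateMeasurement], config: SimulationConfig, rng: np.random.Generator
) -> list[RateMeasurement]:
    """Assign study ids; every study id is used at least once."""
    import dataclasses

    n = len(measurements)
    n_studies = config.n_studies
    if n_studies is None:
        # literature syntheses typically carry a handful of sites per study
        n_studies = max(1, round(n / 4.5))
    n_studies = min(n_studies, n)
    ids = np.concatenate(
        [np.arange(n_studies), rng.integers(0, n_studies, size=n - n_studies)]
    )
    rng.shuffle(ids)
    return [
        dataclasses.replace(m, study_id=f"study_{int(sid):04d}")
        for m, sid in zip(measurements, ids)
    ]
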