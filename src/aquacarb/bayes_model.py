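"""Hierarchical Bayesian measurement-error model for group mean rates.

Model (``with_uncertainty`` variant), fit independently per group g:

    y_i | θ_i        ~ Normal(θ_i, s_i²)          observed rate, known SD
    θ_i | μ_g, τ_g   ~ Normal(μ_g, τ_g²)          latent true study rate
    μ_g              ~ Uniform(0.1, 10000)        group mean (g C m⁻² y⁻¹)
    τ_g              ~ Gamma(0.001, 0.001)        between-study SD

The uniform lower bound reflects the practical detection floor of
sediment-dating rate methods; the gamma prior is placed directly on the
between-study standard deviation, with both shape and rate exposed in
the config.  Because each observed rate enters with its own measurement
SD, imprecise high values are automatically down-weighted in the
posterior for μ_g.  The ``excluding_uncertainty`` variant drops the
measurement-error layer and models y_i ~ Normal(μ_g, τ_g²) directly,
which serves as a sensitivity check on the role of reported uncertainty.

Sampling is Metropolis-within-Gibbs: θ_i and μ_g have conjugate normal
full conditionals (μ_g truncated to the uniform support); τ_g, whose
gamma-on-SD prior is non-conjugate, takes a random-walk step on log τ
with step size adapted during burn-in only.  Both the μ and τ updates
are *collapsed* over the latent layer: with θ integrated out
analytically the likelihood is y_i ~ Normal(μ, τ² + s_i²), under which
μ | τ, y is a precision-weighted truncated normal (weights
w_i = 1/(τ² + s_i²)) and τ takes its Metropolis step against the same
marginal.  Collapsing leaves the posterior for (μ_g, τ_g) identical to
the latent-variable formulation while sidestepping the well-known
"funnel" pathology of naive latent-θ Gibbs in small groups, where τ
and the θ's mutually collapse toward zero spread and the chain sticks.
The un-collapsed latent-θ kernel is retained for the optional
θ-truncation variant, whose marginal likelihood has no closed form.
Chains start overdispersed
(μ at the 25/50/75th data percentiles, τ at 0.5/1/2 × the data SD) so
the Gelman–Rubin diagnostic is meaningful.

A marginalized formulation, y_i ~ Normal(μ_g, τ_g² + s_i²) with the θ
layer integrated out, is provided as an internal cross-check sampler;
both routes target the same posterior for (μ_g, τ_g).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

VARIANTS = ("with_uncertainty", "excluding_uncertainty")


class SamplerError(RuntimeError):
    """The sampler degenerated (e.g. every τ proposal rejected)."""


@dataclass(frozen=True)
class ModelConfig:
    """Priors, chain settings, and model variant flags.

    Defaults follow the analysis conditions this package reproduces:
    a Uniform(0.1, 10000) prior on the group mean, Gamma(0.001, 0.001)
    on the between-study SD, and three chains of 300 000 iterations with
    100 000 burn-in.  Tests and quick runs use shorter chains.
    """

    prior_mean_lower: float = 0.1
    prior_mean_upper: float = 10000.0
    prior_sd_shape: float = 0.001
    prior_sd_rate: float = 0.001
    n_chains: int = 3
    n_iter: int = 300_000
    n_burnin: int = 100_000
    thin: int = 1
    seed: int = 0
    variant: str = "with_uncertainty"
    fixed_tau: float | None = None  # fix τ_g for conjugacy checks
    truncate_theta: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.prior_mean_lower < self.prior_mean_upper):
            raise ValueError("need 0 < prior_mean_lower < prior_mean_upper")
        if self.prior_sd_shape <= 0 or self.prior_sd_rate <= 0:
            raise ValueError("gamma prior shape and rate must be > 0")
        if not self.n_burnin < self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for the Gelman-Rubin diagnostic")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.fixed_tau is not None and self.fixed_tau <= 0:
            raise ValueError("fixed_tau must be > 0")

    @property
    def samples_per_chain(self) -> int:
        return (self.n_iter - self.n_burnin) // self.thin


@dataclass
class GroupPosterior:
    """Posterior chains and summaries for one group's (μ_g, τ_g)."""

    label: str
    n_obs: int
    mu_chains: np.ndarray  # (n_chains, n_samples)
    tau_chains: np.ndarray
    q2_5: float
    q50: float
    q97_5: float
    rhat_mu: float
    rhat_tau: float | None
    ess_mu: float
    ess_tau: float | None
    tau_acceptance: float | None

    @property
    def mu_samples(self) -> np.ndarray:
        return self.mu_chains.reshape(-1)

    @property
    def tau_samples(self) -> np.ndarray:
        return self.tau_chains.reshape(-1)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_obs": self.n_obs,
            "q2.5": self.q2_5,
            "q50": self.q50,
            "q97.5": self.q97_5,
            "rhat_mu": self.rhat_mu,
            "rhat_tau": self.rhat_tau,
            "ess_mu": self.ess_mu,
            "ess_tau": self.ess_tau,
            "tau_acceptance": self.tau_acceptance,
        }


@dataclass
class PosteriorResult:
    """Per-group posterior summaries keyed by group label."""

    grouping_variable: str
    groups: dict[str, GroupPosterior]
    config: ModelConfig

    def __getitem__(self, label: str) -> GroupPosterior:
        return self.groups[label]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for label, g in self.groups.items():
            rows.append(
                {
                    "group": label,
                    "n_obs": g.n_obs,
                    "q2.5": g.q2_5,
                    "q50": g.q50,
                    "q97.5": g.q97_5,
                    "rhat_mu": g.rhat_mu,
                    "rhat_tau": g.rhat_tau,
                    "ess_mu": g.ess_mu,
                    "ess_tau": g.ess_tau,
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "grouping_variable": self.grouping_variable,
            "variant": self.config.variant,
            "seed": self.config.seed,
            "n_chains": self.config.n_chains,
            "n_iter": self.config.n_iter,
            "n_burnin": self.config.n_burnin,
            "groups": {label: g.to_dict() for label, g in self.groups.items()},
        }

    def chains_frame(self) -> pd.DataFrame:
        """Long-format chain export: group, parameter, chain, iteration, value."""
        frames = []
        for label, g in self.groups.items():
            for name, chains in (("mu", g.mu_chains), ("tau", g.tau_chains)):
                n_chain, n_samp = chains.shape
                frames.append(
                    pd.DataFrame(
                        {
                            "group": label,
                            "parameter": name,
                            "chain": np.repeat(np.arange(n_chain), n_samp),
                            "iteration": np.tile(np.arange(n_samp), n_chain),
                            "value": chains.reshape(-1),
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Diagnostics

def gelman_rubin(chains: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Potential scale reduction factor R̂ for one scalar parameter.

    R̂ = sqrt(((n−1)/n · W + B/n) / W), where W is the mean within-chain
    variance and B is n times the variance of the chain means.  Values
    near 1 indicate the chains have mixed into the same distribution.
    Returns +inf when chains have zero internal variance but different
    levels (W = 0, B > 0).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = x.shape
    if n < 2:
        raise ValueError("need >= 2 samples per chain")
    within = float(np.mean(np.var(x, axis=1, ddof=1)))
    between = n * float(np.var(np.mean(x, axis=1), ddof=1))
    if within == 0.0:
        return math.inf if between > 0 else 1.0
    return math.sqrt(((n - 1) / n * within + between / n) / within)


def effective_sample_size(chains: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Effective sample size via combined autocorrelation with Geyer's
    initial-monotone-positive-sequence truncation."""
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    if n < 4:
        return float(m * n)
    acov = np.empty((m, n))
    for i in range(m):
        acov[i] = _autocov(x[i])
    chain_var = acov[:, 0] * n / (n - 1)
    within = float(np.mean(chain_var))
    if within == 0:
        return float(m * n)
    if m > 1:
        between = n * float(np.var(np.mean(x, axis=1), ddof=1))
        var_plus = within * (n - 1) / n + between / n
    else:
        var_plus = within * (n - 1) / n
    rho = 1.0 - (within - np.mean(acov, axis=0)) / var_plus
    # sum autocorrelations over lag pairs while the pair sums stay
    # positive and non-increasing
    tau_sum = 0.0
    prev_pair = math.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        tau_sum += pair
        prev_pair = pair
        t += 2
    ess = m * n / (1.0 + 2.0 * tau_sum)
    return float(min(ess, m * n))


def _autocov(x: np.ndarray) -> np.ndarray:
    n = len(x)
    xc = x - x.mean()
    size = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, size)
    acov = np.fft.irfft(f * np.conjugate(f), size)[:n].real
    return acov / n


def summarize_posterior(samples: Sequence[float] | np.ndarray) -> tuple[float, float, float]:
    """Empirical (2.5, 50, 97.5) percentiles of pooled post-burn-in draws.

    Uses linear interpolation of order statistics (numpy's default
    quantile rule).
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("no samples to summarize")
    q = np.quantile(x, [0.025, 0.5, 0.975])
    return float(q[0]), float(q[1]), float(q[2])


# ---------------------------------------------------------------------------
# Sampler

def _chain_rng(config: ModelConfig, label: str, chain: int) -> np.random.Generator:
    # label enters through a stable CRC so per-group streams are
    # independent yet reproducible across runs and execution orders
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(label.encode("utf-8")), chain])
    )


def _sample_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, upper: float
) -> float:
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    pa, pb = ndtr(a), ndtr(b)
    if pb - pa > 1e-12:
        u = rng.uniform(pa, pb)
        value = mean + sd * float(ndtri(u))
        if lower <= value <= upper:
            return value
    # conditional mass numerically outside the support: fall back to the
    # nearest boundary region via a one-sided exponential-tail draw
    if mean >= upper:
        return upper - min(sd, upper - lower) * 1e-3 * rng.random()
    if mean <= lower:
        return lower + min(sd, upper - lower) * 1e-3 * rng.random()
    return float(np.clip(mean, lower, upper))


def _log_tau_prior(log_tau: float, shape: float, rate: float) -> float:
    # Gamma(shape, rate) prior on τ itself, plus Jacobian of τ = e^u
    if log_tau > 700.0:  # exp would overflow; prior mass is nil out here
        return -math.inf
    return shape * log_tau - rate * math.exp(log_tau)


def _log_tau_target_marginal(
    log_tau: float, mu: float, y: np.ndarray, s2: np.ndarray, shape: float, rate: float
) -> float:
    """log p(τ | μ, y) up to a constant, with θ integrated out."""
    if log_tau > 700.0:
        return -math.inf
    tau = math.exp(log_tau)
    var = tau * tau + s2
    loglik = -0.5 * float(np.sum(np.log(var) + (y - mu) ** 2 / var))
    return loglik + _log_tau_prior(log_tau, shape, rate)


def _log_tau_target_direct(
    log_tau: float, resid_sq: float, n: int, shape: float, rate: float
) -> float:
    """log p(τ | μ, y) in the variant without the measurement-error layer."""
    if log_tau > 700.0:
        return -math.inf
    tau = math.exp(log_tau)
    if tau == 0.0:
        return -math.inf  # underflow: likelihood vanishes without the s² cushion
    return -n * log_tau - resid_sq / (2.0 * tau * tau) + _log_tau_prior(log_tau, shape, rate)


def _run_chain(
    y: np.ndarray,
    s: np.ndarray | None,
    config: ModelConfig,
    label: str,
    chain: int,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    rng = _chain_rng(config, label, chain)
    n = y.size
    lower, upper = config.prior_mean_lower, config.prior_mean_upper

    # overdispersed starts across chains
    mu_quantiles = (25.0, 50.0, 75.0)
    mu = float(np.clip(np.percentile(y, mu_quantiles[chain % 3]), lower, upper))
    if n > 1:
        base_sd = float(np.std(y, ddof=1))
    else:
        base_sd = max(abs(y[0]) * 0.5, 1.0)
    base_sd = max(base_sd, 1e-3)
    tau_factors = (0.5, 1.0, 2.0)
    tau = config.fixed_tau if config.fixed_tau is not None else base_sd * tau_factors[chain % 3]
    # log τ is the state variable: the gamma-on-SD prior concentrates
    # enormous mass near τ = 0, so chains may legitimately visit values
    # that underflow exp(); carrying the log avoids log(0) blow-ups
    log_tau = math.log(tau)

    with_err = config.variant == "with_uncertainty"
    latent_path = with_err and config.truncate_theta
    if with_err:
        assert s is not None
        s2 = s * s
        inv_s2 = 1.0 / s2
        theta = y.astype(float).copy()
    else:
        # no measurement-error layer: equivalent to collapsed updates
        # with every s_i = 0
        s2 = np.zeros(n)
        theta = y.astype(float)

    shape, rate = config.prior_sd_shape, config.prior_sd_rate
    step = 0.5  # log-τ random-walk scale, adapted during burn-in
    accept_window = 0
    window = 0
    accepted_post = 0
    proposed_post = 0

    n_keep = config.samples_per_chain
    mu_out = np.empty(n_keep)
    tau_out = np.empty(n_keep)
    keep = 0

    exp = math.exp
    log = math.log
    sqrt = math.sqrt

    for it in range(config.n_iter):
        # τ_g — random-walk Metropolis on log τ, given μ.  On the
        # collapsed path this targets p(τ | μ, y) with θ integrated
        # out; on the latent path it conditions on the current θ.
        if config.fixed_tau is None:
            proposal = log_tau + step * rng.standard_normal()
            if latent_path:
                resid_sq = float(np.sum((theta - mu) ** 2))
                lp_cur = _log_tau_target_direct(log_tau, resid_sq, n, shape, rate)
                lp_prop = _log_tau_target_direct(proposal, resid_sq, n, shape, rate)
            else:
                lp_cur = _log_tau_target_marginal(log_tau, mu, y, s2, shape, rate)
                lp_prop = _log_tau_target_marginal(proposal, mu, y, s2, shape, rate)
            delta = lp_prop - lp_cur
            accept = delta >= 0 or rng.random() < exp(delta)
            if accept:
                log_tau = proposal
                tau = exp(log_tau)
            if it < config.n_burnin:
                window += 1
                accept_window += accept
                if window == 100:
                    acc = accept_window / window
                    if acc > 0.5:
                        step *= 1.2
                    elif acc < 0.3:
                        step /= 1.2
                    window = 0
                    accept_window = 0
            else:
                proposed_post += 1
                accepted_post += accept

        tau2 = tau * tau
        if latent_path:
            # θ_i | rest — conjugate normal truncated to θ > 0 by redraw
            prec = inv_s2 + 1.0 / tau2
            mean = (y * inv_s2 + mu / tau2) / prec
            theta = mean + rng.standard_normal(n) / np.sqrt(prec)
            bad = theta <= 0
            tries = 0
            while bad.any() and tries < 100:
                theta[bad] = mean[bad] + rng.standard_normal(int(bad.sum())) / np.sqrt(prec[bad])
                bad = theta <= 0
                tries += 1
            if bad.any():
                theta[bad] = np.maximum(mean[bad], 1e-6)
            # μ_g | θ, τ — normal truncated to the uniform support
            mu = _sample_truncated_normal(
                rng, float(theta.mean()), tau / sqrt(n), lower, upper
            )
        else:
            # μ_g | τ, y — precision-weighted truncated normal under the
            # marginal likelihood y_i ~ Normal(μ, τ² + s_i²)
            w = 1.0 / (tau2 + s2)
            w_sum = float(w.sum())
            cond_mean = float(np.dot(w, y)) / w_sum
            mu = _sample_truncated_normal(
                rng, cond_mean, 1.0 / sqrt(w_sum), lower, upper
            )

        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            mu_out[keep] = mu
            tau_out[keep] = tau
            keep += 1

    acc_rate = accepted_post / proposed_post if proposed_post else None
    return mu_out[:keep], tau_out[:keep], acc_rate


def fit_group(
    y: Sequence[float] | np.ndarray,
    s: Sequence[float] | np.ndarray | None,
    config: ModelConfig,
    label: str = "group",
) -> GroupPosterior:
    """Fit the hierarchical model for one group.

    ``y`` are the observed rates and ``s`` their measurement SDs
    (required for the ``with_uncertainty`` variant, where every SD must
    be strictly positive — guaranteed post-imputation).  Runs
    ``config.n_chains`` chains from overdispersed starting points and
    returns pooled quantile summaries with convergence diagnostics.
    Fully reproducible from ``config.seed``.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError(f"group {label!r} has no observations")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"group {label!r} contains non-finite observations")

    if config.variant == "with_uncertainty":
        if s is None:
            raise ValueError("with_uncertainty variant requires measurement SDs")
        s = np.asarray(s, dtype=float)
        if s.shape != y.shape:
            raise ValueError("y and s must have the same length")
        if not np.all(np.isfinite(s)) or np.any(s <= 0):
            raise ValueError(
                f"group {label!r}: all measurement SDs must be finite and > 0 "
                "(run SD imputation first)"
            )
    else:
        s = None

    mu_chains = []
    tau_chains = []
    acc_rates = []
    for chain in range(config.n_chains):
        mu_c, tau_c, acc = _run_chain(y, s, config, label, chain)
        mu_chains.append(mu_c)
        tau_chains.append(tau_c)
        if acc is not None:
            acc_rates.append(acc)

    mu_arr = np.vstack(mu_chains)
    tau_arr = np.vstack(tau_chains)

    if config.fixed_tau is None and acc_rates and max(acc_rates) == 0.0:
        raise SamplerError(
            f"group {label!r}: every post-burn-in τ proposal was rejected; "
            "the sampler is degenerate for these data"
        )

    q2_5, q50, q97_5 = summarize_posterior(mu_arr.reshape(-1))
    rhat_mu = gelman_rubin(mu_arr)
    if config.fixed_tau is None:
        rhat_tau: float | None = gelman_rubin(tau_arr)
        ess_tau: float | None = effective_sample_size(tau_arr)
    else:
        rhat_tau = None
        ess_tau = None

    return GroupPosterior(
        label=label,
        n_obs=int(y.size),
        mu_chains=mu_arr,
        tau_chains=tau_arr,
        q2_5=q2_5,
        q50=q50,
        q97_5=q97_5,
        rhat_mu=rhat_mu,
        rhat_tau=rhat_tau,
        ess_mu=effective_sample_size(mu_arr),
        ess_tau=ess_tau,
        tau_acceptance=float(np.mean(acc_rates)) if acc_rates else None,
    )


def fit_all(grouped, config: ModelConfig) -> PosteriorResult:
    """Fit each group independently and key results by group label.

    Groups are statistically independent under the model, so fits may
    run in any order with identical results (per-group RNG streams are
    derived from the group label, not the iteration order).
    """
    groups: dict[str, GroupPosterior] = {}
    for label, rows in grouped.groups.items():
        y = np.array([m.rate for m in rows])
        if config.variant == "with_uncertainty":
            if any(m.sd is None for m in rows):
                raise ValueError(
                    f"group {label!r} has unresolved SDs; run imputation before fitting"
                )
            s = np.array([m.sd for m in rows])
        else:
            s = None
        try:
            groups[label] = fit_group(y, s, config, label=label)
        except (ValueError, SamplerError) as exc:
            raise type(exc)(f"group {label!r}: {exc}") from exc
    return PosteriorResult(
        grouping_variable=grouped.grouping_variable, groups=groups, config=config
    )


# ---------------------------------------------------------------------------
# Marginalized cross-check sampler

def _marginal_log_post(
    mu: float, log_tau: float, y: np.ndarray, s2: np.ndarray, config: ModelConfig
) -> float:
    if not (config.prior_mean_lower <= mu <= config.prior_mean_upper):
        return -math.inf
    if log_tau > 700.0:
        return -math.inf
    tau = math.exp(log_tau)
    var = tau * tau + s2
    loglik = float(-0.5 * np.sum(np.log(var) + (y - mu) ** 2 / var))
    log_prior = (config.prior_sd_shape - 1.0) * log_tau - config.prior_sd_rate * tau
    return loglik + log_prior + log_tau  # + Jacobian


def sample_marginal_posterior(
    y: Sequence[float] | np.ndarray,
    s: Sequence[float] | np.ndarray,
    config: ModelConfig,
    n_samples: int = 20_000,
    n_burnin: int = 5_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk MH on (μ, log τ) under the marginalized likelihood
    y_i ~ Normal(μ, τ² + s_i²).

    This integrates the latent θ layer out analytically, so it targets
    the same (μ_g, τ_g) posterior as the Gibbs sampler through an
    entirely different code path; used as an internal consistency
    oracle, not for production fits.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    s2 = np.asarray(s, dtype=float) ** 2
    mu = float(np.median(y))
    log_tau = math.log(max(float(np.std(y, ddof=1)) if y.size > 1 else 1.0, 1e-3))
    scale_mu = max(float(np.std(y, ddof=1)) if y.size > 1 else 1.0, 1e-3) / math.sqrt(y.size)
    lp = _marginal_log_post(mu, log_tau, y, s2, config)
    mus = np.empty(n_samples)
    taus = np.empty(n_samples)
    kept = 0
    total = n_samples + n_burnin
    for it in range(total):
        mu_prop = mu + 2.4 * scale_mu * rng.standard_normal()
        lt_prop = log_tau + 0.4 * rng.standard_normal()
        lp_prop = _marginal_log_post(mu_prop, lt_prop, y, s2, config)
        if lp_prop - lp >= 0 or rng.random() < math.exp(lp_prop - lp):
            mu, log_tau, lp = mu_prop, lt_prop, lp_prop
        if it >= n_burnin:
            mus[kept] = mu
            taus[kept] = math.exp(log_tau)
            kept += 1
    return mus, taus
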