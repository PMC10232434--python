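"""Bayesian inference for the transport model: priors, posterior, and a
differential-evolution MCMC sampler with a sampled-history archive
(DE-MC-Z, the scheme behind the DREAM-ZS family).

The parameter vector of one genus × season fit is θ = (β₁…β_k, p0, τ) with
τ in hours.  Priors:

- β components: independent normal, mean 0, sd 3 (weakly informative on the
  log-linear production scale);
- p0: uniform on [0, 1] (read-equivalent baseline production);
- τ: log-normal constructed from a stated median and mode — the default
  (median 5 h, mode 4 h) encodes laboratory decay-time scales.

Proposals are differences of two states drawn from a thinned archive of
past states, scaled by γ = 2.38/√(2d) (with occasional unit-γ mode jumps),
plus a small uniform jitter; a snooker move along the line to an archive
state is mixed in with small probability.  This adapts to the posterior
covariance without tuning while keeping the chain Markovian with respect to
the growing archive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import DiagnosticError, InitializationError

__all__ = [
    "PriorSpec",
    "make_tau_prior",
    "log_posterior",
    "run_sampler",
    "gelman_rubin",
    "map_estimate",
    "PosteriorSummary",
    "SamplerSettings",
]


def make_tau_prior(median_hours: float, mode_hours: float) -> tuple[float, float]:
    """(meanlog, sdlog) of the log-normal whose median and mode match the
    inputs: meanlog = ln(median), sdlog = √ln(median/mode).

    Requires 0 < mode < median; the log-normal mode exp(meanlog − sdlog²)
    then reproduces ``mode_hours`` exactly.
    """
    if not 0 < mode_hours < median_hours:
        raise ValueError("need 0 < mode < median for a proper log-normal "
                         f"(got mode={mode_hours}, median={median_hours})")
    meanlog = math.log(median_hours)
    sdlog = math.sqrt(math.log(median_hours / mode_hours))
    return meanlog, sdlog


@dataclass
class PriorSpec:
    """Priors for (β…, p0, τ_hours)."""

    n_beta: int
    beta_sd: float = 3.0
    p0_lower: float = 0.0
    p0_upper: float = 1.0
    tau_meanlog: float = field(default_factory=lambda: make_tau_prior(5.0, 4.0)[0])
    tau_sdlog: float = field(default_factory=lambda: make_tau_prior(5.0, 4.0)[1])

    def __post_init__(self):
        if self.tau_sdlog <= 0:
            raise ValueError("tau prior needs strictly positive sdlog")

    @property
    def dim(self) -> int:
        return self.n_beta + 2

    def log_prior(self, theta: np.ndarray) -> float:
        beta = theta[:self.n_beta]
        p0 = theta[self.n_beta]
        tau = theta[self.n_beta + 1]
        if not (self.p0_lower <= p0 <= self.p0_upper) or tau <= 0:
            return -np.inf
        lp = -0.5 * np.sum((beta / self.beta_sd) ** 2) \
            - self.n_beta * math.log(self.beta_sd * math.sqrt(2 * math.pi))
        lp -= math.log(self.p0_upper - self.p0_lower)
        z = (math.log(tau) - self.tau_meanlog) / self.tau_sdlog
        lp += -0.5 * z * z - math.log(tau * self.tau_sdlog * math.sqrt(2 * math.pi))
        return lp

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        beta = rng.normal(0.0, self.beta_sd, size=self.n_beta)
        p0 = rng.uniform(self.p0_lower, self.p0_upper)
        tau = float(np.exp(rng.normal(self.tau_meanlog, self.tau_sdlog)))
        return np.concatenate([beta, [p0, tau]])


def log_posterior(theta: np.ndarray, prior: PriorSpec,
                  loglik: Callable[[np.ndarray], float]) -> float:
    """Unnormalised log posterior: log prior + log likelihood, −∞ outside
    the prior support (the likelihood is then never evaluated)."""
    lp = prior.log_prior(np.asarray(theta, dtype=float))
    if not np.isfinite(lp):
        return -np.inf
    return lp + loglik(np.asarray(theta, dtype=float))


@dataclass
class SamplerSettings:
    n_chains: int = 3
    n_iter: int = 20_000
    burn_in: int = 5_000
    snooker_prob: float = 0.1
    archive_thin: int = 10
    gamma_unit_prob: float = 0.1
    jitter: float = 1e-6
    init_retries: int = 100
    archive_init: int = 10          # archive seeded with archive_init · d prior draws


@dataclass
class PosteriorSummary:
    """Retained post-burn-in samples and derived summaries."""

    samples: np.ndarray            # (n_retained, d), chains stacked
    log_posts: np.ndarray          # (n_retained,)
    chain_samples: np.ndarray      # (n_chains, n_kept, d)
    rhat: np.ndarray               # (d,)
    map_params: np.ndarray         # (d,)
    map_log_post: float
    acceptance_rate: float

    def quantiles(self, qs: Sequence[float] = (0.025, 0.5, 0.975)) -> np.ndarray:
        return np.quantile(self.samples, qs, axis=0)

    def credible_interval(self, index: int, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.samples[:, index], [a, 1.0 - a])
        return float(lo), float(hi)


def map_estimate(summary: PosteriorSummary) -> np.ndarray:
    """The retained sample with the highest log posterior."""
    if summary.samples.shape[0] == 0:
        raise ValueError("no retained samples")
    return summary.samples[int(np.argmax(summary.log_posts))].copy()


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor R̂ per parameter.

    ``chains`` has shape (n_chains, n_iter, d) with equal-length chains.
    Uses the classic between/within variance form; values near 1 indicate
    the chains have mixed.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    m, n, _ = chains.shape
    if m < 2:
        raise DiagnosticError("R̂ needs at least 2 chains")
    if n < 10:
        raise DiagnosticError("R̂ needs chains of length ≥ 10")
    means = chains.mean(axis=1)                      # (m, d)
    B = n * means.var(axis=0, ddof=1)                # between-chain
    W = chains.var(axis=1, ddof=1).mean(axis=0)      # within-chain
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        # values below 1 are finite-sample noise; clamp so identical chains
        # report exactly 1
        rhat = np.sqrt(np.maximum(var_hat / W, 1.0))
    return np.where(W == 0, 1.0, rhat)


def run_sampler(log_post: Callable[[np.ndarray], float], prior: PriorSpec,
                settings: Optional[SamplerSettings] = None, *,
                seed: int, n_chains: Optional[int] = None,
                n_iter: Optional[int] = None,
                burn_in: Optional[int] = None) -> PosteriorSummary:
    """Differential-evolution MCMC with a sampled-history archive.

    Runs ``n_chains`` interacting chains for ``n_iter`` iterations each,
    discarding ``burn_in``.  Reproducible bit-for-bit under a fixed seed.
    """
    s = settings or SamplerSettings()
    if n_chains is not None:
        s = _replace(s, n_chains=n_chains)
    if n_iter is not None:
        s = _replace(s, n_iter=n_iter)
    if burn_in is not None:
        s = _replace(s, burn_in=burn_in)
    if s.n_chains < 3:
        raise ValueError("need at least 3 chains")
    if s.n_iter <= s.burn_in:
        raise ValueError("n_iter must exceed burn_in")

    rng = np.random.default_rng(seed)
    d = prior.dim
    gamma_de = 2.38 / math.sqrt(2.0 * d)

    # archive seeded from the prior; grown by thinned chain snapshots
    n0 = max(s.archive_init * d, s.n_chains, 4)
    archive = [prior.sample(rng) for _ in range(n0)]

    x = np.empty((s.n_chains, d))
    lp = np.full(s.n_chains, -np.inf)
    for c in range(s.n_chains):
        for _ in range(s.init_retries):
            cand = prior.sample(rng)
            v = log_post(cand)
            if np.isfinite(v):
                x[c], lp[c] = cand, v
                break
        else:
            raise InitializationError(
                f"chain {c}: no finite-posterior start in {s.init_retries} draws")

    n_keep = s.n_iter - s.burn_in
    kept = np.empty((s.n_chains, n_keep, d))
    kept_lp = np.empty((s.n_chains, n_keep))
    n_accept = 0
    n_prop = 0

    for it in range(s.n_iter):
        for c in range(s.n_chains):
            n_prop += 1
            if rng.random() < s.snooker_prob:
                # snooker: move along the line through x and an archive state
                zi = _distinct_indices(rng, len(archive), 3)
                z, z1, z2 = (archive[k] for k in zi)
                delta = x[c] - z
                norm2 = float(delta @ delta)
                if norm2 == 0.0:
                    continue
                proj1 = (z1 @ delta) / norm2 * delta
                proj2 = (z2 @ delta) / norm2 * delta
                gamma_s = rng.uniform(1.2, 2.2)
                cand = x[c] + gamma_s * (proj1 - proj2)
                cand_lp = log_post(cand)
                diff = cand - z
                norm2_new = float(diff @ diff)
                if norm2_new == 0.0:
                    continue
                corr = 0.5 * (d - 1) * (math.log(norm2_new) - math.log(norm2))
                log_alpha = cand_lp - lp[c] + corr
            else:
                zi = _distinct_indices(rng, len(archive), 2)
                gamma = 1.0 if rng.random() < s.gamma_unit_prob else gamma_de
                jump = gamma * (archive[zi[0]] - archive[zi[1]])
                jitter = rng.uniform(-s.jitter, s.jitter, size=d)
                cand = x[c] + jump + jitter
                cand_lp = log_post(cand)
                log_alpha = cand_lp - lp[c]
            if np.isfinite(cand_lp) and np.log(rng.random()) < log_alpha:
                x[c], lp[c] = cand, cand_lp
                n_accept += 1
        if (it + 1) % s.archive_thin == 0:
            archive.extend(x[c].copy() for c in range(s.n_chains))
        if it >= s.burn_in:
            kept[:, it - s.burn_in] = x
            kept_lp[:, it - s.burn_in] = lp

    samples = kept.reshape(-1, d)
    log_posts = kept_lp.reshape(-1)
    best = int(np.argmax(log_posts))
    return PosteriorSummary(
        samples=samples,
        log_posts=log_posts,
        chain_samples=kept,
        rhat=gelman_rubin(kept),
        map_params=samples[best].copy(),
        map_log_post=float(log_posts[best]),
        acceptance_rate=n_accept / max(n_prop, 1),
    )


def _replace(s: SamplerSettings, **kw) -> SamplerSettings:
    from dataclasses import replace as _r
    return _r(s, **kw)


def _distinct_indices(rng: np.random.Generator, n: int, k: int) -> list[int]:
    """k distinct uniform indices in [0, n) without the permutation cost of
    ``rng.choice(..., replace=False)``; n is always ≫ k here."""
    out: list[int] = []
    while len(out) < k:
        i = int(rng.integers(n))
        if i not in out:
            out.append(i)
    return out
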