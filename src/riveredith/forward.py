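"""Forward model for eDNA in a river network.

Each reach i sheds eDNA at rate p_i per unit open-water area, with

    p_i = p0 · exp(βᵀ X(i)),

a log-linear (Poisson GLM) response to standardized environmental
covariates X(i).  The shed material is advected downstream and decays
exponentially with characteristic time τ, so the expected concentration at
a sampling reach j is

    C_j = (1/Q_j) · Σ_{i ∈ γ(j)} p_i · A_S,i · exp(−L_ij / (v̄_ij · τ)),

where γ(j) is the upstream set of j (j included), A_S,i the open-water
source area of reach i, Q_j the discharge at j, L_ij the along-stream
distance and v̄_ij the harmonic-mean velocity of the transit, so that the
exponent is simply −(travel time)/τ.  Read counts at a site are modelled as
geometric on {0, 1, 2, …} with mean proportional to C_j; the
proportionality constant is fixed to 1 and absorbed into p0, which
therefore carries read-equivalent units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SingularDischargeError
from .network import (DEFAULT_PATH_ENDPOINTS, RiverNetwork, SamplingSite,
                      path_metrics, upstream_set)

__all__ = [
    "GenusParams",
    "standardize_covariates",
    "production_rates",
    "forward_concentration",
    "expected_reads",
    "geometric_logpmf",
    "log_likelihood",
    "local_detection_probability",
    "detection_map",
    "presence_map",
    "TransportOperator",
    "LikelihoodContext",
]

SECONDS_PER_HOUR = 3600.0


@dataclass
class GenusParams:
    """The unknowns of one genus × season fit: covariate effects β (one per
    covariate, unitless), baseline production p0 (read-equivalent units per
    m² per s, ≥ 0) and decay time τ (hours, > 0)."""

    beta: np.ndarray
    p0: float
    tau_hours: float

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta components must be finite")
        if self.p0 < 0:
            raise ValueError("p0 must be nonnegative")
        if not self.tau_hours > 0:
            raise ValueError("tau must be positive")

    @property
    def tau_seconds(self) -> float:
        return self.tau_hours * SECONDS_PER_HOUR

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.beta, [self.p0, self.tau_hours]])

    @classmethod
    def from_vector(cls, theta: np.ndarray) -> "GenusParams":
        theta = np.asarray(theta, dtype=float)
        return cls(beta=theta[:-2], p0=float(theta[-2]), tau_hours=float(theta[-1]))


def standardize_covariates(X: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each covariate column to zero mean and unit variance
    (population normalisation) over the full reach set.

    Raises on missing values, duplicate column names and constant columns —
    a constant column cannot be standardized and would alias p0.
    """
    if X.isna().any().any():
        raise ValueError("covariate matrix contains missing values")
    if X.columns.duplicated().any():
        raise ValueError("duplicate covariate names")
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant covariate column(s): {bad}")
    return (X - X.mean(axis=0)) / sd


def production_rates(net: RiverNetwork, X: pd.DataFrame,
                     params: GenusParams) -> pd.Series:
    """Per-reach eDNA production rate p_i = p0 · exp(βᵀ X(i))."""
    missing = [rid for rid in net.reach_ids if rid not in X.index]
    if missing:
        raise ValueError(f"covariate rows missing for reaches {missing[:5]}...")
    Xm = X.loc[net.reach_ids].to_numpy(dtype=float)
    if Xm.shape[1] != len(params.beta):
        raise ValueError(f"covariate/effect dimension mismatch: "
                         f"{Xm.shape[1]} columns vs {len(params.beta)} effects")
    p = params.p0 * np.exp(Xm @ params.beta)
    return pd.Series(p, index=net.reach_ids, name="production")


def forward_concentration(net: RiverNetwork, p: Mapping[str, float],
                          tau_hours: float, j: str,
                          endpoints: str = DEFAULT_PATH_ENDPOINTS) -> float:
    """Expected eDNA concentration C_j at reach j.

    Direct evaluation of the transport sum over the upstream set, with the
    decay factor exp(−travel_time/τ) computed reach by reach along each
    path.  Requires hydraulics (widths, discharges, velocities) loaded.
    """
    reach = net[j]
    if reach.discharge is None or reach.discharge <= 0:
        raise SingularDischargeError(f"reach {j!r} has nonpositive or missing "
                                     "discharge")
    tau_s = tau_hours * SECONDS_PER_HOUR
    total = 0.0
    for i in upstream_set(net, j):
        ri = net[i]
        if ri.source_area is None:
            raise ValueError(f"reach {i!r} has no width loaded")
        _, t = path_metrics(net, i, j, endpoints=endpoints)
        total += p[i] * ri.source_area * np.exp(-t / tau_s)
    return total / reach.discharge


def expected_reads(concentration, scale: float = 1.0):
    """Expected read count μ = scale · C.  The default scale of 1 reflects
    the absorption of the read-count proportionality constant into p0."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative concentration")
    out = scale * c
    return float(out) if out.ndim == 0 else out


def geometric_logpmf(n, mu):
    """log P(N = n) for the geometric distribution on {0, 1, 2, …} with mean
    μ: P(N = n) = (1/(1+μ)) · (μ/(1+μ))ⁿ.  μ = 0 is the point mass at 0."""
    n = np.asarray(n)
    mu = np.asarray(mu, dtype=float)
    if np.any(n < 0) or not np.issubdtype(n.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if np.any(mu < 0):
        raise ValueError("mean must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = -np.log1p(mu) + n * (np.log(mu) - np.log1p(mu))
    # 0 · log 0 at (n=0, μ=0) is the point mass: probability 1
    lp = np.where((mu == 0) & (n == 0), 0.0, lp)
    lp = np.where((mu == 0) & (n > 0), -np.inf, lp)
    return float(lp) if lp.ndim == 0 else lp


def local_detection_probability(reach_id: str, net: RiverNetwork,
                                p: Mapping[str, float],
                                scale: float = 1.0) -> float:
    """Probability of a nonzero read count if the reach were disconnected
    from the network: P(N > 0) = μ/(1+μ) with μ = scale · p_i·A_S,i/Q_i."""
    r = net[reach_id]
    if r.discharge is None or r.discharge <= 0:
        raise SingularDischargeError(f"reach {reach_id!r} has nonpositive or "
                                     "missing discharge")
    if r.source_area is None:
        raise ValueError(f"reach {reach_id!r} has no width loaded")
    mu = scale * p[reach_id] * r.source_area / r.discharge
    return mu / (1.0 + mu)


def detection_map(net: RiverNetwork, X: pd.DataFrame, params: GenusParams,
                  scale: float = 1.0) -> pd.Series:
    """Detection probability at every reach from its local production."""
    p = production_rates(net, X, params)
    vals = [local_detection_probability(rid, net, p, scale)
            for rid in net.reach_ids]
    return pd.Series(vals, index=net.reach_ids, name="detection_prob")


def presence_map(detection: pd.Series, threshold: float = 0.5) -> pd.Series:
    """Threshold detection probabilities into presence/absence.  Presence is
    declared at detection ≥ threshold (boundary inclusive)."""
    det = np.asarray(detection, dtype=float)
    if np.any((det < 0) | (det > 1)):
        raise ValueError("detection probabilities must lie in [0, 1]")
    return pd.Series(det >= threshold, index=detection.index, name="present")


class TransportOperator:
    """Precomputed linear operator mapping per-reach production rates to
    expected concentrations at a fixed set of sampling reaches.

    For a fixed network, season and endpoint convention the transport sum
    is C_j = (1/Q_j) Σ_i m_ij exp(−t_ij/τ) A_S,i p_i with m_ij the upstream
    membership mask and t_ij the travel time; everything except the decay
    factor is independent of the parameters, so repeated likelihood
    evaluations reduce to one exp and one matrix product.
    """

    def __init__(self, net: RiverNetwork, sample_reach_ids: Sequence[str],
                 endpoints: str = DEFAULT_PATH_ENDPOINTS):
        self.reach_ids = net.reach_ids
        self.sample_reach_ids = list(sample_reach_ids)
        idx = {rid: k for k, rid in enumerate(self.reach_ids)}
        n_s, n_r = len(self.sample_reach_ids), len(self.reach_ids)
        self._mask = np.zeros((n_s, n_r), dtype=bool)
        self._time = np.zeros((n_s, n_r))
        self._q = np.empty(n_s)
        area = np.array([net[rid].source_area for rid in self.reach_ids],
                        dtype=float)
        if np.any(~np.isfinite(area)):
            raise ValueError("source areas unavailable: load hydraulics first")
        self._area = area
        # local residence time and cumulative time from each reach (its
        # upstream end) down to the outlet: travel times between any pair on
        # a flow path are then differences, adjusted for the endpoint
        # convention, avoiding a per-pair path walk
        t_local: dict[str, float] = {}
        for rid in self.reach_ids:
            r = net[rid]
            if r.velocity is None or r.velocity <= 0:
                raise ValueError(f"reach {rid!r} has no positive velocity loaded")
            t_local[rid] = r.length / r.velocity
        cum: dict[str, float] = {}
        for rid in reversed(self.reach_ids):  # outlet first
            down = net[rid].downstream_id
            cum[rid] = t_local[rid] + (cum[down] if down is not None else 0.0)
        for row, j in enumerate(self.sample_reach_ids):
            q = net[j].discharge
            if q is None or q <= 0:
                raise SingularDischargeError(f"reach {j!r} has nonpositive or "
                                             "missing discharge")
            self._q[row] = q
            for i in upstream_set(net, j):
                col = idx[i]
                self._mask[row, col] = True
                if i == j:
                    t = 0.0
                else:
                    base = cum[i] - cum[j]
                    if endpoints == "full":
                        t = base
                    elif endpoints == "half":
                        t = base - 0.5 * t_local[i] + 0.5 * t_local[j]
                    else:  # exclusive
                        t = base - t_local[i]
                self._time[row, col] = t

    def concentrations(self, p: np.ndarray, tau_hours: float) -> np.ndarray:
        """C at every sampling reach, in reach order of the constructor."""
        tau_s = tau_hours * SECONDS_PER_HOUR
        decay = np.where(self._mask, np.exp(-self._time / tau_s), 0.0)
        return (decay * self._area) @ np.asarray(p, dtype=float) / self._q


class LikelihoodContext:
    """Everything needed to evaluate the read-count log-likelihood of one
    genus × season fast enough for MCMC.

    Sites whose reach was not sampled in the season are dropped at
    construction.  ``loglik`` takes the stacked parameter vector
    (β…, p0, τ_hours).
    """

    def __init__(self, net: RiverNetwork, X: pd.DataFrame,
                 sites: Sequence[SamplingSite], reads: Mapping[str, int],
                 season: str, scale: float = 1.0,
                 endpoints: str = DEFAULT_PATH_ENDPOINTS):
        active = [s for s in sites if s.sampled_in(season) and s.site_id in reads]
        self.site_ids = [s.site_id for s in active]
        self.counts = np.array([int(reads[s.site_id]) for s in active])
        if np.any(self.counts < 0):
            raise ValueError("negative read counts")
        self.operator = TransportOperator(net, [s.reach_id for s in active],
                                          endpoints=endpoints)
        self._X = X.loc[net.reach_ids].to_numpy(dtype=float)
        self.n_covariates = self._X.shape[1]
        self.scale = scale

    def expected(self, theta: np.ndarray) -> np.ndarray:
        beta, p0, tau = theta[:-2], theta[-2], theta[-1]
        p = p0 * np.exp(self._X @ beta)
        return self.scale * self.operator.concentrations(p, tau)

    def loglik(self, theta: np.ndarray) -> float:
        mu = self.expected(theta)
        n = self.counts
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = -np.log1p(mu) + n * (np.log(mu) - np.log1p(mu))
        zero = mu == 0
        if np.any(zero):
            lp = np.where(zero & (n == 0), 0.0, lp)
            lp = np.where(zero & (n > 0), -np.inf, lp)
        return float(np.sum(lp))


def log_likelihood(params: GenusParams, net: RiverNetwork, X: pd.DataFrame,
                   reads: Mapping[str, int], sites: Sequence[SamplingSite],
                   season: str, scale: float = 1.0,
                   endpoints: str = DEFAULT_PATH_ENDPOINTS) -> float:
    """Geometric log-likelihood of one genus's read counts in one season,
    summed over the sites sampled that season.

    ``reads`` maps site_id → count for the genus/season at hand.
    """
    ctx = LikelihoodContext(net, X, sites, reads, season, scale=scale,
                            endpoints=endpoints)
    return ctx.loglik(params.to_vector())
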