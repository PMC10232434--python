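"""Synthetic study scenarios with known ground truth.

Emulates the ingredients of a seasonal riverine eDNA metabarcoding survey:
a single-outlet branching river network, spatially autocorrelated
environmental covariates, hydraulic power laws, genus-level production
parameters, and geometrically distributed read counts at a subset of
sampled reaches — with a fraction of sites unsampled in one season, as
happens when reaches run dry in summer.

Every random draw flows from the scenario seed through named
``numpy.random.SeedSequence`` spawns, so scenarios are bit-reproducible and
individual stages can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .forward import (GenusParams, TransportOperator, detection_map,
                      presence_map, production_rates, standardize_covariates)
from .hydrology import GaugeObservation, PowerLaw, extrapolate_hydraulics
from .network import (RiverNetwork, SamplingSite, accumulate_drainage_area,
                      build_network, partition_reaches, strahler_order)

__all__ = ["ScenarioConfig", "SyntheticScenario", "generate_network",
           "generate_covariates", "simulate_reads", "make_scenario",
           "true_hydraulic_laws"]


@dataclass
class ScenarioConfig:
    """Knobs of a synthetic study.

    Defaults describe a small, strongly identifiable survey: ~50 reaches
    after partitioning, 5 covariates of which 60% carry strong effects
    (|β| = 1.5), 20 sampling sites over three seasons with ~5% of sites dry
    in summer, and a decay time of 4 h.
    """

    n_headwaters: int = 18
    mean_segment_length: float = 900.0          # m
    segment_length_spread: float = 0.5          # ± fraction of the mean
    max_reach_length: float = 1000.0            # m, partitioning threshold
    local_area_range: tuple[float, float] = (0.25, 2.0)   # km²
    n_covariates: int = 5
    n_indicator_covariates: int = 2             # subtree (tributary) indicators
    covariate_autocorrelation: float = 0.7
    n_genera: Mapping[str, int] = field(
        default_factory=lambda: {"fish": 4, "invertebrates": 6})
    effect_sparsity: float = 0.4                # fraction of zero β components
    effect_size: float = 1.5                    # |β| of the non-zero components
    p0_range: tuple[float, float] = (1e-4, 1e-2)   # log-uniform draw
    true_tau_hours: float = 4.0
    seasons: tuple[str, ...] = ("spring", "summer", "autumn")
    n_sites: int = 20
    missing_site_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"summer": 0.05})
    detection_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_headwaters < 2:
            raise ValueError("need at least 2 headwaters")
        if not 0 <= self.covariate_autocorrelation < 1:
            raise ValueError("autocorrelation must be in [0, 1)")
        for frac in self.missing_site_fraction.values():
            if not 0 <= frac <= 1:
                raise ValueError("missing-site fractions must be in [0, 1]")
        if self.n_indicator_covariates >= self.n_covariates:
            raise ValueError("need at least one continuous covariate")


#: Hydraulic scaling used to generate scenarios: exponents near the
#: classical downstream hydraulic-geometry values (discharge ~ A¹,
#: width ~ A^0.5, depth ~ A^0.4), with seasonal discharge/depth multipliers
#: (wet spring, dry summer).
_SEASON_FLOW = {"spring": 1.3, "summer": 0.6, "autumn": 1.0}


def true_hydraulic_laws(seasons: Sequence[str]) -> dict:
    laws: dict = {"width": PowerLaw(2.0, 0.5, "width", "all"),
                  "depth": {}, "discharge": {}}
    for s in seasons:
        f = _SEASON_FLOW.get(s, 1.0)
        laws["depth"][s] = PowerLaw(0.2 * f ** 0.4, 0.4, "depth", s)
        laws["discharge"][s] = PowerLaw(0.05 * f, 1.0, "discharge", s)
    return laws


def generate_network(config: ScenarioConfig,
                     rng: Optional[np.random.Generator] = None) -> RiverNetwork:
    """A random binary-confluence tree, partitioned to the maximum reach
    length, with drainage areas and Strahler orders computed.

    Built by iteratively merging two random active branches below a new
    confluence segment; n headwaters yield 2n−1 segments before
    partitioning.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    lo = config.mean_segment_length * (1 - config.segment_length_spread)
    hi = config.mean_segment_length * (1 + config.segment_length_spread)
    a_lo, a_hi = config.local_area_range

    records: list[tuple] = []
    counter = 0

    def new_segment() -> str:
        nonlocal counter
        counter += 1
        return f"r{counter:04d}"

    active = []
    for _ in range(config.n_headwaters):
        sid = new_segment()
        records.append([sid, None, rng.uniform(lo, hi), rng.uniform(a_lo, a_hi)])
        active.append(sid)
    index = {rec[0]: rec for rec in records}
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        sid = new_segment()
        records.append([sid, None, rng.uniform(lo, hi), rng.uniform(a_lo, a_hi)])
        index[sid] = records[-1]
        index[a][1] = sid
        index[b][1] = sid
        active.append(sid)

    net = build_network([tuple(r) for r in records])
    net = partition_reaches(net, config.max_reach_length)
    accumulate_drainage_area(net)
    strahler_order(net)
    return net


def generate_covariates(net: RiverNetwork, config: ScenarioConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> pd.DataFrame:
    """Standardized reach × covariate matrix.

    Continuous covariates follow an AR(1) cascade down the tree: a reach's
    value is ρ times the mean of its upstream neighbours' values plus
    √(1−ρ²) innovation noise, emulating smoothly varying land-cover or
    geology fields.  The last ``n_indicator_covariates`` columns are
    standardized membership indicators of random tributary subtrees.
    """
    rng = np.random.default_rng(config.seed + 1 if rng is None else rng)
    ids = net.reach_ids
    rho = config.covariate_autocorrelation
    n_cont = config.n_covariates - config.n_indicator_covariates
    cols: dict[str, np.ndarray] = {}
    for k in range(n_cont):
        vals: dict[str, float] = {}
        for rid in ids:  # upstream-first order
            ups = net.upstream_neighbors(rid)
            innov = rng.normal()
            if ups:
                vals[rid] = rho * float(np.mean([vals[u] for u in ups])) \
                    + np.sqrt(1 - rho ** 2) * innov
            else:
                vals[rid] = innov
        cols[f"env{k + 1}"] = np.array([vals[rid] for rid in ids])

    if config.n_indicator_covariates > 0:
        # subtree roots drawn from mid-size reaches so the indicator is
        # neither constant nor a single reach
        from .network import upstream_set
        sizes = {rid: len(upstream_set(net, rid)) for rid in ids}
        eligible = [rid for rid in ids if 2 <= sizes[rid] <= len(ids) - 2]
        for k in range(config.n_indicator_covariates):
            root = eligible[int(rng.integers(len(eligible)))] if eligible \
                else ids[int(rng.integers(len(ids)))]
            members = upstream_set(net, root)
            cols[f"trib{k + 1}"] = np.array(
                [1.0 if rid in members else 0.0 for rid in ids])

    X = pd.DataFrame(cols, index=pd.Index(ids, name="reach_id"))
    # an indicator subtree can degenerate to the whole network on tiny
    # trees; re-draw noise for any constant column
    for c in X.columns:
        if X[c].std(ddof=0) == 0:
            X[c] = rng.normal(size=len(ids))
    return standardize_covariates(X)


def _draw_genus_params(config: ScenarioConfig, rng: np.random.Generator
                       ) -> GenusParams:
    n = config.n_covariates
    n_zero = int(round(config.effect_sparsity * n))
    beta = np.full(n, config.effect_size) * rng.choice([-1.0, 1.0], size=n)
    zero_idx = rng.choice(n, size=n_zero, replace=False)
    beta[zero_idx] = 0.0
    # log-uniform: occupancy then spans rare to widespread genera, since
    # presence flips where p0·exp(βᵀX) crosses the local Q/A_S ratio
    lo, hi = np.log(config.p0_range)
    p0 = float(np.exp(rng.uniform(lo, hi)))
    return GenusParams(beta=beta, p0=p0, tau_hours=config.true_tau_hours)


@dataclass
class SyntheticScenario:
    """A fully wired synthetic study with its ground truth."""

    config: ScenarioConfig
    network: RiverNetwork                       # topology + drainage areas
    seasonal_networks: dict[str, RiverNetwork]  # hydraulics loaded per season
    covariates: pd.DataFrame
    hydraulic_laws: dict
    gauges: list[GaugeObservation]
    sites: list[SamplingSite]
    true_params: dict[str, GenusParams]         # per genus (season-invariant)
    genus_groups: dict[str, str]                # genus → taxonomic group
    reads: pd.DataFrame                         # site_id, genus, season, reads
    true_presence: dict[str, pd.DataFrame]      # season → reach × genus bool

    @property
    def genera(self) -> list[str]:
        return list(self.true_params)


def simulate_reads(seasonal_networks: Mapping[str, RiverNetwork],
                   covariates: pd.DataFrame, sites: Sequence[SamplingSite],
                   true_params: Mapping[str, GenusParams],
                   rng) -> pd.DataFrame:
    """Draw one geometric read count per site × genus × season from the
    forward model under the true parameters; sites missing a season are
    omitted.  The geometric success parameter is 1/(1+μ), giving support
    {0, 1, 2, …} and mean μ."""
    rng = np.random.default_rng(rng)
    rows = []
    for season, net in seasonal_networks.items():
        active = [s for s in sites if s.sampled_in(season)]
        if not active:
            continue
        op = TransportOperator(net, [s.reach_id for s in active])
        for genus in sorted(true_params):
            gp = true_params[genus]
            p = production_rates(net, covariates, gp).to_numpy()
            mu = op.concentrations(p, gp.tau_hours)
            counts = np.where(mu > 0,
                              rng.geometric(1.0 / (1.0 + mu)) - 1, 0)
            for s, n in zip(active, counts):
                rows.append((s.site_id, genus, season, int(n)))
    return pd.DataFrame(rows, columns=["site_id", "genus", "season", "reads"])


def make_scenario(config: Optional[ScenarioConfig] = None) -> SyntheticScenario:
    """Build the full synthetic bundle: network, covariates, hydraulics,
    gauges, sites, true parameters, read table and true presence maps."""
    config = config or ScenarioConfig()
    ss = np.random.SeedSequence(config.seed)
    rngs = {name: np.random.default_rng(s) for name, s in zip(
        ("network", "covariates", "params", "sites", "reads", "gauges"),
        ss.spawn(6))}

    net = generate_network(config, rngs["network"])
    X = generate_covariates(net, config, rngs["covariates"])
    laws = true_hydraulic_laws(config.seasons)
    seasonal = {s: extrapolate_hydraulics(net, laws, s) for s in config.seasons}

    # synthetic gauge observations at the four largest-area reaches, read
    # off the true laws (exact, so law-recovery is testable separately)
    by_area = sorted(net.reach_ids, key=lambda r: -net[r].drainage_area)
    gauges = []
    for rid in by_area[:4]:
        A = net[rid].drainage_area
        for s in config.seasons:
            gauges.append(GaugeObservation(
                reach_id=rid, season=s, drainage_area=A,
                discharge=float(laws["discharge"][s](A)),
                width=float(laws["width"](A)),
                depth=float(laws["depth"][s](A))))

    genus_groups: dict[str, str] = {}
    true_params: dict[str, GenusParams] = {}
    for group, count in config.n_genera.items():
        for k in range(count):
            name = f"{group[:3]}_g{k + 1:02d}"
            genus_groups[name] = group
            true_params[name] = _draw_genus_params(config, rngs["params"])

    site_reaches = rngs["sites"].choice(net.reach_ids, size=config.n_sites,
                                        replace=False)
    sites = []
    for k, rid in enumerate(site_reaches):
        seasons = [s for s in config.seasons
                   if rngs["sites"].random() >= config.missing_site_fraction.get(s, 0.0)]
        if not seasons:
            seasons = [config.seasons[0]]
        sites.append(SamplingSite(site_id=f"S{k + 1:03d}", reach_id=str(rid),
                                  seasons_sampled=tuple(seasons)))

    reads = simulate_reads(seasonal, X, sites, true_params, rngs["reads"])

    true_presence: dict[str, pd.DataFrame] = {}
    for s in config.seasons:
        cols = {}
        for genus, gp in true_params.items():
            det = detection_map(seasonal[s], X, gp)
            cols[genus] = presence_map(det, config.detection_threshold)
        true_presence[s] = pd.DataFrame(cols)

    return SyntheticScenario(
        config=config, network=net, seasonal_networks=seasonal, covariates=X,
        hydraulic_laws=laws, gauges=gauges, sites=sites,
        true_params=true_params, genus_groups=genus_groups, reads=reads,
        true_presence=true_presence)
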