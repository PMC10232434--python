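"""Diversity analyses on predicted and raw genus communities.

α-diversity is genus richness per reach (predicted) or per site (raw eDNA).
Because covariate-driven predictions are spatially autocorrelated, trends
of richness on drainage area are tested not with a classical slope test but
with a decile-stratified bootstrap: reaches are binned by drainage-area
deciles, a fixed number is resampled with replacement from each bin, an OLS
line is fitted on natural (untransformed) area, and the sign of the slope
is tallied over replicates.

Spatial β-diversity compares communities of flow-unconnected reach pairs
within an "upstream" and a "downstream" group (split at the median drainage
area), using the Jaccard dissimilarity and its additive partition into
turnover (species replacement) and nestedness (subset loss) components of
the Jaccard family.  Temporal β-diversity is the per-reach Jaccard distance
between two seasons' communities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BinningError, InsufficientDataError, UndefinedGroupError
from .network import RiverNetwork, upstream_set

__all__ = [
    "contamination_filter",
    "richness",
    "raw_richness",
    "regress_on_area",
    "bootstrap_trend_test",
    "split_by_median_area",
    "select_flow_unconnected_pairs",
    "jaccard_decompose",
    "spatial_beta_test",
    "temporal_beta",
    "compare_predicted_vs_raw",
    "cross_season_summaries",
    "JaccardDecomposition",
    "TrendTestResult",
    "SpatialBetaResult",
]


# ---------------------------------------------------------------------------
# read-table filtering and richness

def contamination_filter(table: pd.DataFrame, fraction: float = 0.001,
                         mode: str = "subtract") -> pd.DataFrame:
    """Remove putative contamination/tag-jumping reads per sample.

    A *sample* is one (site, season) combination.  With ``mode="subtract"``
    (default) an amount equal to ``fraction`` of the sample's total reads is
    subtracted from every genus with nonzero reads, clamped at zero and
    truncated to integer.  With ``mode="threshold"`` genera whose count
    falls below that amount are zeroed and others are left untouched.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if mode not in ("subtract", "threshold"):
        raise ValueError(f"unknown filter mode {mode!r}")
    out = table.copy()
    out["reads"] = out["reads"].astype(np.int64)
    for _, idx in out.groupby(["site_id", "season"]).groups.items():
        reads = out.loc[idx, "reads"]
        cut = fraction * reads.sum()
        nonzero = reads > 0
        if mode == "subtract":
            out.loc[idx, "reads"] = np.where(
                nonzero, np.floor(np.maximum(reads - cut, 0)).astype(np.int64),
                reads)
        else:
            out.loc[idx, "reads"] = np.where(nonzero & (reads < cut), 0, reads)
    return out


def richness(presence: pd.DataFrame) -> pd.Series:
    """Genus richness per reach from a reach × genus boolean table."""
    return presence.astype(bool).sum(axis=1).rename("richness")


def raw_richness(table: pd.DataFrame, genera: Sequence[str],
                 season: str) -> pd.Series:
    """Richness per site computed directly from (filtered) read counts:
    the number of listed genera with reads > 0 in the given season."""
    sub = table[(table["season"] == season) & table["genus"].isin(genera)]
    counts = (sub[sub["reads"] > 0].groupby("site_id")["genus"].nunique())
    sites = sub["site_id"].unique()
    return counts.reindex(sites, fill_value=0).rename("richness").sort_index()


# ---------------------------------------------------------------------------
# trends on drainage area

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def regress_on_area(values: Sequence[float], areas: Sequence[float]) -> RegressionResult:
    """OLS of a diversity value on natural (untransformed) drainage area,
    with the two-sided slope p-value (used for raw-data tests, where
    observations are taken as independent)."""
    v = np.asarray(values, dtype=float)
    a = np.asarray(areas, dtype=float)
    if v.size < 3:
        raise InsufficientDataError("need at least 3 points for a regression")
    res = stats.linregress(a, v)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), float(res.pvalue))


@dataclass
class TrendTestResult:
    """Outcome of the decile-stratified bootstrap slope test."""

    slope: float                  # full-data OLS slope, per km²
    intercept: float
    r_squared: float
    n_positive: int               # replicates with positive slope
    verdict: str                  # positive-significant / negative-significant / non-significant
    area_grid: np.ndarray
    ci_low: np.ndarray            # 2.5th pct of fitted lines on the grid
    ci_high: np.ndarray           # 97.5th pct
    replicate_slopes: np.ndarray


def bootstrap_trend_test(values: Sequence[float], areas: Sequence[float],
                         n_bins: int = 10, per_bin: int = 50, reps: int = 100,
                         seed: int = 0, sig_count: int = 95,
                         grid_points: int = 100) -> TrendTestResult:
    """Test the sign of the richness–area trend by stratified resampling.

    Reaches are split into ``n_bins`` drainage-area decile bins; each
    replicate draws ``per_bin`` reaches with replacement from every bin and
    fits OLS on natural area.  The trend is declared positive-significant
    (negative-significant) when at least ``sig_count`` of ``reps``
    replicates yield a positive (negative) slope.  The 2.5th–97.5th
    percentile envelope of the replicate regression lines over an area grid
    is returned as the confidence band of the fit.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(areas, dtype=float)
    if v.size < n_bins:
        raise InsufficientDataError(f"need at least {n_bins} reaches")
    edges = np.quantile(a, np.linspace(0, 1, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(edges, a, side="right") - 1, 0, n_bins - 1)
    bins = [np.flatnonzero(bin_idx == b) for b in range(n_bins)]
    empty = [b for b, members in enumerate(bins) if members.size == 0]
    if empty:
        raise BinningError(
            f"drainage-area decile bin(s) {empty} are empty — the area "
            "distribution is too discrete; reduce n_bins or jitter areas")

    rng = np.random.default_rng(seed)
    grid = np.linspace(a.min(), a.max(), grid_points)
    slopes = np.empty(reps)
    lines = np.empty((reps, grid_points))
    for r in range(reps):
        idx = np.concatenate([rng.choice(members, size=per_bin, replace=True)
                              for members in bins])
        sl, ic = np.polyfit(a[idx], v[idx], 1)
        slopes[r] = sl
        lines[r] = sl * grid + ic

    n_positive = int(np.sum(slopes > 0))
    if n_positive >= sig_count:
        verdict = "positive-significant"
    elif n_positive <= reps - sig_count:
        verdict = "negative-significant"
    else:
        verdict = "non-significant"
    full = regress_on_area(v, a) if v.size >= 3 else None
    lo, hi = np.percentile(lines, [2.5, 97.5], axis=0)
    return TrendTestResult(slope=full.slope, intercept=full.intercept,
                           r_squared=full.r_squared, n_positive=n_positive,
                           verdict=verdict, area_grid=grid, ci_low=lo,
                           ci_high=hi, replicate_slopes=slopes)


# ---------------------------------------------------------------------------
# spatial β-diversity

def split_by_median_area(net: RiverNetwork) -> dict[str, list[str]]:
    """Partition reaches into an upstream group (drainage area strictly
    below the network median) and a downstream group (at or above it; ties
    go downstream)."""
    ids = net.reach_ids
    areas = np.array([net[rid].drainage_area for rid in ids], dtype=float)
    if np.any(~np.isfinite(areas)):
        raise ValueError("drainage areas must be accumulated first")
    med = float(np.median(areas))
    return {"upstream": [rid for rid, ar in zip(ids, areas) if ar < med],
            "downstream": [rid for rid, ar in zip(ids, areas) if ar >= med]}


def select_flow_unconnected_pairs(net: RiverNetwork, ids: Sequence[str],
                                  rng) -> list[tuple[str, str]]:
    """A random maximal matching of flow-unconnected reach pairs.

    Each id is used in at most one pair; pairing stops when no two unused
    ids are flow-unconnected, so the result is maximal by construction.
    ``rng`` is a seed or a numpy Generator.
    """
    rng = np.random.default_rng(rng)
    ids = list(ids)
    up = {rid: upstream_set(net, rid) for rid in ids}

    def unconnected(x: str, y: str) -> bool:
        return x not in up[y] and y not in up[x]

    remaining = list(ids)
    rng.shuffle(remaining)
    pairs: list[tuple[str, str]] = []
    while len(remaining) >= 2:
        a = remaining.pop()
        candidates = [b for b in remaining if unconnected(a, b)]
        if not candidates:
            continue  # a is connected to every unused id: discard it
        b = candidates[int(rng.integers(len(candidates)))]
        remaining.remove(b)
        pairs.append((a, b))
    return pairs


@dataclass(frozen=True)
class JaccardDecomposition:
    """Total Jaccard dissimilarity and its additive turnover/nestedness
    partition (Jaccard family): total = turnover + nestedness."""

    total: float
    turnover: float
    nestedness: float


def jaccard_decompose(a: int, b: int, c: int) -> JaccardDecomposition:
    """Partition the Jaccard dissimilarity of two communities sharing ``a``
    genera, with ``b`` and ``c`` unique to each.

    total = (b+c)/(a+b+c); turnover = 2·min(b,c)/(a+2·min(b,c));
    nestedness = total − turnover.  Undefined when both communities are
    empty (a = b = c = 0).
    """
    if min(a, b, c) < 0:
        raise ValueError("community counts must be nonnegative")
    if a + b + c == 0:
        raise ValueError("Jaccard dissimilarity is undefined for two empty "
                         "communities")
    total = (b + c) / (a + b + c)
    m = min(b, c)
    turnover = 2 * m / (a + 2 * m) if m > 0 else 0.0
    return JaccardDecomposition(total=total, turnover=turnover,
                                nestedness=total - turnover)


def _pair_jaccard(presence: pd.DataFrame, x: str, y: str) -> Optional[JaccardDecomposition]:
    px = presence.loc[x].to_numpy(dtype=bool)
    py = presence.loc[y].to_numpy(dtype=bool)
    a = int(np.sum(px & py))
    b = int(np.sum(px & ~py))
    c = int(np.sum(~px & py))
    if a + b + c == 0:
        return None
    return jaccard_decompose(a, b, c)


@dataclass
class SpatialBetaResult:
    """Per-location-group distributions of mean Jaccard distance across the
    pair-selection replicates, with equal-tailed 95% intervals and the
    interval-overlap significance verdict."""

    group_means: dict[str, np.ndarray]      # reps values per group
    intervals: dict[str, tuple[float, float]]
    turnover_means: dict[str, float]
    nestedness_means: dict[str, float]
    significant: bool
    direction: Optional[str]                # group with higher mean, if significant


def spatial_beta_test(presence: pd.DataFrame, net: RiverNetwork,
                      reps: int = 100, seed: int = 0,
                      groups: Optional[Mapping[str, Sequence[str]]] = None
                      ) -> SpatialBetaResult:
    """Compare β-diversity of flow-unconnected pairs between the upstream
    and downstream location groups.

    For each replicate and group, a fresh random maximal matching of
    flow-unconnected pairs is drawn and the mean total Jaccard distance
    over pairs (pairs of two empty communities excluded) is recorded.  The
    group effect is significant when the two equal-tailed 95% intervals of
    those means do not overlap.
    """
    if groups is None:
        groups = split_by_median_area(net)
    rng = np.random.default_rng(seed)
    means: dict[str, list[float]] = {g: [] for g in groups}
    turn: dict[str, list[float]] = {g: [] for g in groups}
    nest: dict[str, list[float]] = {g: [] for g in groups}
    for _ in range(reps):
        for g, ids in groups.items():
            pairs = select_flow_unconnected_pairs(net, ids, rng)
            decs = [d for x, y in pairs
                    if (d := _pair_jaccard(presence, x, y)) is not None]
            if decs:
                means[g].append(float(np.mean([d.total for d in decs])))
                turn[g].append(float(np.mean([d.turnover for d in decs])))
                nest[g].append(float(np.mean([d.nestedness for d in decs])))
    for g in groups:
        if not means[g]:
            raise UndefinedGroupError(
                f"location group {g!r} produced no valid flow-unconnected "
                "pair in any replicate")
    dists = {g: np.asarray(means[g]) for g in groups}
    intervals = {g: tuple(np.percentile(dists[g], [2.5, 97.5])) for g in groups}
    gnames = list(groups)
    significant = False
    direction = None
    if len(gnames) == 2:
        (l1, h1), (l2, h2) = intervals[gnames[0]], intervals[gnames[1]]
        significant = h1 < l2 or h2 < l1
        if significant:
            direction = gnames[0] if np.mean(dists[gnames[0]]) > np.mean(
                dists[gnames[1]]) else gnames[1]
    return SpatialBetaResult(
        group_means=dists, intervals=intervals,
        turnover_means={g: float(np.mean(turn[g])) for g in groups},
        nestedness_means={g: float(np.mean(nest[g])) for g in groups},
        significant=significant, direction=direction)


# ---------------------------------------------------------------------------
# temporal β-diversity and predicted-vs-raw comparisons

def temporal_beta(presence_a: pd.DataFrame,
                  presence_b: pd.DataFrame) -> pd.DataFrame:
    """Per-reach Jaccard decomposition between two seasons' communities.

    Returns a frame indexed by reach with columns total/turnover/nestedness
    and a ``defined`` flag; reaches empty in both seasons are undefined
    (NaN) and should be excluded from downstream regressions.
    """
    if not presence_a.index.equals(presence_b.index) or \
            list(presence_a.columns) != list(presence_b.columns):
        raise ValueError("presence tables must share reach and genus sets")
    pa = presence_a.to_numpy(dtype=bool)
    pb = presence_b.to_numpy(dtype=bool)
    a = np.sum(pa & pb, axis=1)
    b = np.sum(pa & ~pb, axis=1)
    c = np.sum(~pa & pb, axis=1)
    n = a + b + c
    defined = n > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        total = np.where(defined, (b + c) / np.maximum(n, 1), np.nan)
        m = np.minimum(b, c)
        turnover = np.where(defined & (m > 0), 2 * m / np.maximum(a + 2 * m, 1), 0.0)
        turnover = np.where(defined, turnover, np.nan)
    return pd.DataFrame({
        "total": total,
        "turnover": turnover,
        "nestedness": total - turnover,
        "defined": defined,
    }, index=presence_a.index)


def compare_predicted_vs_raw(pred: Sequence[float], raw: Sequence[float]
                             ) -> tuple[float, float, float]:
    """Welch two-sample t-test comparing the means of predicted and raw
    diversity distributions.  Returns (t, p, mean difference pred − raw).
    Two identical constant samples give (0, 1) by convention."""
    x = np.asarray(pred, dtype=float)
    y = np.asarray(raw, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("need at least 2 values per sample")
    diff = float(x.mean() - y.mean())
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if diff == 0:
            return 0.0, 1.0, 0.0
        return float(np.sign(diff) * np.inf), 0.0, diff
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p), diff


def cross_season_summaries(presence_by_season: Mapping[str, pd.DataFrame],
                           denominator: str = "union"
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Cross-season consistency of the predictions.

    Returns the Pearson correlation matrix of per-reach richness vectors
    across seasons, and a per-genus occupancy-overlap statistic: the number
    of reaches occupied in *all* seasons divided by the number occupied in
    *any* season (``denominator="union"``) or by the maximum single-season
    occupancy (``denominator="max"``); NaN for genera never present.
    """
    seasons = list(presence_by_season)
    if len(seasons) < 2:
        raise ValueError("need at least 2 seasons")
    rich = pd.DataFrame({s: richness(presence_by_season[s]) for s in seasons})
    corr = rich.corr(method="pearson")
    first = presence_by_season[seasons[0]]
    inter = first.astype(bool).copy()
    union = first.astype(bool).copy()
    maxocc = first.astype(bool).sum(axis=0)
    for s in seasons[1:]:
        p = presence_by_season[s].astype(bool)
        inter &= p
        union |= p
        maxocc = np.maximum(maxocc, p.sum(axis=0))
    if denominator == "union":
        den = union.sum(axis=0)
    elif denominator == "max":
        den = maxocc
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(invalid="ignore"):
        overlap = inter.sum(axis=0) / den.replace(0, np.nan)
    return corr, overlap.rename("occupancy_overlap")
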