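"""Hydraulic geometry: power-law scaling of channel properties on drainage
area, fitted from a handful of gauge observations and extrapolated to every
reach.

Downstream hydraulic geometry classically takes the form value = c · A^e
with A the drainage area; the fit is ordinary least squares on the log-log
pairs, the standard approach in hydrology and exactly reproducible.  Width
is treated as season-invariant (channel geometry), while discharge and
water depth are fitted per season.  Velocity follows from continuity under
rectangular cross-sections, v = Q / (w · d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .errors import ConfigError, InsufficientDataError
from .network import RiverNetwork

__all__ = [
    "GaugeObservation",
    "PowerLaw",
    "fit_power_law",
    "fit_hydraulic_laws",
    "extrapolate_hydraulics",
]

HYDRAULIC_VARIABLES = ("width", "depth", "discharge")


@dataclass(frozen=True)
class GaugeObservation:
    """Channel measurements at one gauged reach for one season."""

    reach_id: str
    season: str
    drainage_area: float  # km²
    discharge: float      # m³/s
    width: float          # m
    depth: float          # m

    def __post_init__(self):
        if self.width <= 0 or self.depth <= 0:
            raise ValueError("gauge width and depth must be positive")
        if self.discharge < 0:
            raise ValueError("gauge discharge must be nonnegative")


@dataclass(frozen=True)
class PowerLaw:
    """value(A) = coefficient · A^exponent, A in km²."""

    coefficient: float
    exponent: float
    variable: str = ""
    season: str = "all"

    def __post_init__(self):
        if self.coefficient <= 0:
            raise ValueError("power-law coefficient must be positive")

    def __call__(self, area) :
        return self.coefficient * np.asarray(area, dtype=float) ** self.exponent


def fit_power_law(points: Sequence[tuple[float, float]],
                  variable: str = "", season: str = "all") -> PowerLaw:
    """Least-squares power law through (drainage area, value) pairs.

    OLS on (log area, log value).  If all areas coincide the exponent is
    indeterminate and set to 0 with the coefficient at the geometric mean of
    the values, so a law fitted at a single support point reproduces the
    observation there.
    """
    pts = [(float(a), float(v)) for a, v in points]
    if len(pts) < 2:
        raise InsufficientDataError(
            f"need at least 2 points to fit a power law, got {len(pts)}")
    areas = np.array([a for a, _ in pts])
    values = np.array([v for _, v in pts])
    if np.any(areas <= 0) or np.any(values <= 0):
        raise ValueError("power-law fit requires strictly positive areas and values")
    la, lv = np.log(areas), np.log(values)
    if np.ptp(la) == 0.0:
        return PowerLaw(float(np.exp(lv.mean())), 0.0, variable, season)
    exponent, intercept = np.polyfit(la, lv, 1)
    return PowerLaw(float(np.exp(intercept)), float(exponent), variable, season)


LawSet = Mapping[str, Union[PowerLaw, Mapping[str, PowerLaw]]]


def fit_hydraulic_laws(gauges: Iterable[GaugeObservation],
                       net: Optional[RiverNetwork] = None,
                       area_tolerance: float = 0.05) -> dict:
    """Fit the full set of hydraulic power laws from gauge observations.

    Width is fitted once on all observations pooled; discharge and depth are
    fitted separately per season.  When ``net`` is given, each gauge's
    reported drainage area is checked against the network's value at that
    reach and a warning is emitted beyond ``area_tolerance`` relative
    mismatch.

    Returns ``{"width": PowerLaw, "depth": {season: PowerLaw},
    "discharge": {season: PowerLaw}}``.
    """
    obs = list(gauges)
    if net is not None:
        for g in obs:
            a_net = net[g.reach_id].drainage_area
            if a_net is not None and a_net > 0:
                if abs(g.drainage_area - a_net) / a_net > area_tolerance:
                    warnings.warn(
                        f"gauge at reach {g.reach_id!r}: drainage area "
                        f"{g.drainage_area} km² differs from network value "
                        f"{a_net:.4g} km² by more than {area_tolerance:.0%}")
    width = fit_power_law([(g.drainage_area, g.width) for g in obs],
                          "width", "all")
    laws: dict = {"width": width, "depth": {}, "discharge": {}}
    for season in sorted({g.season for g in obs}):
        sg = [g for g in obs if g.season == season]
        laws["depth"][season] = fit_power_law(
            [(g.drainage_area, g.depth) for g in sg], "depth", season)
        laws["discharge"][season] = fit_power_law(
            [(g.drainage_area, g.discharge) for g in sg], "discharge", season)
    return laws


def _resolve(laws: LawSet, variable: str, season: str) -> PowerLaw:
    try:
        entry = laws[variable]
    except KeyError:
        raise ConfigError(f"no power law for {variable!r}") from None
    if isinstance(entry, PowerLaw):
        return entry
    try:
        return entry[season]
    except KeyError:
        if "all" in entry:
            return entry["all"]
        raise ConfigError(f"no power law for {variable!r} in season "
                          f"{season!r}") from None


def extrapolate_hydraulics(net: RiverNetwork, laws: LawSet,
                           season: str) -> RiverNetwork:
    """Load one season's hydraulics onto every reach of a copy of ``net``.

    Requires drainage areas.  Sets width, depth, discharge from the power
    laws and velocity = Q/(w·d); the reach source area (length × width)
    becomes available as a consequence.
    """
    w_law = _resolve(laws, "width", season)
    d_law = _resolve(laws, "depth", season)
    q_law = _resolve(laws, "discharge", season)
    out = net.copy()
    out.season_tag = season
    for r in out:
        if r.drainage_area is None:
            raise ConfigError("drainage areas must be accumulated before "
                              "hydraulic extrapolation")
        r.width = float(w_law(r.drainage_area))
        r.depth = float(d_law(r.drainage_area))
        r.discharge = float(q_law(r.drainage_area))
        r.velocity = r.discharge / (r.width * r.depth)
    return out
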