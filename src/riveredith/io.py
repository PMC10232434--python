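"""CSV schemas, run configuration and deterministic seed fan-out.

All tables are plain CSV with fixed headers:

- network:    ``reach_id,downstream_id,length_m,local_area_km2``
  (``downstream_id`` empty for the outlet);
- covariates: ``reach_id,<cov1>,<cov2>,…``;
- reads:      ``site_id,genus,season,reads``;
- gauges:     ``reach_id,season,drainage_area_km2,discharge_m3s,width_m,depth_m``;
- sites:      ``site_id,reach_id``.

Floats are written with ``repr``-level precision so that a write/read
round-trip of canonicalized files is byte-stable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, ValidationError
from .hydrology import GaugeObservation
from .network import RiverNetwork, SamplingSite, build_network

__all__ = [
    "read_network_csv", "write_network_csv",
    "read_covariates_csv", "read_reads_csv", "write_reads_csv",
    "read_gauges_csv", "read_sites_csv", "write_sites_csv",
    "RunConfig", "derive_seed",
]

_FLOAT_FMT = "%.12g"


def derive_seed(run_seed: int, *labels) -> int:
    """A per-stage seed below 2³¹ derived by hashing the run seed together
    with stage labels (stage name, genus, season, …), so re-running one
    genus never shifts the streams of another."""
    key = ":".join([str(run_seed), *map(str, labels)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# readers / writers

def read_network_csv(path) -> RiverNetwork:
    df = pd.read_csv(path, dtype={"reach_id": str, "downstream_id": str})
    required = ["reach_id", "downstream_id", "length_m", "local_area_km2"]
    _require_columns(df, required, path)
    records = [
        (row.reach_id,
         None if pd.isna(row.downstream_id) or row.downstream_id == "" else row.downstream_id,
         float(row.length_m), float(row.local_area_km2))
        for row in df.itertuples(index=False)
    ]
    return build_network(records)


def write_network_csv(net: RiverNetwork, path) -> None:
    rows = [{"reach_id": r.id,
             "downstream_id": "" if r.downstream_id is None else r.downstream_id,
             "length_m": r.length, "local_area_km2": r.local_area}
            for r in (net[rid] for rid in net.reach_ids)]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_covariates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"reach_id": str})
    _require_columns(df, ["reach_id"], path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: no covariate columns")
    df = df.set_index("reach_id")
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing covariate values")
    return df


def read_reads_csv(path, seasons: Optional[Sequence[str]] = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str, "genus": str, "season": str})
    _require_columns(df, ["site_id", "genus", "season", "reads"], path)
    bad = df[(df["reads"] < 0) | (df["reads"] != df["reads"].astype(int))]
    if len(bad):
        raise ValidationError(
            f"{path}: reads must be nonnegative integers "
            f"(first offending row index {bad.index[0]})")
    df["reads"] = df["reads"].astype(int)
    dup = df.duplicated(["site_id", "genus", "season"])
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate (site, genus, season) at row index "
            f"{df.index[dup][0]}")
    if seasons is not None:
        unknown = set(df["season"]) - set(seasons)
        if unknown:
            raise ValidationError(f"{path}: unknown season label(s) "
                                  f"{sorted(unknown)}")
    return df


def write_reads_csv(table: pd.DataFrame, path) -> None:
    table[["site_id", "genus", "season", "reads"]].to_csv(path, index=False)


def read_gauges_csv(path) -> list[GaugeObservation]:
    df = pd.read_csv(path, dtype={"reach_id": str, "season": str})
    _require_columns(df, ["reach_id", "season", "drainage_area_km2",
                          "discharge_m3s", "width_m", "depth_m"], path)
    return [GaugeObservation(row.reach_id, row.season,
                             float(row.drainage_area_km2),
                             float(row.discharge_m3s),
                             float(row.width_m), float(row.depth_m))
            for row in df.itertuples(index=False)]


def read_sites_csv(path, reads: Optional[pd.DataFrame] = None,
                   seasons: Sequence[str] = ()) -> list[SamplingSite]:
    """Load sites; each site's sampled seasons are the seasons for which it
    has any row in the read table (a site with no rows in a season was not
    sampled then, e.g. a temporarily dry reach)."""
    df = pd.read_csv(path, dtype={"site_id": str, "reach_id": str})
    _require_columns(df, ["site_id", "reach_id"], path)
    sampled: Mapping[str, set] = {}
    if reads is not None:
        sampled = reads.groupby("site_id")["season"].agg(set).to_dict()
    out = []
    for row in df.itertuples(index=False):
        ss = sampled.get(row.site_id, set(seasons))
        out.append(SamplingSite(site_id=row.site_id, reach_id=row.reach_id,
                                seasons_sampled=tuple(s for s in seasons
                                                      if s in ss)))
    return out


def write_sites_csv(sites: Sequence[SamplingSite], path) -> None:
    pd.DataFrame([{"site_id": s.site_id, "reach_id": s.reach_id}
                  for s in sites]).to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """End-to-end pipeline configuration (see ``edith run``)."""

    network_csv: str
    covariates_csv: str
    reads_csv: str
    gauges_csv: str
    sites_csv: str
    output_dir: str
    seasons: tuple[str, ...] = ("spring", "summer", "autumn")
    benchmark_season: str = "spring"
    genus_groups: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0
    # inference
    n_chains: int = 3
    n_iter: int = 4000
    burn_in: int = 1000
    # forward model
    path_endpoints: str = "half"
    read_scale: float = 1.0
    detection_threshold: float = 0.5
    # diversity
    contamination_fraction: float = 0.001
    contamination_mode: str = "subtract"
    trend_bins: int = 10
    trend_per_bin: int = 50
    trend_reps: int = 100
    beta_reps: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if k == "seasons" else v for k, v in raw.items()})
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Optional[Path] = None) -> None:
        base = base or Path(".")
        for attr in ("network_csv", "covariates_csv", "reads_csv",
                     "gauges_csv", "sites_csv"):
            p = Path(getattr(self, attr))
            if not p.is_absolute():
                p = base / p
                setattr(self, attr, str(p))
            if not p.exists():
                raise ConfigError(f"{attr}: file not found: {p}")
        if self.benchmark_season not in self.seasons:
            raise ConfigError(f"benchmark season {self.benchmark_season!r} "
                              f"not in seasons {self.seasons}")
        if not self.genus_groups:
            raise ConfigError("genus_groups mapping is empty")
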