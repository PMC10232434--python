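"""End-to-end analysis: filter reads, fit each genus × season, build maps,
and run the α-/β-diversity analyses with significance verdicts.

Each random stage consumes its own seed derived from the run seed and the
stage labels (see :func:`riveredith.io.derive_seed`), so runs with equal
configs are bit-identical and a single genus can be re-fit in isolation
without disturbing any other stream.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import diversity as dv
from .errors import ConfigError
from .forward import (GenusParams, LikelihoodContext, TransportOperator,
                      detection_map, presence_map, production_rates,
                      standardize_covariates)
from .hydrology import extrapolate_hydraulics, fit_hydraulic_laws
from .inference import (PosteriorSummary, PriorSpec, SamplerSettings,
                        map_estimate, run_sampler)
from .io import (RunConfig, derive_seed, read_covariates_csv, read_gauges_csv,
                 read_network_csv, read_reads_csv, read_sites_csv)
from .network import accumulate_drainage_area, strahler_order

__all__ = ["run_pipeline", "fit_genus_season", "write_scenario"]

log = logging.getLogger("riveredith")

_FLOAT_FMT = "%.12g"


def fit_genus_season(ctx: LikelihoodContext, seed: int,
                     settings: SamplerSettings) -> tuple[GenusParams, PosteriorSummary]:
    """Posterior sampling for one genus × season; returns the MAP parameters
    and the full posterior summary."""
    prior = PriorSpec(n_beta=ctx.n_covariates)

    def log_post(theta: np.ndarray) -> float:
        lp = prior.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        return lp + ctx.loglik(theta)

    summary = run_sampler(log_post, prior, settings, seed=seed)
    return GenusParams.from_vector(map_estimate(summary)), summary


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full workflow and write tidy CSVs plus a human-readable
    summary to ``config.output_dir``.  Returns the result tables."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seasons = list(config.seasons)

    log.info("loading inputs")
    net = read_network_csv(config.network_csv)
    accumulate_drainage_area(net)
    strahler_order(net)
    X = standardize_covariates(read_covariates_csv(config.covariates_csv)
                               .loc[net.reach_ids])
    gauges = read_gauges_csv(config.gauges_csv)
    laws = fit_hydraulic_laws(gauges, net)
    seasonal = {s: extrapolate_hydraulics(net, laws, s) for s in seasons}
    reads = read_reads_csv(config.reads_csv, seasons)
    sites = read_sites_csv(config.sites_csv, reads, seasons)
    for s in sites:
        if s.reach_id not in net:
            raise ConfigError(f"site {s.site_id!r} references unknown reach "
                              f"{s.reach_id!r}")
    genera = sorted(config.genus_groups)
    unknown = set(reads["genus"]) - set(genera)
    if unknown:
        raise ConfigError(f"reads reference genera missing from genus_groups: "
                          f"{sorted(unknown)[:5]}")
    groups = sorted(set(config.genus_groups.values()))

    log.info("contamination filter (fraction=%g, mode=%s)",
             config.contamination_fraction, config.contamination_mode)
    filtered = dv.contamination_filter(reads, config.contamination_fraction,
                                       config.contamination_mode)

    settings = SamplerSettings(n_chains=config.n_chains, n_iter=config.n_iter,
                               burn_in=config.burn_in)
    map_rows, map_records = [], []
    presence: dict[str, pd.DataFrame] = {}
    for season in seasons:
        cols = {}
        for genus in genera:
            stage = f"fit:{genus}:{season}"
            sub = filtered[(filtered["genus"] == genus)
                           & (filtered["season"] == season)]
            site_reads = dict(zip(sub["site_id"], sub["reads"]))
            ctx = LikelihoodContext(seasonal[season], X, sites, site_reads,
                                    season, scale=config.read_scale,
                                    endpoints=config.path_endpoints)
            try:
                params, summary = fit_genus_season(
                    ctx, derive_seed(config.seed, stage), settings)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed") from exc
            log.info("%s: MAP logpost %.2f, max R-hat %.3f", stage,
                     summary.map_log_post, summary.rhat.max())
            det = detection_map(seasonal[season], X, params,
                                scale=config.read_scale)
            pres = presence_map(det, config.detection_threshold)
            cols[genus] = pres
            op = TransportOperator(seasonal[season],
                                   seasonal[season].reach_ids,
                                   endpoints=config.path_endpoints)
            conc = op.concentrations(
                production_rates(seasonal[season], X, params).to_numpy(),
                params.tau_hours)
            for rid, c, d, pr in zip(net.reach_ids, conc, det, pres):
                map_rows.append((rid, genus, season, c, d, bool(pr)))
            map_records.append({
                "genus": genus, "season": season, "p0": params.p0,
                "tau_hours": params.tau_hours, "max_rhat": float(summary.rhat.max()),
                **{f"beta_{c}": b for c, b in zip(X.columns, params.beta)}})
        presence[season] = pd.DataFrame(cols)

    maps = pd.DataFrame(map_rows, columns=["reach_id", "genus", "season",
                                           "concentration", "detection_prob",
                                           "present"])
    map_params = pd.DataFrame(map_records)

    areas = np.array([net[rid].drainage_area for rid in net.reach_ids])
    genus_of = config.genus_groups

    richness_rows, verdict_rows, trend_rows, pvr_rows = [], [], [], []
    tb_rows, tb_trend_rows = [], []
    for group in groups:
        members = [g for g in genera if genus_of[g] == group]
        for season in seasons:
            rich = dv.richness(presence[season][members])
            for rid, k in rich.items():
                richness_rows.append((rid, season, group, int(k)))
            trend = dv.bootstrap_trend_test(
                rich.to_numpy(), areas, n_bins=config.trend_bins,
                per_bin=config.trend_per_bin, reps=config.trend_reps,
                seed=derive_seed(config.seed, "alpha-trend", group, season))
            trend_rows.append((group, season, "alpha", trend.slope,
                               trend.r_squared, trend.n_positive, trend.verdict))
            verdict_rows.append((group, season, "alpha-vs-area",
                                 _direction(trend.verdict),
                                 trend.verdict != "non-significant"))

            sb = dv.spatial_beta_test(
                presence[season][members], net, reps=config.beta_reps,
                seed=derive_seed(config.seed, "spatial-beta", group, season))
            verdict_rows.append((group, season, "spatial-beta",
                                 _beta_direction(sb), sb.significant))

            raw_rich = dv.raw_richness(filtered, members, season)
            raw_areas = _site_areas(net, sites, raw_rich.index)
            reg = dv.regress_on_area(raw_rich.to_numpy(), raw_areas)
            trend_rows.append((group, season, "alpha-raw", reg.slope,
                               reg.r_squared, -1,
                               "significant" if reg.p_value < 0.05 else
                               "non-significant"))
            t, p, d = dv.compare_predicted_vs_raw(rich.to_numpy(),
                                                  raw_rich.to_numpy())
            pvr_rows.append((group, season, "alpha", t, p, d))

        bench = config.benchmark_season
        for season in seasons:
            if season == bench:
                continue
            tb = dv.temporal_beta(presence[bench][members],
                                  presence[season][members])
            pair = f"{bench}-{season}"
            for rid, row in tb[tb["defined"]].iterrows():
                tb_rows.append((rid, group, pair, row["total"],
                                row["turnover"], row["nestedness"]))
            ok = tb["defined"].to_numpy()
            if ok.sum() >= config.trend_bins:
                trend = dv.bootstrap_trend_test(
                    tb.loc[ok, "total"].to_numpy(), areas[ok],
                    n_bins=config.trend_bins, per_bin=config.trend_per_bin,
                    reps=config.trend_reps,
                    seed=derive_seed(config.seed, "temporal-trend", group, pair))
                tb_trend_rows.append((group, pair, trend.slope,
                                      trend.n_positive, trend.verdict))
                verdict_rows.append((group, pair, "temporal-beta-vs-area",
                                     _direction(trend.verdict),
                                     trend.verdict != "non-significant"))

    richness_df = pd.DataFrame(richness_rows,
                               columns=["reach_id", "season", "group",
                                        "richness"])
    verdicts = pd.DataFrame(verdict_rows, columns=["group", "season", "metric",
                                                   "direction", "significant"])
    trends = pd.DataFrame(trend_rows, columns=["group", "season", "metric",
                                               "slope", "r_squared",
                                               "n_positive", "verdict"])
    pred_vs_raw = pd.DataFrame(pvr_rows, columns=["group", "season", "metric",
                                                  "t", "p_value", "mean_diff"])
    temporal = pd.DataFrame(tb_rows, columns=["reach_id", "group",
                                              "pair_season", "jaccard_total",
                                              "turnover", "nestedness"])
    temporal_trends = pd.DataFrame(tb_trend_rows,
                                   columns=["group", "pair_season", "slope",
                                            "n_positive", "verdict"])

    corr_frames = []
    if len(seasons) >= 2:
        for group in groups:
            members = [g for g in genera if genus_of[g] == group]
            corr, overlap = dv.cross_season_summaries(
                {s: presence[s][members] for s in seasons})
            corr = corr.reset_index(names="season")
            corr.insert(0, "group", group)
            corr_frames.append(corr)
    cross_season = (pd.concat(corr_frames, ignore_index=True) if corr_frames
                    else pd.DataFrame(columns=["group", "season"]))

    tables = {"maps": maps, "map_params": map_params,
              "richness": richness_df, "trends": trends,
              "temporal_beta": temporal, "temporal_trends": temporal_trends,
              "pred_vs_raw": pred_vs_raw, "cross_season": cross_season,
              "summary": verdicts}
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False,
                  float_format=_FLOAT_FMT)
    (out_dir / "summary.txt").write_text(_render_summary(verdicts, config.seed))
    log.info("wrote %d tables to %s", len(tables), out_dir)
    return tables


def _direction(verdict: str) -> str:
    return {"positive-significant": "increasing",
            "negative-significant": "decreasing"}.get(verdict, "flat")


def _beta_direction(sb) -> str:
    if not sb.significant:
        return "flat"
    return "upstream-higher" if sb.direction == "upstream" else "downstream-higher"


def _site_areas(net, sites, site_ids) -> np.ndarray:
    reach_of = {s.site_id: s.reach_id for s in sites}
    return np.array([net[reach_of[sid]].drainage_area for sid in site_ids])


_ARROW = {"increasing": "↗", "decreasing": "↘", "flat": "→",
          "upstream-higher": "↑up", "downstream-higher": "↓down"}


def _render_summary(verdicts: pd.DataFrame, seed: int) -> str:
    lines = [f"# diversity-pattern summary (seed {seed})",
             f"{'group':<15}{'season':<16}{'metric':<24}{'trend':<8}significant"]
    for row in verdicts.itertuples(index=False):
        lines.append(f"{row.group:<15}{row.season:<16}{row.metric:<24}"
                     f"{_ARROW.get(row.direction, '?'):<8}"
                     f"{'yes' if row.significant else 'no'}")
    return "\n".join(lines) + "\n"


def write_scenario(scenario, out_dir) -> None:
    """Write a synthetic scenario as the standard pipeline input CSVs plus a
    ``truth/`` directory with the generating parameters and presence maps."""
    from .io import write_network_csv, write_reads_csv, write_sites_csv
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_network_csv(scenario.network, out / "network.csv")
    scenario.covariates.reset_index().to_csv(out / "covariates.csv",
                                             index=False,
                                             float_format=_FLOAT_FMT)
    write_reads_csv(scenario.reads, out / "reads.csv")
    write_sites_csv(scenario.sites, out / "sites.csv")
    pd.DataFrame([{"reach_id": g.reach_id, "season": g.season,
                   "drainage_area_km2": g.drainage_area,
                   "discharge_m3s": g.discharge, "width_m": g.width,
                   "depth_m": g.depth} for g in scenario.gauges]).to_csv(
        out / "gauges.csv", index=False, float_format=_FLOAT_FMT)
    truth = out / "truth"
    truth.mkdir(exist_ok=True)
    rows = []
    for genus, gp in scenario.true_params.items():
        rows.append({"genus": genus, "group": scenario.genus_groups[genus],
                     "p0": gp.p0, "tau_hours": gp.tau_hours,
                     **{f"beta_{c}": b for c, b in
                        zip(scenario.covariates.columns, gp.beta)}})
    pd.DataFrame(rows).to_csv(truth / "params.csv", index=False,
                              float_format=_FLOAT_FMT)
    for season, pres in scenario.true_presence.items():
        pres.astype(int).reset_index(names="reach_id").to_csv(
            truth / f"presence_{season}.csv", index=False)
    import yaml
    config = {
        "network_csv": "network.csv", "covariates_csv": "covariates.csv",
        "reads_csv": "reads.csv", "gauges_csv": "gauges.csv",
        "sites_csv": "sites.csv", "output_dir": str(out / "results"),
        "seasons": list(scenario.config.seasons),
        "genus_groups": dict(scenario.genus_groups),
        "seed": scenario.config.seed,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
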