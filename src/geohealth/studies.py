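"""Seeded validation studies for the pipeline's statistical guarantees.

Each function runs a self-contained simulation study against the package's
own synthetic generator and returns plain numbers: oracle deviations for
the numeric kernels, confidence-interval calibration for the odds-ratio
analysis, and parameter-recovery / enhancement checks for the regression
harness. They are the computational backbone of ``scripts/acceptance.py``
and the statistical test suite.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from . import align as al
from . import embed as em
from . import images as im
from . import modeling as mo
from . import prevalence as pr
from . import synthetic as sy
from .analytics import ContingencyTable2x2, odds_ratio, spearman_matrix, urban_rural_or


# ---------------------------------------------------------------------------
# Oracle-equivalence studies
# ---------------------------------------------------------------------------

def zonal_oracle_max_dev(n_pairs: int = 50, seed: int = 0) -> float:
    """Max |zonal_mean - brute-force pixel-center oracle| over random
    polygon/raster pairs (random convex polygons over random 10x10 rasters)."""
    from shapely.geometry import Point

    rng = np.random.default_rng(seed)
    worst = 0.0
    pairs_done = 0
    while pairs_done < n_pairs:
        vals = rng.random((10, 10))
        ras = al.RasterSeries("v", 0.0, 0.0, 1.0,
                              pd.DatetimeIndex(["2016-01-01"]), vals[None])
        pts = rng.uniform(0, 10, size=(rng.integers(3, 9), 2))
        poly = MultiPoint(pts).convex_hull
        if poly.geom_type != "Polygon":
            continue
        table = pd.DataFrame({"region_id": ["R0"], "level": ["cell"],
                              "parent_id": [""], "geometry": [poly]})
        regions = al.RegionSet(table=table, adjacency={"R0": []})
        got = al.zonal_mean(ras, regions)["value"].iloc[0]
        inside = [vals[i, j] for i in range(10) for j in range(10)
                  if poly.covers(Point(j + 0.5, i + 0.5))]
        if not inside:
            if not np.isnan(got):
                worst = max(worst, np.inf)
            pairs_done += 1
            continue
        worst = max(worst, abs(got - float(np.mean(inside))))
        pairs_done += 1
    return worst


def channel_stats_oracle_max_dev(n_tiles: int = 20, seed: int = 0) -> float:
    """Max deviation of the vectorized channel statistics from a brute-force
    per-channel recomputation (numpy one-channel-at-a-time)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tiles):
        tile = rng.random((12, 12, 3))
        comp = im.compute_index_channels(tile)
        s = im.channel_statistics(comp)
        for c, name in enumerate(im.CHANNEL_NAMES):
            px = comp[..., c].ravel()
            lo, hi = im.CHANNEL_RANGES[name]
            counts, _ = np.histogram(np.clip(px, lo, hi), bins=im.N_HIST_BINS,
                                     range=(lo, hi))
            oracle = np.concatenate((
                [px.mean(), px.std(), np.median(px), px.max(), px.min()],
                counts / px.size,
            ))
            mine = s[[f"{name}_{st}" for st in im.STAT_NAMES]].to_numpy()
            worst = max(worst, float(np.abs(mine - oracle).max()))
    return worst


def spearman_exact_p_max_dev(n_draws: int = 50, seed: int = 0, n: int = 5) -> float:
    """Max |reported p - exhaustive permutation p| for tie-free samples."""
    from itertools import permutations

    from scipy.stats import spearmanr

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        x = rng.random(n)
        y = rng.random(n)
        out = spearman_matrix(
            pd.DataFrame({"x": x}, index=pd.RangeIndex(n, name="region_id")),
            pd.DataFrame({"y": y}, index=pd.RangeIndex(n, name="region_id")),
        )
        obs = abs(spearmanr(x, y).statistic)
        hits = sum(abs(spearmanr(x, p).statistic) >= obs - 1e-12
                   for p in permutations(y))
        exact = hits / math.factorial(n)
        worst = max(worst, abs(float(out["p"].iloc[0]) - exact))
    return worst


def woolf_oracle_max_dev(n_tables: int = 1000, seed: int = 0) -> float:
    """Max relative deviation of (OR, CI) from an independent evaluation via
    statsmodels' 2x2 table machinery, over random positive tables."""
    from statsmodels.stats.contingency_tables import Table2x2

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        a, b, c, d = (int(v) for v in rng.integers(1, 500, size=4))
        mine = odds_ratio(ContingencyTable2x2(a, b, c, d))
        t = Table2x2(np.array([[a, b], [c, d]]))
        lo, hi = t.oddsratio_confint(0.05)
        for got, want in ((mine.odds_ratio, t.oddsratio),
                          (mine.ci_low, lo), (mine.ci_high, hi)):
            worst = max(worst, abs(got - want) / abs(want))
    return worst


# ---------------------------------------------------------------------------
# Statistical calibration studies
# ---------------------------------------------------------------------------

def _flat_env(region_ids, years) -> pd.DataFrame:
    idx = pd.MultiIndex.from_product([list(region_ids), list(years)],
                                     names=["region_id", "year"])
    return pd.DataFrame({"x": 0.0}, index=idx)


def or_null_ci_coverage(n_seeds: int = 100, n_patients: int = 20_000,
                        seed: int = 0) -> tuple[int, int]:
    """(CIs containing 1, runs) for a code with no environment link."""
    years = (2016, 2017, 2018)
    links = {"I10": sy.CodeLink(alpha=-2.0, beta={})}
    contain = 0
    for k in range(n_seeds):
        cfg = sy.SimConfig(years=years, n_patients=n_patients,
                           link_spec=links, seed=seed + k)
        rs = sy.make_region_grid(cfg)
        urban = set(rs.table.loc[rs.table["parent_id"] == "P00C00", "region_id"])
        claims, hier_df = sy.simulate_claims(rs, _flat_env(rs.region_ids, years), cfg)
        r = urban_rural_or(claims, urban, "I10", pr.IcdHierarchy(hier_df))
        if r.ci_low < 1 < r.ci_high:
            contain += 1
    return contain, n_seeds


def or_planted_effect(n_patients: int = 20_000, seed: int = 0):
    """Odds ratio for a code whose link loads on an urban-elevated field."""
    years = (2016,)
    links = {"I10": sy.CodeLink(alpha=-1.0, beta={"x": 1.0})}
    cfg = sy.SimConfig(years=years, n_patients=n_patients,
                       link_spec=links, seed=seed)
    rs = sy.make_region_grid(cfg)
    urban = set(rs.table.loc[rs.table["parent_id"] == "P00C00", "region_id"])
    env = _flat_env(rs.region_ids, years)
    env["x"] = [1.0 if r in urban else 0.0 for r, _ in env.index]
    claims, hier_df = sy.simulate_claims(rs, env, cfg)
    return urban_rural_or(claims, urban, "I10", pr.IcdHierarchy(hier_df))


# ---------------------------------------------------------------------------
# End-to-end recovery studies
# ---------------------------------------------------------------------------

def build_panel(config: sy.SimConfig, subset: str = "All"):
    """Simulate every modality and assemble the (region, year) design panel.

    Returns (regions, panel, prevalence_l3, claims, hierarchy)."""
    rs = sy.make_region_grid(config)
    dynamic, landcover = sy.simulate_env_rasters(rs, config)
    monthly = pd.concat(
        [al.to_monthly(al.zonal_mean(r, rs)) for r in dynamic.values()],
        ignore_index=True,
    )
    denv = {y: em.seasonal_embed(monthly, y) for y in config.years}
    if subset == "DEnv":
        return rs, em.annual_panel(denv, subset="DEnv"), None, None, None
    static = pd.concat(
        [al.static_average(al.to_monthly(al.zonal_mean(r, rs)))
         for r in landcover.values()],
        ignore_index=True,
    )
    lc = em.landcover_block(static)
    tiles = sy.simulate_rgb_tiles(rs, config)
    feats = im.tile_feature_table(tiles.tiles, tiles.points["point_id"])
    img = im.aggregate_region_image_features(feats, tiles.points, rs)
    panel = em.annual_panel(denv, lc, img, subset=subset)

    env = sy.annual_env_summary(dynamic, rs)
    claims, hier_df = sy.simulate_claims(rs, env, config)
    hier = pr.IcdHierarchy(hier_df)
    prev = pr.estimate_prevalence(claims, hier, 3)
    return rs, panel, prev, claims, hier


def recovery_link_spec() -> dict[str, sy.CodeLink]:
    """Strong single-variable link used for parameter recovery."""
    spec = dict(sy.default_link_spec())
    spec["I10"] = sy.CodeLink(alpha=0.0, beta={"temperature": 1.5})
    return spec


def interpolation_r2(seed: int, n_estimators: int = 200) -> float:
    """One seeded run: All-subset forest R^2 on a spatial holdout for the
    prevalence of the strongly environment-linked code."""
    cfg = sy.SimConfig(link_spec=recovery_link_spec(), seed=seed)
    rs, panel, prev, _, _ = build_panel(cfg, subset="All")
    target = pr.prevalence_panel(prev, "I10")
    split = mo.make_split(rs, list(cfg.years),
                          mo.SplitSpec("spatial_interpolation",
                                       test_fraction=0.3, seed=seed))
    rep = mo.fit_eval(panel, target, split,
                      mo.ModelSpec(n_estimators=n_estimators, seed=seed),
                      target_name="I10", subset="All",
                      split_mode="spatial_interpolation")
    return rep.r2


def interpolation_r2_study(n_seeds: int = 100, seed: int = 0,
                           n_estimators: int = 200) -> list[float]:
    return [interpolation_r2(seed + k, n_estimators) for k in range(n_seeds)]


def lagged_exposure_targets(panel: em.EmbeddingMatrix, years, seed: int,
                            b_now: float = 0.5, b_lag: float = 1.0,
                            noise_sd: float = 0.2) -> pd.Series:
    """Delayed-dominant exposure response: y_t = b_now*s_t + b_lag*s_{t-1} + eps,
    with s the standardized row mean of the DEnv panel (temporally
    autocorrelated through the environment's persistence)."""
    X = panel.data
    z = (X - X.mean()) / X.std(ddof=0)
    s = z.mean(axis=1)
    rng = np.random.default_rng(seed)
    years = sorted(years)
    pieces = {}
    for i, yr in enumerate(years):
        drive = s.xs(yr, level="year")
        lag = (s.xs(years[i - 1], level="year").reindex(drive.index).to_numpy()
               if i else drive.to_numpy())
        eps = rng.normal(0.0, noise_sd, size=len(drive))
        pieces[yr] = pd.Series(b_now * drive.to_numpy() + b_lag * lag + eps,
                               index=drive.index)
    y = pd.concat(pieces, names=["year", "region_id"]).swaplevel().sort_index()
    y.index.names = ["region_id", "year"]
    return y


def plus_t_forecasting_wins(n_seeds: int = 100, seed: int = 0,
                            n_estimators: int = 200) -> tuple[int, int]:
    """Runs where +T augmentation improves forecasting R^2 on lag-driven
    targets (6x6 lattice, last two years held out)."""
    wins = 0
    for k in range(n_seeds):
        s = seed + k
        cfg = sy.SimConfig(n_rows=6, n_cols=6, seed=s)
        rs, panel, _, _, _ = build_panel(cfg, subset="DEnv")
        y = lagged_exposure_targets(panel, cfg.years, seed=s + 10_000)
        split = mo.make_split(rs, list(cfg.years),
                              mo.SplitSpec("temporal_forecasting",
                                           cutoff_year=cfg.years[-2], seed=s))
        model = mo.ModelSpec(n_estimators=n_estimators, seed=s)
        base = mo.fit_eval(panel, y, split, model)
        aug = mo.augment_spatiotemporal(panel, rs, add_history=True)
        plus = mo.fit_eval(aug, y, split, model)
        if plus.r2 > base.r2:
            wins += 1
    return wins, n_seeds
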