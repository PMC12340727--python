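"""Regional regression harness and spatiotemporal generalization.

Targets (z-scored on the training rows) are regressed on embedding feature
subsets with a seeded random forest, and evaluated under three
generalization regimes:

* spatial interpolation — a uniformly random holdout of whole regions
  (all their years go to test);
* spatial extrapolation — a spatially contiguous block of regions beyond a
  percentile cut of the centroid x-coordinate;
* temporal forecasting — train on years before a cutoff, test on the rest.

"+S" augments each region-year row with the elementwise mean of its rook
neighbors' rows; "+T" appends the same region's prior-year row. Both are
plain feature augmentation, isolated behind one operation so an alternative
enhancement could be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .align import RegionSet
from .embed import EmbeddingMatrix

log = logging.getLogger("geohealth")

SPLIT_MODES = ("spatial_interpolation", "spatial_extrapolation", "temporal_forecasting")


@dataclass(frozen=True)
class SplitSpec:
    mode: str
    test_fraction: float = 0.3
    cutoff_year: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in SPLIT_MODES:
            raise ValueError(f"mode must be one of {SPLIT_MODES}")
        if self.mode == "temporal_forecasting" and self.cutoff_year is None:
            raise ValueError("temporal_forecasting needs cutoff_year")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    """Random-forest settings; 500 unlimited-depth trees by default."""

    n_estimators: int = 500
    max_depth: int | None = None
    seed: int = 0


@dataclass
class EvalReport:
    target: str
    subset: str
    flags: tuple[str, ...]
    split_mode: str
    mae: float
    mse: float
    r2: float
    n_train: int
    n_test: int
    seed: int
    model: ModelSpec = field(default_factory=ModelSpec)


# ---------------------------------------------------------------------------
# Target normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZScore:
    mean: float
    sd: float

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def invert(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.sd + self.mean


def zscore_targets(
    train_values: np.ndarray, apply_values: np.ndarray, name: str = "target"
) -> tuple[np.ndarray, np.ndarray, ZScore]:
    """Standardize with mean/sd fit on the training values only."""
    train_values = np.asarray(train_values, dtype=float)
    mu = float(train_values.mean())
    sd = float(train_values.std(ddof=0))
    if sd == 0:
        raise ValueError(f"target {name!r} is constant on the training rows")
    z = ZScore(mu, sd)
    return z.apply(train_values), z.apply(apply_values), z


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def make_split(
    regions: RegionSet, years: list[int], spec: SplitSpec
) -> tuple[pd.MultiIndex, pd.MultiIndex]:
    """Disjoint train/test (region_id, year) indices for one regime."""
    rids = list(regions.region_ids)
    if len(rids) < 4:
        raise ValueError("need >= 4 regions")
    years = sorted(years)

    if spec.mode == "spatial_interpolation":
        rng = np.random.default_rng(spec.seed)
        n_test = max(1, int(round(spec.test_fraction * len(rids))))
        if n_test >= len(rids):
            raise ValueError("test fraction leaves no training regions")
        test_regions = set(rng.choice(rids, size=n_test, replace=False))
        train_regions = [r for r in rids if r not in test_regions]
    elif spec.mode == "spatial_extrapolation":
        cx = {rid: regions.geometry(rid).centroid.x for rid in rids}
        cut = np.quantile(list(cx.values()), 1 - spec.test_fraction)
        test_regions = {r for r in rids if cx[r] > cut}
        if not test_regions:  # degenerate quantile (few distinct x values)
            xmax = max(cx.values())
            test_regions = {r for r in rids if cx[r] == xmax}
        train_regions = [r for r in rids if r not in test_regions]
        if not train_regions:
            raise ValueError("extrapolation cut left no training regions")
    else:  # temporal_forecasting
        if len(years) < 2:
            raise ValueError("forecasting needs >= 2 years")
        train_years = [y for y in years if y < spec.cutoff_year]
        test_years = [y for y in years if y >= spec.cutoff_year]
        if not train_years or not test_years:
            raise ValueError("cutoff_year leaves an empty side")
        train = pd.MultiIndex.from_product([rids, train_years], names=["region_id", "year"])
        test = pd.MultiIndex.from_product([rids, test_years], names=["region_id", "year"])
        return train.sortlevel()[0], test.sortlevel()[0]

    train = pd.MultiIndex.from_product([sorted(train_regions), years],
                                       names=["region_id", "year"])
    test = pd.MultiIndex.from_product([sorted(test_regions), years],
                                      names=["region_id", "year"])
    return train.sortlevel()[0], test.sortlevel()[0]


# ---------------------------------------------------------------------------
# +S / +T augmentation
# ---------------------------------------------------------------------------

def augment_spatiotemporal(
    features: EmbeddingMatrix,
    regions: RegionSet,
    add_neighbors: bool = False,
    add_history: bool = False,
) -> EmbeddingMatrix:
    """Append neighbor-mean ("+S") and/or lagged-self ("+T") feature blocks.

    ``features.data`` must be indexed by (region_id, year). +S appends, per
    region-year, the elementwise mean over rook-adjacent regions' rows of
    the same year (an isolated region falls back to its own row, flagged).
    +T appends the same region's prior-year row; first-year rows get NaN in
    the lag block and are expected to be dropped from training by the
    caller's missing-row policy. Appended columns are namespaced ``nbr__*``
    and ``lag__*``.
    """
    data = features.data
    if list(data.index.names) != ["region_id", "year"]:
        raise ValueError("features must be indexed by (region_id, year)")
    out = [data]
    blocks = dict(features.blocks)

    if add_neighbors:
        nbr_rows = []
        for (rid, year), _ in data.iterrows():
            nbrs = [n for n in regions.adjacency.get(rid, [])
                    if (n, year) in data.index]
            if nbrs:
                nbr_rows.append(data.loc[[(n, year) for n in nbrs]].mean(axis=0))
            else:
                log.warning("+S: region %s is isolated; using its own row", rid)
                nbr_rows.append(data.loc[(rid, year)])
        nbr = pd.DataFrame(nbr_rows, index=data.index)
        nbr.columns = [f"nbr__{c}" for c in data.columns]
        out.append(nbr)
        blocks["S"] = list(nbr.columns)

    if add_history:
        lag = data.copy()
        lag.index = pd.MultiIndex.from_arrays(
            [lag.index.get_level_values("region_id"),
             lag.index.get_level_values("year") + 1],
            names=["region_id", "year"],
        )
        lag = lag.reindex(data.index)
        n_first = int(lag.isna().all(axis=1).sum())
        if n_first:
            log.info("+T: %d first-year rows have no prior year (NaN lag block)", n_first)
        lag.columns = [f"lag__{c}" for c in data.columns]
        out.append(lag)
        blocks["T"] = list(lag.columns)

    return EmbeddingMatrix(data=pd.concat(out, axis=1), blocks=blocks)


# ---------------------------------------------------------------------------
# Fit / evaluate
# ---------------------------------------------------------------------------

def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """MAE, MSE and R^2 = 1 - SS_res/SS_tot about the test-set mean."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    err = y_pred - y_true
    mae = float(np.abs(err).mean())
    mse = float((err ** 2).mean())
    ss_res = float((err ** 2).sum())
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return mae, mse, r2


def fit_eval(
    features: EmbeddingMatrix,
    target: pd.Series,
    split: tuple[pd.MultiIndex, pd.MultiIndex],
    model: ModelSpec | None = None,
    target_name: str = "target",
    subset: str = "All",
    flags: tuple[str, ...] = (),
    split_mode: str = "",
) -> EvalReport:
    """Train a seeded random forest on the train rows, report test metrics.

    The target is z-scored with training statistics (so metrics are on the
    standardized scale); rows with any missing feature or target are
    dropped with a logged count. Fewer than 3 usable test rows is an error
    (R^2 would be meaningless).
    """
    model = model or ModelSpec()
    train_idx, test_idx = split
    X = features.data
    df = X.join(target.rename("__y__"), how="inner")

    def usable(idx: pd.MultiIndex) -> pd.DataFrame:
        sub = df.loc[df.index.intersection(idx)]
        complete = sub.notna().all(axis=1)
        n_drop = int((~complete).sum())
        if n_drop:
            log.info("fit_eval: dropped %d rows with missing values", n_drop)
        return sub[complete]

    train, test = usable(train_idx), usable(test_idx)
    if len(train) < 2:
        raise ValueError("fewer than 2 usable training rows")
    if len(test) < 3:
        raise ValueError("fewer than 3 usable test rows; refusing to report R^2")

    y_tr, y_te, _ = zscore_targets(
        train["__y__"].to_numpy(), test["__y__"].to_numpy(), target_name
    )
    rf = RandomForestRegressor(
        n_estimators=model.n_estimators,
        max_depth=model.max_depth,
        random_state=model.seed,
        n_jobs=1,
    )
    rf.fit(train.drop(columns="__y__").to_numpy(), y_tr)
    pred = rf.predict(test.drop(columns="__y__").to_numpy())
    mae, mse, r2 = regression_metrics(y_te, pred)
    return EvalReport(
        target=target_name, subset=subset, flags=tuple(flags), split_mode=split_mode,
        mae=mae, mse=mse, r2=r2, n_train=len(train), n_test=len(test),
        seed=model.seed, model=model,
    )


FLAG_COMBOS = ((), ("T",), ("S",), ("T", "S"))


def run_comparison(
    panels: dict[str, EmbeddingMatrix],
    targets: dict[str, pd.Series],
    regions: RegionSet,
    splits: dict[str, SplitSpec],
    years: list[int],
    flag_combos: tuple[tuple[str, ...], ...] = ((),),
    model: ModelSpec | None = None,
) -> pd.DataFrame:
    """Evaluate every target x feature-subset x flag-combo x split regime.

    ``panels`` maps subset name (DEnv/LC/Img/All) to a (region_id, year)
    panel. Returns a tidy frame with one row per cell (target, subset,
    flags, split, mae, mse, r2, n_train, n_test, seed).
    """
    rows = []
    for split_name, spec in splits.items():
        split = make_split(regions, years, spec)
        for subset, panel in panels.items():
            for flags in flag_combos:
                feats = augment_spatiotemporal(
                    panel, regions,
                    add_neighbors="S" in flags,
                    add_history="T" in flags,
                )
                for tname, tvals in targets.items():
                    rep = fit_eval(
                        feats, tvals, split, model=model, target_name=tname,
                        subset=subset, flags=flags, split_mode=spec.mode,
                    )
                    rows.append({
                        "target": tname, "subset": subset,
                        "flags": "+".join(flags), "split": split_name,
                        "mae": rep.mae, "mse": rep.mse, "r2": rep.r2,
                        "n_train": rep.n_train, "n_test": rep.n_test,
                        "seed": rep.seed,
                    })
    return pd.DataFrame(rows)


def render_report(table: pd.DataFrame) -> str:
    """Plain-text pivot of a run_comparison table (rows = targets)."""
    piv = table.pivot_table(
        index="target", columns=["split", "subset", "flags"],
        values="r2", aggfunc="first",
    )
    return piv.round(3).to_string()
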