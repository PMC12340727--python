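"""Regional environment embeddings.

An annual embedding for a region concatenates, per dynamic variable, four
meteorological-season means of the monthly regional series — winter {Jan,
Feb, Dec}, spring {Mar-May}, summer {Jun-Aug}, fall {Sep-Nov}, all within
the same calendar year — with static land-cover fractions (LC) and static
image features (Img) available as further column blocks. Fusion is plain
column-wise concatenation of the requested blocks; any scaling is fit on a
declared training index only, so no test information leaks into it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("geohealth")

SEASONS: dict[str, tuple[int, ...]] = {
    "winter": (1, 2, 12),   # December of the same calendar year
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "fall": (9, 10, 11),
}
SEASON_ORDER = ("winter", "spring", "summer", "fall")
BLOCK_ORDER = ("DEnv", "LC", "Img")


@dataclass
class EmbeddingMatrix:
    """Region x feature matrix with named, non-overlapping column blocks.

    ``data`` is indexed by region_id (or (region_id, year) for panels);
    ``blocks`` maps a block tag (DEnv/LC/Img) to its ordered column list.
    """

    data: pd.DataFrame
    blocks: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = [c for block in self.blocks.values() for c in block]
        if len(cols) != len(set(cols)):
            raise ValueError("blocks overlap or contain duplicate columns")
        missing = set(cols) - set(self.data.columns)
        if missing:
            raise ValueError(f"block columns missing from data: {sorted(missing)}")

    @property
    def width(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def seasonal_embed(monthly: pd.DataFrame, year: int) -> EmbeddingMatrix:
    """Seasonal means of each variable for one calendar year ("DEnv" block).

    ``monthly`` is tidy (region_id, variable, month, value). Each season
    value is the mean of that season's available (non-missing) months; a
    season with no data is NaN and logged. Columns are ordered variable-major
    (sorted variable name), season-minor in winter/spring/summer/fall order.
    """
    df = monthly.copy()
    df["month"] = pd.to_datetime(df["month"])
    df = df[df["month"].dt.year == year]
    if df.empty:
        raise ValueError(f"year {year} absent from monthly series")
    df["m"] = df["month"].dt.month

    variables = sorted(df["variable"].unique())
    regions = sorted(df["region_id"].unique())
    cols = {}
    for var in variables:
        sub = df[df["variable"] == var]
        for season in SEASON_ORDER:
            months = SEASONS[season]
            vals = (
                sub[sub["m"].isin(months)]
                .groupby("region_id")["value"].mean()
                .reindex(regions)
            )
            cols[f"{var}_{season}"] = vals
    out = pd.DataFrame(cols, index=pd.Index(regions, name="region_id"))
    n_missing = int(out.isna().sum().sum())
    if n_missing:
        log.warning("seasonal_embed(%d): %d season cells missing", year, n_missing)
    return EmbeddingMatrix(data=out, blocks={"DEnv": list(out.columns)})


def landcover_block(static: pd.DataFrame) -> EmbeddingMatrix:
    """Static land-cover fractions as the "LC" block.

    ``static`` is (region_id, variable, value) from ``static_average``.
    """
    wide = static.pivot(index="region_id", columns="variable", values="value")
    wide = wide[sorted(wide.columns)]
    wide.columns.name = None
    return EmbeddingMatrix(data=wide, blocks={"LC": list(wide.columns)})


def fuse(
    blocks: dict[str, EmbeddingMatrix],
    subset: str = "All",
    zscore_train_index: pd.Index | None = None,
) -> EmbeddingMatrix:
    """Concatenate modality blocks column-wise.

    ``subset`` is one of DEnv/LC/Img/All. All requested blocks must share
    the same region index (mismatch errors list the offending regions).
    With ``zscore_train_index`` given, every column is z-scored using mean
    and sd fit on those rows only.
    """
    wanted = list(BLOCK_ORDER) if subset == "All" else [subset]
    unknown = [w for w in wanted if w not in blocks]
    if unknown:
        raise KeyError(f"requested blocks not provided: {unknown}")
    base_index = blocks[wanted[0]].data.index
    for tag in wanted[1:]:
        other = blocks[tag].data.index
        if not base_index.equals(other):
            off = sorted(base_index.symmetric_difference(other).tolist())
            raise ValueError(f"region index mismatch in block {tag}: {off}")
    data = pd.concat([blocks[t].data for t in wanted], axis=1)
    out_blocks = {t: list(blocks[t].blocks.get(t, blocks[t].data.columns)) for t in wanted}

    if zscore_train_index is not None:
        mu = data.loc[zscore_train_index].mean()
        sd = data.loc[zscore_train_index].std(ddof=0)
        sd = sd.replace(0.0, np.nan)
        data = (data - mu) / sd
    return EmbeddingMatrix(data=data, blocks=out_blocks)


def annual_panel(
    denv_by_year: dict[int, EmbeddingMatrix],
    lc: EmbeddingMatrix | None = None,
    img: EmbeddingMatrix | None = None,
    subset: str = "All",
) -> EmbeddingMatrix:
    """Stack per-year DEnv blocks into a (region_id, year) panel, repeating
    the static LC/Img blocks for every year. This is the design matrix the
    regression harness consumes."""
    years = sorted(denv_by_year)
    frames = []
    for y in years:
        blocks = {"DEnv": denv_by_year[y]}
        if lc is not None:
            blocks["LC"] = lc
        if img is not None:
            blocks["Img"] = img
        avail = {t: b for t, b in blocks.items()
                 if subset == "All" or t == subset}
        fused = fuse(avail, subset=subset)
        d = fused.data.copy()
        d.index = pd.MultiIndex.from_product(
            [d.index, [y]], names=["region_id", "year"]
        )
        frames.append((d, fused.blocks))
    data = pd.concat([f for f, _ in frames], axis=0).sort_index()
    return EmbeddingMatrix(data=data, blocks=frames[0][1])


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_embedding(emb: EmbeddingMatrix, csv_path, blockmap_path) -> None:
    emb.data.to_csv(csv_path)
    with open(blockmap_path, "w") as fh:
        json.dump(emb.blocks, fh, indent=0, sort_keys=True)


def read_embedding(csv_path, blockmap_path, index_col=0) -> EmbeddingMatrix:
    data = pd.read_csv(csv_path, index_col=index_col)
    with open(blockmap_path) as fh:
        blocks = json.load(fh)
    return EmbeddingMatrix(data=data, blocks=blocks)
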