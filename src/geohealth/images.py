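"""Visual features from RGB tiles.

Each tile is expanded into a 12-channel compound image — the original R, G,
B plus nine standard RGB-only remote-sensing indices — and each channel is
summarized by 25 statistics (mean, population sd, median, max, min, and a
20-bin histogram over the channel's fixed analytic range), giving a
300-entry feature vector per tile. Region-level visual features are the
elementwise mean over the tile vectors of the region's grid points.

The index set is a versioned registry: swapping an alternate index keeps
the vector length and column naming scheme stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .align import RegionSet
from .embed import EmbeddingMatrix

log = logging.getLogger("geohealth")

EPS = 1e-8
N_HIST_BINS = 20
STAT_NAMES = ["mean", "std", "median", "max", "min"] + \
    [f"hist{b:02d}" for b in range(N_HIST_BINS)]


def _guard(den: np.ndarray) -> np.ndarray:
    """Add EPS with the denominator's sign (sign 0 -> +EPS) so ratios stay finite."""
    s = np.where(den >= 0, 1.0, -1.0)
    return den + s * EPS


@dataclass(frozen=True)
class IndexDef:
    """A named scalar function of (R, G, B) in [0,1] with its histogram range."""

    name: str
    fn: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    hist_range: tuple[float, float]


# Registry v1: nine standard RGB vegetation/soil indices. Histogram ranges
# are the analytic ranges for RGB in [0,1]; VARI's guarded ratio is
# unbounded, so its range is pinned to [-1, 1] with overflow clipped into
# the edge bins (registry constant, versioned with the set).
INDEX_REGISTRY_V1: tuple[IndexDef, ...] = (
    IndexDef("ExG", lambda r, g, b: 2 * g - r - b, (-2.0, 2.0)),
    IndexDef("ExR", lambda r, g, b: 1.4 * r - g, (-1.0, 1.4)),
    IndexDef("ExGR", lambda r, g, b: (2 * g - r - b) - (1.4 * r - g), (-3.4, 3.0)),
    IndexDef("NGRDI", lambda r, g, b: (g - r) / (g + r + EPS), (-1.0, 1.0)),
    IndexDef("GLI", lambda r, g, b: (2 * g - r - b) / (2 * g + r + b + EPS), (-1.0, 1.0)),
    IndexDef("VARI", lambda r, g, b: (g - r) / _guard(g + r - b), (-1.0, 1.0)),
    IndexDef("MGRVI", lambda r, g, b: (g**2 - r**2) / (g**2 + r**2 + EPS), (-1.0, 1.0)),
    IndexDef("RGBVI", lambda r, g, b: (g**2 - r * b) / (g**2 + r * b + EPS), (-1.0, 1.0)),
    IndexDef("IKAW", lambda r, g, b: (r - b) / (r + b + EPS), (-1.0, 1.0)),
)

CHANNEL_NAMES: tuple[str, ...] = ("R", "G", "B") + tuple(d.name for d in INDEX_REGISTRY_V1)
CHANNEL_RANGES: dict[str, tuple[float, float]] = {
    "R": (0.0, 1.0), "G": (0.0, 1.0), "B": (0.0, 1.0),
    **{d.name: d.hist_range for d in INDEX_REGISTRY_V1},
}

FEATURE_NAMES: list[str] = [
    f"{ch}_{st}" for ch in CHANNEL_NAMES for st in STAT_NAMES
]
N_FEATURES = len(FEATURE_NAMES)  # 12 channels x 25 statistics = 300


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_index_channels(tile: np.ndarray) -> np.ndarray:
    """Append the nine index channels to an RGB tile.

    ``tile``: array (..., H, W, 3) with values in [0,1] (clipped on entry).
    Returns the compound image (..., H, W, 12) with channels ordered as
    ``CHANNEL_NAMES``. All index channels are finite (epsilon-guarded).
    """
    tile = np.asarray(tile)
    if not np.issubdtype(tile.dtype, np.floating):
        tile = tile.astype(float)
    if tile.ndim < 3 or tile.shape[-1] != 3:
        raise ValueError(f"expected (..., H, W, 3) RGB input, got shape {tile.shape}")
    tile = np.clip(tile, 0.0, 1.0)
    r, g, b = tile[..., 0], tile[..., 1], tile[..., 2]
    out = np.empty(tile.shape[:-1] + (len(CHANNEL_NAMES),), dtype=tile.dtype)
    out[..., 0], out[..., 1], out[..., 2] = r, g, b
    for k, d in enumerate(INDEX_REGISTRY_V1):
        out[..., 3 + k] = d.fn(r, g, b)
    return out


def channel_statistics(compound: np.ndarray) -> pd.Series:
    """25 statistics per channel of a single compound image.

    mean, population std, median, max, min, then 20 equal-width histogram
    bin masses over the channel's fixed range (masses sum to 1; values at
    or beyond an edge fall into the edge bin). Returns a length-300 Series
    indexed by ``FEATURE_NAMES``.
    """
    vals = _channel_statistics_batch(np.asarray(compound, dtype=float)[None, ...])
    return pd.Series(vals[0], index=FEATURE_NAMES)


def _channel_statistics_batch(compound: np.ndarray) -> np.ndarray:
    """Vectorized statistics for a batch (N, H, W, 12) -> (N, 300)."""
    if compound.ndim != 4 or compound.shape[-1] != len(CHANNEL_NAMES):
        raise ValueError(
            f"expected (N, H, W, {len(CHANNEL_NAMES)}) compound batch, "
            f"got shape {compound.shape}"
        )
    n, h, w, nch = compound.shape
    if h * w == 0:
        raise ValueError("empty image")
    # channel-major layout so each channel's pixels are contiguous
    flat = np.ascontiguousarray(compound.reshape(n, h * w, nch).transpose(0, 2, 1))
    out = np.empty((n, nch, len(STAT_NAMES)))
    npx = h * w
    s1 = np.einsum("ncp->nc", flat, dtype=np.float64)
    s2 = np.einsum("ncp,ncp->nc", flat, flat, dtype=np.float64)
    mean = s1 / npx
    out[:, :, 0] = mean
    # population std via single-pass moments (values are O(1), so the
    # float64 moment difference is numerically safe)
    out[:, :, 1] = np.sqrt(np.maximum(s2 / npx - mean ** 2, 0.0))
    out[:, :, 2] = np.median(flat, axis=2)
    out[:, :, 3] = flat.max(axis=2)
    out[:, :, 4] = flat.min(axis=2)
    row_offset = (np.arange(n)[:, None] * N_HIST_BINS).astype(np.int64)
    for c, ch in enumerate(CHANNEL_NAMES):
        lo, hi = CHANNEL_RANGES[ch]
        width = (hi - lo) / N_HIST_BINS
        idx = ((flat[:, c, :] - lo) * (1.0 / width)).astype(np.int64)
        np.clip(idx, 0, N_HIST_BINS - 1, out=idx)
        counts = np.bincount((idx + row_offset).ravel(), minlength=n * N_HIST_BINS)
        out[:, c, 5:] = counts.reshape(n, N_HIST_BINS) / (h * w)
    return out.reshape(n, nch * len(STAT_NAMES))


def tile_feature_table(tiles: np.ndarray, point_ids, batch: int = 128) -> pd.DataFrame:
    """Feature vectors for a stack of RGB tiles (n, H, W, 3), batched to
    bound memory. Returns a DataFrame indexed by point_id with the 300
    named feature columns."""
    tiles = np.asarray(tiles)
    chunks = []
    for s in range(0, len(tiles), batch):
        comp = compute_index_channels(tiles[s:s + batch])
        chunks.append(_channel_statistics_batch(comp))
    data = np.concatenate(chunks, axis=0) if chunks else np.empty((0, N_FEATURES))
    return pd.DataFrame(data, index=pd.Index(point_ids, name="point_id"),
                        columns=FEATURE_NAMES)


def aggregate_region_image_features(
    point_features: pd.DataFrame, points: pd.DataFrame, regions: RegionSet
) -> EmbeddingMatrix:
    """Elementwise mean of point feature vectors per region ("Img" block).

    ``points`` carries the point -> region assignment (point_id, region_id).
    Regions with no grid points get an all-NaN row and a logged warning.
    """
    assignment = points.set_index("point_id")["region_id"]
    joined = point_features.join(assignment, how="left")
    joined = joined[joined["region_id"] != ""]
    means = joined.groupby("region_id").mean()
    means = means.reindex(regions.region_ids)
    empty = means.isna().all(axis=1)
    for rid in means.index[empty]:
        log.warning("region %s has no image grid points; Img row is missing", rid)
    means.index.name = "region_id"
    return EmbeddingMatrix(data=means, blocks={"Img": list(means.columns)})
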