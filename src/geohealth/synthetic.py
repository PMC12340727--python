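"""Synthetic multimodal inputs with the statistical structure the pipeline assumes.

Real deployments of this pipeline ingest satellite rasters, aerial image
tiles and medical claims. This module generates stand-ins for all three on a
planar km lattice so that every downstream stage is testable end to end:

* ``make_region_grid`` — a lattice of square regions with rook adjacency and
  a 2x2-block parent tier (a two-tier stand-in for tract/county hierarchies).
* ``simulate_env_rasters`` — per-variable monthly rasters built as
  ``spatial Gaussian random field + annual anomaly + seasonal sine + white
  noise``, plus one static land-cover raster per land type with per-pixel
  fractions summing to 1.
* ``simulate_rgb_tiles`` — RGB tiles on a 500 m point grid whose green
  channel increases monotonically with a latent smooth greenness field.
* ``simulate_claims`` — patients with a fixed residence region, 1-5 visits
  per year, and per-year ICD code carriage driven by a logistic link
  ``P(code) = logistic(alpha + beta . z(region, year))`` on the z-scored
  regional environment, together with a toy 3-level ICD hierarchy.

The generator's link parameters (alpha, beta) are ground truth for
parameter-recovery and calibration tests. All randomness flows from
``SimConfig.seed``; a fixed config yields byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .align import RasterSeries, RegionSet, assign_points_to_regions, zonal_mean, to_monthly

log = logging.getLogger("geohealth")

# fixed substream ids so each component draws from an independent stream
_STREAM_FIELD = 1
_STREAM_ANOMALY = 2
_STREAM_NOISE = 3
_STREAM_LANDCOVER = 4
_STREAM_GREEN = 5
_STREAM_TILES = 6
_STREAM_CLAIMS = 7


class ConfigError(ValueError):
    """Raised when a SimConfig (or derived precondition) is invalid."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvVarSpec:
    """One dynamic environmental variable.

    amplitude: seasonal sine amplitude A in value(t) = field + anomaly +
    A*sin(2*pi*month/12 + phase) + noise; corr_length_km: e-folding scale of
    the spatial field; field_sd: marginal sd of the spatial field;
    anomaly_sd: marginal sd of the interannual anomaly — a fresh spatially
    correlated field drawn per calendar year (regional climate anomalies);
    noise_sd: per-pixel-month white noise sd.
    """

    name: str
    amplitude: float = 1.0
    phase: float = 0.0
    corr_length_km: float = 10.0
    field_sd: float = 1.0
    anomaly_sd: float = 0.5
    noise_sd: float = 0.5


@dataclass(frozen=True)
class CodeLink:
    """Logistic link for one leaf ICD code: alpha + sum_v beta[v] * z_v."""

    alpha: float
    beta: dict[str, float] = field(default_factory=dict)


def default_env_vars() -> list[EnvVarSpec]:
    return [
        EnvVarSpec("temperature", amplitude=1.0, phase=0.0),
        EnvVarSpec("humidity", amplitude=0.6, phase=1.0),
        EnvVarSpec("ndvi", amplitude=0.8, phase=2.0),
    ]


def default_link_spec() -> dict[str, CodeLink]:
    # leaves of the toy hierarchy below; E71 is a null (flat) code
    return {
        "I10": CodeLink(alpha=0.0, beta={"temperature": 1.5}),
        "I11": CodeLink(alpha=-1.0, beta={"humidity": 0.8}),
        "I20": CodeLink(alpha=-1.0, beta={"temperature": -0.7}),
        "I21": CodeLink(alpha=-2.0, beta={}),
        "E10": CodeLink(alpha=0.0, beta={"ndvi": -1.0}),
        "E11": CodeLink(alpha=-1.0, beta={"temperature": 0.5, "ndvi": -0.5}),
        "E70": CodeLink(alpha=-2.0, beta={"humidity": 0.6}),
        "E71": CodeLink(alpha=0.0, beta={}),
    }


@dataclass(frozen=True)
class SimConfig:
    n_rows: int = 4
    n_cols: int = 4
    cell_km: float = 4.0
    years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020, 2021, 2022)
    n_patients: int = 20_000
    env_vars: tuple[EnvVarSpec, ...] = field(default_factory=lambda: tuple(default_env_vars()))
    land_types: tuple[str, ...] = ("forest", "urban", "water")
    link_spec: dict[str, CodeLink] = field(default_factory=default_link_spec)
    greenness_weight: float = 1.0
    tile_size: int = 64
    tile_spacing_km: float = 0.5
    pixel_km: float | None = None  # default cell_km / 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigError("lattice dimensions must be positive")
        if self.n_rows * self.n_cols < 4:
            raise ConfigError("lattice must have at least 4 cells")
        if self.cell_km <= 0:
            raise ConfigError("cell_km must be positive")
        ys = list(self.years)
        if ys != list(range(ys[0], ys[0] + len(ys))):
            raise ConfigError("years must be consecutive")
        if self.pixel_size > self.cell_km / 4:
            raise ConfigError(
                f"pixel size {self.pixel_size} km too coarse: must be <= cell_km/4 "
                f"so every region contains >= 16 pixels"
            )

    @property
    def pixel_size(self) -> float:
        return self.pixel_km if self.pixel_km is not None else self.cell_km / 4

    @property
    def extent_km(self) -> tuple[float, float]:
        """(width, height) of the lattice in km."""
        return self.n_cols * self.cell_km, self.n_rows * self.cell_km


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def make_region_grid(config: SimConfig) -> RegionSet:
    """Square regions tiling an n_rows x n_cols planar km lattice.

    Rook adjacency between edge-sharing cells; regions are grouped into a
    parent tier by 2x2 blocks, with remainder rows/columns attached to the
    nearest block.
    """
    nr, nc, c = config.n_rows, config.n_cols, config.cell_km
    nbr_blocks = max(1, nr // 2)
    nbc_blocks = max(1, nc // 2)
    rows = []
    adjacency: dict[str, list[str]] = {}

    def rid(i: int, j: int) -> str:
        return f"R{i:02d}C{j:02d}"

    for i in range(nr):
        for j in range(nc):
            bi, bj = min(i // 2, nbr_blocks - 1), min(j // 2, nbc_blocks - 1)
            rows.append({
                "region_id": rid(i, j),
                "level": "cell",
                "parent_id": f"P{bi:02d}C{bj:02d}",
                "geometry": box(j * c, i * c, (j + 1) * c, (i + 1) * c),
            })
            nbrs = [rid(i + di, j + dj)
                    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1))
                    if 0 <= i + di < nr and 0 <= j + dj < nc]
            adjacency[rid(i, j)] = sorted(nbrs)
    table = pd.DataFrame(rows, columns=["region_id", "level", "parent_id", "geometry"])
    return RegionSet(table=table, adjacency=adjacency, crs="planar_km")


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------

def _gaussian_field(rng: np.random.Generator, ny: int, nx: int,
                    corr_length_px: float, sd: float) -> np.ndarray:
    """Stationary Gaussian random field with unit-ish marginal sd scaled to sd."""
    white = rng.standard_normal((ny, nx))
    if corr_length_px <= 0 or sd == 0:
        return sd * white
    smooth = gaussian_filter(white, sigma=corr_length_px, mode="reflect")
    smooth -= smooth.mean()  # smoothing does not preserve marginal scale
    s = smooth.std()
    if s == 0:
        return np.zeros((ny, nx))
    return sd * smooth / s


def monthly_index(years: tuple[int, ...]) -> pd.DatetimeIndex:
    return pd.date_range(f"{years[0]}-01-01", periods=12 * len(years), freq="MS")


def simulate_env_rasters(
    regions: RegionSet, config: SimConfig
) -> tuple[dict[str, RasterSeries], dict[str, RasterSeries]]:
    """Simulate monthly dynamic rasters and static land-cover fraction rasters.

    Dynamic value at (pixel, t) = static spatial field + annual anomaly
    field (a fresh spatially correlated field per year) + amplitude *
    sin(2*pi*month/12 + phase) + white noise. Land-cover fractions are a
    softmax of independent smooth fields, so they sum to 1 at every pixel.
    """
    px = config.pixel_size
    w, h = config.extent_km
    nx, ny = int(round(w / px)), int(round(h / px))
    times = monthly_index(config.years)
    month_no = times.month.to_numpy()          # 1..12
    year_idx = times.year.to_numpy() - config.years[0]
    n_years = len(config.years)

    rng_f = _rng(config, _STREAM_FIELD)
    rng_a = _rng(config, _STREAM_ANOMALY)
    rng_n = _rng(config, _STREAM_NOISE)

    dynamic: dict[str, RasterSeries] = {}
    for spec in config.env_vars:
        fld = _gaussian_field(rng_f, ny, nx, spec.corr_length_km / px, spec.field_sd)
        anomaly = np.stack([
            _gaussian_field(rng_a, ny, nx, spec.corr_length_km / px, spec.anomaly_sd)
            for _ in range(n_years)
        ])
        seasonal = spec.amplitude * np.sin(2 * np.pi * month_no / 12 + spec.phase)
        noise = (rng_n.normal(0.0, spec.noise_sd, size=(len(times), ny, nx))
                 if spec.noise_sd > 0 else 0.0)
        values = fld[None, :, :] + anomaly[year_idx] + seasonal[:, None, None] + noise
        dynamic[spec.name] = RasterSeries(
            variable=spec.name, x0=0.0, y0=0.0, pixel_size=px,
            times=times, values=values,
        )

    rng_lc = _rng(config, _STREAM_LANDCOVER)
    logits = np.stack([
        _gaussian_field(rng_lc, ny, nx, config.cell_km / px, 1.0)
        for _ in config.land_types
    ])
    logits -= logits.max(axis=0, keepdims=True)
    fracs = np.exp(logits)
    fracs /= fracs.sum(axis=0, keepdims=True)
    t0 = pd.DatetimeIndex([times[0]])
    landcover = {
        lt: RasterSeries(variable=f"lc_{lt}", x0=0.0, y0=0.0, pixel_size=px,
                         times=t0, values=fracs[k][None, :, :])
        for k, lt in enumerate(config.land_types)
    }
    return dynamic, landcover


# ---------------------------------------------------------------------------
# RGB tiles
# ---------------------------------------------------------------------------

@dataclass
class TileSet:
    """RGB tiles on a regular point grid.

    ``points``: DataFrame (point_id, x, y, region_id); ``tiles``: float32
    array (n_points, H, W, 3) in [0, 1]; ``greenness``: the latent smooth
    field at each point (generator truth, used by recovery tests).
    """

    points: pd.DataFrame
    tiles: np.ndarray
    greenness: np.ndarray


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_rgb_tiles(regions: RegionSet, config: SimConfig) -> TileSet:
    """Tiles at 500 m grid points; green channel monotone in latent greenness.

    Grid points sit at the centers of ``tile_spacing_km`` cells covering the
    lattice (x = (k + 1/2)*spacing), so a 10 km x 10 km area at 500 m spacing
    holds a 20 x 20 interior grid. Each point is assigned to the region
    covering it (lexicographically smaller region id on shared edges).
    """
    sp = config.tile_spacing_km
    w, h = config.extent_km
    nx, ny = int(round(w / sp)), int(round(h / sp))
    xs = (np.arange(nx) + 0.5) * sp
    ys = (np.arange(ny) + 0.5) * sp
    gx, gy = np.meshgrid(xs, ys)

    rng_g = _rng(config, _STREAM_GREEN)
    green_field = _gaussian_field(rng_g, ny, nx, config.cell_km / sp, 1.0)

    region_ids = assign_points_to_regions(gx.ravel(), gy.ravel(), regions)
    points = pd.DataFrame({
        "point_id": [f"pt{k:06d}" for k in range(nx * ny)],
        "x": gx.ravel(), "y": gy.ravel(),
        "region_id": region_ids,
    })

    n = nx * ny
    ts = config.tile_size
    g = green_field.ravel()
    rng_t = _rng(config, _STREAM_TILES)
    # per-tile texture around channel base levels; green base shifts with g
    green_mean = 0.25 + 0.5 * _sigmoid(config.greenness_weight * g)
    base = np.empty((n, 3), dtype=np.float32)
    base[:, 0] = 0.40
    base[:, 1] = green_mean
    base[:, 2] = 0.35
    texture = 0.08 * rng_t.standard_normal((n, ts, ts, 3), dtype=np.float32)
    tiles = np.clip(base[:, None, None, :] + texture, 0.0, 1.0)
    return TileSet(points=points, tiles=tiles, greenness=g)


# ---------------------------------------------------------------------------
# ICD hierarchy and claims
# ---------------------------------------------------------------------------

def toy_icd_hierarchy() -> pd.DataFrame:
    """A 3-level toy hierarchy (chapter > block > category), ICD-10-shaped.

    Columns (code, parent, level); level 1 = chapter, 2 = block,
    3 = category. The leaves are the codes the claims generator can emit.
    """
    rows = [
        ("I00-I99", "", 1), ("E00-E89", "", 1),
        ("I10-I1A", "I00-I99", 2), ("I20-I25", "I00-I99", 2),
        ("E08-E13", "E00-E89", 2), ("E70-E88", "E00-E89", 2),
        ("I10", "I10-I1A", 3), ("I11", "I10-I1A", 3),
        ("I20", "I20-I25", 3), ("I21", "I20-I25", 3),
        ("E10", "E08-E13", 3), ("E11", "E08-E13", 3),
        ("E70", "E70-E88", 3), ("E71", "E70-E88", 3),
    ]
    return pd.DataFrame(rows, columns=["code", "parent", "level"])


def annual_env_summary(
    dynamic: dict[str, RasterSeries], regions: RegionSet
) -> pd.DataFrame:
    """Annual regional means of each dynamic variable.

    Returns a frame indexed by (region_id, year) with one column per
    variable — the regional environment summary the claims link consumes.
    """
    frames = []
    for name, raster in dynamic.items():
        monthly = to_monthly(zonal_mean(raster, regions))
        monthly["year"] = monthly["month"].dt.year
        annual = monthly.groupby(["region_id", "year"])["value"].mean().rename(name)
        frames.append(annual)
    return pd.concat(frames, axis=1).sort_index()


def zscore_env_summary(env_summary: pd.DataFrame) -> pd.DataFrame:
    """Z-score each variable across all region-years (population sd)."""
    z = env_summary.copy()
    for col in z.columns:
        v = z[col].to_numpy(dtype=float)
        sd = v.std()
        z[col] = (v - v.mean()) / sd if sd > 0 else 0.0
    return z


def simulate_claims(
    regions: RegionSet, env_summary: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate patient visits with environment-linked ICD code carriage.

    Each patient has a fixed residence region and 1-5 visits per year, with
    visit dates uniform within the year. For each leaf code c the patient
    carries c in year y with probability
    ``logistic(alpha_c + beta_c . z(region, year))``; carried codes are
    attached to one uniformly chosen visit of that patient-year. Visits
    carrying no code appear with an empty ``icd_code``.

    Returns (claims, hierarchy); claims columns are
    (patient_id, visit_id, date, region_id, icd_code).
    """
    hierarchy = toy_icd_hierarchy()
    leaves = set(hierarchy.loc[hierarchy["level"] == 3, "code"])
    codes = sorted(config.link_spec)
    unknown_codes = sorted(set(codes) - leaves)
    if unknown_codes:
        raise ConfigError(f"link_spec codes not in hierarchy leaves: {unknown_codes}")
    env_vars = list(env_summary.columns)
    for c, link in config.link_spec.items():
        bad = sorted(set(link.beta) - set(env_vars))
        if bad:
            raise ConfigError(f"link for {c} references unknown env variables: {bad}")

    z = zscore_env_summary(env_summary)
    region_ids = np.asarray(regions.region_ids, dtype=object)
    n_regions = len(region_ids)
    years = np.asarray(config.years)
    n_years = len(years)
    n_pat = config.n_patients

    # P[r, y, c] from the logistic link on the z-scored environment
    zmat = np.zeros((n_regions, n_years, len(env_vars)))
    z_lookup = z.reindex(
        pd.MultiIndex.from_product([region_ids, years], names=["region_id", "year"])
    )
    zmat = z_lookup.to_numpy(dtype=float).reshape(n_regions, n_years, len(env_vars))
    probs = np.empty((n_regions, n_years, len(codes)))
    for k, c in enumerate(codes):
        link = config.link_spec[c]
        eta = np.full((n_regions, n_years), float(link.alpha))
        for v, b in link.beta.items():
            eta += b * zmat[:, :, env_vars.index(v)]
        probs[:, :, k] = _sigmoid(eta)

    rng = _rng(config, _STREAM_CLAIMS)
    residence = rng.integers(0, n_regions, size=n_pat)
    n_visits = rng.integers(1, 6, size=(n_pat, n_years))
    carries = rng.random(size=(n_pat, n_years, len(codes))) < probs[residence]

    # flat visit table
    total_visits = int(n_visits.sum())
    visit_pat = np.repeat(np.arange(n_pat)[:, None], n_years, axis=1)
    pat_flat = np.repeat(visit_pat.ravel(), n_visits.ravel())
    year_flat = np.repeat(np.tile(years, n_pat), n_visits.ravel())
    day = rng.integers(0, 365, size=total_visits)
    dates = (pd.to_datetime(year_flat.astype(str) + "-01-01")
             + pd.to_timedelta(day, unit="D"))
    first_visit = np.concatenate(([0], np.cumsum(n_visits.ravel())))[:-1] \
        .reshape(n_pat, n_years)

    # attach each carried (patient, year, code) to a random visit of that year
    p_idx, y_idx, c_idx = np.nonzero(carries)
    offs = rng.integers(0, n_visits[p_idx, y_idx])
    code_visit = first_visit[p_idx, y_idx] + offs

    has_code = np.zeros(total_visits, dtype=bool)
    has_code[code_visit] = True
    empty_visits = np.nonzero(~has_code)[0]

    all_visit_idx = np.concatenate([code_visit, empty_visits])
    all_codes = np.concatenate([
        np.asarray(codes, dtype=object)[c_idx],
        np.full(len(empty_visits), "", dtype=object),
    ])
    order = np.lexsort((all_codes, all_visit_idx))
    vi = all_visit_idx[order]
    claims = pd.DataFrame({
        "patient_id": pat_flat[vi],
        "visit_id": vi,
        "date": dates[vi],
        "region_id": region_ids[residence[pat_flat[vi]]],
        "icd_code": all_codes[order],
    })
    return claims.reset_index(drop=True), hierarchy


# ---------------------------------------------------------------------------
# Validation helper
# ---------------------------------------------------------------------------

def morans_i(values: pd.Series, adjacency: dict[str, list[str]]) -> float:
    """Moran's I spatial autocorrelation of per-region values under the
    given adjacency (binary weights). Used to validate the field generator."""
    ids = list(values.index)
    pos = {r: k for k, r in enumerate(ids)}
    zv = values.to_numpy(dtype=float)
    zv = zv - zv.mean()
    num = 0.0
    w_sum = 0
    for r, nbrs in adjacency.items():
        if r not in pos:
            continue
        for s in nbrs:
            if s in pos:
                num += zv[pos[r]] * zv[pos[s]]
                w_sum += 1
    denom = (zv ** 2).sum()
    if denom == 0 or w_sum == 0:
        return float("nan")
    return (len(ids) / w_sum) * (num / denom)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_tiles(tileset: TileSet, outdir) -> None:
    """Write tiles as PNGs plus a points CSV (point_id, x, y, region_id)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tileset.points.to_csv(outdir / "points.csv", index=False)
    arr8 = np.clip(np.rint(tileset.tiles * 255), 0, 255).astype(np.uint8)
    for pid, img in zip(tileset.points["point_id"], arr8):
        Image.fromarray(img, mode="RGB").save(outdir / f"{pid}.png")


def read_tiles(indir) -> TileSet:
    from pathlib import Path

    indir = Path(indir)
    points = pd.read_csv(indir / "points.csv", dtype={"region_id": str})
    points["region_id"] = points["region_id"].fillna("")
    tiles = np.stack([
        np.asarray(Image.open(indir / f"{pid}.png"), dtype=np.float32) / 255.0
        for pid in points["point_id"]
    ])
    return TileSet(points=points, tiles=tiles, greenness=np.full(len(points), np.nan))


def write_claims(claims: pd.DataFrame, path) -> None:
    out = claims.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_claims(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"icd_code": str}, parse_dates=["date"])
    df["icd_code"] = df["icd_code"].fillna("")
    return df


def write_hierarchy(hierarchy: pd.DataFrame, path) -> None:
    hierarchy.to_csv(path, index=False)


def read_hierarchy(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"code": str, "parent": str})
    df["parent"] = df["parent"].fillna("")
    return df
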