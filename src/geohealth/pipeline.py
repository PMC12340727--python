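"""End-to-end orchestration behind one YAML config.

Stages run in dependency order::

    simulate -> align -> imgfeat -> embed -> prevalence -> analyze
    -> model -> report

Every stage is also callable as a library function; ``run`` only wires
files between them, validates the config against the documented schema,
and writes a run manifest (config hash, seed, stage list, SHA-256 digest
of every output file). The manifest contains nothing volatile, so two runs
with the same config are byte-identical.

Config schema (all keys optional unless noted)::

    seed: int
    sim:
      n_rows, n_cols: int     # region lattice
      cell_km: float
      year_start, year_end: int
      n_patients: int
      greenness_weight: float
      tile_size: int
    analysis:
      urban_parent: str       # parent block whose cells count as "urban"
      or_level: int           # hierarchy level for odds ratios (default 2)
    model:
      subsets: [DEnv|LC|Img|All, ...]
      targets: [icd_group, ...]   # default: all level-2 groups
      n_estimators: int
      test_fraction: float
      cutoff_year: int            # forecasting cutoff (default last year)
      flags: [[", "T", "S" combos]]
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import align as al
from . import analytics as an
from . import embed as em
from . import images as im
from . import modeling as mo
from . import prevalence as pr
from . import synthetic as sy

log = logging.getLogger("geohealth")

STAGES = ("simulate", "align", "imgfeat", "embed", "prevalence", "analyze",
          "model", "report")

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "sim", "analysis", "model"},
    "sim": {"n_rows", "n_cols", "cell_km", "year_start", "year_end",
            "n_patients", "greenness_weight", "tile_size"},
    "analysis": {"urban_parent", "or_level"},
    "model": {"subsets", "targets", "n_estimators", "test_fraction",
              "cutoff_year", "flags"},
}

#: files each stage needs -> the stage that produces them
_PREREQ: dict[str, dict[str, str]] = {
    "align": {"regions.geojson": "simulate"},
    "imgfeat": {"tiles/points.csv": "simulate"},
    "embed": {"monthly.csv": "align", "landcover_static.csv": "align",
              "img_features.csv": "imgfeat"},
    "prevalence": {"claims.csv": "simulate", "hierarchy.csv": "simulate"},
    "analyze": {"claims.csv": "simulate", "prevalence_l2.csv": "prevalence",
                "embedding_panel.csv": "embed"},
    "model": {"embedding_panel.csv": "embed", "prevalence_l2.csv": "prevalence"},
    "report": {"eval.csv": "model"},
}


class PipelineConfigError(ValueError):
    pass


def validate_config(cfg: dict) -> dict:
    """Reject unknown keys with a field-level message; fill defaults."""
    if not isinstance(cfg, dict):
        raise PipelineConfigError("config root must be a mapping")
    for section, allowed in _SCHEMA.items():
        block = cfg if section == "" else cfg.get(section, {})
        if not isinstance(block, dict):
            raise PipelineConfigError(f"section {section or 'root'!r} must be a mapping")
        unknown = set(block) - allowed
        if unknown:
            where = section or "root"
            raise PipelineConfigError(
                f"unknown config key(s) in {where}: {sorted(unknown)}"
            )
    out = {"seed": int(cfg.get("seed", 0)),
           "sim": dict(cfg.get("sim", {})),
           "analysis": dict(cfg.get("analysis", {})),
           "model": dict(cfg.get("model", {}))}
    return out


def sim_config_from(cfg: dict) -> sy.SimConfig:
    s = cfg["sim"]
    y0 = int(s.get("year_start", 2016))
    y1 = int(s.get("year_end", 2022))
    return sy.SimConfig(
        n_rows=int(s.get("n_rows", 4)),
        n_cols=int(s.get("n_cols", 4)),
        cell_km=float(s.get("cell_km", 4.0)),
        years=tuple(range(y0, y1 + 1)),
        n_patients=int(s.get("n_patients", 20_000)),
        greenness_weight=float(s.get("greenness_weight", 1.0)),
        tile_size=int(s.get("tile_size", 64)),
        seed=cfg["seed"],
    )


# ---------------------------------------------------------------------------
# Stage implementations (file-level wiring around the library functions)
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> list[Path]:
    sc = sim_config_from(cfg)
    regions = sy.make_region_grid(sc)
    dynamic, landcover = sy.simulate_env_rasters(regions, sc)
    tiles = sy.simulate_rgb_tiles(regions, sc)
    env = sy.annual_env_summary(dynamic, regions)
    claims, hierarchy = sy.simulate_claims(regions, env, sc)

    written = []
    al.write_regions_geojson(regions, outdir / "regions.geojson")
    written.append(outdir / "regions.geojson")
    (outdir / "rasters").mkdir(exist_ok=True)
    for name, ras in {**dynamic, **landcover}.items():
        p = outdir / "rasters" / f"{ras.variable}.nc"
        al.write_raster_netcdf(ras, p)
        written.append(p)
    sy.write_tiles(tiles, outdir / "tiles")
    written.append(outdir / "tiles" / "points.csv")
    sy.write_claims(claims, outdir / "claims.csv")
    sy.write_hierarchy(hierarchy, outdir / "hierarchy.csv")
    written += [outdir / "claims.csv", outdir / "hierarchy.csv"]
    return written


def stage_align(cfg: dict, outdir: Path) -> list[Path]:
    regions = al.read_regions_geojson(outdir / "regions.geojson")
    monthly_parts, static_parts = [], []
    for p in sorted((outdir / "rasters").glob("*.nc")):
        ras = al.read_raster_netcdf(p)
        series = al.to_monthly(al.zonal_mean(ras, regions))
        if ras.variable.startswith("lc_"):
            static_parts.append(al.static_average(series))
        else:
            monthly_parts.append(series)
    monthly = pd.concat(monthly_parts, ignore_index=True)
    static = pd.concat(static_parts, ignore_index=True)
    al.write_regional_series(monthly, outdir / "monthly.csv")
    static.to_csv(outdir / "landcover_static.csv", index=False)
    return [outdir / "monthly.csv", outdir / "landcover_static.csv"]


def stage_imgfeat(cfg: dict, outdir: Path) -> list[Path]:
    tiles = sy.read_tiles(outdir / "tiles")
    feats = im.tile_feature_table(tiles.tiles, tiles.points["point_id"])
    feats.to_csv(outdir / "img_features.csv")
    with open(outdir / "img_features_schema.json", "w") as fh:
        json.dump({"columns": im.FEATURE_NAMES, "registry": "v1"}, fh)
    return [outdir / "img_features.csv", outdir / "img_features_schema.json"]


def stage_embed(cfg: dict, outdir: Path) -> list[Path]:
    regions = al.read_regions_geojson(outdir / "regions.geojson")
    monthly = al.read_regional_series(outdir / "monthly.csv")
    static = pd.read_csv(outdir / "landcover_static.csv")
    feats = pd.read_csv(outdir / "img_features.csv", index_col="point_id")
    points = pd.read_csv(outdir / "tiles" / "points.csv",
                         dtype={"region_id": str}).fillna({"region_id": ""})

    years = sorted(monthly["month"].dt.year.unique())
    denv = {int(y): em.seasonal_embed(monthly, int(y)) for y in years}
    lc = em.landcover_block(static)
    img = im.aggregate_region_image_features(feats, points, regions)
    panel = em.annual_panel(denv, lc, img, subset="All")
    em.write_embedding(panel, outdir / "embedding_panel.csv",
                       outdir / "embedding_blockmap.json")
    return [outdir / "embedding_panel.csv", outdir / "embedding_blockmap.json"]


def stage_prevalence(cfg: dict, outdir: Path) -> list[Path]:
    claims = sy.read_claims(outdir / "claims.csv")
    hierarchy = pr.IcdHierarchy(sy.read_hierarchy(outdir / "hierarchy.csv"))
    written = []
    for level in (1, 2, 3):
        prev = pr.estimate_prevalence(claims, hierarchy, level)
        p = outdir / f"prevalence_l{level}.csv"
        pr.write_prevalence(prev, p)
        written.append(p)
    return written


def _urban_ids(cfg: dict, regions: al.RegionSet) -> set[str]:
    parent = cfg["analysis"].get("urban_parent", "P00C00")
    ids = set(regions.table.loc[regions.table["parent_id"] == parent, "region_id"])
    if not ids:
        raise PipelineConfigError(f"urban_parent {parent!r} matches no regions")
    return ids


def stage_analyze(cfg: dict, outdir: Path) -> list[Path]:
    regions = al.read_regions_geojson(outdir / "regions.geojson")
    claims = sy.read_claims(outdir / "claims.csv")
    hierarchy = pr.IcdHierarchy(sy.read_hierarchy(outdir / "hierarchy.csv"))
    level = int(cfg["analysis"].get("or_level", 2))
    urban = _urban_ids(cfg, regions)

    results = {}
    for group in hierarchy.groups_at_level(level):
        try:
            results[group] = an.urban_rural_or(claims, urban, group, hierarchy)
        except ValueError as exc:
            log.warning("odds ratio skipped for %s: %s", group, exc)
    an.or_results_table(results).to_csv(outdir / "odds_ratios.csv", index=False)

    panel = em.read_embedding(outdir / "embedding_panel.csv",
                              outdir / "embedding_blockmap.json", index_col=[0, 1])
    prev = pr.read_prevalence(outdir / f"prevalence_l{level}.csv")
    targets = prev.pivot_table(index=["region_id", "year"], columns="icd_group",
                               values="prevalence")
    env_cols = panel.blocks.get("DEnv", []) + panel.blocks.get("LC", [])
    corr = an.spearman_matrix(panel.data[env_cols], targets)
    corr.to_csv(outdir / "correlations.csv", index=False)
    return [outdir / "odds_ratios.csv", outdir / "correlations.csv"]


def stage_model(cfg: dict, outdir: Path) -> list[Path]:
    regions = al.read_regions_geojson(outdir / "regions.geojson")
    panel = em.read_embedding(outdir / "embedding_panel.csv",
                              outdir / "embedding_blockmap.json", index_col=[0, 1])
    prev = pr.read_prevalence(outdir / "prevalence_l2.csv")
    m = cfg["model"]
    subsets = list(m.get("subsets", ["DEnv", "All"]))
    target_names = list(m.get("targets", sorted(prev["icd_group"].unique())))
    years = sorted({y for _, y in panel.data.index})
    cutoff = int(m.get("cutoff_year", years[-1]))
    seed = cfg["seed"]

    panels = {}
    for s in subsets:
        cols = (list(panel.data.columns) if s == "All"
                else panel.blocks.get(s, []))
        if not cols:
            raise PipelineConfigError(f"unknown feature subset {s!r}")
        panels[s] = em.EmbeddingMatrix(
            data=panel.data[cols],
            blocks={s: cols} if s != "All" else panel.blocks,
        )
    targets = {t: pr.prevalence_panel(prev, t) for t in target_names}
    splits = {
        "interpolation": mo.SplitSpec("spatial_interpolation",
                                      test_fraction=float(m.get("test_fraction", 0.3)),
                                      seed=seed),
        "extrapolation": mo.SplitSpec("spatial_extrapolation",
                                      test_fraction=float(m.get("test_fraction", 0.3)),
                                      seed=seed),
        "forecasting": mo.SplitSpec("temporal_forecasting", cutoff_year=cutoff,
                                    seed=seed),
    }
    flag_combos = tuple(
        tuple(f) for f in m.get("flags", [[], ["T"], ["S"], ["T", "S"]])
    )
    table = mo.run_comparison(
        panels, targets, regions, splits, years,
        flag_combos=flag_combos,
        model=mo.ModelSpec(n_estimators=int(m.get("n_estimators", 500)), seed=seed),
    )
    table.to_csv(outdir / "eval.csv", index=False)
    return [outdir / "eval.csv"]


def stage_report(cfg: dict, outdir: Path) -> list[Path]:
    table = pd.read_csv(outdir / "eval.csv").fillna({"flags": ""})
    with open(outdir / "eval_report.txt", "w") as fh:
        fh.write(mo.render_report(table) + "\n")
    return [outdir / "eval_report.txt"]


_STAGE_FN = {
    "simulate": stage_simulate, "align": stage_align, "imgfeat": stage_imgfeat,
    "embed": stage_embed, "prevalence": stage_prevalence,
    "analyze": stage_analyze, "model": stage_model, "report": stage_report,
}


# ---------------------------------------------------------------------------
# Runner and manifest
# ---------------------------------------------------------------------------

def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()


def file_digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1


def run(config_path, stages: list[str] | None = None, outdir=None,
        seed: int | None = None) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    Stage inputs that are user-supplied (already present in ``outdir``) are
    used as-is; a missing upstream artifact raises an error naming the
    stage to run first.
    """
    with open(config_path) as fh:
        cfg = validate_config(yaml.safe_load(fh) or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir if outdir is not None else Path(config_path).parent / "out")
    outdir.mkdir(parents=True, exist_ok=True)

    requested = list(stages) if stages else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise PipelineConfigError(f"unknown stage(s): {sorted(unknown)}")
    ordered = [s for s in STAGES if s in requested]

    counter = _WarningCounter()
    log.addHandler(counter)
    written: dict[str, str] = {}
    try:
        for stage in ordered:
            for rel, producer in _PREREQ.get(stage, {}).items():
                if producer not in ordered and not (outdir / rel).exists():
                    raise FileNotFoundError(
                        f"stage {stage!r} needs {rel} — run stage {producer!r} first"
                    )
            log.info("running stage %s", stage)
            for p in _STAGE_FN[stage](cfg, outdir):
                written[str(p.relative_to(outdir))] = file_digest(p)
    finally:
        log.removeHandler(counter)

    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "stages": ordered,
        "stage_versions": {s: "1" for s in ordered},
        "years": [int(cfg["sim"].get("year_start", 2016)),
                  int(cfg["sim"].get("year_end", 2022))],
        "outputs": dict(sorted(written.items())),
        "warnings": counter.count,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
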