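import numpy as np
import pandas as pd
import pytest

import geohealth as gh
from geohealth import align as al
from geohealth import embed as em
from geohealth import images as im
from geohealth import prevalence as pr


@pytest.fixture(scope="session")
def tiny_cfg() -> gh.SimConfig:
    """Small, fast study configuration shared by the unit tests."""
    return gh.SimConfig(
        n_rows=3, n_cols=3, cell_km=2.0,
        years=(2016, 2017), n_patients=600, seed=7,
    )


@pytest.fixture(scope="session")
def regions(tiny_cfg):
    return gh.make_region_grid(tiny_cfg)


@pytest.fixture(scope="session")
def rasters(regions, tiny_cfg):
    return gh.simulate_env_rasters(regions, tiny_cfg)


@pytest.fixture(scope="session")
def monthly(rasters, regions):
    dynamic, _ = rasters
    return pd.concat(
        [al.to_monthly(al.zonal_mean(r, regions)) for r in dynamic.values()],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def landcover_static(rasters, regions):
    _, landcover = rasters
    return pd.concat(
        [al.static_average(al.to_monthly(al.zonal_mean(r, regions)))
         for r in landcover.values()],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def env_summary(rasters, regions):
    dynamic, _ = rasters
    return gh.annual_env_summary(dynamic, regions)


@pytest.fixture(scope="session")
def claims_and_hierarchy(regions, env_summary, tiny_cfg):
    return gh.simulate_claims(regions, env_summary, tiny_cfg)


@pytest.fixture(scope="session")
def hierarchy(claims_and_hierarchy):
    return pr.IcdHierarchy(claims_and_hierarchy[1])


@pytest.fixture(scope="session")
def tiles(regions, tiny_cfg):
    return gh.simulate_rgb_tiles(regions, tiny_cfg)


@pytest.fixture(scope="session")
def panel(monthly, landcover_static, tiles, regions, tiny_cfg):
    """Full All-subset (region_id, year) embedding panel for the tiny config."""
    feats = im.tile_feature_table(tiles.tiles, tiles.points["point_id"])
    img = im.aggregate_region_image_features(feats, tiles.points, regions)
    denv = {y: em.seasonal_embed(monthly, y) for y in tiny_cfg.years}
    lc = em.landcover_block(landcover_static)
    return em.annual_panel(denv, lc, img, subset="All")


def rng_tile(seed: int, shape=(8, 8)) -> np.ndarray:
    """Random RGB tile in [0,1] for oracle comparisons."""
    return np.random.default_rng(seed).random(size=shape + (3,))
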