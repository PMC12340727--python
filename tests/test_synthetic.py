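"""Generator contracts: lattice geometry, field structure, link fidelity."""

import numpy as np
import pandas as pd
import pytest

import geohealth as gh
from geohealth import align as al
from geohealth.synthetic import ConfigError


def brute_force_rook_adjacency(n_rows, n_cols):
    edges = set()
    for i in range(n_rows):
        for j in range(n_cols):
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < n_rows and 0 <= jj < n_cols:
                    edges.add(frozenset({(i, j), (ii, jj)}))
    return edges


class TestRegionGrid:
    def test_2x2_lattice_has_4_regions_and_4_edges(self):
        cfg = gh.SimConfig(n_rows=2, n_cols=2, cell_km=10.0, years=(2016,))
        rs = gh.make_region_grid(cfg)
        assert len(rs) == 4
        n_edges = sum(len(v) for v in rs.adjacency.values()) // 2
        assert n_edges == 4

    def test_sub_minimum_lattice_rejected(self):
        with pytest.raises(ConfigError):
            gh.SimConfig(n_rows=1, n_cols=1, years=(2016,))
        with pytest.raises(ConfigError):
            gh.SimConfig(n_rows=0, n_cols=5, years=(2016,))

    @pytest.mark.parametrize("shape", [(3, 3), (2, 5), (4, 3)])
    def test_adjacency_matches_brute_force(self, shape):
        nr, nc = shape
        cfg = gh.SimConfig(n_rows=nr, n_cols=nc, cell_km=4.0, years=(2016,))
        rs = gh.make_region_grid(cfg)
        got = {
            frozenset({a, b})
            for a, nbrs in rs.adjacency.items() for b in nbrs
        }
        def rid(i, j):
            return f"R{i:02d}C{j:02d}"
        want = {
            frozenset({rid(*u), rid(*v)})
            for e in brute_force_rook_adjacency(nr, nc) for u, v in [tuple(e)]
        }
        assert got == want
        # corner regions have exactly two rook neighbors
        assert len(rs.adjacency[rid(0, 0)]) == 2

    def test_polygons_tile_without_overlap_and_parents_assigned(self):
        cfg = gh.SimConfig(n_rows=3, n_cols=3, cell_km=2.0, years=(2016,))
        rs = gh.make_region_grid(cfg)
        import shapely.ops

        union = shapely.ops.unary_union(list(rs.table["geometry"]))
        assert union.area == pytest.approx(9 * 4.0)
        assert sum(g.area for g in rs.table["geometry"]) == pytest.approx(union.area)
        assert (rs.table["parent_id"] != "").all()
        assert all(r not in nbrs for r, nbrs in rs.adjacency.items())


class TestEnvRasters:
    def test_degenerate_generator_is_constant_over_time(self):
        spec = gh.EnvVarSpec("flat", amplitude=0.0, noise_sd=0.0, anomaly_sd=0.0)
        cfg = gh.SimConfig(n_rows=2, n_cols=2, years=(2016,), env_vars=(spec,))
        rs = gh.make_region_grid(cfg)
        dyn, _ = gh.simulate_env_rasters(rs, cfg)
        v = dyn["flat"].values
        assert np.allclose(v, v[0][None, ...])

    def test_seasonal_closed_form(self):
        spec = gh.EnvVarSpec("seas", amplitude=1.0, phase=0.0, field_sd=0.0,
                             noise_sd=0.0, anomaly_sd=0.0)
        cfg = gh.SimConfig(n_rows=2, n_cols=2, years=(2016,), env_vars=(spec,))
        rs = gh.make_region_grid(cfg)
        dyn, _ = gh.simulate_env_rasters(rs, cfg)
        v = dyn["seas"].values
        july_minus_jan = v[6, 0, 0] - v[0, 0, 0]
        expected = np.sin(2 * np.pi * 7 / 12) - np.sin(2 * np.pi * 1 / 12)
        assert july_minus_jan == pytest.approx(expected, abs=1e-12)

    def test_landcover_fractions_sum_to_one_per_pixel(self, rasters):
        _, landcover = rasters
        total = sum(r.values[0] for r in landcover.values())
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_too_coarse_pixel_rejected(self):
        with pytest.raises(ConfigError):
            gh.SimConfig(n_rows=2, n_cols=2, cell_km=4.0, pixel_km=2.0,
                         years=(2016,))

    def test_nonconsecutive_years_rejected(self):
        with pytest.raises(ConfigError):
            gh.SimConfig(years=(2016, 2018))

    def test_spatial_autocorrelation_positive_sign_test(self):
        """Moran's I of the generated field is positive in essentially every
        seed when the correlation length is at least the cell size."""
        spec = gh.EnvVarSpec("f", amplitude=0.0, noise_sd=0.0, anomaly_sd=0.0,
                             corr_length_km=4.0)
        positives = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = gh.SimConfig(n_rows=4, n_cols=4, cell_km=4.0, years=(2016,),
                               env_vars=(spec,), seed=seed)
            rs = gh.make_region_grid(cfg)
            dyn, _ = gh.simulate_env_rasters(rs, cfg)
            zm = al.zonal_mean(dyn["f"], rs)
            per_region = zm.groupby("region_id")["value"].mean()
            if gh.morans_i(per_region, rs.adjacency) > 0:
                positives += 1
        # one-sided sign test: 66/100 rejects "median <= 0" at p < 1e-3
        assert positives >= 66


class TestTiles:
    def test_grid_point_count_10km_region(self):
        cfg = gh.SimConfig(n_rows=2, n_cols=2, cell_km=10.0, years=(2016,))
        rs = gh.make_region_grid(cfg)
        ts = gh.simulate_rgb_tiles(rs, cfg)
        counts = ts.points.groupby("region_id").size()
        # 10 km x 10 km at 500 m spacing: 20 x 20 interior points per region
        assert (counts == 400).all()
        assert len(ts.points) == 1600

    def test_green_channel_monotone_in_greenness(self, tiles):
        green_means = tiles.tiles[..., 1].mean(axis=(1, 2))
        rho = pd.Series(green_means).corr(pd.Series(tiles.greenness), method="spearman")
        assert rho > 0.9

    def test_zero_weight_decouples_tiles_from_greenness(self, tiny_cfg, regions):
        cfg = gh.SimConfig(n_rows=3, n_cols=3, cell_km=2.0, years=(2016, 2017),
                           greenness_weight=0.0, seed=tiny_cfg.seed)
        ts = gh.simulate_rgb_tiles(regions, cfg)
        green_means = ts.tiles[..., 1].mean(axis=(1, 2))
        r = np.corrcoef(green_means, ts.greenness)[0, 1]
        assert abs(r) < 0.2
        assert np.all(ts.tiles >= 0) and np.all(ts.tiles <= 1)


class TestClaims:
    def test_flat_link_gives_half_prevalence_everywhere(self):
        links = {"I10": gh.CodeLink(alpha=0.0, beta={})}
        cfg = gh.SimConfig(n_rows=2, n_cols=2, cell_km=10.0, years=(2016,),
                           n_patients=5000, link_spec=links, seed=3)
        rs = gh.make_region_grid(cfg)
        env = pd.DataFrame(
            {"temperature": 0.0},
            index=pd.MultiIndex.from_product(
                [rs.region_ids, cfg.years], names=["region_id", "year"]),
        )
        claims, _ = gh.simulate_claims(rs, env, cfg)
        coded = claims[claims["icd_code"] == "I10"]
        prev = (coded.groupby("region_id")["patient_id"].nunique()
                / claims.groupby("region_id")["patient_id"].nunique())
        assert np.allclose(prev, 0.5, atol=0.05)

    def test_impossible_code_never_emitted(self):
        links = {"I10": gh.CodeLink(alpha=-np.inf, beta={}),
                 "E10": gh.CodeLink(alpha=0.0, beta={})}
        cfg = gh.SimConfig(n_rows=2, n_cols=2, cell_km=10.0, years=(2016,),
                           n_patients=500, link_spec=links, seed=4)
        rs = gh.make_region_grid(cfg)
        env = pd.DataFrame(
            {"temperature": 0.0},
            index=pd.MultiIndex.from_product(
                [rs.region_ids, cfg.years], names=["region_id", "year"]),
        )
        claims, _ = gh.simulate_claims(rs, env, cfg)
        assert "I10" not in set(claims["icd_code"])

    def test_link_fidelity_monte_carlo(self):
        """Regional prevalence tracks the logistic link to < 0.02 at n=20000."""
        links = {"I10": gh.CodeLink(alpha=0.0, beta={"x": 1.0})}
        cfg = gh.SimConfig(n_rows=2, n_cols=2, cell_km=10.0, years=(2016,),
                           n_patients=20_000, link_spec=links, seed=11)
        rs = gh.make_region_grid(cfg)
        env = pd.DataFrame(
            {"x": [-1.5, -0.5, 0.5, 1.5]},
            index=pd.MultiIndex.from_product(
                [rs.region_ids, cfg.years], names=["region_id", "year"]),
        )
        from geohealth.synthetic import zscore_env_summary

        z = zscore_env_summary(env)["x"]
        expected = 1 / (1 + np.exp(-z.droplevel("year")))
        claims, _ = gh.simulate_claims(rs, env, cfg)
        coded = claims[claims["icd_code"] == "I10"]
        prev = (coded.groupby("region_id")["patient_id"].nunique()
                / claims.groupby("region_id")["patient_id"].nunique())
        dev = (prev - expected).abs().max()
        assert dev < 0.02

    def test_unknown_env_variable_in_link_rejected(self, regions, env_summary):
        links = {"I10": gh.CodeLink(alpha=0.0, beta={"no_such_var": 1.0})}
        cfg = gh.SimConfig(n_rows=3, n_cols=3, cell_km=2.0,
                           years=(2016, 2017), link_spec=links)
        with pytest.raises(ConfigError, match="no_such_var"):
            gh.simulate_claims(regions, env_summary, cfg)

    def test_every_patient_has_1_to_5_visits_per_year(self, claims_and_hierarchy,
                                                      tiny_cfg):
        claims, _ = claims_and_hierarchy
        per_py = (claims.drop_duplicates("visit_id")
                  .assign(year=lambda d: pd.to_datetime(d["date"]).dt.year)
                  .groupby(["patient_id", "year"]).size())
        assert per_py.min() >= 1 and per_py.max() <= 5
        assert claims["patient_id"].nunique() == tiny_cfg.n_patients


class TestDeterminism:
    def test_identical_config_gives_identical_outputs(self, tiny_cfg):
        outs = []
        for _ in range(2):
            rs = gh.make_region_grid(tiny_cfg)
            dyn, lc = gh.simulate_env_rasters(rs, tiny_cfg)
            ts = gh.simulate_rgb_tiles(rs, tiny_cfg)
            env = gh.annual_env_summary(dyn, rs)
            claims, _ = gh.simulate_claims(rs, env, tiny_cfg)
            outs.append((dyn, lc, ts, claims))
        (d1, l1, t1, c1), (d2, l2, t2, c2) = outs
        for k in d1:
            assert d1[k].values.tobytes() == d2[k].values.tobytes()
        for k in l1:
            assert l1[k].values.tobytes() == l2[k].values.tobytes()
        assert t1.tiles.tobytes() == t2.tiles.tobytes()
        pd.testing.assert_frame_equal(c1, c2)
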