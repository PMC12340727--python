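"""Splits, +S/+T augmentation and the regression harness."""

import numpy as np
import pandas as pd
import pytest

import geohealth as gh
from geohealth import modeling as mo
from geohealth.embed import EmbeddingMatrix


@pytest.fixture(scope="module")
def lattice10():
    cfg = gh.SimConfig(n_rows=2, n_cols=5, cell_km=4.0, years=(2016,))
    return gh.make_region_grid(cfg)


def panel_from(regions, years, fn, names=("f0", "f1")):
    idx = pd.MultiIndex.from_product([regions.region_ids, list(years)],
                                     names=["region_id", "year"])
    data = pd.DataFrame({n: [fn(r, y, k) for r, y in idx]
                         for k, n in enumerate(names)}, index=idx)
    return EmbeddingMatrix(data=data, blocks={"DEnv": list(names)})


class TestZScore:
    def test_train_set_standardized(self):
        x = np.array([1.0, 2.0, 3.0, 10.0])
        z_tr, z_ap, _ = mo.zscore_targets(x, x)
        assert z_tr.mean() == pytest.approx(0.0, abs=1e-12)
        assert z_tr.std() == pytest.approx(1.0)
        np.testing.assert_allclose(z_tr, z_ap)

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mo.zscore_targets(np.ones(5), np.ones(5), "flat")

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        x = rng.random(50)
        _, z, scaler = mo.zscore_targets(x[:30], x)
        np.testing.assert_allclose(scaler.invert(z), x, atol=1e-12)

    def test_no_leakage_test_rows_not_standardized(self):
        rng = np.random.default_rng(1)
        train = rng.normal(0, 1, 100)
        test = rng.normal(2, 1, 100)  # shifted population
        _, z_te, _ = mo.zscore_targets(train, test)
        assert abs(z_te.mean()) > 1.0


class TestMetrics:
    def test_perfect_predictions(self):
        mae, mse, r2 = mo.regression_metrics([1, 2, 3], [1, 2, 3])
        assert (mae, mse, r2) == (0.0, 0.0, 1.0)

    def test_predicting_the_mean_gives_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        _, _, r2 = mo.regression_metrics(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        mae, mse, r2 = mo.regression_metrics([1, 2, 3], [1, 2, 6])
        assert mae == pytest.approx(1.0)
        assert mse == pytest.approx(3.0)
        assert r2 == pytest.approx(-3.5)  # SS_res 9 over SS_tot 2


class TestMakeSplit:
    def test_interpolation_cardinality_and_disjointness(self, lattice10):
        spec = mo.SplitSpec("spatial_interpolation", test_fraction=0.3, seed=4)
        train, test = mo.make_split(lattice10, [2016, 2017], spec)
        test_regions = set(test.get_level_values("region_id"))
        train_regions = set(train.get_level_values("region_id"))
        assert len(test_regions) == 3
        assert not (test_regions & train_regions)
        assert len(train) + len(test) == 10 * 2

    def test_extrapolation_block_connected_under_rook_adjacency(self):
        cfg = gh.SimConfig(n_rows=3, n_cols=3, cell_km=4.0, years=(2016,))
        rs = gh.make_region_grid(cfg)
        spec = mo.SplitSpec("spatial_extrapolation", test_fraction=0.34, seed=0)
        _, test = mo.make_split(rs, [2016], spec)
        block = set(test.get_level_values("region_id"))
        # BFS connectivity oracle
        start = next(iter(block))
        seen, frontier = {start}, [start]
        while frontier:
            nxt = frontier.pop()
            for nbr in rs.adjacency[nxt]:
                if nbr in block and nbr not in seen:
                    seen.add(nbr)
                    frontier.append(nbr)
        assert seen == block

    def test_forecasting_cutoff_last_year(self, lattice10):
        spec = mo.SplitSpec("temporal_forecasting", cutoff_year=2018)
        train, test = mo.make_split(lattice10, [2016, 2017, 2018], spec)
        assert set(test.get_level_values("year")) == {2018}
        assert set(train.get_level_values("year")) == {2016, 2017}

    def test_split_determinism(self, lattice10):
        spec = mo.SplitSpec("spatial_interpolation", test_fraction=0.3, seed=11)
        a = mo.make_split(lattice10, [2016], spec)
        b = mo.make_split(lattice10, [2016], spec)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_empty_side_rejected(self, lattice10):
        spec = mo.SplitSpec("temporal_forecasting", cutoff_year=2010)
        with pytest.raises(ValueError):
            mo.make_split(lattice10, [2016, 2017], spec)


class TestAugment:
    def test_identical_rows_make_neighbor_block_equal_base(self, lattice10):
        panel = panel_from(lattice10, [2016], lambda r, y, k: 3.0 + k)
        out = mo.augment_spatiotemporal(panel, lattice10, add_neighbors=True)
        np.testing.assert_allclose(out.data[["nbr__f0", "nbr__f1"]].to_numpy(),
                                   out.data[["f0", "f1"]].to_numpy())

    def test_history_block_is_exact_prior_year_copy(self, lattice10):
        rng = np.random.default_rng(2)
        panel = panel_from(lattice10, [2016, 2017],
                           lambda r, y, k: float(rng.random()))
        out = mo.augment_spatiotemporal(panel, lattice10, add_history=True)
        lag17 = out.data.xs(2017, level="year")[["lag__f0", "lag__f1"]]
        base16 = panel.data.xs(2016, level="year")[["f0", "f1"]]
        np.testing.assert_allclose(lag17.to_numpy(), base16.to_numpy())
        assert out.data.xs(2016, level="year")[["lag__f0"]].isna().all().all()

    def test_corner_region_neighbor_mean_brute_force(self):
        cfg = gh.SimConfig(n_rows=3, n_cols=3, cell_km=4.0, years=(2016,))
        rs = gh.make_region_grid(cfg)
        rng = np.random.default_rng(3)
        panel = panel_from(rs, [2016], lambda r, y, k: float(rng.random()))
        out = mo.augment_spatiotemporal(panel, rs, add_neighbors=True)
        corner = "R00C00"
        nbrs = rs.adjacency[corner]
        assert len(nbrs) == 2
        expected = panel.data.loc[[(n, 2016) for n in nbrs]].mean(axis=0)
        got = out.data.loc[(corner, 2016), ["nbr__f0", "nbr__f1"]]
        np.testing.assert_allclose(got.to_numpy(), expected.to_numpy())

    def test_isolated_region_falls_back_to_own_row(self, caplog):
        table = pd.DataFrame({
            "region_id": ["A", "B", "C", "D"], "level": "cell", "parent_id": "P",
            "geometry": [None] * 4,
        })
        rs = gh.RegionSet(table=table, adjacency={"A": [], "B": [], "C": [], "D": []})
        panel = panel_from(rs, [2016], lambda r, y, k: float(ord(r[0])))
        with caplog.at_level("WARNING", logger="geohealth"):
            out = mo.augment_spatiotemporal(panel, rs, add_neighbors=True)
        np.testing.assert_allclose(out.data["nbr__f0"], out.data["f0"])
        assert any("isolated" in r.message for r in caplog.records)


class TestFitEval:
    def test_learnable_signal_and_report_fields(self, lattice10):
        rng = np.random.default_rng(5)
        panel = panel_from(lattice10, range(2016, 2020),
                           lambda r, y, k: float(rng.random()))
        y = panel.data["f0"] * 2.0 + 0.01 * rng.random(len(panel.data))
        split = mo.make_split(lattice10, list(range(2016, 2020)),
                              mo.SplitSpec("spatial_interpolation", seed=0))
        rep = mo.fit_eval(panel, y, split, mo.ModelSpec(n_estimators=50, seed=0),
                          target_name="t")
        assert rep.r2 > 0.8
        assert rep.n_train + rep.n_test == len(panel.data)
        assert rep.mse >= 0 and rep.r2 <= 1

    def test_few_test_rows_refused(self, lattice10):
        panel = panel_from(lattice10, [2016], lambda r, y, k: 1.0 * k)
        y = pd.Series(np.arange(10, dtype=float), index=panel.data.index)
        train = panel.data.index[:8]
        test = panel.data.index[8:]
        with pytest.raises(ValueError, match="test rows"):
            mo.fit_eval(panel, y, (train, test))


class TestRunComparison:
    @staticmethod
    def _setup(lattice10):
        rng = np.random.default_rng(6)
        panel = panel_from(lattice10, [2016, 2017, 2018],
                           lambda r, y, k: float(rng.random()))
        y = panel.data["f0"] + 0.1 * rng.random(len(panel.data))
        splits = {"interp": mo.SplitSpec("spatial_interpolation", seed=1)}
        return panel, {"tgt": y}, splits

    def test_denv_only_request(self, lattice10):
        panel, targets, splits = self._setup(lattice10)
        table = mo.run_comparison({"DEnv": panel}, targets, lattice10, splits,
                                  [2016, 2017, 2018],
                                  model=mo.ModelSpec(n_estimators=20, seed=0))
        assert set(table["subset"]) == {"DEnv"}

    def test_identical_seeds_identical_tables(self, lattice10):
        panel, targets, splits = self._setup(lattice10)
        kw = dict(flag_combos=((), ("S",)),
                  model=mo.ModelSpec(n_estimators=20, seed=0))
        t1 = mo.run_comparison({"DEnv": panel}, targets, lattice10, splits,
                               [2016, 2017, 2018], **kw)
        t2 = mo.run_comparison({"DEnv": panel}, targets, lattice10, splits,
                               [2016, 2017, 2018], **kw)
        pd.testing.assert_frame_equal(t1, t2)
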