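import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

from popdis import (
    InvalidInputError,
    OccupancyWeights,
    RFConfig,
    UrbanMask,
    WeightLayer,
    ZoneSet,
    build_grid,
    combined_disaggregate,
    dasymetric_binary,
    dasymetric_categorical,
    estimate_to_grid,
    fit_weight_model,
    predict_weight_layer,
    search_occupancy_weights,
    statistical_disaggregate,
)
from tests.conftest import random_allocation_fixture


def sz_one(pop=100.0, size=100.0):
    return ZoneSet(
        "L2",
        pd.DataFrame({"unit_id": ["S"], "geometry": [box(0, 0, size, size)],
                      "pop": [pop]}),
    )


def footprint_mask(rows, land_use=True):
    df = pd.DataFrame(rows)
    df["area"] = shapely.area(np.asarray(df["geometry"], dtype=object))
    if not land_use and "land_use" in df.columns:
        df = df.drop(columns="land_use")
    return UrbanMask("FOOTPRINT", "AREA", buildings=df)


def two_buildings(a1=30.0, a2=70.0, f1=1, f2=1, lu=("R", "R"), land_use=True):
    return footprint_mask([
        {"building_id": "b1", "geometry": box(0, 0, a1 / 10, 10), "floors": f1,
         "land_use": lu[0]},
        {"building_id": "b2", "geometry": box(20, 0, 20 + a2 / 10, 10),
         "floors": f2, "land_use": lu[1]},
    ], land_use=land_use)


class TestBinaryDasymetric:
    def test_proportional_30_70(self):
        est = dasymetric_binary(sz_one(100.0), two_buildings())
        assert est.df["pop"].tolist() == pytest.approx([30.0, 70.0])

    def test_single_tz_identity(self):
        mask = footprint_mask([
            {"building_id": "b", "geometry": box(0, 0, 10, 10), "floors": 2,
             "land_use": "R"}
        ])
        est = dasymetric_binary(sz_one(100.0), mask)
        assert est.df["pop"].iloc[0] == pytest.approx(100.0)

    def test_volume_dimension(self):
        # sizes 50*1 = 50 and 25*6 = 150 -> shares 25 / 75
        mask = footprint_mask([
            {"building_id": "b1", "geometry": box(0, 0, 5, 10), "floors": 1,
             "land_use": "R"},
            {"building_id": "b2", "geometry": box(20, 0, 22.5, 10), "floors": 6,
             "land_use": "R"},
        ])
        est = dasymetric_binary(sz_one(100.0), mask, dimension="VOLUME")
        assert est.df["pop"].tolist() == pytest.approx([25.0, 75.0])

    def test_fallback_preserves_population(self):
        # populated SZ without any urban feature inside it
        sz = ZoneSet(
            "L2",
            pd.DataFrame({
                "unit_id": ["A", "B"],
                "geometry": [box(0, 0, 50, 100), box(50, 0, 100, 100)],
                "pop": [100.0, 40.0],
            }),
        )
        mask = footprint_mask([
            {"building_id": "b", "geometry": box(10, 10, 20, 20), "floors": 1,
             "land_use": "R"}
        ])
        est = dasymetric_binary(sz, mask)
        assert est.fallback_szs == ["B"]
        assert est.total() == pytest.approx(140.0)


class TestCategoricalDasymetric:
    def test_weighted_shares(self):
        # residential 50 (w 1) vs commercial 50 (w 0.4): 100*50/70, 100*20/70
        mask = two_buildings(50.0, 50.0, lu=("R", "C"))
        est = dasymetric_categorical(sz_one(100.0), mask,
                                     w=OccupancyWeights(w_C=0.4, w_O=0.3))
        assert est.df["pop"].tolist() == pytest.approx([500 / 7, 200 / 7])

    def test_single_land_use_reduces_to_binary(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            sz, b = random_allocation_fixture(rng)
            b = b.assign(land_use="R")
            mask = UrbanMask("FOOTPRINT", "AREA", buildings=b)
            cat = dasymetric_categorical(sz, mask, w=OccupancyWeights(0.2, 0.7))
            binary = dasymetric_binary(sz, mask)
            assert np.allclose(cat.df["pop"], binary.df["pop"], atol=1e-9)

    def test_zero_weights_annihilate_non_residential(self):
        mask = two_buildings(50.0, 50.0, lu=("R", "C"))
        est = dasymetric_categorical(sz_one(100.0), mask,
                                     w=OccupancyWeights(w_C=0.0, w_O=0.0))
        assert est.df["pop"].tolist() == pytest.approx([100.0, 0.0])

    def test_requires_land_use(self):
        mask = two_buildings(land_use=False)
        with pytest.raises(InvalidInputError):
            dasymetric_categorical(sz_one(), mask)


class TestStatistical:
    def test_uniform_weights_symmetric(self):
        grid = build_grid((0, 0, 100, 100), 50.0)
        layer = WeightLayer(grid, np.ones(4))
        est = statistical_disaggregate(sz_one(100.0), layer)
        assert est.df["pop"].tolist() == pytest.approx([25.0] * 4)

    def test_weight_ratio(self):
        grid = build_grid((0, 0, 100, 50), 50.0)
        layer = WeightLayer(grid, np.array([1.0, 3.0]))
        est = statistical_disaggregate(sz_one(100.0, 100.0), layer)
        # only the lower half of the SZ is covered by this 2-cell grid,
        # so conservation still holds: shares 25/75 of the full count
        assert est.df["pop"].tolist() == pytest.approx([25.0, 75.0])

    def test_zero_population_sz_zero_output(self):
        grid = build_grid((0, 0, 100, 100), 50.0)
        layer = WeightLayer(grid, np.ones(4))
        est = statistical_disaggregate(sz_one(0.0), layer)
        assert (est.df["pop"] == 0).all()


class TestWeightModel:
    @staticmethod
    def _cov(n, rng, k=4):
        return pd.DataFrame(
            rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)],
            index=[f"S{i}" for i in range(n)],
        )

    @staticmethod
    def _sz(n, pops):
        return ZoneSet(
            "L2",
            pd.DataFrame({
                "unit_id": [f"S{i}" for i in range(n)],
                "geometry": [box(i * 10, 0, i * 10 + 10, 10) for i in range(n)],
                "pop": pops,
            }),
        )

    def test_recoverable_signal_high_oob_r2(self):
        rng = np.random.default_rng(0)
        n = 200
        cov = self._cov(n, rng)
        dens = np.abs(cov["x0"].to_numpy()) + 0.1   # density = one covariate
        sz = self._sz(n, dens * 100.0)              # area 100 per unit
        fit = fit_weight_model(sz, cov, RFConfig(seed=1))
        assert fit.oob_r2 > 90.0

    def test_pure_noise_near_zero_oob_r2(self):
        rng = np.random.default_rng(1)
        n = 200
        cov = self._cov(n, rng)
        sz = self._sz(n, rng.uniform(10, 1000, n))
        fit = fit_weight_model(sz, cov, RFConfig(seed=1))
        assert fit.oob_r2 < 10.0

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(2)
        n = 60
        cov = self._cov(n, rng)
        sz = self._sz(n, rng.uniform(10, 500, n))
        grid = build_grid((0, 0, 100, 100), 50.0)
        gcov = pd.DataFrame(rng.normal(size=(4, 4)), columns=cov.columns,
                            index=grid.unit_ids)
        f1 = fit_weight_model(sz, cov, RFConfig(seed=9))
        f2 = fit_weight_model(sz, cov, RFConfig(seed=9))
        w1 = predict_weight_layer(f1, gcov, grid)
        w2 = predict_weight_layer(f2, gcov, grid)
        assert np.array_equal(w1.values, w2.values)

    def test_monotone_single_covariate(self):
        rng = np.random.default_rng(3)
        n = 120
        x = np.linspace(0, 1, n)
        cov = pd.DataFrame({"x0": x}, index=[f"S{i}" for i in range(n)])
        sz = self._sz(n, 100.0 * (1 + 5 * x))
        fit = fit_weight_model(sz, cov, RFConfig(seed=1))
        grid = build_grid((0, 0, 200, 50), 50.0)
        gx = np.array([0.1, 0.4, 0.6, 0.9])
        layer = predict_weight_layer(
            fit, pd.DataFrame({"x0": gx}, index=grid.unit_ids), grid
        )
        assert (np.diff(layer.values) >= -1e-12).all()

    def test_column_mismatch_error(self):
        rng = np.random.default_rng(4)
        cov = self._cov(30, rng)
        sz = self._sz(30, rng.uniform(10, 100, 30))
        fit = fit_weight_model(sz, cov, RFConfig(seed=1))
        grid = build_grid((0, 0, 100, 100), 50.0)
        bad = pd.DataFrame({"wrong": np.zeros(4)}, index=grid.unit_ids)
        with pytest.raises(InvalidInputError, match="x0"):
            predict_weight_layer(fit, bad, grid)

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(5)
        cov = self._cov(4, rng)
        sz = self._sz(4, [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(InvalidInputError):
            fit_weight_model(sz, cov, RFConfig(seed=0))


class TestCombined:
    def test_constant_weights_reduce_to_binary(self):
        rng = np.random.default_rng(6)
        grid = build_grid((0, 0, 400, 400), 100.0)
        layer = WeightLayer(grid, np.full(16, 2.5))
        for _ in range(5):
            sz, b = random_allocation_fixture(rng)
            mask = UrbanMask("FOOTPRINT", "AREA", buildings=b)
            comb = combined_disaggregate(sz, mask, "AREA", layer)
            binary = dasymetric_binary(sz, mask)
            assert np.allclose(comb.df["pop"], binary.df["pop"], atol=1e-9)

    def test_constant_weights_reduce_to_categorical(self):
        rng = np.random.default_rng(7)
        grid = build_grid((0, 0, 400, 400), 100.0)
        layer = WeightLayer(grid, np.full(16, 0.7))
        w = OccupancyWeights(w_C=0.4, w_O=0.3)
        for _ in range(5):
            sz, b = random_allocation_fixture(rng)
            mask = UrbanMask("FOOTPRINT", "AREA", buildings=b)
            comb = combined_disaggregate(sz, mask, "AREA", layer, w=w)
            cat = dasymetric_categorical(sz, mask, w=w)
            assert np.allclose(comb.df["pop"], cat.df["pop"], atol=1e-9)

    def test_equal_occupancy_reduces_categorical_to_binary_form(self):
        rng = np.random.default_rng(8)
        grid = build_grid((0, 0, 400, 400), 100.0)
        layer = WeightLayer(grid, rng.uniform(0.5, 2.0, 16))
        sz, b = random_allocation_fixture(rng)
        mask = UrbanMask("FOOTPRINT", "AREA", buildings=b)
        same_w = OccupancyWeights(w_C=1.0, w_O=1.0, w_R=1.0)
        cat = combined_disaggregate(sz, mask, "AREA", layer, w=same_w)
        binary = combined_disaggregate(sz, mask, "AREA", layer)
        assert np.allclose(cat.df["pop"], binary.df["pop"], atol=1e-9)

    def test_cell_weight_lookup_hand_example(self):
        # two equal buildings whose centroids fall in cells weighted 1 and 3
        grid = build_grid((0, 0, 200, 100), 100.0)
        layer = WeightLayer(grid, np.array([1.0, 3.0]))
        sz = ZoneSet(
            "L2",
            pd.DataFrame({"unit_id": ["S"], "geometry": [box(0, 0, 200, 100)],
                          "pop": [100.0]}),
        )
        mask = footprint_mask([
            {"building_id": "b1", "geometry": box(40, 40, 60, 60), "floors": 1,
             "land_use": "R"},
            {"building_id": "b2", "geometry": box(140, 40, 160, 60), "floors": 1,
             "land_use": "R"},
        ])
        est = combined_disaggregate(sz, mask, "AREA", layer)
        assert est.df["pop"].tolist() == pytest.approx([25.0, 75.0])


class TestInvariantsAndOracle:
    def brute_force(self, sz, feats, factors):
        """Independent direct-summation disaggregation (nested loops)."""
        out = np.zeros(len(feats))
        for zidx, zrow in sz.df.iterrows():
            weights = np.zeros(len(feats))
            for i, frow in feats.iterrows():
                inter = frow["geometry"].intersection(zrow["geometry"]).area
                if inter > 0:
                    weights[i] = (
                        frow["size"] * inter / frow["geometry"].area * factors[i]
                    )
            tot = weights.sum()
            if tot > 0:
                out += weights / tot * zrow["pop"]
        return out

    def test_all_methods_match_direct_summation(self):
        rng = np.random.default_rng(9)
        w = OccupancyWeights(w_C=0.4, w_O=0.3)
        grid = build_grid((0, 0, 400, 400), 100.0)
        values = rng.uniform(0.2, 2.0, 16)
        layer = WeightLayer(grid, values)
        for _ in range(8):
            sz, b = random_allocation_fixture(rng)
            mask = UrbanMask("FOOTPRINT", "AREA", buildings=b)
            feats = mask.features().assign(
                size=lambda d: [g.area for g in d["geometry"]]
            )
            cents = shapely.centroid(np.asarray(feats["geometry"], dtype=object))
            wp = layer.at_points(shapely.get_x(cents), shapely.get_y(cents))
            lu_f = w.factor(feats["land_use"].to_numpy())
            cases = [
                (dasymetric_binary(sz, mask), np.ones(len(feats))),
                (dasymetric_categorical(sz, mask, w=w), lu_f),
                (combined_disaggregate(sz, mask, "AREA", layer), wp),
                (combined_disaggregate(sz, mask, "AREA", layer, w=w), wp * lu_f),
            ]
            for est, factors in cases:
                expect = self.brute_force(sz, feats, factors)
                got = est.df["pop"].to_numpy()[: len(feats)]
                fb = est.df["pop"].to_numpy()[len(feats):].sum()
                assert np.allclose(got, expect, atol=1e-9)
                # any fallback mass accounts exactly for SZs with zero weight
                assert got.sum() + fb == pytest.approx(sz.populations.sum(),
                                                       rel=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(10)
        sz, b = random_allocation_fixture(rng)
        mask = UrbanMask("FOOTPRINT", "AREA", buildings=b)
        est1 = dasymetric_binary(sz, mask)
        sz2 = ZoneSet("L2", sz.df.assign(pop=sz.df["pop"] * 2))
        est2 = dasymetric_binary(sz2, mask)
        assert np.allclose(est2.df["pop"], est1.df["pop"] * 2, atol=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        sz, b = random_allocation_fixture(rng)
        perm = rng.permutation(len(b))
        mask1 = UrbanMask("FOOTPRINT", "AREA", buildings=b)
        mask2 = UrbanMask("FOOTPRINT", "AREA",
                          buildings=b.iloc[perm].reset_index(drop=True))
        est1 = dasymetric_binary(sz, mask1).df.set_index("tz_id")["pop"]
        est2 = dasymetric_binary(sz, mask2).df.set_index("tz_id")["pop"]
        assert np.allclose(est1.sort_index(), est2.sort_index(), atol=1e-12)


class TestEstimateToGrid:
    def test_building_in_one_cell(self):
        grid = build_grid((0, 0, 200, 200), 100.0)
        mask = footprint_mask([
            {"building_id": "b", "geometry": box(10, 110, 30, 130), "floors": 1,
             "land_use": "R"}
        ])
        est = dasymetric_binary(sz_one(50.0, 200.0), mask)
        on_grid = estimate_to_grid(est, grid)
        assert on_grid.df["pop"].iloc[0] == pytest.approx(50.0)
        assert on_grid.total() == pytest.approx(50.0)

    def test_split_building(self):
        grid = build_grid((0, 0, 200, 100), 100.0)
        mask = footprint_mask([
            {"building_id": "b", "geometry": box(90, 40, 110, 60), "floors": 1,
             "land_use": "R"}
        ])
        est = dasymetric_binary(sz_one(10.0, 200.0), mask)
        on_grid = estimate_to_grid(est, grid)
        assert on_grid.df["pop"].tolist() == pytest.approx([5.0, 5.0])

    def test_conservation_random(self):
        rng = np.random.default_rng(12)
        grid = build_grid((0, 0, 400, 400), 100.0)
        sz, b = random_allocation_fixture(rng)
        est = dasymetric_binary(sz, UrbanMask("FOOTPRINT", "AREA", buildings=b))
        on_grid = estimate_to_grid(est, grid)
        assert on_grid.total() == pytest.approx(est.total(), rel=1e-9)


class TestOccupancySearch:
    def test_grid_step_enumerates_121_pairs(self, small_city, small_ctx):
        occ, table = search_occupancy_weights(
            small_ctx.sz,
            {"AREA": small_city.mask("VHR_LU"),
             "VOLUME": small_city.mask("3D_VHR_LU")},
            {"L1": small_ctx.vz_l1, "L0": small_ctx.vz_l0},
            grid_step=0.1,
        )
        assert table[["w_C", "w_O"]].drop_duplicates().shape[0] == 121
        assert {"nrmse_L1", "rtae_L0", "oe_L0", "ue_L0"} <= set(table.columns)

    def test_all_residential_city_ties_to_highest(self):
        cfg_kwargs = dict(width=1200.0, height=1200.0, n_l2=2, n_l1_per_l2=2,
                          blocks_per_l1=2, seed=3,
                          p_mix=(1.0, 0.0, 0.0), p_empty_block=0.0)
        from popdis import CityConfig, ExperimentContext, generate_city

        city = generate_city(CityConfig(**cfg_kwargs))
        ctx = ExperimentContext(city)
        occ, table = search_occupancy_weights(
            ctx.sz,
            {"AREA": city.mask("VHR_LU"), "VOLUME": city.mask("3D_VHR_LU")},
            {"L1": ctx.vz_l1, "L0": ctx.vz_l0},
            grid_step=0.5,
        )
        assert (occ.w_C, occ.w_O) == (1.0, 1.0)

    def test_invalid_step_rejected(self, small_city, small_ctx):
        with pytest.raises(InvalidInputError):
            search_occupancy_weights(
                small_ctx.sz, {"AREA": small_city.mask("VHR_LU")},
                {"L0": small_ctx.vz_l0}, grid_step=0.3,
            )
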