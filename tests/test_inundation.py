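import numpy as np
import pytest

from mangrove_slr.errors import NoContourError, OutOfRangeError
from mangrove_slr.inundation import (SeaLevelContext, build_accretion_field,
                                     future_sea_level, inundation_mask,
                                     loss_summary, results_table,
                                     scenario_matrix, select_h0_contour)
from mangrove_slr.raster import GridTransform, Raster
from mangrove_slr.scenarios import QUANTILES, builtin_scenario_table
from mangrove_slr.synthetic_site import SiteConfig, make_dem, \
    make_mangrove_mask

T30 = GridTransform(0.0, 3000.0, 30.0)


def _ramp_site(rows=60, cols=40, emin=-1.0, emax=3.0, msl=0.4, mhws=1.2):
    cfg = SiteConfig(grid_rows=rows, grid_cols=cols, creek_count=0,
                     noise_sd=0.0, elevation_range=(emin, emax),
                     msl_height=msl, mhws_height=mhws)
    dem = make_dem(cfg)
    mask = make_mangrove_mask(dem, msl, mhws)
    return cfg, dem, mask


class TestSelectH0Contour:
    def test_recovers_generator_msl(self, default_fixture):
        fx = default_fixture
        h0, contour = select_h0_contour(fx.dem, fx.mangrove_mask, 0.1)
        assert h0 == pytest.approx(fx.config.msl_height, abs=1e-9)
        assert len(contour) > 0

    def test_flat_dem_has_no_contour(self):
        dem = Raster(np.full((20, 20), 1.0), T30)
        mask = dem.like(np.ones((20, 20), dtype=bool))
        with pytest.raises(NoContourError):
            select_h0_contour(dem, mask, 0.1)

    def test_coarse_interval_returns_nearest_level(self):
        _, dem, mask = _ramp_site()
        h0, _ = select_h0_contour(dem, mask, contour_interval=1.0)
        # nearest whole-metre contour to the 0.4 m seaward boundary
        assert h0 in (0.0, 1.0)


class TestFutureSeaLevel:
    def test_reduces_to_scenario_level(self):
        ctx = SeaLevelContext(h0=0.0, delta_h_2000_2018=0.0,
                              accretion_reference_year=2018)
        table = builtin_scenario_table()
        h = future_sea_level(ctx, table, "RCP2.6", 2100, "mean", va=0.0)
        assert h == pytest.approx(0.65)

    def test_accretion_exactly_balancing_rise(self):
        ctx = SeaLevelContext(h0=0.4, delta_h_2000_2018=0.0,
                              accretion_reference_year=2018)
        table = builtin_scenario_table()
        # 65 cm over 82 years needs va = 65/82 cm/yr to cancel
        h = future_sea_level(ctx, table, "RCP2.6", 2100, "mean", va=65.0 / 82)
        assert h == pytest.approx(ctx.h0)

    def test_hand_arithmetic(self):
        ctx = SeaLevelContext(h0=0.40, delta_h_2000_2018=8.28,
                              accretion_reference_year=2018)
        table = builtin_scenario_table()
        h = future_sea_level(ctx, table, "RCP2.6", 2100, "mean", va=0.53)
        assert h == pytest.approx(0.40 - 0.0828 + 0.65 - 0.0053 * 82,
                                  abs=1e-12)
        assert h == pytest.approx(0.5326, abs=1e-12)

    def test_year_before_reference_rejected(self):
        ctx = SeaLevelContext(h0=0.4, accretion_reference_year=2060)
        with pytest.raises(OutOfRangeError):
            future_sea_level(ctx, builtin_scenario_table(), "RCP2.6", 2050)


class TestAccretionField:
    def test_single_station_uniform(self):
        _, dem, mask = _ramp_site()
        field = build_accretion_field({"HG": 0.53}, [("HG", 30, 20)], mask)
        inside = field.va.data[mask.data]
        assert (inside == 0.53).all()

    def test_two_stations_split_at_bisector(self):
        mask = Raster(np.ones((20, 21), dtype=bool), T30)
        field = build_accretion_field({"A": 0.4, "B": 0.6},
                                      [("A", 10, 0), ("B", 10, 20)], mask)
        assert (field.va.data[:, :10] == 0.4).all()
        assert (field.va.data[:, 11:] == 0.6).all()

    def test_four_stations_match_per_cell_loop(self, rng):
        mask = Raster(rng.random((30, 30)) < 0.7, T30)
        sites = [("A", 3, 4), ("B", 25, 5), ("C", 6, 27), ("D", 22, 22)]
        rates = {"A": 0.41, "B": 0.64, "C": 0.53, "D": 0.40}
        field = build_accretion_field(rates, sites, mask)
        for r in range(30):
            for c in range(30):
                if not mask.data[r, c]:
                    assert np.isnan(field.va.data[r, c])
                    continue
                dists = [np.hypot(r - sr, c - sc) for _, sr, sc in sites]
                nearest = sites[int(np.argmin(dists))][0]
                assert field.va.data[r, c] == rates[nearest]


class TestInundationMask:
    def test_level_below_everything_loses_nothing(self):
        _, dem, mask = _ramp_site()
        lost = inundation_mask(dem, mask, h_future=-5.0)
        assert not lost.data.any()

    def test_level_above_everything_loses_whole_mask(self):
        _, dem, mask = _ramp_site()
        lost = inundation_mask(dem, mask, h_future=99.0)
        np.testing.assert_array_equal(lost.data, mask.data)

    def test_matches_per_cell_oracle(self, rng):
        for _ in range(5):
            dem = Raster(rng.uniform(-1, 3, size=(40, 40)), T30)
            mask = dem.like(rng.random((40, 40)) < 0.5)
            h = rng.uniform(-0.5, 2.5)
            lost = inundation_mask(dem, mask, h)
            for r in range(40):
                for c in range(40):
                    expected = mask.data[r, c] and dem.data[r, c] < h
                    assert lost.data[r, c] == expected

    def test_sea_connected_is_subset(self, default_fixture):
        fx = default_fixture
        h = 0.9
        off = inundation_mask(fx.dem, fx.mangrove_mask, h)
        conn = inundation_mask(fx.dem, fx.mangrove_mask, h,
                               connectivity="sea-connected")
        assert not (conn.data & ~off.data).any()

    def test_strict_inequality_at_level(self):
        dem = Raster(np.full((4, 4), 1.0), T30)
        mask = dem.like(np.ones((4, 4), dtype=bool))
        assert not inundation_mask(dem, mask, 1.0).data.any()


class TestLossSummary:
    def test_published_percentage_arithmetic(self):
        # 489 of 1841 hm²: percentage follows from cell accounting alone
        cell = 100.0  # 1 hm² cells
        lost = Raster(np.zeros((50, 50), dtype=bool), GridTransform(0, 5000, cell))
        total = lost.like(np.zeros((50, 50), dtype=bool))
        lost.data.flat[:489] = True
        total.data.flat[:1841] = True
        lost_hm2, pct, total_hm2 = loss_summary(lost, total)
        assert (lost_hm2, total_hm2) == (489.0, 1841.0)
        assert round(pct, 2) == 26.56

    def test_zero_loss(self):
        _, dem, mask = _ramp_site()
        lost = dem.like(np.zeros(dem.shape, dtype=bool))
        lost_hm2, pct, _ = loss_summary(lost, mask)
        assert lost_hm2 == 0.0 and pct == 0.0

    def test_unit_conversion_30m_cells(self):
        mask = Raster(np.ones((10, 10), dtype=bool), T30)
        lost = mask.like(np.zeros((10, 10), dtype=bool))
        lost.data.flat[:100] = True
        lost_hm2, _, _ = loss_summary(lost, mask)
        assert lost_hm2 == pytest.approx(9.0)

    def test_conservation(self, default_fixture):
        fx = default_fixture
        lost = inundation_mask(fx.dem, fx.mangrove_mask, 0.8)
        surviving = fx.mangrove_mask.like(fx.mangrove_mask.data
                                          & ~lost.data)
        la, _, total = loss_summary(lost, fx.mangrove_mask)
        sa, _, _ = loss_summary(surviving, fx.mangrove_mask)
        assert la + sa == pytest.approx(total, abs=1e-9)


@pytest.fixture(scope="module")
def matrix_setup():
    cfg, dem, mask = _ramp_site(rows=100, cols=50)
    field = build_accretion_field({"HG": 0.53, "SJ": 0.40},
                                  [("HG", 20, 10), ("SJ", 20, 40)], mask)
    ctx = SeaLevelContext(h0=cfg.msl_height, delta_h_2000_2018=8.28,
                          accretion_reference_year=2018)
    return ctx, builtin_scenario_table(), field, dem, mask


class TestScenarioMatrix:
    def test_consistent_with_direct_calls(self, matrix_setup):
        ctx, table, field, dem, mask = matrix_setup
        results = scenario_matrix(ctx, table, field, dem, mask,
                                  scenarios=["RCP8.5"], years=[2100],
                                  quantiles=["mean"])
        res = results[0]
        h_cell = future_sea_level(ctx, table, "RCP8.5", 2100, "mean",
                                  va=np.nan_to_num(field.va.data, nan=0.0))
        lost = inundation_mask(dem, mask, h_cell)
        la, lp, total = loss_summary(lost, mask)
        assert res.lost_area_hm2["mean"] == pytest.approx(la)
        assert res.lost_pct["mean"] == pytest.approx(lp)
        assert res.total_area_hm2 == pytest.approx(total)

    def test_ordered_quantiles_give_ordered_losses(self, matrix_setup):
        ctx, table, field, dem, mask = matrix_setup
        for res in scenario_matrix(ctx, table, field, dem, mask):
            areas = [res.lost_area_hm2[q] for q in QUANTILES]
            assert areas == sorted(areas)
            hs = [res.h_future_m[q] for q in QUANTILES]
            assert hs == sorted(hs)

    def test_ramp_loss_matches_strip_hypsometry(self):
        """On a pure ramp the lost area is a closed-form strip count."""
        cfg, dem, mask = _ramp_site(rows=100, cols=50)
        field = build_accretion_field({"U": 0.0}, [("U", 50, 25)], mask)
        ctx = SeaLevelContext(h0=cfg.msl_height, delta_h_2000_2018=0.0,
                              accretion_reference_year=2018)
        table = builtin_scenario_table()
        res = scenario_matrix(ctx, table, field, dem, mask,
                              scenarios=["RCP2.6"], years=[2100],
                              quantiles=["mean"])[0]
        h = cfg.msl_height + 0.65
        elev_rows = np.linspace(*cfg.elevation_range, 100)  # 1-D ramp profile
        n_rows = ((elev_rows >= cfg.msl_height)
                  & (elev_rows <= cfg.mhws_height)
                  & (elev_rows < h)).sum()
        expected = n_rows * 50 * cfg.cell_size ** 2 / 1e4
        assert res.lost_area_hm2["mean"] == pytest.approx(expected)

    def test_eq3_cancellation_zero_terms_zero_loss(self):
        """With all rise terms and accretion zero, H = h0 and the mask
        (which sits at or above MSL) is untouched."""
        cfg, dem, mask = _ramp_site()
        field = build_accretion_field({"U": 0.0}, [("U", 30, 20)], mask)
        ctx = SeaLevelContext(h0=cfg.msl_height, delta_h_2000_2018=0.0,
                              accretion_reference_year=2018)
        table = builtin_scenario_table()
        zero = table.entries.copy()
        zero["level_cm"] = 0.0
        from mangrove_slr.scenarios import ScenarioTable
        res = scenario_matrix(ctx, ScenarioTable(zero), field, dem, mask,
                              scenarios=["RCP2.6"], years=[2100],
                              quantiles=["mean"])[0]
        assert res.lost_area_hm2["mean"] == 0.0

    def test_more_accretion_never_increases_loss(self, matrix_setup):
        ctx, table, _, dem, mask = matrix_setup
        losses = []
        for va in (0.0, 0.3, 0.6):
            f = build_accretion_field({"U": va}, [("U", 50, 25)], mask)
            res = scenario_matrix(ctx, table, f, dem, mask,
                                  scenarios=["RCP8.5"], years=[2100],
                                  quantiles=["mean"])[0]
            losses.append(res.lost_area_hm2["mean"])
        assert losses[0] >= losses[1] >= losses[2]

    def test_results_table_shape(self, matrix_setup):
        ctx, table, field, dem, mask = matrix_setup
        results = scenario_matrix(ctx, table, field, dem, mask)
        df = results_table(results)
        assert len(df) == 3 * 3 * 5  # scenarios × years × quantiles
        assert {"scenario", "year", "quantile", "h_future_m",
                "lost_area_hm2", "lost_pct"} <= set(df.columns)
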