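import numpy as np
import pytest

from geolca import EdgeParams, FragTable, Grid, IntensificationResponse, derive_terrain
from geolca.impacts import (
    biodiversity_damage,
    blue_water,
    carbon_change,
    carbon_stock,
    intensification_inputs,
    msa_map,
    nitrogen_export,
    sediment_export,
    usle,
)

from conftest import make_table, plane_dem


def one_ha(vals):
    return Grid(np.asarray(vals, dtype=float), cell_size=100.0)


class TestCarbon:
    def test_stock_is_class_density(self):
        table = make_table([dict(code=1, name="agriculture", is_agriculture=True,
                                 kc=1.0, n_load=0.0, carbon_density=100.0)])
        stock = carbon_stock(one_ha([[1.0]]), table)
        assert stock.values[0, 0] == 100.0

    def test_ninety_tonnes_carbon_is_330_co2e(self):
        before, after = one_ha([[100.0]]), one_ha([[10.0]])
        cc = carbon_change(before, after, amortization_years=20.0)
        assert cc["tonnes_c"] == pytest.approx(90.0)
        assert cc["tonnes_co2e"] == pytest.approx(330.0)
        assert cc["tonnes_co2e_per_year"] == pytest.approx(16.5)

    def test_no_change_is_zero(self):
        g = one_ha([[50.0, 60.0]])
        assert carbon_change(g, g)["tonnes_co2e"] == 0.0

    def test_edge_depression_monotone_and_bounded(self):
        table = make_table([
            dict(code=1, name="agriculture", is_agriculture=True, kc=1.0,
                 n_load=0.0, carbon_density=0.0),
            dict(code=2, name="forest", is_natural=True, carbon_density=300.0),
        ])
        # a wide forest slab beside agriculture: depth increases with column
        lulc = one_ha(np.where(np.arange(30) < 1, 1.0, 2.0) * np.ones((5, 30)))
        edge = EdgeParams(enabled=True, interior_fraction_at_edge=0.6, e_fold_distance=300.0)
        stock = carbon_stock(lulc, table, edge)
        profile = stock.values[2, 1:]
        assert (np.diff(profile) >= -1e-9).all()  # non-decreasing with depth
        assert (profile <= 300.0 + 1e-9).all()
        assert profile[0] < 0.75 * 300.0  # clearly depressed at the edge
        assert profile[-1] > 0.97 * 300.0  # asymptotes to interior density


@pytest.fixture
def routing_table():
    # code 1 ag, 2 buffer-a (ret 0.5/0.3), 3 buffer-b (ret 0.4/0.3), 4 bare
    return make_table([
        dict(code=1, name="agriculture", is_agriculture=True, kc=1.25, n_load=20.0,
             usle_c=0.2, usle_p=1.0, msa_lu=0.3),
        dict(code=2, name="bufa", is_natural=True, convertible=True,
             sed_retention_eff=0.5, n_retention_eff=0.3),
        dict(code=3, name="bufb", is_natural=True, convertible=True,
             sed_retention_eff=0.4, n_retention_eff=0.3),
        dict(code=4, name="bare"),
    ])


def column_terrain(nrows=5, ncols=3):
    """Plane dipping south; bottom row is the stream."""
    dem = plane_dem(nrows, ncols)
    return derive_terrain(dem, stream_threshold=nrows)


class TestUsle:
    def test_factor_product(self, routing_table):
        r, k, ls = one_ha([[100.0]]), one_ha([[0.3]]), one_ha([[1.2]])
        out = usle(r, k, ls, one_ha([[1.0]]), routing_table)
        assert out.values[0, 0] == pytest.approx(7.2)

    def test_zero_cover_factor_gives_zero(self, routing_table):
        r = k = ls = one_ha([[1.0]])
        out = usle(r, k, ls, one_ha([[4.0]]), routing_table)  # bare: usle_c 0
        assert out.values[0, 0] == 0.0


class TestSedimentExport:
    def test_cell_adjacent_to_stream_exports_everything(self, routing_table):
        terrain = column_terrain()
        lulc = one_ha(np.full((5, 3), 2.0))
        usle_grid = one_ha(np.zeros((5, 3)))
        usle_grid.values[3, 1] = 10.0  # one row above the stream
        _, total = sediment_export(usle_grid, terrain, lulc, routing_table)
        assert total == pytest.approx(10.0)

    def test_known_retention_chain(self, routing_table):
        # path of (1,1): cells (2,1) ret 0.5 and (3,1) ret 0.4 -> 10*0.5*0.6 = 3
        terrain = column_terrain()
        lulc_vals = np.full((5, 3), 4.0)
        lulc_vals[2, :] = 2.0
        lulc_vals[3, :] = 3.0
        usle_grid = one_ha(np.zeros((5, 3)))
        usle_grid.values[1, 1] = 10.0
        _, total = sediment_export(usle_grid, terrain, one_ha(lulc_vals), routing_table)
        assert total == pytest.approx(3.0)

    def test_full_retention_absorbs_everything(self, routing_table):
        table = make_table([
            dict(code=2, name="sink", is_natural=True, sed_retention_eff=1.0),
        ])
        terrain = column_terrain()
        lulc = one_ha(np.full((5, 3), 2.0))
        usle_grid = one_ha(np.zeros((5, 3)))
        usle_grid.values[0, 1] = 10.0
        _, total = sediment_export(usle_grid, terrain, lulc, table)
        assert total == pytest.approx(0.0)

    def test_export_never_exceeds_gross_erosion(self, routing_table):
        rng = np.random.default_rng(8)
        for trial in range(10):
            dem = Grid(rng.normal(0, 2, (12, 12)) + plane_dem(12, 12, drop=0.6).values,
                       cell_size=100.0)
            terrain = derive_terrain(dem, stream_threshold=20)
            lulc = one_ha(rng.choice([1.0, 2.0, 3.0, 4.0], (12, 12)))
            usle_grid = one_ha(rng.uniform(0, 5, (12, 12)))
            _, total = sediment_export(usle_grid, terrain, lulc, routing_table)
            assert total <= usle_grid.values.sum() * 1.0 + 1e-9


class TestNitrogenExport:
    def test_zero_load_zero_export(self, routing_table):
        table = make_table([dict(code=4, name="bare")])
        terrain = column_terrain()
        _, total = nitrogen_export(one_ha(np.full((5, 3), 4.0)), table, terrain)
        assert total == 0.0

    def test_known_retention_chain(self, routing_table):
        # ag cell at (1,1) loads 20 kg/ha; two downslope cells retain 0.3 each
        terrain = column_terrain()
        lulc_vals = np.full((5, 3), 4.0)
        lulc_vals[1, 1] = 1.0
        lulc_vals[2, :] = 2.0
        lulc_vals[3, :] = 3.0
        _, total = nitrogen_export(one_ha(lulc_vals), routing_table, terrain)
        assert total == pytest.approx(20.0 * 0.7 * 0.7)

    def test_added_load_with_empty_path_is_additive(self, routing_table):
        terrain = column_terrain()
        lulc = one_ha(np.full((5, 3), 4.0))  # zero baseline load
        added = one_ha(np.zeros((5, 3)))
        added.values[3, 1] = 5.0  # adjacent to stream: empty path
        _, base = nitrogen_export(lulc, routing_table, terrain)
        _, with_add = nitrogen_export(lulc, routing_table, terrain, added_load=added)
        assert with_add - base == pytest.approx(5.0)

    def test_linear_superposition_in_loads(self, routing_table):
        terrain = column_terrain(6, 4)
        rng = np.random.default_rng(3)
        lulc = one_ha(rng.choice([2.0, 3.0], (6, 4)))
        a = one_ha(rng.uniform(0, 10, (6, 4)))
        b = one_ha(rng.uniform(0, 10, (6, 4)))
        _, base = nitrogen_export(lulc, routing_table, terrain)
        _, ea = nitrogen_export(lulc, routing_table, terrain, added_load=a)
        _, eb = nitrogen_export(lulc, routing_table, terrain, added_load=b)
        _, eab = nitrogen_export(lulc, routing_table, terrain,
                                 added_load=a.like(a.values + b.values))
        assert eab - base == pytest.approx((ea - base) + (eb - base), rel=1e-9)

    def test_negative_added_load_rejected(self, routing_table):
        terrain = column_terrain()
        with pytest.raises(ValueError, match="non-negative"):
            nitrogen_export(one_ha(np.full((5, 3), 4.0)), routing_table, terrain,
                            added_load=one_ha(np.full((5, 3), -1.0)))


class TestIntensificationInputs:
    def test_known_linear_response(self):
        resp = IntensificationResponse(slope_n=10.0, leach_fraction=0.25, slope_w=30.0)
        inc = one_ha([[2.0]])
        out = intensification_inputs(inc, resp)
        assert out["added_n_application"].values[0, 0] == pytest.approx(20.0)
        assert out["added_n_load"].values[0, 0] == pytest.approx(5.0)
        assert out["added_irrigation"].values[0, 0] == pytest.approx(60.0)

    def test_zero_increment_zero_additions(self):
        out = intensification_inputs(one_ha([[0.0]]), IntensificationResponse())
        assert all(g.values.sum() == 0.0 for g in out.values())

    def test_doubling_increment_doubles_additions(self):
        resp = IntensificationResponse()
        a = intensification_inputs(one_ha([[1.5]]), resp)
        b = intensification_inputs(one_ha([[3.0]]), resp)
        for key in a:
            assert b[key].values[0, 0] == pytest.approx(2 * a[key].values[0, 0])


class TestBlueWater:
    def test_deficit_micro_oracle(self, routing_table):
        # (1.25 * 480 - 300) mm over 1 ha -> 3,000 m3
        lulc = one_ha([[1.0]])
        _, total = blue_water(lulc, routing_table, one_ha([[480.0]]), one_ha([[300.0]]),
                              np.ones((1, 1), bool))
        assert total == pytest.approx(3000.0)

    def test_sufficient_rain_means_no_irrigation(self, routing_table):
        lulc = one_ha([[1.0]])
        _, total = blue_water(lulc, routing_table, one_ha([[480.0]]), one_ha([[700.0]]),
                              np.ones((1, 1), bool))
        assert total == 0.0

    def test_non_irrigated_cell_consumes_nothing(self, routing_table):
        lulc = one_ha([[1.0]])
        _, total = blue_water(lulc, routing_table, one_ha([[480.0]]), one_ha([[300.0]]),
                              np.zeros((1, 1), bool))
        assert total == 0.0


class TestMsa:
    TABLE = make_table([
        dict(code=1, name="agriculture", is_agriculture=True, kc=1.0, n_load=0.0, msa_lu=0.3),
        dict(code=2, name="forest", is_natural=True, convertible=True, msa_lu=1.0),
    ])

    def test_huge_patch_keeps_full_msa(self):
        frag = FragTable(thresholds=(10.0,), multipliers=(0.5,))
        lulc = one_ha(np.full((10, 10), 2.0))  # one 100-ha patch
        msa = msa_map(lulc, self.TABLE, frag)
        np.testing.assert_allclose(msa.values, 1.0)

    def test_cropland_has_no_fragmentation_term(self):
        frag = FragTable(thresholds=(1e6,), multipliers=(0.5,))
        msa = msa_map(one_ha([[1.0]]), self.TABLE, frag)
        assert msa.values[0, 0] == pytest.approx(0.3)

    def test_small_patch_takes_smallest_multiplier(self):
        frag = FragTable(thresholds=(10.0, 100.0), multipliers=(0.5, 0.8))
        vals = np.full((5, 5), 1.0)
        vals[2, 2] = 2.0  # isolated 1-ha forest patch
        msa = msa_map(one_ha(vals), self.TABLE, frag)
        assert msa.values[2, 2] == pytest.approx(0.5)

    def test_bisecting_a_patch_damages_adjacent_land(self):
        """Converting one cell splits a 21-ha strip into two 10-ha patches."""
        frag = FragTable(thresholds=(10.0,), multipliers=(0.5,))
        before = np.full((3, 23), 1.0)
        before[1, 1:22] = 2.0  # 21-cell forest strip, multiplier 1.0
        after = before.copy()
        after[1, 11] = 1.0  # bisect: two 10-ha patches, multiplier 0.5
        m0 = msa_map(one_ha(before), self.TABLE, frag)
        m1 = msa_map(one_ha(after), self.TABLE, frag)
        damage = biodiversity_damage(m0, m1)
        converted_loss = 1.0 - 0.3
        adjacent_loss = 20 * (1.0 - 0.5)  # hand-computed multiplier drop
        assert damage == pytest.approx(converted_loss + adjacent_loss)
        assert damage > converted_loss  # strictly exceeds on-site loss

    def test_identical_landscapes_no_damage(self):
        m = msa_map(one_ha(np.full((4, 4), 2.0)), self.TABLE, None)
        assert biodiversity_damage(m, m) == 0.0

    def test_simple_conversion_damage(self):
        # 10 ha from MSA 1.0 to 0.3, no fragmentation terms -> 7.0 MSA-ha
        before = one_ha(np.full((2, 5), 2.0))
        after = one_ha(np.full((2, 5), 1.0))
        m0 = msa_map(before, self.TABLE, None)
        m1 = msa_map(after, self.TABLE, None)
        assert biodiversity_damage(m0, m1) == pytest.approx(7.0)

    def test_msa_always_in_unit_interval(self, landscape_small):
        msa = msa_map(landscape_small.lulc, landscape_small.class_table, FragTable())
        vals = msa.values[np.isfinite(msa.values)]
        assert vals.min() >= 0.0 and vals.max() <= 1.0


class TestBufferingProperty:
    def test_converting_riparian_buffer_raises_export_more(self, routing_table):
        """Removing the buffer below a high-erosion cell beats converting an
        equal-area, equal-erosion cell with no buffering role."""
        terrain = column_terrain(5, 5)
        # column 1: ag source over buffer cells; column 3: bare over buffers
        base = np.full((5, 5), 4.0)
        base[1, 1] = 1.0  # high-USLE agriculture source
        base[2, 1] = 2.0  # its riparian buffer (ret 0.5)
        base[2, 3] = 2.0  # equal cell, but nothing erodes upslope of it
        lulc_a = base.copy()
        lulc_a[2, 1] = 1.0  # convert the buffering cell
        lulc_b = base.copy()
        lulc_b[2, 3] = 1.0  # convert the non-buffering cell
        r = one_ha(np.full((5, 5), 100.0))
        k = one_ha(np.full((5, 5), 0.3))
        ls = one_ha(np.full((5, 5), 1.0))
        totals = {}
        for label, vals in (("buffer", lulc_a), ("plain", lulc_b)):
            lulc = one_ha(vals)
            _, totals[label] = sediment_export(
                usle(r, k, ls, lulc, routing_table), terrain, lulc, routing_table)
        assert totals["buffer"] > totals["plain"]
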