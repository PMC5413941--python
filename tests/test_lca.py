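import numpy as np
import pytest

from geolca import (
    ConversionChain,
    DemandScenario,
    FragTable,
    Grid,
    ImpactModelConfig,
    LandscapeBundle,
    ParamRange,
    StandardFactors,
    allocate_expansion,
    luci_lca,
    proximity_allocate,
    relative_difference,
    sensitivity_envelope,
    standard_lca,
    validate_against_observed,
)
from geolca.demand import SupplyPartition, crop_demand
from geolca.lca import CATEGORIES, apply_change, matched_standard_factors
from geolca.terrain import derive_terrain

from conftest import make_table, plane_dem

UNIT_CHAIN = ConversionChain(1.0, 1.0, 3.0)  # 3 t crop per t HDPE, exact in floats


def flat_table():
    """Two-class table with retention and fragmentation effects off."""
    return make_table([
        dict(code=1, name="agriculture", is_agriculture=True, kc=1.2, n_load=30.0,
             usle_c=0.2, usle_p=1.0, msa_lu=0.3, carbon_density=55.0),
        dict(code=4, name="grassland", is_natural=True, convertible=True,
             carbon_density=90.0, usle_c=0.02, n_load=4.0, msa_lu=0.7),
        dict(code=2, name="forest", is_natural=True, convertible=True,
             carbon_density=280.0, usle_c=0.003, n_load=1.5, msa_lu=1.0),
    ])


def uniform_bundle(nrows=20, ncols=20, lulc_vals=None, yield_t_ha=8.0):
    """Homogeneous landscape: uniform soils, climate, yields, planar terrain."""
    geo = dict(cell_size=100.0, origin=(0.0, 0.0))
    shape = (nrows, ncols)
    if lulc_vals is None:
        lulc_vals = np.full(shape, 4.0)
    const = lambda v: Grid(np.full(shape, float(v)), **geo)
    return LandscapeBundle(
        lulc=Grid(np.asarray(lulc_vals, dtype=float), **geo),
        dem=Grid(plane_dem(nrows, ncols).values, **geo),
        ph=const(6.5), silt=const(30.0), clay=const(20.0), som=const(3.0),
        precip=const(800.0), et0=const(1000.0),
        yield_current=const(yield_t_ha), yield_attainable=const(yield_t_ha),
        class_table=flat_table(),
    )


def expansion_only_partition(bundle, demand):
    zeros = bundle.yield_current.like(np.zeros(bundle.yield_current.shape))
    return SupplyPartition(demand, 0.0, demand, zeros)


def trivial_config(**kw):
    return ImpactModelConfig(frag=FragTable((1.0,), (1.0,)), **kw)


class TestStandardBranch:
    def test_per_tonne_volume_invariant_to_machine_precision(self):
        factors = StandardFactors()
        results = [standard_lca(DemandScenario(v), factors)
                   for v in (23_000.0, 86_000.0, 321_000.0)]
        for res in results:
            res.check()
            assert res.per_tonne == results[0].per_tonne  # bit-identical

    def test_luc_gwp_arithmetic(self):
        # 10.81 t CO2e/ha/yr at 0.2 ha*yr/t crop -> 2.162 t CO2e per t crop
        factors = StandardFactors(luc_gwp_factor=10.81, land_occupation=0.2,
                                  non_ag_stage_impacts={})
        res = standard_lca(DemandScenario(1.0, chain=ConversionChain(1.0, 1.0, 1.0)), factors)
        assert res.per_tonne["gwp"] == pytest.approx(2.162)

    def test_biodiversity_occupation_arithmetic(self):
        factors = StandardFactors(pnv_msa=1.0, current_msa=0.3, land_occupation=0.5,
                                  non_ag_stage_impacts={})
        res = standard_lca(DemandScenario(1.0, chain=ConversionChain(1.0, 1.0, 1.0)), factors)
        assert res.per_tonne["biodiversity"] == pytest.approx(0.35)


class TestRelativeDifference:
    @pytest.mark.parametrize("a,b,expected", [(1.0, 1.0, 0.0), (1.4, 1.0, 40.0), (0.5, 1.0, -50.0)])
    def test_signed_percent(self, a, b, expected):
        assert relative_difference(a, b) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            relative_difference(1.0, 0.0)


class TestDegeneracyBridge:
    def test_homogeneous_landscape_brings_branches_together(self):
        """With zero spatial heterogeneity and matched factors, the linear
        and spatial branches must agree: their difference is purely spatial."""
        bundle = uniform_bundle()
        config = trivial_config()
        terrain = derive_terrain(bundle.dem, stream_threshold=10_000)
        # convert exactly 30 cells: 30 cells * 8 t/ha * 1 ha = 240 t crop
        hdpe = 80.0  # 240 t crop via the 3 t/t chain
        scenario = DemandScenario(hdpe, chain=UNIT_CHAIN, closure_fraction=0.0)
        demand = crop_demand(scenario)
        suit = bundle.lulc.like(np.full(bundle.lulc.shape, 0.5))
        change = allocate_expansion(suit, bundle.lulc, bundle.class_table,
                                    bundle.yield_current, demand)
        assert change.total_production == pytest.approx(demand)
        luci = luci_lca(change, expansion_only_partition(bundle, demand),
                        bundle, scenario, config, terrain=terrain)
        factors = matched_standard_factors(bundle, "grassland", config, terrain=terrain)
        std = standard_lca(scenario, factors)
        for k in CATEGORIES:
            assert luci.per_tonne[k] == pytest.approx(std.per_tonne[k], rel=1e-6), k

    def test_heterogeneous_carbon_makes_gwp_rise_with_volume(self):
        """When later-converted cells are forest, per-tonne GWP grows with scale."""
        lulc_vals = np.full((20, 20), 2.0)  # forest
        lulc_vals[:5, :] = 4.0  # grassland ranks first in suitability below
        bundle = uniform_bundle(lulc_vals=lulc_vals)
        config = trivial_config()
        terrain = derive_terrain(bundle.dem, stream_threshold=10_000)
        suit = bundle.lulc.like(
            -np.arange(400, dtype=float).reshape(20, 20))  # row-major descending
        per_tonne = []
        for hdpe in (100.0, 400.0, 800.0):
            scenario = DemandScenario(hdpe, chain=UNIT_CHAIN, closure_fraction=0.0)
            demand = crop_demand(scenario)
            change = allocate_expansion(suit, bundle.lulc, bundle.class_table,
                                        bundle.yield_current, demand)
            res = luci_lca(change, expansion_only_partition(bundle, demand),
                           bundle, scenario, config, terrain=terrain)
            per_tonne.append(res.per_tonne["gwp"])
        assert per_tonne[0] < per_tonne[1] < per_tonne[2]


class TestSensitivityEnvelope:
    RANGES = [
        ParamRange("a", 0.5, 1.0, 2.0),
        ParamRange("b", -1.0, 0.0, 1.0),
        ParamRange("c", 1.0, 1.5, 3.0),
        ParamRange("d", 0.0, 0.2, 0.4),
    ]

    @staticmethod
    def toy_eval(assign):
        a, b, c, d = assign["a"], assign["b"], assign["c"], assign["d"]
        return {
            "gwp": 2 * a - 3 * b + 0.5 * c + d,
            "water": -a + b + c - 2 * d,
        }

    def test_corners_match_full_enumeration(self):
        low, high, central = sensitivity_envelope(self.RANGES, self.toy_eval,
                                                  categories=("gwp", "water"))
        import itertools

        for cat in ("gwp", "water"):
            corners = []
            for bits in itertools.product((0, 1), repeat=4):
                assign = {r.parameter: (r.low if bit == 0 else r.high)
                          for r, bit in zip(self.RANGES, bits)}
                corners.append(self.toy_eval(assign)[cat])
            assert low[cat] == pytest.approx(min(corners))
            assert high[cat] == pytest.approx(max(corners))
            assert low[cat] <= central[cat] <= high[cat]

    def test_zero_width_ranges_collapse_to_central(self):
        ranges = [ParamRange("a", 1.0, 1.0, 1.0), ParamRange("b", 0.0, 0.0, 0.0),
                  ParamRange("c", 2.0, 2.0, 2.0), ParamRange("d", 0.3, 0.3, 0.3)]
        low, high, central = sensitivity_envelope(ranges, self.toy_eval,
                                                  categories=("gwp", "water"))
        assert low == central == high

    def test_non_bracketing_range_rejected(self):
        with pytest.raises(ValueError):
            ParamRange("a", 2.0, 1.0, 3.0)


class TestValidation:
    @pytest.mark.parametrize("allocator", ["logistic", "proximity"])
    def test_self_consistency_ratio_is_one(self, landscape_small, allocator):
        """A t1 produced by an allocator must be reproduced exactly by the
        same allocator's branch of the validation table."""
        from geolca import fit_suitability, predict_suitability

        bundle = landscape_small
        table = bundle.class_table
        demand = 60_000.0  # t crop
        if allocator == "logistic":
            model = fit_suitability(
                bundle.lulc.like(bundle.ag_mask.astype(float)), bundle.predictors(),
                exclusion_mask=~table.mask(bundle.lulc.values.astype(int), "convertible")
                & ~bundle.ag_mask)
            suit = predict_suitability(model, bundle.predictors())
            change = allocate_expansion(suit, bundle.lulc, table,
                                        bundle.yield_current, demand)
        else:
            change = proximity_allocate(bundle.lulc, table, bundle.yield_current, demand)
        t1 = apply_change(bundle.lulc, change, table)
        df = validate_against_observed(bundle.lulc, t1, bundle, StandardFactors())
        ratios = df[f"ratio_{allocator}"].dropna()
        assert len(ratios) > 0
        np.testing.assert_allclose(ratios.to_numpy(), 1.0, rtol=1e-9)

    def test_empty_change_rejected(self, landscape_small):
        with pytest.raises(ValueError, match="no observed conversion"):
            validate_against_observed(landscape_small.lulc, landscape_small.lulc,
                                      landscape_small, StandardFactors())
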