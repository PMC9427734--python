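import numpy as np
import pandas as pd
import pytest

import woodcarbon as wc
from woodcarbon.synthetic import (ParameterSet, population_to_frame,
                                  read_population_csv, write_population_csv)


class TestRegions:
    def test_single_region_covers_world(self):
        rs = wc.generate_regions(1, seed=0)
        assert len(rs) == 1
        assert rs.total_land == pytest.approx(13000.0)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            wc.generate_regions(0, seed=0)

    def test_seed_determinism(self):
        a = wc.generate_regions(12, seed=42)
        b = wc.generate_regions(12, seed=42)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_seeds_differ(self):
        a = wc.generate_regions(12, seed=42)
        b = wc.generate_regions(12, seed=43)
        assert not np.allclose(
            a.to_frame().protection_share, b.to_frame().protection_share)

    def test_protection_within_default_range(self, regions):
        shares = regions.to_frame().protection_share
        assert shares.between(0.1, 0.4).all()

    def test_duplicate_ids_rejected(self):
        r = wc.Region("R01", "a", 10.0, 0.2)
        with pytest.raises(ValueError):
            wc.synthetic.RegionSet((r, r))

    def test_csv_round_trip(self, regions, tmp_path):
        path = tmp_path / "regions.csv"
        regions.write_csv(path)
        back = wc.synthetic.RegionSet.read_csv(path)
        pd.testing.assert_frame_equal(regions.to_frame(), back.to_frame())


class TestPopulation:
    @pytest.mark.parametrize("ssp,anchor", [("SSP1", 92.0), ("SSP2", 80.0),
                                            ("SSP3", 58.0)])
    def test_global_urban_share_2100_hits_anchor(self, regions, ssp, anchor):
        for seed in range(20):
            trajs = wc.generate_population(regions, ssp, seed=seed)
            urban = sum(t.urban[-1] for t in trajs.values())
            total = sum(t.total[-1] for t in trajs.values())
            assert 100 * urban / total == pytest.approx(anchor, abs=1.0)

    def test_unknown_ssp_rejected(self, regions):
        with pytest.raises(ValueError):
            wc.generate_population(regions, "SSP9", seed=0)

    def test_zero_population_region_is_all_zero(self, regions):
        weights = np.full(len(regions), 1.0 / (len(regions) - 1))
        weights[3] = 0.0
        trajs = wc.generate_population(regions, "SSP2", seed=0,
                                       pop_weights=weights)
        rid = regions.ids[3]
        assert not trajs[rid].urban.any()
        assert not trajs[rid].rural.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_trajectory_shape_invariants(self, regions, seed):
        trajs = wc.generate_population(regions, "SSP2", seed=seed)
        for t in trajs.values():
            assert np.all(np.isfinite(t.urban)) and np.all(t.urban >= 0)
            assert np.all(np.isfinite(t.rural)) and np.all(t.rural >= 0)
            assert np.all((t.urban_share >= 0) & (t.urban_share <= 1))
            assert 2020 <= t.peak_year <= 2100
            up_to_peak = t.urban[t.years <= t.peak_year]
            assert np.all(np.diff(up_to_peak) >= -1e-9)
            after_peak = t.urban[t.years >= t.peak_year]
            assert np.allclose(after_peak, after_peak[0])

    def test_seed_determinism(self, regions):
        a = wc.generate_population(regions, "SSP2", seed=7)
        b = wc.generate_population(regions, "SSP2", seed=7)
        for rid in a:
            assert np.array_equal(a[rid].urban, b[rid].urban)
            assert np.array_equal(a[rid].rural, b[rid].rural)

    def test_csv_round_trip(self, regions, tmp_path):
        trajs = wc.generate_population(regions, "SSP2", seed=0)
        path = tmp_path / "population.csv"
        write_population_csv(trajs, path)
        back = read_population_csv(path)
        pd.testing.assert_frame_equal(population_to_frame(trajs),
                                      population_to_frame(back))


class TestParameters:
    def test_pools_close_region_area_balance(self, regions):
        params = wc.generate_parameters(regions, seed=0)
        for region in regions:
            p = params[region.region_id]
            assert p.total_land == pytest.approx(region.total_land,
                                                 rel=1e-9)

    def test_global_anchors(self, regions):
        params = wc.generate_parameters(regions, seed=0)
        assert params.global_pool("plantation") == pytest.approx(137, rel=0.01)
        assert params.global_pool("cropland") == pytest.approx(1595, rel=0.01)
        natural = params.global_pool("primary_forest") \
            + params.global_pool("secondary_forest")
        assert natural == pytest.approx(3629, rel=0.01)

    def test_homogeneity_under_land_scaling(self, regions):
        params = wc.generate_parameters(regions, seed=5)
        doubled = wc.synthetic.RegionSet(tuple(
            wc.Region(r.region_id, r.name, 2 * r.total_land,
                      r.protection_share) for r in regions))
        params2 = wc.generate_parameters(doubled, seed=5)
        for rid in params.regions:
            for pool in ("cropland", "plantation", "primary_forest",
                         "secondary_forest", "pasture", "other_land"):
                assert getattr(params2[rid], pool) == pytest.approx(
                    2 * getattr(params[rid], pool), rel=1e-9)

    def test_seed_determinism(self, regions):
        a = wc.generate_parameters(regions, seed=3)
        b = wc.generate_parameters(regions, seed=3)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError):
            wc.generate_parameters(wc.synthetic.RegionSet(()), seed=0)

    def test_csv_round_trip(self, regions, tmp_path):
        params = wc.generate_parameters(regions, seed=0)
        path = tmp_path / "parameters.csv"
        params.write_csv(path)
        back = ParameterSet.read_csv(path)
        pd.testing.assert_frame_equal(
            params.to_frame().sort_values(["region_id", "parameter"])
            .reset_index(drop=True),
            back.to_frame().sort_values(["region_id", "parameter"])
            .reset_index(drop=True),
            check_exact=False,
        )
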