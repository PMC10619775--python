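import dataclasses

import pytest

from icuaccess.accessibility import (
    compute_access_records,
    facility_ratio,
    block_ratio,
)
from icuaccess.catchment import Facility, build_catchments

from conftest import line_network, point_block_group


def records_by_id(block_groups, facilities, index, variant="sum_of_facility_ratios"):
    recs = compute_access_records(block_groups, facilities, index, variant)
    return {r.blockgroup_id: r for r in recs}


class TestFacilityRatio:
    def test_twenty_beds_per_hundred_thousand_adults(self):
        net = line_network(2, edge_minutes=10.0)
        fac = Facility("F", 0.0, 0.0, 20, "R1")
        bg = point_block_group("bg", 0.0, 0.0, 100_000)
        index = build_catchments(net, [fac], [bg], 60)
        assert facility_ratio(fac, index) == pytest.approx(20.0)

    def test_one_bed_one_adult_extreme(self):
        net = line_network(2, edge_minutes=10.0)
        fac = Facility("F", 0.0, 0.0, 1, "R1")
        bg = point_block_group("bg", 0.0, 0.0, 1)
        index = build_catchments(net, [fac], [bg], 60)
        assert facility_ratio(fac, index) == pytest.approx(100000.0)

    def test_facility_serving_nobody_is_undefined_and_dropped(self, caplog):
        net = line_network(2, edge_minutes=120.0)
        fac = Facility("F", 0.0, 0.0, 10, "R1")
        bg = point_block_group("bg", net.coords(1)[0], 0.0, 1000)
        index = build_catchments(net, [fac], [bg], 60)
        with caplog.at_level("WARNING"):
            assert facility_ratio(fac, index) is None
        assert "serves no populated block group" in caplog.text


class TestToyRegionHandComputation:
    """Hand-derived values for the 3-facility / 5-block-group line region."""

    EXPECTED_DEFAULT = {
        # sum over accessible facilities of 1e5 * beds / served population:
        # F1: 1e5*10/6000, F2: 1e5*5/10000, F3: 1e5*20/7000
        "bg0": 1e5 * 10 / 6000 + 1e5 * 5 / 10000,
        "bg1": 1e5 * 10 / 6000 + 1e5 * 5 / 10000,
        "bg2": 1e5 * 10 / 6000 + 1e5 * 5 / 10000 + 1e5 * 20 / 7000,
        "bg3": 1e5 * 5 / 10000 + 1e5 * 20 / 7000,
    }
    EXPECTED_UNION = {
        # pooled beds over the union of the accessible facilities' catchments
        "bg0": 1e5 * 15 / 10000,
        "bg1": 1e5 * 15 / 10000,
        "bg2": 1e5 * 35 / 10000,
        "bg3": 1e5 * 25 / 10000,
    }

    def test_default_variant_matches_hand_values(self, toy_region):
        net, facs, bgs = toy_region
        index = build_catchments(net, facs, bgs, 60)
        recs = records_by_id(bgs, facs, index)
        assert set(recs) == set(self.EXPECTED_DEFAULT)  # bg4 unpopulated
        for bid, expected in self.EXPECTED_DEFAULT.items():
            assert recs[bid].ratio == pytest.approx(expected)

    def test_union_pool_variant_matches_hand_values(self, toy_region):
        net, facs, bgs = toy_region
        index = build_catchments(net, facs, bgs, 60)
        recs = records_by_id(bgs, facs, index, "union_pool")
        for bid, expected in self.EXPECTED_UNION.items():
            assert recs[bid].ratio == pytest.approx(expected)

    def test_single_facility_makes_variants_coincide(self):
        net = line_network(3, edge_minutes=10.0)
        fac = Facility("F", 0.0, 0.0, 8, "R1")
        bgs = [point_block_group(f"bg{i}", net.coords(i)[0], 0.0, 1000) for i in range(3)]
        index = build_catchments(net, [fac], bgs, 60)
        expected = 1e5 * 8 / 3000
        for variant in ("sum_of_facility_ratios", "union_pool"):
            recs = records_by_id(bgs, [fac], index, variant)
            for r in recs.values():
                assert r.ratio == pytest.approx(expected)

    def test_uncovered_block_group_has_no_ratio(self):
        net = line_network(2, edge_minutes=120.0)
        fac = Facility("F", 0.0, 0.0, 5, "R1")
        bg = point_block_group("bg", net.coords(1)[0], 0.0, 1000)
        index = build_catchments(net, [fac], [bg], 60)
        rec = records_by_id([bg], [fac], index)["bg"]
        assert rec.covered is False and rec.ratio is None

    def test_unknown_variant_rejected(self, toy_region):
        net, facs, bgs = toy_region
        index = build_catchments(net, facs, bgs, 60)
        with pytest.raises(ValueError, match="variant"):
            block_ratio(bgs[0], index, {f.id: f for f in facs}, "bogus")


class TestConservation:
    @pytest.mark.parametrize("seed", range(5))
    def test_population_weighted_ratio_sum_equals_total_beds(self, seed, region_factory):
        """2SFCA identity: sum_j pop_j * ratio_j = 1e5 * total serving beds."""
        region = region_factory(seed)
        index = build_catchments(region.network, region.facilities, region.block_groups, 60)
        recs = compute_access_records(region.block_groups, region.facilities, index)
        pop = {bg.id: bg.pop_total for bg in region.block_groups}
        lhs = sum(pop[r.blockgroup_id] * r.ratio for r in recs if r.covered)
        serving_beds = sum(
            f.adult_icu_beds
            for f in region.facilities
            if index.served_population[f.id] > 0
        )
        assert lhs == pytest.approx(1e5 * serving_beds, rel=1e-9)


class TestRatioProperties:
    def test_adding_beds_never_decreases_any_ratio(self, toy_region):
        net, facs, bgs = toy_region
        index = build_catchments(net, facs, bgs, 60)
        base = records_by_id(bgs, facs, index)
        boosted = [dataclasses.replace(facs[1], adult_icu_beds=facs[1].adult_icu_beds + 7)]
        facs2 = [facs[0], boosted[0], facs[2]]
        index2 = build_catchments(net, facs2, bgs, 60)
        for variant in ("sum_of_facility_ratios", "union_pool"):
            a = records_by_id(bgs, facs, index, variant)
            b = records_by_id(bgs, facs2, index2, variant)
            for bid in a:
                assert b[bid].ratio >= a[bid].ratio - 1e-12

    def test_scaling_populations_inversely_scales_ratios(self, toy_region):
        net, facs, bgs = toy_region
        c = 4
        scaled = [
            dataclasses.replace(bg, pop_total=bg.pop_total * c) for bg in bgs
        ]
        i1 = build_catchments(net, facs, bgs, 60)
        i2 = build_catchments(net, facs, scaled, 60)
        a = records_by_id(bgs, facs, i1)
        b = records_by_id(scaled, facs, i2)
        for bid in a:
            assert b[bid].ratio == pytest.approx(a[bid].ratio / c)
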