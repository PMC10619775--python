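import filecmp

import numpy as np
import pytest
from scipy import stats

from icuaccess.catchment import build_catchments, no_access_set
from icuaccess.synthetic import (
    ConfigurationError,
    RegionConfig,
    RegionParseError,
    generate_region,
    read_region,
    regions_equal,
    write_region,
)

from conftest import group_no_access_pct, small_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"beds_per_facility_range": (0, 5)},
            {"beds_per_facility_range": (6, 3)},
            {"extent_km": -10.0},
            {"n_block_groups": 3, "n_facilities": 5},
            {"disparity_knob": 1.5},
            {"rural_speed_kmh": 0.0},
        ],
    )
    def test_invalid_config_rejected(self, overrides):
        with pytest.raises(ConfigurationError):
            RegionConfig(**overrides).validate()


class TestGeneration:
    def test_deterministic_given_seed(self):
        cfg = small_config(5)
        assert regions_equal(generate_region(cfg), generate_region(cfg))

    def test_different_seeds_differ(self):
        assert not regions_equal(
            generate_region(small_config(1)), generate_region(small_config(2))
        )

    def test_entities_inside_extent_and_beds_in_range(self, region_factory):
        region = region_factory(3)
        cfg = region.config
        lo, hi = cfg.beds_per_facility_range
        for f in region.facilities:
            assert 0 <= f.x_km <= cfg.extent_km and 0 <= f.y_km <= cfg.extent_km
            assert lo <= f.adult_icu_beds <= hi
        for bg in region.block_groups:
            cx, cy = bg.centroid
            assert 0 <= cx <= cfg.extent_km and 0 <= cy <= cfg.extent_km

    def test_per_group_counts_bounded_by_total(self, region_factory):
        region = region_factory(4)
        for bg in region.block_groups:
            for g, n in bg.pop_by_group.items():
                assert 0 <= n <= bg.pop_total

    def test_six_urbanization_classes_present(self, region_factory):
        region = region_factory(0, n_block_groups=400)
        labels = {bg.urbanization for bg in region.block_groups}
        assert len(labels) == 6

    def test_no_facilities_yields_total_no_access(self, region_factory):
        region = region_factory(9, n_facilities=0)
        index = build_catchments(region.network, region.facilities, region.block_groups, 60)
        na = no_access_set(index, region.block_groups)
        populated = {bg.id for bg in region.block_groups if bg.populated}
        assert na == populated

    def test_some_block_groups_beyond_reach_at_default_extent(self, region_factory):
        region = region_factory(2)
        index = build_catchments(region.network, region.facilities, region.block_groups, 60)
        assert len(no_access_set(index, region.block_groups)) > 0


class TestCoverageControl:
    def test_no_access_population_non_decreasing_in_extent(self):
        """Growing the extent at fixed speeds/counts shrinks coverage."""
        prev = -1
        for extent in (150.0, 250.0, 350.0, 450.0):
            region = generate_region(small_config(6, extent_km=extent))
            index = build_catchments(
                region.network, region.facilities, region.block_groups, 60
            )
            na = no_access_set(index, region.block_groups)
            pop = {bg.id: bg.pop_total for bg in region.block_groups}
            na_pop = sum(pop[j] for j in na)
            assert na_pop >= prev
            prev = na_pop


class TestDisparityKnob:
    def test_knob_zero_gives_no_systematic_group_ordering(self):
        """With composition independent of location, minority-vs-white
        no-access comparisons across seeds behave like fair coin flips."""
        wins = 0
        for seed in range(20):
            region = generate_region(small_config(seed, disparity_knob=0.0))
            pct = group_no_access_pct(region)
            minority = (pct["ai_an"] + pct["pacific_islander"]) / 2
            if minority > pct["white"]:
                wins += 1
        assert stats.binomtest(wins, 20, 0.5).pvalue > 0.05

    def test_knob_zero_pooled_rates_within_sampling_error(self):
        """Pooled over seeds, per-group no-access rates coincide up to
        block-group-level sampling noise."""
        pcts = {g: [] for g in ("ai_an", "pacific_islander", "white", "black")}
        for seed in range(20):
            region = generate_region(small_config(seed, disparity_knob=0.0))
            pct = group_no_access_pct(region)
            for g in pcts:
                pcts[g].append(pct[g])
        means = {g: np.mean(v) for g, v in pcts.items()}
        spread = max(means.values()) - min(means.values())
        assert spread < 5.0  # percentage points

    def test_knob_one_concentrates_minorities_far_from_facilities(self):
        region = generate_region(small_config(1, disparity_knob=1.0))
        z = region.truth["z"].to_numpy()
        shares = []
        for bg in region.block_groups:
            if bg.populated:
                m = bg.pop_by_group["ai_an"] + bg.pop_by_group["pacific_islander"]
                shares.append(m / bg.pop_total)
            else:
                shares.append(np.nan)
        shares = np.array(shares)
        ok = ~np.isnan(shares)
        r = stats.spearmanr(z[ok], shares[ok]).statistic
        assert r > 0.5


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, region_factory):
        region = region_factory(8)
        write_region(region, tmp_path)
        assert regions_equal(region, read_region(tmp_path))

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = small_config(12)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_region(generate_region(cfg), d1)
        write_region(generate_region(cfg), d2)
        for key, path in p1.items():
            assert filecmp.cmp(path, d2 / path.name, shallow=False), key

    def test_missing_bed_column_is_parse_error(self, tmp_path, region_factory):
        write_region(region_factory(1), tmp_path)
        fac = tmp_path / "facilities.csv"
        lines = fac.read_text().splitlines()
        header = lines[0].split(",")
        idx = header.index("adult_icu_beds")
        stripped = [
            ",".join(v for i, v in enumerate(line.split(",")) if i != idx)
            for line in lines
        ]
        fac.write_text("\n".join(stripped))
        with pytest.raises(RegionParseError, match="adult_icu_beds"):
            read_region(tmp_path)

    def test_negative_population_is_validation_error(self, tmp_path, region_factory):
        region = region_factory(1)
        write_region(region, tmp_path)
        gj = tmp_path / "block_groups.geojson"
        text = gj.read_text()
        first_bg = region.block_groups[0]
        text = text.replace(f'"pop_total": {first_bg.pop_total}', '"pop_total": -5', 1)
        gj.write_text(text)
        with pytest.raises(RegionParseError, match="feature 0"):
            read_region(tmp_path)
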