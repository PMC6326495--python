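"""Focal-area coverage, random baseline, paired t-test, equal-area comparison."""

import numpy as np
import pytest
from scipy import stats

from umbrascape import (
    Grid,
    LandscapeStack,
    PrioritizerConfig,
    RegionMask,
    RemovalMask,
    coverage_vs_random,
    equal_area_comparison,
    group_summary,
    overlap_fraction,
    paired_t,
    rank_landscape,
    random_baseline,
)
from umbrascape.errors import (
    DegenerateTestError,
    EmptyLandscapeError,
    GridMismatchError,
    InvalidComparisonError,
    MissingLabelError,
)
from conftest import make_feature, random_stack


def region(grid, idx):
    member = np.zeros(grid.shape, bool)
    member.ravel()[list(idx)] = True
    return RegionMask(grid, member)


class TestOverlapFraction:
    def test_direct_sum(self):
        g = Grid(1, 3)
        f = make_feature([[0.2, 0.3, 0.5]], g)
        assert overlap_fraction(f, region(g, [2])) == pytest.approx(0.5)

    def test_full_mask_is_one(self):
        g = Grid(1, 3)
        f = make_feature([[0.2, 0.3, 0.5]], g)
        assert overlap_fraction(f, region(g, [0, 1, 2])) == pytest.approx(1.0)

    def test_empty_region_is_zero(self):
        g = Grid(1, 3)
        f = make_feature([[0.2, 0.3, 0.5]], g)
        assert overlap_fraction(f, region(g, [])) == 0.0

    def test_additive_over_disjoint_regions(self, rng):
        g = Grid(4, 5)
        q = rng.random(g.shape)
        f = make_feature(q / q.sum(), g)
        idx = rng.permutation(20)
        a, b = region(g, idx[:7]), region(g, idx[7:15])
        both = region(g, idx[:15])
        assert overlap_fraction(f, a) + overlap_fraction(f, b) == pytest.approx(
            overlap_fraction(f, both), abs=1e-12
        )

    def test_grid_mismatch(self):
        f = make_feature([[0.5, 0.5]], Grid(1, 2))
        with pytest.raises(GridMismatchError):
            overlap_fraction(f, region(Grid(1, 3), [0]))


class TestRandomBaseline:
    def test_area_ratio(self):
        g = Grid(20, 50)  # 1000 cells
        analysis = RegionMask(g, np.ones(g.shape, bool))
        assert random_baseline(region(g, range(233)), analysis) == pytest.approx(0.233)

    def test_whole_region_is_one(self):
        g = Grid(2, 3)
        analysis = RegionMask(g, np.ones(g.shape, bool))
        assert random_baseline(analysis, analysis) == 1.0

    def test_empty_analysis_raises(self):
        g = Grid(2, 3)
        empty = RegionMask(g, np.zeros(g.shape, bool))
        with pytest.raises(EmptyLandscapeError):
            random_baseline(empty, empty)

    def test_matches_monte_carlo_single_cell_features(self, rng):
        # mean overlap of uniformly random single-cell features ~ area fraction
        g = Grid(10, 10)
        analysis = RegionMask(g, np.ones(g.shape, bool))
        reg = region(g, rng.permutation(100)[:23])
        baseline = random_baseline(reg, analysis)
        n = 1000
        cells = rng.integers(0, 100, size=n)
        overlaps = reg.member.ravel()[cells].astype(float)
        se = overlaps.std(ddof=1) / np.sqrt(n)
        assert abs(overlaps.mean() - baseline) < 3 * se


class TestPairedT:
    def test_symmetric_null(self):
        res = paired_t([1, 2, 3], [3, 2, 1])
        assert res.mean_difference == 0.0
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form(self):
        # d = (1,2,3): mean 2, sd 1, t = 2/(1/sqrt(3)) = 3.4641..., df 2
        res = paired_t([2, 4, 6], [1, 2, 3])
        t_expected = 2.0 / (1.0 / np.sqrt(3.0))
        assert res.t_statistic == pytest.approx(t_expected, abs=1e-9)
        assert res.degrees_of_freedom == 2
        assert res.mean_difference == pytest.approx(2.0, abs=1e-12)
        assert res.p_value == pytest.approx(2 * stats.t.sf(t_expected, 2), abs=1e-12)
        assert res.p_value == pytest.approx(0.0742, abs=5e-5)

    def test_antisymmetry(self):
        a = paired_t([2, 4, 6], [1, 2, 3])
        b = paired_t([1, 2, 3], [2, 4, 6])
        assert b.t_statistic == pytest.approx(-a.t_statistic)
        assert b.mean_difference == pytest.approx(-a.mean_difference)
        assert b.p_value == pytest.approx(a.p_value)

    def test_shift_invariance(self, rng):
        x, y = rng.random(10), rng.random(10)
        a, b = paired_t(x, y), paired_t(x + 5.0, y + 5.0)
        assert b.t_statistic == pytest.approx(a.t_statistic, abs=1e-9)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-9)

    def test_ci_brackets_mean(self, rng):
        x, y = rng.random(15), rng.random(15)
        r = paired_t(x, y)
        assert r.ci_low <= r.mean_difference <= r.ci_high
        # CI endpoints from the t distribution directly
        se = (x - y).std(ddof=1) / np.sqrt(15)
        tc = stats.t.ppf(0.975, 14)
        assert r.ci_low == pytest.approx(r.mean_difference - tc * se, abs=1e-12)

    def test_degenerate_cases(self):
        with pytest.raises(DegenerateTestError):
            paired_t([2, 3, 4], [1, 2, 3])  # constant non-zero difference
        res = paired_t([1, 2], [1, 2])
        assert res.t_statistic == 0.0 and res.p_value == 1.0


class TestCoverageVsRandom:
    def test_counting_and_strict_inequality(self):
        g = Grid(1, 10)
        analysis = RegionMask(g, np.ones(g.shape, bool))
        reg = region(g, [0, 1])  # baseline 0.2
        feats = [
            make_feature(np.array([[1, 1, 1, 1, 1, 0, 0, 0, 0, 0]]) / 5, g, "inside", species="s1"),
            make_feature(np.full((1, 10), 0.1), g, "uniform", species="s2"),
            make_feature(np.array([[0, 0, 1, 1, 1, 1, 1, 0, 0, 0]]) / 5, g, "outside", species="s3"),
        ]
        records, summary = coverage_vs_random(feats, reg, analysis)
        assert [r.above_baseline for r in records] == [True, False, False]
        # uniform feature equals the baseline exactly: equality is not "above"
        assert records[1].overlap == pytest.approx(records[1].baseline)
        assert summary["n_features_above"] == 1
        assert summary["n_species_above"] == 1

    def test_species_above_if_any_season_is(self):
        g = Grid(1, 4)
        analysis = RegionMask(g, np.ones(g.shape, bool))
        reg = region(g, [0])  # baseline 0.25
        feats = [
            make_feature([[1, 0, 0, 0]], g, "spA_summer", season="summer", species="spA"),
            make_feature([[0, 0, 0, 1.0]], g, "spA_winter", season="winter", species="spA"),
        ]
        _, summary = coverage_vs_random(feats, reg, analysis)
        assert summary["n_features"] == 2 and summary["n_features_above"] == 1
        assert summary["n_species"] == 1 and summary["n_species_above"] == 1


class TestEqualAreaComparison:
    def _stack(self, rng, n=24):
        return random_stack(rng, n_rows=4, n_cols=6, n_features=4, partial_mask=False)

    def test_masked_region_gives_zero_difference(self, rng):
        # locking the current region into the top ranks makes the comparison
        # self-consistent: at the masked fraction both strategies coincide
        stack = self._stack(rng)
        current = region(stack.grid, rng.permutation(24)[:8])
        level = np.zeros(stack.grid.shape, dtype=int)
        level[current.member] = 1
        rank_map, _ = rank_landscape(stack, PrioritizerConfig("abf"), RemovalMask(stack.grid, level))
        frame, test = equal_area_comparison(stack.features, current, rank_map)
        np.testing.assert_allclose(frame.difference, 0.0, atol=1e-9)
        assert test.t_statistic == 0.0 and test.p_value == 1.0

    def test_unmasked_prioritization_at_least_as_good_on_average(self, rng):
        stack = self._stack(rng)
        current = region(stack.grid, rng.permutation(24)[:8])
        rank_map, _ = rank_landscape(stack, PrioritizerConfig("caz"))
        frame, test = equal_area_comparison(stack.features, current, rank_map)
        assert test.mean_difference == pytest.approx(
            float(frame.prioritized_coverage.mean() - frame.current_coverage.mean()), abs=1e-12
        )

    def test_fraction_mismatch_rejected(self, rng):
        stack = self._stack(rng)
        current = region(stack.grid, rng.permutation(24)[:8])
        rank_map, _ = rank_landscape(stack)
        with pytest.raises(InvalidComparisonError):
            equal_area_comparison(stack.features, current, rank_map, fraction=0.5)

    def test_closed_form_t(self):
        # current (0.2,0.4,0.6) vs prioritized (0.3,0.6,0.9): mean diff 0.2,
        # t = 0.2/(0.1/sqrt(3)) = 3.4641, df 2
        res = paired_t([0.3, 0.6, 0.9], [0.2, 0.4, 0.6])
        assert res.mean_difference == pytest.approx(0.2, abs=1e-12)
        assert res.t_statistic == pytest.approx(0.2 / (0.1 / np.sqrt(3)), abs=1e-9)
        assert res.degrees_of_freedom == 2


class TestGroupSummary:
    def _records(self, overlaps):
        g = Grid(1, 2)
        analysis = RegionMask(g, np.ones(g.shape, bool))
        reg = region(g, [0])
        from umbrascape.coverage import CoverageRecord

        return [
            CoverageRecord(f"f{i}", f"f{i}", "year_round", ov, 0.5, ov > 0.5)
            for i, ov in enumerate(overlaps)
        ]

    def test_median_per_group(self):
        recs = self._records([0.1, 0.3, 0.5, 0.9])
        groups = {"f0": "a", "f1": "a", "f2": "a", "f3": "b"}
        out = group_summary(recs, groups)
        assert out["a"] == pytest.approx(0.3)
        assert out["b"] == pytest.approx(0.9)  # singleton group

    def test_even_group_mean_of_middle(self):
        recs = self._records([0.2, 0.4])
        out = group_summary(recs, {"f0": "g", "f1": "g"})
        assert out["g"] == pytest.approx(0.3)

    def test_missing_label(self):
        recs = self._records([0.2])
        with pytest.raises(MissingLabelError):
            group_summary(recs, {})
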