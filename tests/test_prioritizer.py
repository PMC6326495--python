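"""Greedy ranking: marginal-loss formulas, removal order, hierarchical masks,
performance bookkeeping, and exact equivalence with the naive reference."""

import numpy as np
import pytest

from umbrascape import (
    Grid,
    PrioritizerConfig,
    PrioritizerState,
    RegionMask,
    RemovalMask,
    coverage_at_fraction,
    marginal_loss_abf,
    marginal_loss_caz,
    rank_landscape,
    rank_landscape_reference,
)
from umbrascape.errors import (
    EmptyLandscapeError,
    InvalidCellError,
    InvalidParameterError,
    StateCorruptionError,
)
from conftest import line_stack, make_feature, random_stack


def state_from(q_rows, cost=None):
    """Hand-built state: q_rows is (n_features, n_cells); all cells remaining."""
    q = np.asarray(q_rows, dtype=float)
    cost = np.ones(q.shape[1]) if cost is None else np.asarray(cost, float)
    return PrioritizerState(q, cost, np.ones(q.shape[1], bool))


class TestMarginalLossABF:
    def test_single_feature_partial_mass(self):
        # q_jn = 1, q_ji = 0.2, c = 1, z = 0.25: delta = 1 - 0.8^0.25
        st = state_from([[0.2, 0.8]])
        expected = 1.0 - 0.8**0.25  # = 0.05425839...
        assert marginal_loss_abf(st, 0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.05426, abs=5e-6)

    def test_cell_holding_all_remaining_mass(self):
        # q_jn = 0.5, q_ji = 0.5: delta = 0.5^0.25
        st = state_from([[0.5, 0.5]])
        st.remove(np.array([1]))  # q_jn drops to 0.5
        assert marginal_loss_abf(st, 0) == pytest.approx(0.5**0.25, abs=1e-12)
        assert 0.5**0.25 == pytest.approx(0.84090, abs=5e-6)

    def test_zero_cell(self):
        st = state_from([[0.0, 1.0]])
        assert marginal_loss_abf(st, 0) == 0.0

    def test_multi_feature_sum_and_cost(self):
        st = state_from([[0.3, 0.7], [0.1, 0.9]], cost=[2.0, 1.0])
        expected = ((1 - 0.7**0.25) + (1 - 0.9**0.25)) / 2.0
        assert marginal_loss_abf(st, 0) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_cell_share(self):
        a = marginal_loss_abf(state_from([[0.2, 0.8]]), 0)
        b = marginal_loss_abf(state_from([[0.4, 0.6]]), 0)
        assert b > a

    def test_removed_cell_rejected(self):
        st = state_from([[0.5, 0.5]])
        st.remove(np.array([0]))
        with pytest.raises(InvalidCellError):
            marginal_loss_abf(st, 0)

    def test_state_corruption_detected(self):
        st = state_from([[0.5, 0.5]])
        st.q_remaining[:] = 0.1  # inconsistent with q matrix
        with pytest.raises(StateCorruptionError):
            marginal_loss_abf(st, 0)


class TestMarginalLossCAZ:
    def test_max_over_features(self):
        st = state_from([[0.1, 0.9], [0.4, 0.6]])
        assert marginal_loss_caz(st, 0) == pytest.approx(0.4, abs=1e-12)

    def test_zero_cell(self):
        st = state_from([[0.0, 1.0]])
        assert marginal_loss_caz(st, 0) == 0.0

    def test_entire_remaining_distribution(self):
        st = state_from([[0.5, 0.5], [0.2, 0.8]])
        st.remove(np.array([1]))  # feature 0 now entirely in cell 0
        assert marginal_loss_caz(st, 0) == pytest.approx(1.0, abs=1e-12)

    def test_fully_removed_feature_contributes_zero(self):
        st = state_from([[1.0, 0.0], [0.5, 0.5]])
        st.remove(np.array([0]))  # feature 0 has q_jn = 0 now
        assert marginal_loss_caz(st, 1) == pytest.approx(1.0, abs=1e-12)


class TestRankLandscape:
    def test_single_feature_removal_order(self):
        stack = line_stack([0.2, 0.3, 0.5])
        rank_map, _ = rank_landscape(stack, PrioritizerConfig("abf"))
        np.testing.assert_allclose(rank_map.rank_fraction, [[1 / 3, 2 / 3, 1.0]])

    def test_mask_forces_cell_to_top(self):
        stack = line_stack([0.2, 0.3, 0.5])
        mask = RemovalMask(stack.grid, np.array([[1, 0, 0]]))
        rank_map, _ = rank_landscape(stack, PrioritizerConfig("abf"), mask)
        # cell0 locked to the top despite the smallest q
        np.testing.assert_allclose(rank_map.rank_fraction, [[1.0, 1 / 3, 2 / 3]])

    def test_performance_at_one_third(self):
        stack = line_stack([0.2, 0.3, 0.5])
        _, table = rank_landscape(stack, PrioritizerConfig("abf"))
        retained = table.at_fraction(1 / 3)
        assert retained[0] == pytest.approx(0.5, abs=1e-12)

    def test_curve_monotone_with_unit_endpoints(self, rng):
        stack = random_stack(rng, n_features=4)
        _, table = rank_landscape(stack, PrioritizerConfig("caz"))
        assert table.fractions[0] == 1.0 and table.fractions[-1] == 0.0
        np.testing.assert_allclose(table.proportions[0], 1.0)
        np.testing.assert_allclose(table.proportions[-1], 0.0, atol=1e-12)
        diffs = np.diff(table.proportions, axis=0)
        assert (diffs <= 1e-12).all()  # non-increasing as cells are removed

    def test_empty_landscape(self):
        from umbrascape import LandscapeStack

        grid = Grid(1, 2)
        analysis = RegionMask(grid, np.zeros(grid.shape, bool))
        feat = make_feature([[0.5, 0.5]], grid)
        stack = LandscapeStack(grid, [feat], analysis)
        with pytest.raises(EmptyLandscapeError):
            rank_landscape(stack)

    def test_abf_single_feature_sorts_by_share(self, rng):
        vals = rng.random(12) + 0.01
        stack = line_stack(vals)
        rank_map, _ = rank_landscape(stack, PrioritizerConfig("abf"))
        order = np.argsort(rank_map.rank.ravel())
        q = stack.features[0].q.ravel()
        expected = np.lexsort((np.arange(12), q))
        np.testing.assert_array_equal(order, expected)

    def test_caz_core_area_cell_removed_last(self, rng):
        # one feature concentrated in a single cell: that cell outranks all others
        grid = Grid(1, 5)
        analysis = RegionMask(grid, np.ones(grid.shape, bool))
        rare = make_feature([[0, 0, 1.0, 0, 0]], grid, "rare")
        common_q = np.full((1, 5), 0.2)
        common = make_feature(common_q, grid, "common")
        from umbrascape import LandscapeStack

        stack = LandscapeStack(grid, [rare, common], analysis)
        rank_map, _ = rank_landscape(stack, PrioritizerConfig("caz"))
        assert rank_map.rank[0, 2] == 5

    def test_determinism(self, rng):
        stack = random_stack(rng, n_features=3)
        a, _ = rank_landscape(stack, PrioritizerConfig("caz"))
        b, _ = rank_landscape(stack, PrioritizerConfig("caz"))
        np.testing.assert_array_equal(a.rank, b.rank)

    def test_conservation_at_every_step(self, rng):
        # table's retained proportion + mass of cells removed so far == 1
        stack = random_stack(rng, n_features=3)
        rank_map, table = rank_landscape(stack, PrioritizerConfig("abf"))
        q = stack.feature_matrix()
        ranks = rank_map.rank.ravel()
        for k, props in enumerate(table.proportions):
            removed = q[:, (ranks > 0) & (ranks <= k)].sum(axis=1)
            np.testing.assert_allclose(props + removed, 1.0, atol=1e-9)

    def test_warp_batches_cover_all_cells(self, rng):
        stack = random_stack(rng, n_rows=5, n_cols=8, n_features=2)
        rank_map, _ = rank_landscape(stack, PrioritizerConfig("abf", warp=7))
        n = stack.analysis_mask.n_cells
        ranks = rank_map.rank[stack.analysis_mask.member]
        assert sorted(ranks) == list(range(1, n + 1))


class TestOracleEquivalence:
    @pytest.mark.parametrize("objective", ["abf", "caz"])
    @pytest.mark.parametrize("masked", [False, True])
    def test_fast_matches_reference(self, objective, masked, rng):
        for _ in range(5):
            stack = random_stack(rng, n_rows=5, n_cols=6, n_features=3)
            mask = None
            if masked:
                lv = (rng.random(stack.grid.shape) < 0.3).astype(int)
                mask = RemovalMask(stack.grid, lv)
            cfg = PrioritizerConfig(objective)
            fast, _ = rank_landscape(stack, cfg, mask)
            ref, _ = rank_landscape_reference(stack, cfg, mask)
            np.testing.assert_array_equal(fast.rank, ref.rank)

    def test_single_cell_landscape(self):
        stack = line_stack([1.0])
        rank_map, _ = rank_landscape_reference(stack)
        assert rank_map.rank_fraction[0, 0] == 1.0

    def test_duplicate_feature_invariance_under_caz(self, rng):
        stack = random_stack(rng, n_features=2, partial_mask=False)
        f = stack.features
        from umbrascape import LandscapeStack

        doubled = LandscapeStack(
            stack.grid,
            [f[0], f[1], make_feature(f[1].q.copy(), stack.grid, "dup")],
            stack.analysis_mask,
        )
        a, _ = rank_landscape(stack, PrioritizerConfig("caz"))
        b, _ = rank_landscape(doubled, PrioritizerConfig("caz"))
        np.testing.assert_array_equal(a.rank, b.rank)


class TestCoverageAtFraction:
    def test_endpoints(self):
        stack = line_stack([0.2, 0.3, 0.5])
        rank_map, _ = rank_landscape(stack)
        feats = stack.features
        assert coverage_at_fraction(rank_map, 1.0, feats)[0] == pytest.approx(1.0)
        assert coverage_at_fraction(rank_map, 0.0, feats)[0] == 0.0

    def test_top_two_thirds(self):
        stack = line_stack([0.2, 0.3, 0.5])
        rank_map, _ = rank_landscape(stack)
        got = coverage_at_fraction(rank_map, 2 / 3, stack.features)
        assert got[0] == pytest.approx(0.8, abs=1e-12)

    def test_table_source_agrees_with_rank_map(self, rng):
        stack = random_stack(rng, n_features=3)
        rank_map, table = rank_landscape(stack)
        n = stack.analysis_mask.n_cells
        for k in (0, 1, n // 2, n):
            frac = k / n
            np.testing.assert_allclose(
                coverage_at_fraction(rank_map, frac, stack.features),
                coverage_at_fraction(table, frac),
                atol=1e-9,
            )

    def test_fraction_out_of_range(self):
        stack = line_stack([1.0, 1.0])
        rank_map, _ = rank_landscape(stack)
        with pytest.raises(InvalidParameterError):
            coverage_at_fraction(rank_map, 1.5, stack.features)


def test_mask_hierarchy_strict(rng):
    stack = random_stack(rng, n_rows=6, n_cols=6, n_features=3)
    levels = rng.integers(0, 3, size=stack.grid.shape)
    mask = RemovalMask(stack.grid, levels)
    rank_map, _ = rank_landscape(stack, PrioritizerConfig("abf"), mask)
    member = stack.analysis_mask.member
    for lo in range(2):
        hi_ranks = rank_map.rank[(levels > lo) & member]
        lo_ranks = rank_map.rank[(levels == lo) & member]
        if hi_ranks.size and lo_ranks.size:
            assert hi_ranks.min() > lo_ranks.max()
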