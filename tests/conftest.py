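import numpy as np
import pytest

from umbrascape import (
    Grid,
    LandscapeStack,
    NormalizedFeature,
    RegionMask,
)


def make_feature(q, grid=None, feature_id="f", season="year_round", species=""):
    q = np.asarray(q, dtype=float)
    if grid is None:
        grid = Grid(*q.shape) if q.ndim == 2 else Grid(1, q.size)
    return NormalizedFeature(grid, q.reshape(grid.shape), feature_id, season, species)


def line_stack(q_values, cost=None):
    """1xN landscape with one feature from raw q proportions."""
    q = np.asarray(q_values, dtype=float)
    grid = Grid(1, q.size)
    analysis = RegionMask(grid, np.ones(grid.shape, bool), "analysis")
    feat = make_feature(q / q.sum(), grid)
    c = None if cost is None else np.asarray(cost, float).reshape(grid.shape)
    return LandscapeStack(grid, [feat], analysis, cost=c)


def random_stack(rng, n_rows=6, n_cols=7, n_features=3, partial_mask=True):
    """Random small landscape: random analysis mask, random sparse features."""
    grid = Grid(n_rows, n_cols)
    if partial_mask:
        member = rng.random(grid.shape) < 0.8
        if not member.any():
            member[0, 0] = True
    else:
        member = np.ones(grid.shape, bool)
    analysis = RegionMask(grid, member, "analysis")
    feats = []
    for j in range(n_features):
        vals = rng.random(grid.shape) * (rng.random(grid.shape) < 0.6)
        vals[~member] = 0.0
        if vals.sum() == 0:
            r, c = np.argwhere(member)[0]
            vals[r, c] = 1.0
        feats.append(make_feature(vals / vals.sum(), grid, feature_id=f"f{j}"))
    return LandscapeStack(grid, feats, analysis)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
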