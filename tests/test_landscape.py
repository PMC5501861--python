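"""Grid geometry, river barriers, standardization, forest typing, patches."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import LineString

from apedyn.landscape import (GridLandscape, LandscapeError, build_neighbor_graph,
                              cell_center, connected_forest_patches,
                              forest_type_indicators, standardize_covariates,
                              zscore)
from conftest import make_landscape


# ---------------------------------------------------------------------------
# neighbour graph


def test_moore_degrees_on_full_rectangle(landscape):
    g = build_neighbor_graph(landscape, [])
    assert set(g.deg.tolist()) == {3, 5, 8}
    interior = (landscape.rows > 0) & (landscape.rows < landscape.nrow - 1) & \
               (landscape.cols > 0) & (landscape.cols < landscape.ncol - 1)
    assert np.all(g.deg[interior] == 8)
    corner = 0
    assert g.deg[corner] == 3
    assert g.deg.sum() % 2 == 0
    assert np.all(g.w[g.nbr >= 0] == 1.0)  # no rivers -> no barriers


def test_graph_symmetry_with_random_rivers(rng):
    land = make_landscape(nrow=6, ncol=6, seed=3)
    rivers = [LineString(rng.uniform(0, 6, (4, 2))) for _ in range(3)]
    g = build_neighbor_graph(land, rivers)
    for i in range(land.ncell):
        for j, w in g.neighbors(i):
            back = dict(g.neighbors(j))
            assert i in back and back[i] == w


def _segments_intersect(p1, p2, p3, p4):
    """Brute-force proper/improper segment intersection returning the point
    parameter, or None (parallel handled as no single crossing)."""
    d1 = (p2[0] - p1[0], p2[1] - p1[1])
    d2 = (p4[0] - p3[0], p4[1] - p3[1])
    den = d1[0] * d2[1] - d1[1] * d2[0]
    if den == 0:
        return None
    t = ((p3[0] - p1[0]) * d2[1] - (p3[1] - p1[1]) * d2[0]) / den
    s = ((p3[0] - p1[0]) * d1[1] - (p3[1] - p1[1]) * d1[0]) / den
    if 0 <= t <= 1 and 0 <= s <= 1:
        return (p1[0] + t * d1[0], p1[1] + t * d1[1])
    return None


def _brute_force_graph(land, river_pts):
    """Independent barrier computation: explicit segment-segment
    intersections, blocking when a crossing lies strictly inside either
    endpoint cell."""
    from apedyn.landscape import _OFFSETS
    C = land.ncell
    w = {}
    for i in range(C):
        r, c = divmod(i, land.ncol)
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < land.nrow and 0 <= cc < land.ncol):
                continue
            j = rr * land.ncol + cc
            a, b = cell_center(r, c), cell_center(rr, cc)
            blocked = False
            for k in range(len(river_pts) - 1):
                pt = _segments_intersect(a, b, river_pts[k], river_pts[k + 1])
                if pt is None:
                    continue
                for (cr, ccol) in ((r, c), (rr, cc)):
                    if ccol < pt[0] < ccol + 1 and cr < pt[1] < cr + 1:
                        blocked = True
            w[(i, j)] = 0.0 if blocked else 1.0
    return w


def test_vertical_river_blocks_crossing_links():
    land = make_landscape(nrow=5, ncol=5, seed=1)
    # river between columns 2 and 3 (x = 3.0 in km coordinates), jittered
    # slightly off the cell edge so crossings are strict-interior
    river = LineString([(3.05, -1.0), (2.9, 6.0)])
    g = build_neighbor_graph(land, [river])
    for i in range(land.ncell):
        ci = i % 5
        for j, w in g.neighbors(i):
            cj = j % 5
            crosses = (ci <= 2 < cj) or (cj <= 2 < ci)
            assert w == (0.0 if crosses else 1.0), (i, j)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_barrier_agrees_with_brute_force(seed):
    rng = np.random.default_rng(seed)
    nrow = int(rng.integers(3, 9))
    ncol = int(rng.integers(3, 9))
    land = make_landscape(nrow=nrow, ncol=ncol, seed=seed)
    pts = rng.uniform(-0.5, max(nrow, ncol) + 0.5, (5, 2))
    g = build_neighbor_graph(land, [LineString(pts)])
    expect = _brute_force_graph(land, [tuple(p) for p in pts])
    for i in range(land.ncell):
        for j, w in g.neighbors(i):
            assert w == expect[(i, j)], (i, j, seed)


def test_duplicate_coordinates_rejected(landscape):
    df = landscape.to_frame()
    df.loc[1, ["row", "col"]] = df.loc[0, ["row", "col"]].to_numpy()
    df.loc[1, "cell_id"] = df.loc[0, "cell_id"]
    with pytest.raises(LandscapeError):
        GridLandscape.from_frame(df)


# ---------------------------------------------------------------------------
# standardization


def test_zscore_population_convention():
    z, m, s = zscore(np.array([1.0, 2.0, 3.0]))
    assert np.allclose(z, [-1.22474487, 0.0, 1.22474487])
    assert m == 2.0 and np.isclose(s, np.sqrt(2.0 / 3.0))


def test_standardize_moments_and_idempotence(landscape):
    z = standardize_covariates(landscape)
    for name in ("ALT", "DRY", "WET", "MS"):
        col = getattr(z, name)
        assert abs(col.mean()) < 1e-8 and abs(col.std() - 1) < 1e-8
    for name in ("DPA", "FR", "CFA"):
        col = getattr(z, name).ravel()   # pooled over periods
        assert abs(col.mean()) < 1e-8 and abs(col.std() - 1) < 1e-8
    # standardizing an already standard column changes nothing
    z2, _, _ = zscore(z.ALT)
    assert np.allclose(z2, z.ALT, atol=1e-12)


def test_back_transformation_recovers_original(landscape):
    z = standardize_covariates(landscape)
    assert np.allclose(z.back_transform("ALT"), landscape.ALT, atol=1e-10)
    assert np.allclose(z.back_transform("FR"), landscape.FR, atol=1e-10)


def test_constant_column_raises(landscape):
    landscape.ALT = np.full(landscape.ncell, 250.0)
    with pytest.raises(LandscapeError, match="ALT"):
        standardize_covariates(landscape)


# ---------------------------------------------------------------------------
# forest types


def test_forest_type_mapping(landscape):
    landscape.forest_class[:, 0] = "other"
    landscape.forest_class[0, 0] = "mangrove"
    landscape.forest_class[1, 0] = "peat"
    landscape.ALT[2] = 600.0   # montane split
    landscape.ALT[3] = 100.0
    landscape.FR[4, 0] = 0.2   # fragmented
    ind = forest_type_indicators(landscape, 0)
    assert ind.loc[0, ["MGV", "PT", "LOWL", "MONT"]].tolist() == [1, 0, 0, 0]
    assert ind.loc[1, ["MGV", "PT", "LOWL", "MONT"]].tolist() == [0, 1, 0, 0]
    assert ind.loc[2, "MONT"] == 1 and ind.loc[2, "LOWL"] == 0
    assert ind.loc[3, "LOWL"] == 1
    assert ind.loc[4, "FRGM"] == 1
    # at most one type flag per cell
    assert ind[["MGV", "PT", "LOWL", "MONT"]].sum(axis=1).max() <= 1


def test_unknown_forest_class_raises(landscape):
    landscape.forest_class[0, 1] = "bamboo"
    with pytest.raises(LandscapeError, match="bamboo"):
        forest_type_indicators(landscape, 1)


# ---------------------------------------------------------------------------
# patches


def _flood_fill(mask):
    """Oracle 8-connected labelling by explicit flood fill."""
    nrow, ncol = mask.shape
    labels = np.zeros_like(mask, dtype=int)
    nxt = 0
    for r0 in range(nrow):
        for c0 in range(ncol):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                stack = [(r0, c0)]
                while stack:
                    r, c = stack.pop()
                    if not (0 <= r < nrow and 0 <= c < ncol):
                        continue
                    if not mask[r, c] or labels[r, c]:
                        continue
                    labels[r, c] = nxt
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            stack.append((r + dr, c + dc))
    return labels


def _set_mask(land, mask):
    land.FR[:, 0] = np.where(mask.ravel(), 0.9, 0.0)


def test_single_block_is_one_patch():
    land = make_landscape(nrow=5, ncol=5)
    mask = np.zeros((5, 5), bool)
    mask[1:4, 1:4] = True
    _set_mask(land, mask)
    p = connected_forest_patches(land, 0)
    assert p.npatch == 1 and p.sizes_km2[0] == 9.0
    assert np.isnan(p.nearest_km[0])   # isolation undefined, flagged as NaN


def test_diagonal_cells_form_one_patch():
    land = make_landscape(nrow=3, ncol=3)
    mask = np.zeros((3, 3), bool)
    mask[0, 0] = mask[1, 1] = True
    _set_mask(land, mask)
    assert connected_forest_patches(land, 0).npatch == 1


def test_two_blocks_gap_distance():
    land = make_landscape(nrow=4, ncol=8)
    mask = np.zeros((4, 8), bool)
    mask[0:2, 0:2] = True
    mask[0:2, 4:6] = True   # two-cell gap
    _set_mask(land, mask)
    p = connected_forest_patches(land, 0)
    assert p.npatch == 2
    assert sorted(p.sizes_km2.tolist()) == [4.0, 4.0]
    assert np.allclose(p.nearest_km, 2.0)


def test_no_forest_returns_empty():
    land = make_landscape(nrow=3, ncol=3)
    land.FR[:, 0] = 0.0
    p = connected_forest_patches(land, 0)
    assert p.npatch == 0


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_patch_labels_match_flood_fill(seed):
    rng = np.random.default_rng(seed)
    nrow, ncol = int(rng.integers(3, 20)), int(rng.integers(3, 20))
    mask = rng.random((nrow, ncol)) < 0.4
    land = make_landscape(nrow=nrow, ncol=ncol, seed=seed)
    _set_mask(land, mask)
    got = connected_forest_patches(land, 0).labels.reshape(nrow, ncol)
    want = _flood_fill(mask)
    # same partition up to label permutation
    assert (got > 0).sum() == (want > 0).sum()
    mapping = {}
    for g, w in zip(got.ravel(), want.ravel()):
        if g == 0:
            assert w == 0
            continue
        assert mapping.setdefault(g, w) == w
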