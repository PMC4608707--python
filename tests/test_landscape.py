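"""Grid construction, patch labeling, distance metrics, standardization, VIF."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from fawnscape.landscape import (
    CategoricalRaster,
    build_grid,
    distance_to_lines,
    label_patches,
    nearest3_patch_distance,
    standardize,
    vif_screen,
)
from tests.conftest import uniform_raster


# ---------------------------------------------------------------- build_grid
class TestBuildGrid:
    def test_two_by_two_layout(self):
        # 91.98 m extent is exactly two cell sides of sqrt(2115) = 45.99 m
        raster = CategoricalRaster(np.ones((4, 4)), (0.0, 0.0), 91.98 / 4)
        grid = build_grid(raster, cell_area_m2=2115.0)
        assert (grid.n_rows, grid.n_cols) == (2, 2)
        assert grid.cell_side == pytest.approx(np.sqrt(2115.0))

    def test_uniform_raster_proportions(self):
        grid = build_grid(uniform_raster(10, cls=3))
        props = grid.cells.filter(like="prop_").to_numpy()
        expect = np.zeros(8)
        expect[2] = 1.0
        assert np.allclose(props, expect[None, :])

    def test_single_cell_matches_pixel_tally_oracle(self):
        # one grid cell covered by a 3x3 block of pixels
        rng = np.random.default_rng(5)
        side = np.sqrt(2115.0)
        raster = CategoricalRaster(rng.integers(1, 9, (3, 3)), (0.0, 0.0), side / 3)
        grid = build_grid(raster)
        assert grid.n_cells == 1
        oracle = np.bincount(raster.values.ravel(), minlength=9)[1:] / 9
        props = grid.cells.filter(like="prop_").to_numpy()[0]
        assert np.allclose(props, oracle, atol=1e-12)

    def test_overlay_conserves_class_area(self, small_landscape):
        raster, _, _ = small_landscape
        grid = build_grid(raster)
        props = grid.cells.filter(like="prop_").to_numpy()
        assert props.min() >= 0 and np.allclose(props.sum(axis=1), 1, atol=1e-9)
        # total class area over cells equals the exact pixel-overlap tally
        ys = np.arange(raster.shape[0]) * raster.pixel_size
        xs = np.arange(raster.shape[1]) * raster.pixel_size
        cy = grid.n_rows * grid.cell_side
        cx = grid.n_cols * grid.cell_side
        wy = np.clip(np.minimum(ys + raster.pixel_size, cy) - ys, 0, None)
        wx = np.clip(np.minimum(xs + raster.pixel_size, cx) - xs, 0, None)
        for k in range(8):
            mask = (raster.values == k + 1).astype(float)
            want = float(wy @ mask @ wx)
            got = props[:, k].sum() * grid.cell_area_m2
            assert got == pytest.approx(want, rel=1e-6, abs=1e-6)

    def test_extent_smaller_than_cell_rejected(self):
        raster = CategoricalRaster(np.ones((1, 1)), (0.0, 0.0), 10.0)
        with pytest.raises(ValueError, match="smaller than one"):
            build_grid(raster)


# ------------------------------------------------------------- label_patches
def _flood_fill_oracle(values):
    """Independent 4-connected labeling by explicit BFS."""
    nr, nc = values.shape
    labels = np.zeros((nr, nc), dtype=int)
    nxt = 0
    for r0 in range(nr):
        for c0 in range(nc):
            if labels[r0, c0]:
                continue
            nxt += 1
            stack = [(r0, c0)]
            labels[r0, c0] = nxt
            while stack:
                r, c = stack.pop()
                for rr, cc in ((r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)):
                    if (0 <= rr < nr and 0 <= cc < nc and not labels[rr, cc]
                            and values[rr, cc] == values[r, c]):
                        labels[rr, cc] = nxt
                        stack.append((rr, cc))
    return labels


class TestLabelPatches:
    def test_single_class_is_one_patch(self):
        ps = label_patches(uniform_raster(6))
        assert ps.n_patches == 1
        assert ps.patch_area_km2[0] == pytest.approx(36 * 900 / 1e6)

    def test_checkerboard_each_pixel_own_patch(self):
        vals = (np.indices((6, 6)).sum(axis=0) % 2) + 1
        ps = label_patches(CategoricalRaster(vals, (0.0, 0.0), 30.0))
        assert ps.n_patches == 36

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(11)
        vals = rng.integers(1, 4, (50, 50))
        ps = label_patches(CategoricalRaster(vals, (0.0, 0.0), 30.0))
        oracle = _flood_fill_oracle(vals)
        # same partition: labels agree up to renaming
        pairs = set(zip(ps.labels.ravel(), oracle.ravel()))
        assert len(pairs) == ps.n_patches == oracle.max()


# ------------------------------------------------- nearest3_patch_distance
def _nearest3_oracle(point, patches, k=3):
    pid = int(patches.patch_at(point[0], point[1]))
    cls = patches.patch_class[pid - 1]
    dists = []
    for other in range(1, patches.n_patches + 1):
        if other == pid or patches.patch_class[other - 1] != cls:
            continue
        bxy = patches.boundary_xy[other - 1]
        dists.append(np.sqrt(((bxy - point) ** 2).sum(axis=1)).min())
    dists.sort()
    return np.nan if not dists else np.mean(dists[:k]) / 1000.0


class TestNearestPatchDistance:
    def test_hand_case_mean_of_three(self):
        # three single-pixel patches of class 2 at known distances from origin patch
        vals = np.ones((1, 40), dtype=int)
        for col in (0, 10, 20, 30):
            vals[0, col] = 2
        ps = label_patches(CategoricalRaster(vals, (0.0, 0.0), 1.0))
        d = nearest3_patch_distance(np.array([[0.5, 0.5]]), ps)
        assert d[0] == pytest.approx((10 + 20 + 30) / 3 / 1000.0)

    def test_single_other_patch_rule(self):
        vals = np.ones((1, 101), dtype=int)
        vals[0, 0] = vals[0, 100] = 2
        ps = label_patches(CategoricalRaster(vals, (0.0, 0.0), 1.0))
        d = nearest3_patch_distance(np.array([[0.5, 0.5]]), ps)
        assert d[0] == pytest.approx(0.100)

    def test_matches_exhaustive_oracle(self, small_patches):
        rng = np.random.default_rng(3)
        raster = small_patches.raster
        xmin, ymin, xmax, ymax = raster.extent
        pts = rng.uniform([xmin, ymin], [xmax - 1e-6, ymax - 1e-6], (20, 2))
        got = nearest3_patch_distance(pts, small_patches)
        want = np.array([_nearest3_oracle(p, small_patches) for p in pts])
        assert np.allclose(got, want, equal_nan=True, atol=1e-9)

    def test_monotone_under_patch_deletion(self):
        # removing candidate patches cannot decrease the mean distance
        vals = np.ones((1, 50), dtype=int)
        for col in (10, 20, 30, 40):
            vals[0, col] = 2
        ps_all = label_patches(CategoricalRaster(vals, (0.0, 0.0), 1.0))
        vals2 = vals.copy()
        vals2[0, 10] = 1  # delete the closest candidate
        ps_del = label_patches(CategoricalRaster(vals2, (0.0, 0.0), 1.0))
        p = np.array([[0.5, 0.5]])
        assert nearest3_patch_distance(p, ps_del)[0] >= nearest3_patch_distance(p, ps_all)[0]

    def test_no_other_patch_warns_nan(self):
        vals = np.ones((3, 3), dtype=int)
        ps = label_patches(CategoricalRaster(vals, (0.0, 0.0), 30.0))
        with pytest.warns(UserWarning, match="no other patch"):
            d = nearest3_patch_distance(np.array([[10.0, 10.0]]), ps)
        assert np.isnan(d[0])


# ---------------------------------------------------------- distance_to_lines
class TestDistanceToLines:
    def test_point_on_segment_is_zero(self):
        d = distance_to_lines(np.array([[1.0, 0.0]]), [LineString([(-5, 0), (5, 0)])])
        assert d[0] == 0.0

    def test_perpendicular_foot(self):
        d = distance_to_lines(np.array([[0.0, 10.0]]), [LineString([(-5, 0), (5, 0)])])
        assert d[0] == pytest.approx(10.0)

    def test_empty_line_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            distance_to_lines(np.array([[0.0, 0.0]]), [])

    def test_matches_dense_vertex_oracle(self):
        rng = np.random.default_rng(9)
        lines = [LineString(rng.uniform(0, 1000, (4, 2))) for _ in range(3)]
        pts = rng.uniform(0, 1000, (100, 2))
        got = distance_to_lines(pts, lines)
        # oracle: densify each segment at 1 cm spacing and take vertex minima
        vertices = []
        for ln in lines:
            coords = np.asarray(ln.coords)
            for a, b in zip(coords[:-1], coords[1:]):
                npts = max(2, int(np.linalg.norm(b - a) / 0.01))
                vertices.append(np.linspace(a, b, npts))
        verts = np.vstack(vertices)
        want = np.array([np.sqrt(((verts - p) ** 2).sum(axis=1)).min() for p in pts])
        assert np.max(np.abs(got - want)) < 0.01


# ------------------------------------------------------ standardize & VIF
class TestStandardize:
    def test_known_column(self):
        out, _ = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}), ["a"])
        assert np.allclose(out["a"], [-1, 0, 1])

    def test_idempotent(self):
        df = pd.DataFrame({"a": np.random.default_rng(0).normal(size=50)})
        once, st = standardize(df, ["a"])
        twice = st.transform(once)  # frozen params: twice differs...
        again, _ = standardize(once, ["a"])  # ...refit on standardized: unchanged
        assert np.allclose(again["a"], once["a"], atol=1e-12)

    def test_postcondition_mean0_sd1(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.uniform(5, 9, 40), "b": rng.normal(-3, 7, 40)})
        out, _ = standardize(df, ["a", "b"])
        assert np.allclose(out[["a", "b"]].mean(), 0, atol=1e-9)
        assert np.allclose(out[["a", "b"]].std(ddof=1), 1, atol=1e-9)

    def test_zero_variance_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 4.0]})
        with pytest.warns(UserWarning, match="zero-variance column dropped: a"):
            out, st = standardize(df, ["a", "b"])
        assert st.columns == ["b"] and st.dropped == ["a"]


class TestVIF:
    def test_orthogonal_columns_unit_vif(self):
        df = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        out = vif_screen(df, ["a", "b"])
        assert np.allclose(out["vif"], 1.0)

    def test_near_collinear_pair_explodes(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": 2 * x + rng.normal(0, 1e-3, 200)})
        out = vif_screen(df, ["a", "b"])
        assert (out["vif"] > 100).all()
        assert not out["retained"].any()

    def test_all_below_threshold_retained(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(100, 3)), columns=["a", "b", "c"])
        out = vif_screen(df, ["a", "b", "c"], threshold=7.0)
        assert out["retained"].all()


# -------------------------------------------------------- global invariants
def test_covariates_translation_invariant(small_landscape):
    raster, roads, water = small_landscape
    grid0 = build_grid(raster, roads, water)
    shift = np.array([1234.5, -987.0])
    raster2 = CategoricalRaster(raster.values, tuple(np.array(raster.origin) + shift),
                                raster.pixel_size)
    from shapely.affinity import translate
    roads2 = [translate(r, *shift) for r in roads]
    water2 = [translate(w, *shift) for w in water]
    grid2 = build_grid(raster2, roads2, water2)
    cols = [c for c in grid0.cells.columns if c not in ("x", "y")]
    for c in cols:
        assert np.allclose(grid0.cells[c], grid2.cells[c], atol=1e-9, equal_nan=True), c
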