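"""Figures of merit: pixelization, thresholding, splitting, PE/RES/SD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eitpost.metrics import (
    GRID,
    MetricsReport,
    PixelImage32,
    TargetMask,
    aggregate_study,
    delta_res,
    inside_mask,
    pixel_centers,
    pixelize,
    position_error,
    quarter_threshold,
    rasterize_polygon_mask,
    resolution,
    score_image,
    shape_deformation,
    split_targets,
)


def _px(grid):
    ins = inside_mask()
    g = np.where(ins, grid, np.nan)
    return PixelImage32(grid=g, inside=ins)


class TestPixelize:
    def test_constant_image(self, ref_mesh):
        px = pixelize(np.full(ref_mesh.n_elements, 2.5), ref_mesh)
        assert np.allclose(px.grid[px.inside], 2.5)

    def test_inside_count_matches_disc_fraction(self, ref_mesh):
        px = pixelize(np.zeros(ref_mesh.n_elements), ref_mesh)
        # pi/4 of the bounding square, ~804 of 1024 pixels
        assert abs(px.inside_count - np.pi / 4 * GRID * GRID) < 15

    def test_centered_disc_inclusion_pixel_fraction(self, ref_mesh):
        """A disc covering 25% of the area flags ~25% of inside pixels."""
        cent = ref_mesh.element_centroids()
        r = np.hypot(cent[:, 0], cent[:, 1])
        img = np.where(r <= 0.25, 1.0, 0.0)  # radius 0.5*sqrt(0.25)... r=0.25
        px = pixelize(img, ref_mesh)
        mask = quarter_threshold(px)
        frac = mask.area_pixels / px.inside_count
        assert abs(frac - 0.25) < 2 * GRID / px.inside_count + 0.02

    def test_node_image_interpolation(self, ref_mesh):
        """A linear nodal field x+y pixelizes to the pixel coordinates."""
        vals = ref_mesh.nodes[:, 0] + ref_mesh.nodes[:, 1]
        px = pixelize(vals, ref_mesh)
        xs, ys = pixel_centers()
        assert np.allclose(px.grid[px.inside], (xs + ys)[px.inside], atol=1e-9)


class TestThreshold:
    def test_single_peak(self):
        g = np.zeros((GRID, GRID))
        g[16, 16] = 1.0
        mask = quarter_threshold(_px(g))
        assert mask.area_pixels == 1
        assert mask.pixels[16, 16]

    def test_all_inside_flagged_for_flat_image(self):
        px = _px(np.ones((GRID, GRID)))
        mask = quarter_threshold(px)
        assert mask.area_pixels == px.inside_count

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        px = _px(rng.normal(size=(GRID, GRID)))
        mask = quarter_threshold(px)
        vmax = np.nanmax(np.abs(px.grid[px.inside]))
        for i in range(GRID):
            for j in range(GRID):
                expect = bool(px.inside[i, j] and abs(px.grid[i, j]) >= 0.25 * vmax)
                assert mask.pixels[i, j] == expect

    def test_all_zero_gives_empty_mask_not_error(self):
        mask = quarter_threshold(_px(np.zeros((GRID, GRID))))
        assert mask.empty

    def test_sign_agnostic(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=(GRID, GRID))
        m1 = quarter_threshold(_px(g))
        m2 = quarter_threshold(_px(-g))
        assert np.array_equal(m1.pixels, m2.pixels)


class TestSplit:
    def test_symmetric_bisector_is_y_axis(self):
        full = TargetMask(inside_mask())
        left, right = split_targets(full, [(-0.3, 0.0), (0.3, 0.0)])
        xs, _ = pixel_centers()
        assert np.all(xs[left.pixels] <= 0)
        assert np.all(xs[right.pixels] > 0)
        assert np.array_equal(left.pixels | right.pixels, full.pixels)
        assert not np.any(left.pixels & right.pixels)

    def test_one_sided_mask_leaves_empty_partner(self):
        g = np.zeros((GRID, GRID), dtype=bool)
        g[16, 25] = True  # x > 0 pixel
        m1, m2 = split_targets(TargetMask(g), [(-0.3, 0.0), (0.3, 0.0)])
        assert m1.empty and m2.area_pixels == 1

    def test_matches_per_pixel_distance_classification(self):
        rng = np.random.default_rng(2)
        mask = TargetMask(rng.random((GRID, GRID)) < 0.3)
        c1, c2 = (0.1, -0.2), (-0.25, 0.15)
        m1, m2 = split_targets(mask, [c1, c2])
        xs, ys = pixel_centers()
        for i in range(GRID):
            for j in range(GRID):
                if mask.pixels[i, j]:
                    d1 = (xs[i, j] - c1[0]) ** 2 + (ys[i, j] - c1[1]) ** 2
                    d2 = (xs[i, j] - c2[0]) ** 2 + (ys[i, j] - c2[1]) ** 2
                    assert m1.pixels[i, j] == (d1 <= d2)

    def test_coincident_centers_error(self):
        with pytest.raises(ValueError, match="coincident"):
            split_targets(TargetMask(inside_mask()), [(0.1, 0.1), (0.1, 0.1)])


class TestErrors:
    def test_identical_masks_zero_pe(self):
        m = TargetMask(inside_mask())
        assert position_error(m, m) == 0.0

    def test_half_diameter_separation(self):
        a = np.zeros((GRID, GRID), dtype=bool)
        b = np.zeros((GRID, GRID), dtype=bool)
        xs, ys = pixel_centers()
        ia = np.unravel_index(np.argmin((xs + 0.25) ** 2 + ys**2), xs.shape)
        ib = np.unravel_index(np.argmin((xs - 0.25) ** 2 + ys**2), xs.shape)
        a[ia], b[ib] = True, True
        pe = position_error(TargetMask(a), TargetMask(b), diameter=1.0)
        assert pe == pytest.approx(50.0, abs=1.0)

    def test_antipodal_pixels_near_hundred_percent(self):
        """Single pixels at opposite ends of the disc: PE ~ 100%."""
        a = np.zeros((GRID, GRID), dtype=bool)
        b = np.zeros((GRID, GRID), dtype=bool)
        xs, ys = pixel_centers()
        ins = inside_mask()
        left = np.where(ins & (np.abs(ys) < 0.02), xs, np.inf)
        right = np.where(ins & (np.abs(ys) < 0.02), xs, -np.inf)
        a[np.unravel_index(np.argmin(left), xs.shape)] = True
        b[np.unravel_index(np.argmax(right), xs.shape)] = True
        pe = position_error(TargetMask(a), TargetMask(b))
        assert pe == pytest.approx(100.0, abs=5.0)

    def test_res_whole_domain_and_quarter(self):
        ins = inside_mask()
        full = TargetMask(ins)
        n_in = int(ins.sum())
        assert resolution(full, n_in) == 1.0
        # a mask of a quarter of the domain pixels -> RES 0.5
        idx = np.argwhere(ins)[: n_in // 4]
        quarter = np.zeros_like(ins)
        quarter[tuple(idx.T)] = True
        assert resolution(TargetMask(quarter), n_in) == pytest.approx(0.5, abs=0.01)

    def test_delta_res_zero_for_equal_masks(self):
        m = TargetMask(inside_mask())
        assert delta_res(m, m, int(inside_mask().sum())) == 0.0

    def test_sd_subset_zero_disjoint_hundred(self):
        ins = inside_mask()
        big = TargetMask(ins)
        idx = np.argwhere(ins)
        sub = np.zeros_like(ins)
        sub[tuple(idx[:50].T)] = True
        other = np.zeros_like(ins)
        other[tuple(idx[50:100].T)] = True
        assert shape_deformation(TargetMask(sub), big) == 0.0
        assert shape_deformation(TargetMask(sub), TargetMask(other)) == 100.0

    def test_sd_matches_brute_force(self):
        rng = np.random.default_rng(3)
        a = TargetMask(rng.random((GRID, GRID)) < 0.2)
        b = TargetMask(rng.random((GRID, GRID)) < 0.2)
        manual = 100.0 * sum(
            1
            for i in range(GRID)
            for j in range(GRID)
            if a.pixels[i, j] and not b.pixels[i, j]
        ) / a.area_pixels
        assert shape_deformation(a, b) == pytest.approx(manual)


class TestInvariance:
    @given(scale=st.floats(1e-3, 1e3))
    @settings(max_examples=15, deadline=None)
    def test_metrics_invariant_under_positive_scaling(self, ref_mesh_cached, scale):
        """Thresholding is relative: scaling the image changes nothing."""
        mesh, img, truth = ref_mesh_cached
        r1 = score_image(img, mesh, [truth])[0]
        r2 = score_image(scale * img, mesh, [truth])[0]
        assert r1 == r2

    def test_perfect_reconstruction_near_zero_errors(self, ref_mesh):
        """Image proportional to the truth raster: PE, dRES, SD ~ 0."""
        from eitpost.scenes import PhantomScene, TargetSpec, rasterize_scene

        scene = PhantomScene([TargetSpec("rectangle", (0.1, -0.05), 0.15, 0.4, 0.01)])
        sigma = rasterize_scene(scene, ref_mesh)
        img = 0.9 - sigma  # proportional to the (negative) truth change
        truth = rasterize_polygon_mask(scene.targets[0].polygon())
        rep = score_image(img, ref_mesh, [truth])[0]
        assert rep.pe_percent < 3.0
        assert rep.delta_res_percent < 3.0
        assert rep.sd_percent < 10.0


@pytest.fixture(scope="module")
def ref_mesh_cached(ref_mesh):
    from eitpost.scenes import PhantomScene, TargetSpec, rasterize_scene

    scene = PhantomScene([TargetSpec("ellipse", (0.05, 0.12), 0.1, 0.2, 0.01)])
    sigma = rasterize_scene(scene, ref_mesh)
    img = sigma - 0.9
    truth = rasterize_polygon_mask(scene.targets[0].polygon())
    return ref_mesh, img, truth


class TestAggregate:
    def _rep(self, pe, dres, sd, status="ok"):
        return MetricsReport(pe, 0.3, dres, sd, status)

    def test_identical_reports_zero_std(self):
        agg = aggregate_study([self._rep(5, 2, 10)] * 4)
        assert agg["pe"] == (5.0, 0.0)

    def test_two_value_hand_computation(self):
        agg = aggregate_study([self._rep(1, 0, 0), self._rep(3, 0, 0)])
        assert agg["pe"][0] == pytest.approx(2.0)
        assert agg["pe"][1] == pytest.approx(np.sqrt(2.0))

    def test_matches_two_pass_brute_force(self):
        rng = np.random.default_rng(4)
        reports = [self._rep(*rng.uniform(0, 100, 3)) for _ in range(1000)]
        agg = aggregate_study(reports)
        pes = np.array([r.pe_percent for r in reports])
        assert agg["pe"][0] == pytest.approx(pes.mean(), abs=1e-12)
        assert agg["pe"][1] == pytest.approx(pes.std(ddof=1), abs=1e-12)

    def test_undefined_entries_excluded_and_counted(self):
        reports = [self._rep(2, 2, 2), self._rep(np.nan, np.nan, np.nan, "no-target")]
        agg = aggregate_study(reports)
        assert agg["n"] == 1 and agg["n_excluded"] == 1

    def test_all_undefined_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            aggregate_study([self._rep(np.nan, np.nan, np.nan, "no-target")])
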