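"""Tests for tiling/assembly, morphology, Helmert fits and shape export."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.morphology import dilation, disk

from plaquelipid.lmd import (
    ActivationMap,
    AmideShiftScorer,
    HelmertTransform2D,
    MorphParams,
    Tile,
    TileSpec,
    assemble_activation,
    binarize_activation,
    detect_plaques,
    export_shapes,
    fit_helmert,
    morphological_refine,
    read_shapes_geojson,
    read_shapes_wkt,
    score_tiles,
    shape_metrics,
    shapes_from_mask,
    tile_wsi,
)
from plaquelipid.registration import PointPairSet


class TestTiling:
    def test_single_tile_image(self):
        tiles = tile_wsi(np.zeros((64, 64, 3)), TileSpec(64, 16))
        assert len(tiles) == 1 and (tiles[0].row0, tiles[0].col0) == (0, 0)

    def test_480px_anchor_arithmetic(self):
        tiles = tile_wsi(np.zeros((480, 480, 2)), TileSpec(64, 16))
        anchors = sorted({t.row0 for t in tiles})
        assert anchors == [0, 48, 96, 144, 192, 240, 288, 336, 384, 416]
        covered = np.zeros(480, bool)
        for a in anchors:
            covered[a:a + 64] = True
        assert covered.all()

    def test_zero_overlap(self):
        tiles = tile_wsi(np.zeros((128, 128, 1)), TileSpec(64, 0))
        assert sorted({t.row0 for t in tiles}) == [0, 64]

    def test_too_small_image_errors(self):
        with pytest.raises(ValueError, match="smaller"):
            tile_wsi(np.zeros((32, 128, 1)), TileSpec(64, 16))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            TileSpec(64, 64)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(h=st.integers(64, 200), w=st.integers(64, 200),
           overlap=st.integers(0, 63))
    def test_tiles_cover_every_pixel(self, h, w, overlap):
        tiles = tile_wsi(np.zeros((h, w, 1)), TileSpec(64, overlap))
        covered = np.zeros((h, w), bool)
        for t in tiles:
            covered[t.row0:t.row0 + 64, t.col0:t.col0 + 64] = True
        assert covered.all()


class TestScoring:
    def test_constant_one_scorer(self):
        tiles = tile_wsi(np.zeros((64, 64, 2)), TileSpec(64, 16))
        out = score_tiles(tiles, lambda tile, wn: np.ones(tile.shape[:2]), None)
        assert np.all(out[0].data == 1.0)

    def test_out_of_range_scorer_rejected(self):
        tiles = tile_wsi(np.zeros((64, 64, 2)), TileSpec(64, 16))
        with pytest.raises(ValueError, match=r"outside \[0, 1\]"):
            score_tiles(tiles, lambda tile, wn: 2 * np.ones(tile.shape[:2]), None)

    def test_reference_scorer_contrast(self, qcl_lesion_scene):
        image, truth = qcl_lesion_scene
        tiles = tile_wsi(image, TileSpec(64, 16))
        scored = score_tiles(tiles, AmideShiftScorer(), image.wavenumbers)
        amap = assemble_activation(scored, image.shape)
        lesion_mean = amap.scores[truth["plaque_mask"]].mean()
        bg_mean = amap.scores[~truth["plaque_mask"]].mean()
        assert bg_mean < 0.05
        assert lesion_mean > bg_mean + 0.5


class TestAssembly:
    def test_overlap_takes_maximum(self):
        t1 = Tile(0, 0, np.full((4, 4), 0.3))
        t2 = Tile(0, 2, np.full((4, 4), 0.7))
        amap = assemble_activation([t1, t2], (4, 6))
        assert np.all(amap.scores[:, 2:4] == 0.7)
        assert np.all(amap.scores[:, :2] == 0.3)

    def test_single_tile_identity(self, rng):
        data = rng.uniform(size=(8, 8))
        amap = assemble_activation([Tile(0, 0, data)], (8, 8))
        assert np.array_equal(amap.scores, data)

    def test_uncovered_pixel_errors(self):
        with pytest.raises(ValueError, match="cover"):
            assemble_activation([Tile(0, 0, np.zeros((4, 4)))], (8, 8))

    def test_matches_brute_force_max_on_random_tilings(self, rng):
        # oracle equivalence on 100 fuzz cases
        for _ in range(100):
            h, w = rng.integers(16, 40, 2)
            n_tiles = rng.integers(3, 8)
            tiles = []
            brute = np.full((h, w), -np.inf)
            # guarantee coverage with one full-image tile
            full = rng.uniform(size=(h, w))
            tiles.append(Tile(0, 0, full))
            brute = np.maximum(brute, full)
            for _ in range(n_tiles):
                th, tw = rng.integers(4, h + 1), rng.integers(4, w + 1)
                r0 = rng.integers(0, h - th + 1)
                c0 = rng.integers(0, w - tw + 1)
                data = rng.uniform(size=(th, tw))
                tiles.append(Tile(r0, c0, data))
                brute[r0:r0 + th, c0:c0 + tw] = np.maximum(
                    brute[r0:r0 + th, c0:c0 + tw], data)
            amap = assemble_activation(tiles, (h, w))
            assert np.array_equal(amap.scores, brute)


class TestBinarize:
    def test_all_zero_map_empty(self):
        assert not binarize_activation(np.zeros((4, 4))).any()

    def test_single_hot_pixel(self):
        scores = np.zeros((4, 4))
        scores[1, 2] = 0.95
        mask = binarize_activation(ActivationMap(scores))
        assert mask.sum() == 1 and mask[1, 2]

    def test_threshold_zero_selects_everything(self):
        assert binarize_activation(np.zeros((3, 3)), threshold=0.0).all()


def _disc_mask(shape, center, radius_px):
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius_px**2


class TestMorphology:
    PX = 4.25  # QCL pixel size in um

    def test_empty_in_empty_out(self):
        out = morphological_refine(np.zeros((10, 10), bool), self.PX)
        assert not out.any()

    def test_small_object_below_100_um2_removed(self):
        mask = np.zeros((30, 30), bool)
        mask[10, 10:15] = True  # 5 px * 18.06 um^2 = 90.3 um^2 < 100
        out = morphological_refine(mask, self.PX)
        assert not out.any()

    def test_disc_survives_with_net_pixel_margin(self):
        # dilate 15 um -> 4 px, erode 10 um -> 2 px: net +2 px margin
        r_px = 20.0 / self.PX
        mask = _disc_mask((60, 60), (30, 30), r_px)
        out = morphological_refine(mask, self.PX)
        assert out.any()
        eq_radius = np.sqrt(out.sum() / np.pi)
        net = round(15.0 / self.PX) - round(10.0 / self.PX)
        assert abs(eq_radius - (np.sqrt(mask.sum() / np.pi) + net)) <= 1.0
        area_um2 = out.sum() * self.PX**2
        nominal = np.pi * (20.0 + net * self.PX) ** 2
        assert abs(area_um2 - nominal) / nominal < 0.10

    def test_holes_filled(self):
        mask = _disc_mask((60, 60), (30, 30), 8)
        mask[28:33, 28:33] = False
        out = morphological_refine(mask, self.PX)
        rows, cols = np.mgrid[0:60, 0:60]
        inner = (rows - 30) ** 2 + (cols - 30) ** 2 <= 4
        assert out[inner].all()

    def test_eccentric_bar_removed(self):
        mask = np.zeros((80, 80), bool)
        mask[40, 5:75] = True  # long thin bar stays eccentric after cascade
        out = morphological_refine(mask, self.PX)
        assert not out.any()

    def test_net_margin_nonnegative_enforced(self):
        with pytest.raises(ValueError, match="net margin"):
            MorphParams(dilate_radius=5.0, erode_radius=10.0)


class TestShapeMetrics:
    def test_disc_round_and_solid(self):
        mask = _disc_mask((50, 50), (25, 25), 15)
        area, ecc, solidity = shape_metrics(mask, 1.0)
        assert area == mask.sum()
        assert ecc < 0.1 and solidity > 0.95

    def test_bar_highly_eccentric(self):
        mask = np.zeros((30, 30), bool)
        mask[15, 5:25] = True
        _, ecc, _ = shape_metrics(mask, 1.0)
        assert ecc > 0.99

    def test_plus_sign_solidity(self):
        # plus of three 1-unit arms: hull is the bounding octagon; for a
        # thick plus made of 5 equal squares solidity -> 5/9 as blocks grow
        k = 15
        mask = np.zeros((3 * k, 3 * k), bool)
        mask[k:2 * k, :] = True
        mask[:, k:2 * k] = True
        _, _, solidity = shape_metrics(mask, 1.0)
        # convex hull of the plus is the octagon with cut corners: area
        # 9k^2 - 4 * (k^2/2) = 7k^2; solidity = 5/7
        assert solidity == pytest.approx(5.0 / 7.0, rel=0.05)

    def test_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        area, ecc, solidity = shape_metrics(mask, 2.0)
        assert area == 4.0 and ecc == 0.0 and solidity == 1.0


class TestHelmert:
    def test_identity_pairs(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1]])
        h = fit_helmert(PointPairSet(pts, pts))
        assert h.scale == pytest.approx(1.0)
        assert h.rotation == pytest.approx(0.0)
        assert np.allclose(h.translation, 0.0)

    def test_scale_two_rotation_90(self):
        pairs = PointPairSet([(0, 0), (1, 0), (0, 1)], [(5, 5), (5, 7), (3, 5)])
        h = fit_helmert(pairs)
        assert h.scale == pytest.approx(2.0, abs=1e-12)
        assert np.degrees(h.rotation) == pytest.approx(90.0, abs=1e-9)
        assert np.allclose(h.translation, (5.0, 5.0), atol=1e-12)
        assert np.allclose(h.apply(pairs.source), pairs.target, atol=1e-12)

    def test_exact_for_two_pairs(self):
        pairs = PointPairSet([(0, 0), (2, 0)], [(1, 1), (1, 5)])
        h = fit_helmert(pairs)
        assert np.allclose(h.apply(pairs.source), pairs.target, atol=1e-12)

    def test_fit_apply_round_trip_noiseless(self, rng):
        for _ in range(20):
            scale = rng.uniform(0.5, 3.0)
            theta = rng.uniform(-np.pi, np.pi)
            t = rng.uniform(-100, 100, 2)
            truth = HelmertTransform2D(scale, theta, tuple(t))
            src = rng.uniform(-50, 50, (6, 2))
            h = fit_helmert(PointPairSet(src, truth.apply(src)))
            assert np.max(np.abs(h.apply(src) - truth.apply(src))) < 1e-9
            assert np.max(np.abs(h.inverse().apply(h.apply(src)) - src)) < 1e-9

    def test_noisy_parameter_recovery(self, rng):
        truth = HelmertTransform2D(2.0, 0.3, (10.0, -5.0))
        sigma, n = 0.05, 12
        scales = []
        for _ in range(100):
            src = rng.uniform(0, 100, (n, 2))
            tgt = truth.apply(src) + rng.normal(0, sigma, (n, 2))
            scales.append(fit_helmert(PointPairSet(src, tgt)).scale)
        # scale estimate is unbiased to O(sigma/spread); 3-sigma band
        assert abs(np.mean(scales) - 2.0) < 3 * np.std(scales) / 10 + 0.01

    def test_coincident_source_points_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            fit_helmert(PointPairSet([(1, 1), (1, 1)], [(0, 0), (2, 2)]))


class TestShapes:
    def test_square_component_area(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        shapes = shapes_from_mask(mask, 4.25)
        assert len(shapes) == 1
        assert shapes.areas[0] == pytest.approx((10 * 4.25) ** 2, abs=1e-9)

    def test_identity_transform_preserves_pixel_um_coordinates(self):
        mask = np.zeros((10, 10), bool)
        mask[3:6, 4:8] = True
        shapes = shapes_from_mask(mask, 2.0)
        xs, ys = np.asarray(shapes.polygons[0].exterior.coords).T
        assert xs.min() == pytest.approx(8.0) and xs.max() == pytest.approx(16.0)
        assert ys.min() == pytest.approx(6.0) and ys.max() == pytest.approx(12.0)

    def test_total_area_additivity(self):
        mask = np.zeros((40, 40), bool)
        mask[5:10, 5:10] = True
        mask[20:30, 20:28] = True
        shapes = shapes_from_mask(mask, 1.0)
        assert shapes.areas.sum() == pytest.approx(
            sum(p.area for p in shapes.polygons))
        assert shapes.areas.sum() == pytest.approx(25.0 + 80.0)

    def test_border_touching_component_excluded(self):
        mask = np.zeros((10, 10), bool)
        mask[0:3, 0:3] = True
        mask[5:8, 5:8] = True
        with pytest.warns(UserWarning, match="border"):
            shapes = shapes_from_mask(mask, 1.0)
        assert len(shapes) == 1

    def test_helmert_transform_scales_area(self):
        mask = np.zeros((12, 12), bool)
        mask[4:8, 4:8] = True
        h = HelmertTransform2D(3.0, 0.7, (100.0, 200.0))
        shapes = shapes_from_mask(mask, 1.0, transform=h)
        assert shapes.areas[0] == pytest.approx(16.0 * 9.0, rel=1e-9)

    def test_shoelace_consistency(self):
        mask = np.zeros((30, 30), bool)
        mask[5:20, 5:15] = True
        mask[10:15, 15:25] = True  # L-shaped single component
        shapes = shapes_from_mask(mask, 1.5)
        ring = np.asarray(shapes.polygons[0].exterior.coords)
        x, y = ring[:, 0], ring[:, 1]
        shoelace = 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
        assert shapes.areas[0] == pytest.approx(shoelace, abs=1e-9)
        assert shapes.areas[0] == pytest.approx(mask.sum() * 1.5**2, abs=1e-9)


class TestExport:
    def _shapes(self):
        mask = np.zeros((20, 20), bool)
        mask[3:8, 3:9] = True
        mask[12:17, 10:16] = True
        return shapes_from_mask(mask, 4.25,
                                HelmertTransform2D(1.5, 0.2, (30.0, -12.0)))

    @pytest.mark.parametrize("fmt, reader", [("wkt", read_shapes_wkt),
                                             ("geojson", read_shapes_geojson)])
    def test_round_trip(self, tmp_path, fmt, reader):
        shapes = self._shapes()
        path = tmp_path / f"shapes.{fmt}"
        export_shapes(shapes, path, fmt=fmt)
        back = reader(path)
        assert back.source_object_ids == shapes.source_object_ids
        for a, b in zip(shapes.polygons, back.polygons):
            ca, cb = np.asarray(a.exterior.coords), np.asarray(b.exterior.coords)
            assert np.max(np.abs(ca - cb)) < 1e-6

    def test_empty_set_header_only(self, tmp_path):
        from plaquelipid.lmd import ShapeSet
        empty = ShapeSet(polygons=[], areas=np.array([]), source_object_ids=[])
        path = tmp_path / "empty.csv"
        export_shapes(empty, path, fmt="wkt")
        assert path.read_text() == "id,area_um2,wkt\n"

    def test_areas_in_file_match_shoelace_recomputation(self, tmp_path):
        shapes = self._shapes()
        path = tmp_path / "shapes.csv"
        export_shapes(shapes, path, fmt="wkt")
        back = read_shapes_wkt(path)
        for area, poly in zip(back.areas, back.polygons):
            ring = np.asarray(poly.exterior.coords)
            x, y = ring[:, 0], ring[:, 1]
            shoelace = 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
            assert area == pytest.approx(shoelace, rel=1e-9)


class TestEndToEnd:
    def test_detection_recall_and_margin_precision(self, qcl_lesion_scene):
        image, truth = qcl_lesion_scene
        amap, refined = detect_plaques(image)
        truth_mask = truth["plaque_mask"]
        net_px = round(15.0 / image.pixel_size) - round(10.0 / image.pixel_size)
        expanded = dilation(truth_mask, disk(net_px))
        recall = (refined & truth_mask).sum() / truth_mask.sum()
        precision = (refined & expanded).sum() / refined.sum()
        assert recall >= 0.9
        assert precision >= 0.9
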