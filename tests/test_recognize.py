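import numpy as np
import pytest

from earcount.config import PipelineConfig
from earcount.raster import BinaryMask, GrayImage, RgbImage
from earcount.recognize import (
    PipelineError,
    RecognitionPoint,
    count_kernels,
    eliminate_spurious,
    erosion_separation_count,
    find_local_maxima,
    gaussian_smooth,
    hough_baseline,
)
from earcount.synthetic import (
    EarFixtureSpec,
    TOPOLOGIES,
    evaluate,
    generate_ear,
    generate_touching_pair,
)

from oracles import local_maxima_oracle


def _disc_mask(shape, centre, radius):
    rr = np.arange(shape[0])[:, None] - centre[0]
    cc = np.arange(shape[1])[None, :] - centre[1]
    return BinaryMask.from_bool(rr**2 + cc**2 <= radius**2)


class TestGaussianSmooth:
    def test_impulse_peaks_at_source(self):
        px = np.zeros((15, 15), dtype=np.uint8)
        px[7, 7] = 255
        out = gaussian_smooth(BinaryMask(px), 5)
        assert np.unravel_index(np.argmax(out.pixels), out.pixels.shape) == (7, 7)

    def test_disc_peak_at_centre(self):
        # the interior saturates into a plateau; the plateau rule puts
        # the unique recognition point at the disc centre
        mask = _disc_mask((32, 32), (16, 16), 10)
        out = gaussian_smooth(mask, 11)
        pts = find_local_maxima(out, 11)
        assert len(pts) == 1
        assert abs(pts[0].row - 16) <= 1 and abs(pts[0].col - 16) <= 1

    def test_fused_discs_keep_two_maxima_with_saddle(self):
        # the mechanism that separates touching kernels: smoothing a
        # dumbbell leaves one peak per lobe and a saddle between them
        fg = _disc_mask((40, 60), (20, 20), 10).as_bool | _disc_mask(
            (40, 60), (20, 39), 10
        ).as_bool
        out = gaussian_smooth(BinaryMask.from_bool(fg), 21)
        pts = find_local_maxima(out, 15)
        assert len(pts) == 2
        mid = out.pixels[20, 29]
        assert all(p.peak_value > mid for p in pts)

    def test_even_window_rounded_up(self):
        px = np.zeros((10, 10), dtype=np.uint8)
        px[5, 5] = 255
        a = gaussian_smooth(BinaryMask(px), 6)
        b = gaussian_smooth(BinaryMask(px), 7)
        np.testing.assert_allclose(a.pixels, b.pixels)


class TestFindLocalMaxima:
    def test_single_concave_bump(self):
        rr, cc = np.meshgrid(np.arange(21), np.arange(21), indexing="ij")
        px = 200 * np.exp(-((rr - 10) ** 2 + (cc - 10) ** 2) / 30.0)
        pts = find_local_maxima(GrayImage(px), 5)
        assert len(pts) == 1
        assert (pts[0].row, pts[0].col) == (10, 10)

    def test_all_zero_image_has_no_points(self):
        assert find_local_maxima(GrayImage(np.zeros((16, 16))), 5) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_block_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(10, 65, size=2)
        block = int(rng.choice([3, 5, 7]))
        from scipy import ndimage

        px = rng.integers(0, 256, size=(h, w)).astype(float)
        px = np.clip(ndimage.gaussian_filter(px, 1.2), 0, 255)
        pts = find_local_maxima(GrayImage(px), block)
        got = sorted((int(p.row), int(p.col)) for p in pts)
        assert got == local_maxima_oracle(px, block)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_oracle_on_quantised_plateaus(self, seed):
        rng = np.random.default_rng(1000 + seed)
        px = rng.integers(0, 6, size=(24, 24)).astype(float) * 40
        pts = find_local_maxima(GrayImage(px), 5)
        got = sorted((int(p.row), int(p.col)) for p in pts)
        assert got == local_maxima_oracle(px, 5)


class TestEliminateSpurious:
    def _mk(self, coords, value=100.0):
        return [RecognitionPoint(r, c, value) for r, c in coords]

    def test_close_points_merge_to_weighted_centroid(self):
        sm = GrayImage(np.full((20, 20), 50.0))
        pts = [RecognitionPoint(10, 10, 100.0), RecognitionPoint(10, 11, 300.0)]
        out = eliminate_spurious(pts, sm, 7)
        assert len(out) == 1

    def test_distant_points_both_kept(self):
        sm = GrayImage(np.full((40, 40), 50.0))
        out = eliminate_spurious(self._mk([(5, 5), (5, 19)]), sm, 7)
        assert len(out) == 2

    def test_plateau_blob_yields_single_centred_point(self):
        fg = np.zeros((30, 30), dtype=bool)
        fg[10:20, 8:22] = True  # flat-topped blob
        sm = gaussian_smooth(BinaryMask.from_bool(fg), 7)
        pts = find_local_maxima(sm, 7)
        out = eliminate_spurious(pts, sm, 7)
        assert len(out) == 1
        assert out[0].row == pytest.approx(14.5, abs=0.6)
        assert out[0].col == pytest.approx(14.5, abs=0.6)

    def test_idempotent_and_min_distance(self):
        rng = np.random.default_rng(4)
        sm = GrayImage(np.full((64, 64), 10.0))
        pts = self._mk(rng.uniform(0, 63, size=(30, 2)))
        once = eliminate_spurious(pts, sm, 9)
        twice = eliminate_spurious(once, sm, 9)
        assert len(twice) == len(once)
        coords = np.array([(p.row, p.col) for p in once])
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                assert np.linalg.norm(coords[i] - coords[j]) >= 4.5 - 1e-9

    def test_output_never_larger(self):
        sm = GrayImage(np.full((30, 30), 10.0))
        pts = self._mk([(3, 3), (3, 4), (20, 20), (22, 21)])
        assert len(eliminate_spurious(pts, sm, 7)) <= len(pts)


class TestCountKernels:
    def test_nontouching_grid_counted_exactly(self, nontouching_ear):
        spec, img, truth = nontouching_ear
        res = count_kernels(img)
        assert res.count == truth.n_kernels == 40
        ev = evaluate(res.points, truth, match_radius=0.5 * spec.kernel_width)
        assert ev.n_correct == truth.n_kernels

    def test_blank_background_counts_zero(self):
        px = np.zeros((128, 128, 3), dtype=np.uint8)
        px[...] = (40, 55, 175)
        with pytest.warns(UserWarning):
            res = count_kernels(RgbImage(px))
        assert res.count == 0 and res.points == []

    def test_count_equals_points_and_deterministic(self, gradient_ear):
        _, img, _ = gradient_ear
        a = count_kernels(img)
        b = count_kernels(img)
        assert a.count == len(a.points) == b.count
        for p, q in zip(a.points, b.points):
            assert (p.row, p.col) == (q.row, q.col)

    def test_touching_pairs_counted_as_two(self):
        for topo in TOPOLOGIES:
            img, truth, _ = generate_touching_pair(topo)
            with pytest.warns(UserWarning):  # MBR falls back on 2-kernel image
                res = count_kernels(img)
            assert res.count == 2, topo

    def test_illumination_offset_robustness(self, nontouching_ear):
        _, img, truth = nontouching_ear
        base = count_kernels(img).count
        for off in (-30, 30):
            shifted = RgbImage(
                np.clip(img.pixels.astype(int) + off, 0, 255).astype(np.uint8)
            )
            assert count_kernels(shifted).count == base

    def test_stage_error_carries_stage_name(self):
        img = RgbImage(np.zeros((100, 100, 3), dtype=np.uint8))
        cfg = PipelineConfig(blocksize=999)  # larger than the G2 layer
        with pytest.raises(PipelineError, match="adaptive_threshold"), pytest.warns(
            UserWarning
        ):
            px = np.zeros((100, 100, 3), dtype=np.uint8)
            px[...] = (40, 55, 175)
            px[30:70, 30:70] = (230, 200, 75)
            count_kernels(RgbImage(px), cfg)

    def test_points_mapped_to_original_scale(self, nontouching_ear):
        spec, img, truth = nontouching_ear
        res = count_kernels(img)
        pts = np.array([(p.row, p.col) for p in res.points])
        assert pts[:, 0].max() < img.height and pts[:, 1].max() < img.width
        # every point lies within half a kernel width of a true centre
        for p in pts:
            d = np.hypot(truth.centres[:, 0] - p[0], truth.centres[:, 1] - p[1])
            assert d.min() <= 0.5 * spec.kernel_width


class TestHoughBaseline:
    def test_single_circle_found(self):
        px = np.full((64, 64), 40.0)
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        px[(rr - 32) ** 2 + (cc - 32) ** 2 <= 10**2] = 220.0
        pts = hough_baseline(GrayImage(px), None, r_min=7, r_max=13)
        assert len(pts) >= 1
        best = min(pts, key=lambda p: (p.row - 32) ** 2 + (p.col - 32) ** 2)
        assert abs(best.row - 32) <= 2 and abs(best.col - 32) <= 2

    def test_low_roundness_ellipse_miscounted(self):
        # axis ratio 2: the baseline is allowed to miss it or split it,
        # which is precisely the failure the local-maxima method avoids
        px = np.full((64, 64), 40.0)
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        px[((rr - 32) / 20) ** 2 + ((cc - 32) / 10) ** 2 <= 1] = 220.0
        pts = hough_baseline(GrayImage(px), None, r_min=7, r_max=13)
        assert len(pts) != 1 or True  # any count tolerated for the baseline

    def test_empty_image_no_points(self):
        pts = hough_baseline(GrayImage(np.zeros((32, 32))), None, 5, 9)
        assert pts == []

    def test_bad_radii_rejected(self):
        with pytest.raises(ValueError):
            hough_baseline(GrayImage(np.zeros((16, 16))), None, 9, 5)


class TestErosionBaseline:
    def test_separates_corner_contacts_only(self):
        results = {}
        for topo in TOPOLOGIES:
            _, _, mask = generate_touching_pair(topo)
            results[topo] = erosion_separation_count(mask)
        assert results["corner_corner"] == 2
        assert results["edge_corner"] == 2
        assert results["edge_edge"] == 1  # fails: blob vanishes unsplit

    def test_disjoint_blobs_report_two(self):
        fg = np.zeros((30, 30), dtype=bool)
        fg[5:12, 5:12] = True
        fg[18:25, 18:25] = True
        assert erosion_separation_count(BinaryMask.from_bool(fg)) == 2
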