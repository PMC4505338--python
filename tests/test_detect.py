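"""Detection, FWHM sizing, mask morphometry, density."""

import numpy as np
import pytest

from temweb import (
    CensoredSizeError,
    Cluster,
    ClusterMap,
    SheetImage,
    SyntheticSpec,
    annotate_clusters,
    cluster_density,
    exclude_edges,
    generate_sheet,
    measure_fwhm,
    render_spots,
    segment_masks,
)

PITCH = 20.0


def flat_sheet(shape=(100, 100), level=10.0):
    return SheetImage(channels={"ch1": np.full(shape, level)}, pixel_pitch_nm=PITCH)


class TestExcludeEdges:
    def test_zero_margin_is_identity(self):
        img = flat_sheet()
        assert exclude_edges(img, 0).mask.sum() == img.mask.sum()

    def test_square_field_geometry(self):
        # 10x10 um full-true mask, 500 nm margin -> (10-1)^2 = 81 um^2
        img = flat_sheet(shape=(500, 500))
        out = exclude_edges(img, 500.0)
        assert out.mask_area_um2 == pytest.approx(81.0)

    def test_overlarge_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            exclude_edges(flat_sheet(shape=(50, 50)), 600.0)


class TestAnnotate:
    def test_pure_background_finds_nothing(self):
        spec = SyntheticSpec(field_width_um=5, field_height_um=5,
                             density_ch1=0, density_ch2=0, seed=2)
        image, _ = generate_sheet(spec)
        assert len(annotate_clusters(image, "ch1")) == 0

    def test_well_separated_spots_all_found_to_a_pixel(self, rng):
        # 49 spots on a 1-um grid, realistic brightness, shot noise
        xy = np.array([[x, y] for x in range(1, 8) for y in range(1, 8)]) * 1000.0
        grid = render_spots((400, 400), PITCH, xy, 120.0, 2000.0,
                            psf_fwhm_nm=50.0, background=5.0)
        img = SheetImage(channels={"ch1": rng.poisson(grid).astype(float)},
                         pixel_pitch_nm=PITCH)
        found = annotate_clusters(img, "ch1")
        assert len(found) == 49
        from scipy.spatial import cKDTree

        d, _ = cKDTree(found.centers_nm()).query(xy)
        assert d.max() <= 20.0  # one pixel

    def test_unresolvable_pair_merges_into_one(self):
        # two clusters 60 nm apart with 100 nm FWHM cannot be split
        grid = render_spots((150, 150), PITCH, [[1470, 1500], [1530, 1500]],
                            100.0, 3000.0, psf_fwhm_nm=50.0, background=5.0)
        img = SheetImage(channels={"ch1": grid}, pixel_pitch_nm=PITCH)
        assert len(annotate_clusters(img, "ch1")) == 1

    def test_missing_channel_raises(self):
        with pytest.raises(KeyError, match="ch9"):
            annotate_clusters(flat_sheet(), "ch9")

    def test_scale_invariance_of_detection(self, independent_sheet):
        """Multiplying the image by a constant changes nothing: the
        threshold is background-relative."""
        _, image, _ = independent_sheet
        base = annotate_clusters(image, "ch1")
        scaled = SheetImage(
            channels={"ch1": image.channels["ch1"] * 3.0},
            pixel_pitch_nm=image.pixel_pitch_nm,
        )
        out = annotate_clusters(scaled, "ch1")
        assert len(out) == len(base)
        np.testing.assert_allclose(out.centers_nm(), base.centers_nm())


class TestFWHM:
    def cluster_at(self, x, y):
        return Cluster(x_nm=x, y_nm=y, peak=0.0, channel="ch1")

    def test_pure_gaussian_analytic_width(self):
        # sigma = 42.47 nm -> FWHM 100 nm, no PSF, no noise
        grid = render_spots((150, 150), PITCH, [[1500, 1500]], 100.0, 5000.0,
                            background=2.0)
        img = SheetImage(channels={"ch1": grid}, pixel_pitch_nm=PITCH)
        w = measure_fwhm(img, self.cluster_at(1500, 1500))
        assert w == pytest.approx(100.0, rel=0.03)

    def test_psf_convolution_closed_form(self):
        # true 96 nm convolved with 50 nm PSF -> sqrt(96^2+50^2) = 108.2 nm
        grid = render_spots((150, 150), PITCH, [[1500, 1500]], 96.0, 5000.0,
                            psf_fwhm_nm=50.0, background=2.0)
        img = SheetImage(channels={"ch1": grid}, pixel_pitch_nm=PITCH)
        w = measure_fwhm(img, self.cluster_at(1500, 1500))
        assert w == pytest.approx(np.hypot(96.0, 50.0), rel=0.05)

    def test_flat_image_is_censored(self):
        with pytest.raises(CensoredSizeError):
            measure_fwhm(flat_sheet(), self.cluster_at(1000, 1000))


class TestMasksAndShape:
    def disc_image(self, radius_px=10):
        yy, xx = np.indices((80, 80))
        disc = (xx - 40) ** 2 + (yy - 40) ** 2 <= radius_px**2
        grid = np.where(disc, 100.0, 1.0)
        return SheetImage(channels={"ch1": grid}, pixel_pitch_nm=PITCH)

    def test_disc_is_circular(self):
        shapes = segment_masks(self.disc_image(), "ch1")
        assert len(shapes) == 1
        area, circ = shapes[0]
        assert circ >= 0.95
        assert area == pytest.approx(np.pi * (10 * PITCH / 1000) ** 2, rel=0.05)

    def test_bar_is_elongated(self):
        grid = np.ones((60, 60))
        grid[30, 20:40] = 100.0
        img = SheetImage(channels={"ch1": grid}, pixel_pitch_nm=PITCH)
        shapes = segment_masks(img, "ch1", min_pixels=4)
        assert len(shapes) == 1
        assert shapes[0][1] < 0.4

    def test_merged_pair_is_larger_and_less_circular(self):
        single = render_spots((150, 150), PITCH, [[1500, 1500]], 150.0, 5000.0,
                              background=2.0)
        merged = render_spots((150, 150), PITCH,
                              [[1400, 1500], [1600, 1500]], 150.0, 5000.0,
                              background=2.0)
        img_s = SheetImage(channels={"ch1": single}, pixel_pitch_nm=PITCH)
        img_m = SheetImage(channels={"ch1": merged}, pixel_pitch_nm=PITCH)
        (area_s, circ_s), = segment_masks(img_s, "ch1")
        shapes_m = segment_masks(img_m, "ch1")
        assert len(shapes_m) == 1  # 200 nm apart: merged detection
        area_m, circ_m = shapes_m[0]
        assert area_m >= 0.025
        assert area_m > area_s
        assert circ_m < circ_s

    def test_reported_shapes_are_valid(self, independent_sheet):
        _, image, _ = independent_sheet
        for area, circ in segment_masks(image, "ch1"):
            assert 0.0 <= circ <= 1.0
            assert area > 0.0


class TestDensity:
    def make_map(self, n, area):
        clusters = [Cluster(x_nm=i * 100.0, y_nm=0.0, peak=1.0, channel="ch1")
                    for i in range(n)]
        return ClusterMap(clusters=clusters, analyzed_area_um2=area, channel="ch1")

    def test_simple_arithmetic(self):
        assert cluster_density(self.make_map(44, 10.0)) == pytest.approx(4.4)

    def test_empty_map_zero_density(self):
        assert cluster_density(self.make_map(0, 10.0)) == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            self.make_map(5, 0.0)
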