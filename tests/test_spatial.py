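"""Nearest-neighbor statistics and the analytic Poisson null."""

import numpy as np
import pytest
from scipy import integrate, stats

from temweb import (
    ClusterMap,
    Cluster,
    NNDistribution,
    SheetImage,
    analytic_nn_cdf,
    analytic_nn_mean_nm,
    analytic_nn_median_nm,
    analytic_nn_pdf,
    expected_overlap_pct,
    fit_random_distribution,
    nn_distances,
    overlap_fraction,
    pearson_per_sheet,
)


def point_map(xy, area=100.0, channel="ch1", field=(10000.0, 10000.0)):
    clusters = [Cluster(x_nm=float(x), y_nm=float(y), peak=1.0, channel=channel)
                for x, y in np.atleast_2d(xy)]
    return ClusterMap(clusters=clusters, analyzed_area_um2=area,
                      channel=channel, field_size_nm=field)


class TestAnalyticLaw:
    @pytest.mark.parametrize("rho", [0.5, 1.0, 4.4, 5.0])
    def test_pdf_normalization(self, rho):
        total, _ = integrate.quad(lambda r: analytic_nn_pdf(rho, r), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("rho", [0.5, 4.4])
    def test_mean_and_median_closed_forms(self, rho):
        mean_num, _ = integrate.quad(
            lambda r: r * analytic_nn_pdf(rho, r), 0, np.inf
        )
        assert analytic_nn_mean_nm(rho) == pytest.approx(mean_num, rel=1e-8)
        med = analytic_nn_median_nm(rho)
        assert analytic_nn_cdf(rho, med) == pytest.approx(0.5, abs=1e-12)

    def test_reference_values_at_density_4p4(self):
        assert analytic_nn_mean_nm(4.4) == pytest.approx(238.4, abs=0.1)
        assert analytic_nn_median_nm(4.4) == pytest.approx(224.0, abs=0.5)

    def test_pdf_zero_at_origin_and_rejects_bad_input(self):
        assert analytic_nn_pdf(4.4, 0.0) == 0.0
        with pytest.raises(ValueError):
            analytic_nn_pdf(0.0, 10.0)
        with pytest.raises(ValueError):
            analytic_nn_pdf(1.0, -1.0)


class TestNNDistances:
    def test_same_species_pair(self):
        m = point_map([[0, 0], [100, 0]])
        d = nn_distances(m, m, same_species=True)
        np.testing.assert_allclose(sorted(d.distances_nm), [100.0, 100.0])

    def test_coincident_cross_channel_is_zero(self):
        ref = point_map([[500, 500]])
        tgt = point_map([[500, 500], [900, 900]], channel="ch2")
        d = nn_distances(ref, tgt)
        assert d.distances_nm[0] == 0.0

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError, match="target"):
            nn_distances(point_map([[0, 0]]), point_map(np.empty((0, 2))))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        xy_ref = rng.uniform(2000, 8000, (30, 2))
        xy_tgt = rng.uniform(2000, 8000, (40, 2))
        base = nn_distances(point_map(xy_ref), point_map(xy_tgt, channel="ch2"))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        shift = np.array([123.0, -456.0])
        moved = nn_distances(
            point_map(xy_ref @ rot.T + shift),
            point_map(xy_tgt @ rot.T + shift, channel="ch2"),
        )
        np.testing.assert_allclose(
            np.sort(moved.distances_nm), np.sort(base.distances_nm), rtol=1e-9
        )

    def test_minus_sampling_keeps_interior_references_only(self):
        ref = point_map([[100, 5000], [5000, 5000]])
        tgt = point_map([[0, 5000], [5000, 5200]], channel="ch2")
        d = nn_distances(ref, tgt, border_margin_nm=500.0)
        # the reference at x=100 nm is inside the margin and dropped, but
        # margin targets still serve as neighbors
        assert d.n_reference == 1
        assert d.distances_nm[0] == pytest.approx(200.0)

    def test_margin_without_geometry_errors(self):
        m = point_map([[0, 0], [100, 0]], field=None)
        with pytest.raises(ValueError, match="margin"):
            nn_distances(m, m, same_species=True, border_margin_nm=100.0)


class TestRandomFit:
    def sample_law(self, rho, n, rng):
        u = rng.uniform(size=n)
        return np.sqrt(-np.log1p(-u) / (np.pi * rho / 1e6))

    def make_dist(self, distances, rho):
        edges = np.arange(0, 1020, 20.0)
        counts, _ = np.histogram(distances, edges)
        return NNDistribution(distances, edges, counts, "ch1", "ch1", rho)

    def test_accepts_its_own_law(self, rng):
        d = self.make_dist(self.sample_law(4.4, 500, rng), 4.4)
        assert fit_random_distribution(d).p_value > 0.01

    def test_rejects_clustered_alternative(self, rng):
        # co-centered-like data: most distances near zero
        d = self.make_dist(np.abs(rng.normal(0, 20, 500)), 4.4)
        fit = fit_random_distribution(d)
        assert fit.p_value < 1e-6

    def test_small_sample_refused(self, rng):
        d = self.make_dist(self.sample_law(4.4, 10, rng), 4.4)
        with pytest.raises(ValueError, match="at least 20"):
            fit_random_distribution(d)


class TestOverlap:
    def test_trivial_cases(self, rng):
        edges = np.arange(0, 1020, 20.0)
        all_zero = NNDistribution(np.zeros(10), edges, None, "a", "b", 1.0)
        all_zero.counts, _ = np.histogram(all_zero.distances_nm, edges)
        assert overlap_fraction(all_zero) == 100.0
        single = NNDistribution(np.array([150.0]), edges, None, "a", "b", 1.0)
        assert overlap_fraction(single, 100.0) == 0.0

    def test_monotone_in_threshold(self, rng):
        d = NNDistribution(rng.uniform(0, 500, 200), np.arange(0, 1020, 20.0),
                           None, "a", "b", 1.0)
        fracs = [overlap_fraction(d, x) for x in np.linspace(0, 600, 25)]
        assert np.all(np.diff(fracs) >= 0)

    def test_expected_overlap_closed_form(self):
        # 1 - exp(-pi * 5 um^-2 * (0.1 um)^2) = 14.54 %
        assert expected_overlap_pct(5.0, 100.0) == pytest.approx(14.54, abs=0.01)


class TestPearson:
    def test_self_and_negated(self, rng):
        a = rng.poisson(10, (50, 50)).astype(float)
        img = SheetImage(channels={"a": a, "b": a, "c": -a}, pixel_pitch_nm=20)
        assert pearson_per_sheet(img, "a", "b") == pytest.approx(1.0)
        assert pearson_per_sheet(img, "a", "c") == pytest.approx(-1.0)

    def test_independent_channels_near_zero(self, independent_sheet):
        _, image, _ = independent_sheet
        assert image.mask.sum() >= 1e5
        assert abs(pearson_per_sheet(image, "ch1", "ch2")) < 0.1

    def test_zero_variance_rejected(self):
        img = SheetImage(channels={"a": np.ones((10, 10)),
                                   "b": np.ones((10, 10))}, pixel_pitch_nm=20)
        with pytest.raises(ValueError, match="variance"):
            pearson_per_sheet(img, "a", "b")
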