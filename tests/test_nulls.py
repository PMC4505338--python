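"""Mock-image null ensemble: construction, provenance, calibration, power."""

import numpy as np
import pytest

from temweb import (
    Cluster,
    ClusterMap,
    NullEnsembleSpec,
    SyntheticSpec,
    analyze_ensemble,
    build_mock_ensemble,
    cluster_map_from_truth,
    compare_to_null,
    generate_sheet,
    nn_distances,
    spec_from_observed,
)
from temweb.spatial import default_bin_edges


def fake_map(n, area, channel, fwhm=120.0):
    rng = np.random.default_rng(n)
    clusters = [
        Cluster(x_nm=x, y_nm=y, peak=1.0, channel=channel, fwhm_nm=fwhm)
        for x, y in rng.uniform(0, 1000 * np.sqrt(area), (n, 2))
    ]
    return ClusterMap(clusters=clusters, analyzed_area_um2=area, channel=channel)


class TestSpecFromObserved:
    def test_single_map_density(self):
        spec = spec_from_observed(
            {"a": [fake_map(44, 10.0, "a")], "b": [fake_map(30, 10.0, "b")]}
        )
        assert spec.density_ch1 == pytest.approx(4.4)

    def test_density_is_mean_over_sheets(self):
        spec = spec_from_observed(
            {"a": [fake_map(40, 10.0, "a"), fake_map(50, 10.0, "a")],
             "b": [fake_map(10, 10.0, "b")]}
        )
        assert spec.density_ch1 == pytest.approx(4.5)

    def test_fwhm_sample_is_pooled_concatenation(self):
        m1, m2 = fake_map(5, 10.0, "a", fwhm=100.0), fake_map(7, 10.0, "a", fwhm=140.0)
        spec = spec_from_observed({"a": [m1, m2], "b": [fake_map(3, 10.0, "b")]})
        assert sorted(spec.fwhm_sample_ch1) == sorted(
            np.concatenate([m1.fwhms_nm(), m2.fwhms_nm()])
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            spec_from_observed({"a": [], "b": [fake_map(3, 10.0, "b")]})


class TestEnsemble:
    def small_spec(self, n_images=3):
        return NullEnsembleSpec(
            density_ch1=2.0, density_ch2=2.0, n_images=n_images,
            field_width_um=5.0, field_height_um=5.0, seed=7,
        )

    def test_fixed_seed_reproduces_ensemble(self):
        e1 = build_mock_ensemble(self.small_spec())
        e2 = build_mock_ensemble(self.small_spec())
        for (im1, _), (im2, _) in zip(e1, e2):
            np.testing.assert_array_equal(im1.channels["ch1"], im2.channels["ch1"])

    def test_zero_images_rejected(self):
        with pytest.raises(ValueError):
            NullEnsembleSpec(density_ch1=1, density_ch2=1, n_images=0)

    def test_pooled_realized_density_concentrates(self):
        spec = NullEnsembleSpec(
            density_ch1=4.4, density_ch2=0.0, n_images=10,
            field_width_um=20.0, field_height_um=20.0, seed=1,
        )
        ensemble = build_mock_ensemble(spec)
        n = sum(t.n_clusters("ch1") for _, t in ensemble)
        area = sum(t.field_area_um2 for _, t in ensemble)
        assert n / area == pytest.approx(4.4, rel=0.05)


class TestCompare:
    def truth_dists(self, coupling, seed0, n_mock=8, rho=3.0, **kw):
        """Observed + mock NN distributions computed on ground truth."""
        obs_spec = SyntheticSpec(
            field_width_um=20, field_height_um=20, density_ch1=rho,
            density_ch2=rho, coupling=coupling, shot_noise=False,
            seed=seed0, **kw,
        )
        _, truth = generate_sheet(obs_spec)
        bins = default_bin_edges()
        observed = nn_distances(
            cluster_map_from_truth(truth, "ch2"),
            cluster_map_from_truth(truth, "ch1"),
            bin_edges_nm=bins,
        )
        nspec = NullEnsembleSpec(
            density_ch1=truth.density_per_um2("ch1"),
            density_ch2=truth.density_per_um2("ch2"),
            n_images=n_mock, field_width_um=20, field_height_um=20,
            seed=seed0 + 1,
            generator_kwargs={"shot_noise": False},
        )
        nulls = analyze_ensemble(
            build_mock_ensemble(nspec), "ch2", "ch1",
            use_truth=True, bin_edges_nm=bins,
        )
        return observed, nulls

    def test_truth_provenance_is_refused_by_default(self):
        observed, nulls = self.truth_dists("independent", seed0=3, n_mock=2, rho=1.0)
        with pytest.raises(ValueError, match="ground-truth"):
            compare_to_null(observed, nulls)

    def test_bin_mismatch_rejected(self):
        observed, nulls = self.truth_dists("independent", seed0=3, n_mock=2, rho=1.0)
        observed.bin_edges_nm = observed.bin_edges_nm[:-2]
        with pytest.raises(ValueError, match="bin"):
            compare_to_null(observed, nulls, allow_truth=True)

    def test_null_observed_shows_no_excess(self):
        observed, nulls = self.truth_dists("independent", seed0=21, rho=4.0)
        cmp_ = compare_to_null(observed, nulls, allow_truth=True)
        p = cmp_.null_overlap_pct / 100.0
        se_obs = 100.0 * np.sqrt(p * (1 - p) / cmp_.n_observed)
        assert abs(cmp_.excess_pct) <= 2 * se_obs + cmp_.null_overlap_sd_pct
        assert cmp_.p_value > 0.01

    def test_offset_alternative_is_detected(self):
        observed, nulls = self.truth_dists(
            "offset", seed0=5, offset_mean_nm=150.0, offset_sd_nm=30.0
        )
        # the 150 nm offset puts most partners just beyond 100 nm, so the
        # excess is judged below 200 nm (where nearly every partner falls)
        cmp_ = compare_to_null(observed, nulls, d_nm=200.0, allow_truth=True)
        assert cmp_.excess_pct > 10.0
        assert cmp_.p_value < 0.01

    def test_co_centered_overlap_approaches_100(self):
        observed, nulls = self.truth_dists("co_centered", seed0=9)
        cmp_ = compare_to_null(observed, nulls, allow_truth=True)
        assert cmp_.observed_overlap_pct > 99.0
        assert cmp_.observed_overlap_pct - cmp_.null_overlap_pct > 50.0
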