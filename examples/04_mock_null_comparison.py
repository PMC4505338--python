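"""Cross-channel proximity against a Monte-Carlo mock-image null.

Channel 2 clusters are placed ~150 nm from channel 1 clusters (adjacent
but not overlapping domains).  Both channels are detected from the image,
then compared to 10 mock images with the same detected densities and size
distributions but completely random, uncorrelated placements — the
Monte-Carlo null for "are these proteins near each other?".
"""

from temweb import (
    SyntheticSpec,
    annotate_clusters,
    compare_to_null,
    exclude_edges,
    generate_sheet,
    mock_null_distributions,
    nn_distances,
    spec_from_observed,
)
from temweb.spatial import default_bin_edges

bins = default_bin_edges()
spec = SyntheticSpec(
    field_width_um=20, field_height_um=20, density_ch1=1.5, density_ch2=1.5,
    coupling="offset", offset_mean_nm=150.0, offset_sd_nm=50.0,
    photons_per_molecule=2000, seed=13,
)
image, _ = generate_sheet(spec)
trimmed = exclude_edges(image, 500.0)
ref = annotate_clusters(trimmed, "ch2")
tgt = annotate_clusters(trimmed, "ch1")
observed = nn_distances(ref, tgt, border_margin_nm=500.0, image=trimmed,
                        bin_edges_nm=bins)

nspec = spec_from_observed({"ch2": [ref], "ch1": [tgt]}, n_images=10,
                           field_width_um=20, field_height_um=20, seed=14)
nulls = mock_null_distributions(nspec, "ch2", "ch1", edge_margin_nm=500.0,
                                border_margin_nm=500.0, bin_edges_nm=bins)

for d in (100.0, 200.0):
    cmp_ = compare_to_null(observed, nulls, d_nm=d)
    print(f"within {d:.0f} nm: observed {cmp_.observed_overlap_pct:.1f}% vs "
          f"null {cmp_.null_overlap_pct:.1f}% -> excess {cmp_.excess_pct:+.1f} points")
cmp_ = compare_to_null(observed, nulls)
print(f"KS observed vs pooled null: D = {cmp_.ks_stat:.3f}, p = {cmp_.p_value:.2e}")
# Adjacent coupling shows little excess at 100 nm (the domains do not
# overlap) but a large excess by 200 nm and a decisive KS rejection —
# proximity without colocalization.
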