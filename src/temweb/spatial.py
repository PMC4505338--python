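"""Nearest-neighbor spatial statistics and the analytic random null.

For a homogeneous 2D Poisson process of density ρ, the distance r from a
point to its nearest neighbor follows

    p(r) = 2πρ r exp(-πρ r²)

(complete spatial randomness).  Observed within- or cross-channel
nearest-neighbor distance distributions are compared against this law at
the density measured independently from the same image, and against a
100 nm center-to-center criterion for "(partly) overlapping" clusters.
Distances are in nm throughout; densities in clusters·μm⁻².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .detect import ClusterMap, SheetImage, boundary_distance_nm

__all__ = [
    "NNDistribution",
    "RandomFitReport",
    "nn_distances",
    "analytic_nn_pdf",
    "analytic_nn_cdf",
    "analytic_nn_mean_nm",
    "analytic_nn_median_nm",
    "expected_overlap_pct",
    "fit_random_distribution",
    "overlap_fraction",
    "pearson_per_sheet",
    "default_bin_edges",
]

NM2_PER_UM2 = 1e6


def default_bin_edges(max_nm: float = 1000.0, width_nm: float = 20.0) -> np.ndarray:
    """Histogram bins for NN distances: one-pixel (20 nm) bins to 1 μm."""
    return np.arange(0.0, max_nm + width_nm, width_nm)


@dataclass
class NNDistribution:
    """Nearest-neighbor distances from a reference to a target channel."""

    distances_nm: np.ndarray
    bin_edges_nm: np.ndarray
    counts: np.ndarray
    ref_channel: str
    target_channel: str
    rho_target_per_um2: float
    image_id: str = ""
    source: str = "pipeline"  # "truth" when computed from simulator coordinates
    ref_xy_nm: np.ndarray | None = None  # (n, 2) surviving reference centers

    @property
    def n_reference(self) -> int:
        return len(self.distances_nm)

    def __post_init__(self) -> None:
        self.distances_nm = np.asarray(self.distances_nm, dtype=float)
        if (self.distances_nm < 0).any():
            raise ValueError("NN distances must be >= 0")
        if self.rho_target_per_um2 < 0:
            raise ValueError("target density must be >= 0")


def _margin_keep(
    reference: ClusterMap,
    border_margin_nm: float,
    image: SheetImage | None,
) -> np.ndarray:
    xy = reference.centers_nm()
    if border_margin_nm <= 0 or len(xy) == 0:
        return np.ones(len(xy), dtype=bool)
    if image is not None:
        dist = boundary_distance_nm(image.mask, image.pixel_pitch_nm)
        pitch = image.pixel_pitch_nm
        ny, nx = image.mask.shape
        i = np.clip(np.round(xy[:, 1] / pitch).astype(int), 0, ny - 1)
        j = np.clip(np.round(xy[:, 0] / pitch).astype(int), 0, nx - 1)
        return dist[i, j] >= border_margin_nm
    if reference.field_size_nm is None:
        raise ValueError(
            "border margin requested but neither an image mask nor a field size "
            "is available for the reference map"
        )
    w, h = reference.field_size_nm
    m = border_margin_nm
    return (
        (xy[:, 0] >= m) & (xy[:, 0] <= w - m) & (xy[:, 1] >= m) & (xy[:, 1] <= h - m)
    )


def nn_distances(
    reference: ClusterMap,
    target: ClusterMap,
    same_species: bool = False,
    border_margin_nm: float = 0.0,
    image: SheetImage | None = None,
    bin_edges_nm: np.ndarray | None = None,
) -> NNDistribution:
    """Center-to-center nearest-neighbor distances, reference → target.

    Edge correction is minus-sampling: reference clusters closer than
    ``border_margin_nm`` to the mask (or field) boundary are dropped, but
    every target cluster — including those inside the margin — remains a
    candidate neighbor, so near-boundary distances are not inflated.
    With ``same_species`` the reference map is also the target map and each
    cluster's zero-distance self-match is excluded.
    """
    ref_xy = reference.centers_nm()
    tgt_xy = target.centers_nm()
    min_target = 2 if same_species else 1
    if len(tgt_xy) < min_target:
        raise ValueError(
            f"target map has {len(tgt_xy)} clusters; need >= {min_target}"
        )
    keep = _margin_keep(reference, border_margin_nm, image)
    if not keep.any():
        raise ValueError("all reference clusters fall inside the border margin")
    ref_xy = ref_xy[keep]
    tree = cKDTree(tgt_xy)
    if same_species:
        d, _ = tree.query(ref_xy, k=2)
        dist = d[:, 1]
    else:
        dist, _ = tree.query(ref_xy, k=1)
    if bin_edges_nm is None:
        bin_edges_nm = default_bin_edges()
    counts, _ = np.histogram(dist, bins=bin_edges_nm)
    return NNDistribution(
        distances_nm=dist,
        bin_edges_nm=np.asarray(bin_edges_nm, dtype=float),
        counts=counts,
        ref_channel=reference.channel,
        target_channel=target.channel,
        rho_target_per_um2=target.density_per_um2,
        image_id=reference.image_id,
        source="truth" if "truth" in (reference.source, target.source) else "pipeline",
        ref_xy_nm=ref_xy,
    )


def analytic_nn_pdf(rho_per_um2: float, r_nm) -> np.ndarray:
    """Nearest-neighbor distance density (per nm) under complete spatial
    randomness at density ρ: 2πρ r exp(-πρ r²)."""
    if rho_per_um2 <= 0:
        raise ValueError("density must be > 0")
    r = np.asarray(r_nm, dtype=float)
    if (r < 0).any():
        raise ValueError("r must be >= 0")
    rho_nm = rho_per_um2 / NM2_PER_UM2
    return 2.0 * np.pi * rho_nm * r * np.exp(-np.pi * rho_nm * r**2)


def analytic_nn_cdf(rho_per_um2: float, r_nm) -> np.ndarray:
    """P(nearest neighbor <= r) = 1 - exp(-πρ r²) under the Poisson null."""
    if rho_per_um2 <= 0:
        raise ValueError("density must be > 0")
    r = np.asarray(r_nm, dtype=float)
    if (r < 0).any():
        raise ValueError("r must be >= 0")
    rho_nm = rho_per_um2 / NM2_PER_UM2
    return 1.0 - np.exp(-np.pi * rho_nm * r**2)


def analytic_nn_mean_nm(rho_per_um2: float) -> float:
    """Mean NN distance under the Poisson null: 1 / (2 √ρ), in nm."""
    if rho_per_um2 <= 0:
        raise ValueError("density must be > 0")
    return 1000.0 / (2.0 * np.sqrt(rho_per_um2))


def analytic_nn_median_nm(rho_per_um2: float) -> float:
    """Median NN distance under the Poisson null: sqrt(ln 2 / (πρ)), in nm."""
    if rho_per_um2 <= 0:
        raise ValueError("density must be > 0")
    return 1000.0 * np.sqrt(np.log(2.0) / (np.pi * rho_per_um2))


def expected_overlap_pct(rho_per_um2: float, d_nm: float = 100.0) -> float:
    """Expected % of references within d of an independent target cluster."""
    return 100.0 * float(analytic_nn_cdf(rho_per_um2, d_nm))


@dataclass
class RandomFitReport:
    """Goodness of fit of observed NN distances to the fixed-ρ Poisson law."""

    rho_per_um2: float
    n: int
    ks_stat: float
    p_value: float
    expected_counts: np.ndarray
    note: str = (
        "KS statistic against the analytic CSR law at the independently "
        "measured density (quantitative extension of a visual curve overlay)"
    )


def fit_random_distribution(dist: NNDistribution, min_n: int = 20) -> RandomFitReport:
    """Compare observed NN distances to the analytic random law at fixed ρ.

    The density is taken from the distribution's independently measured
    target density — it is not a free fit parameter.  Reports the
    Kolmogorov–Smirnov statistic and p-value plus expected per-bin counts
    for overlaying the analytic curve on the histogram.
    """
    if dist.n_reference < min_n:
        raise ValueError(
            f"need at least {min_n} reference clusters, got {dist.n_reference}"
        )
    rho = dist.rho_target_per_um2
    if rho <= 0:
        raise ValueError("target density must be > 0 for the analytic null")
    res = stats.kstest(dist.distances_nm, lambda r: analytic_nn_cdf(rho, r))
    edges = dist.bin_edges_nm
    cdf = analytic_nn_cdf(rho, edges)
    expected = dist.n_reference * np.diff(cdf)
    return RandomFitReport(
        rho_per_um2=rho,
        n=dist.n_reference,
        ks_stat=float(res.statistic),
        p_value=float(res.pvalue),
        expected_counts=expected,
    )


def overlap_fraction(dist: NNDistribution, d_nm: float = 100.0) -> float:
    """% of reference clusters whose nearest target center lies within d.

    The 100 nm default is the center-to-center criterion for calling two
    ~100 nm clusters "(partly) overlapping"."""
    if dist.n_reference < 1:
        raise ValueError("empty distance distribution")
    return 100.0 * float(np.mean(dist.distances_nm <= d_nm))


def pearson_per_sheet(image: SheetImage, ch_a: str, ch_b: str) -> float:
    """Pearson correlation of raw pixel intensities over mask pixels only."""
    a = image.channel(ch_a)[image.mask]
    b = image.channel(ch_b)[image.mask]
    if a.size < 2:
        raise ValueError("need at least two mask pixels")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance channel: Pearson r undefined")
    return float(np.corrcoef(a, b)[0, 1])
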