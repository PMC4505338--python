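"""Synthetic membrane-sheet generator with ground truth.

Emulates flat plasma-membrane sheets carrying diffraction-limited protein
nanoclusters, as seen by ~50 nm-resolution STED microscopy at 20 nm pixel
pitch: cluster centers follow a homogeneous 2D Poisson process (densities
0.5-5 μm⁻² in the real data), each cluster is an isotropic Gaussian spot
whose integrated signal is proportional to its molecule count (~3.5
molecules on average), the image is the analytic convolution with a
Gaussian PSF, and Poisson shot noise plus a uniform background is added.

A second channel can be generated independent of the first (the
complete-spatial-randomness null), co-centered with it (same protein seen
by two antibodies), or displaced from it by a random-angle offset
(adjacent-but-distinct domains).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .detect import GAUSS_FWHM_PER_SIGMA, SheetImage

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_sheet",
    "truth_nn_distances",
    "cluster_map_from_truth",
    "render_spots",
]

Coupling = Literal["independent", "co_centered", "offset"]


@dataclass
class SyntheticSpec:
    """Parameters of one simulated dual-channel membrane sheet.

    Densities are clusters·μm⁻²; all lengths are nm except the field size
    (μm).  ``density_ch2`` is ignored for the co_centered and offset
    couplings, where every channel-1 cluster spawns one channel-2 cluster.
    ``min_separation_nm`` > 0 applies hard-core thinning within each
    independently placed channel (useful for resolvability-controlled
    detection tests); 0 keeps the pure Poisson process.
    """

    field_width_um: float = 20.0
    field_height_um: float = 20.0
    pixel_pitch_nm: float = 20.0
    density_ch1: float = 4.4
    density_ch2: float = 0.0
    cluster_fwhm_mean_nm: float = 120.0
    cluster_fwhm_sd_nm: float = 25.0
    molecules_per_cluster_mean: float = 3.5
    psf_fwhm_nm: float = 50.0
    photons_per_molecule: float = 500.0
    background_level: float = 5.0
    coupling: Coupling = "independent"
    offset_mean_nm: float = 0.0
    offset_sd_nm: float = 0.0
    min_separation_nm: float = 0.0
    shot_noise: bool = True
    seed: int = 0
    max_clusters: int = 500_000
    channel_names: tuple[str, str] = ("ch1", "ch2")
    fwhm_sample_ch1: np.ndarray | None = None
    fwhm_sample_ch2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field size must be positive")
        if self.pixel_pitch_nm <= 0:
            raise ValueError("pixel_pitch_nm must be > 0")
        if self.density_ch1 < 0 or self.density_ch2 < 0:
            raise ValueError("densities must be >= 0")
        if self.cluster_fwhm_mean_nm <= 0 or self.psf_fwhm_nm <= 0:
            raise ValueError("FWHM values must be > 0")
        if self.molecules_per_cluster_mean < 1:
            raise ValueError("mean molecules per cluster must be >= 1")
        if self.coupling not in ("independent", "co_centered", "offset"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.coupling == "offset" and self.offset_mean_nm < 0:
            raise ValueError("offset coupling requires offset_mean_nm >= 0")

    @property
    def field_area_um2(self) -> float:
        return self.field_width_um * self.field_height_um

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        for k in ("fwhm_sample_ch1", "fwhm_sample_ch2"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        d["channel_names"] = list(self.channel_names)
        return d


@dataclass
class GroundTruth:
    """True cluster centers (nm), FWHMs and molecule counts per channel."""

    channels: dict[str, np.ndarray]  # structured: x_nm, y_nm, fwhm_nm, molecules
    field_area_um2: float
    field_size_nm: tuple[float, float] | None = None  # (width, height)

    def centers_nm(self, channel: str) -> np.ndarray:
        t = self.channels[channel]
        return np.column_stack([t["x_nm"], t["y_nm"]])

    def n_clusters(self, channel: str) -> int:
        return len(self.channels[channel])

    def density_per_um2(self, channel: str) -> float:
        return self.n_clusters(channel) / self.field_area_um2

    def to_records(self) -> list[dict]:
        rows = []
        for ch, t in self.channels.items():
            for r in t:
                rows.append(
                    {
                        "channel": ch,
                        "x_nm": float(r["x_nm"]),
                        "y_nm": float(r["y_nm"]),
                        "fwhm_nm": float(r["fwhm_nm"]),
                        "molecules": int(r["molecules"]),
                    }
                )
        return rows


_TRUTH_DTYPE = np.dtype(
    [("x_nm", float), ("y_nm", float), ("fwhm_nm", float), ("molecules", int)]
)


def _truth_table(xy: np.ndarray, fwhm: np.ndarray, mol: np.ndarray) -> np.ndarray:
    t = np.empty(len(xy), dtype=_TRUTH_DTYPE)
    t["x_nm"], t["y_nm"] = xy[:, 0], xy[:, 1]
    t["fwhm_nm"], t["molecules"] = fwhm, mol
    return t


def _draw_fwhm(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    sample: np.ndarray | None,
) -> np.ndarray:
    if sample is not None:
        sample = np.asarray(sample, dtype=float)
        if sample.size == 0:
            raise ValueError("empirical FWHM sample is empty")
        return rng.choice(sample, size=n, replace=True)
    if sd <= 0:
        return np.full(n, mean)
    # truncated normal: redraw until positive
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def _hardcore_thin(xy: np.ndarray, r_min: float, rng: np.random.Generator) -> np.ndarray:
    """Sequential hard-core thinning: keep points >= r_min from all kept ones."""
    if len(xy) == 0 or r_min <= 0:
        return xy
    order = rng.permutation(len(xy))
    kept: list[int] = []
    kept_xy = np.empty((0, 2))
    for idx in order:
        p = xy[idx]
        if len(kept) == 0 or np.min(np.hypot(*(kept_xy - p).T)) >= r_min:
            kept.append(idx)
            kept_xy = np.vstack([kept_xy, p])
    return xy[np.sort(kept)]


def _poisson_centers(
    rng: np.random.Generator,
    density_per_um2: float,
    lo: np.ndarray,
    hi: np.ndarray,
    max_clusters: int,
) -> np.ndarray:
    area_um2 = float(np.prod((hi - lo) / 1000.0))
    expected = density_per_um2 * area_um2
    if expected > max_clusters:
        raise ValueError(
            f"expected cluster count {expected:.0f} exceeds cap {max_clusters}"
        )
    n = rng.poisson(expected)
    return rng.uniform(lo, hi, size=(n, 2))


def _render(
    shape: tuple[int, int],
    pitch: float,
    xy: np.ndarray,
    fwhm: np.ndarray,
    mol: np.ndarray,
    psf_fwhm: float,
    photons_per_molecule: float,
    background: float,
) -> np.ndarray:
    """Sum of Gaussian spots (already convolved with the Gaussian PSF)."""
    img = np.full(shape, float(background))
    ny, nx = shape
    sigma_psf = psf_fwhm / GAUSS_FWHM_PER_SIGMA
    for (x, y), f, m in zip(xy, fwhm, mol):
        sigma = float(np.hypot(f / GAUSS_FWHM_PER_SIGMA, sigma_psf))
        total = m * photons_per_molecule
        half = 4.0 * sigma
        j_lo = max(int(np.floor((x - half) / pitch)), 0)
        j_hi = min(int(np.ceil((x + half) / pitch)), nx - 1)
        i_lo = max(int(np.floor((y - half) / pitch)), 0)
        i_hi = min(int(np.ceil((y + half) / pitch)), ny - 1)
        if j_lo > j_hi or i_lo > i_hi:
            continue
        xs = np.arange(j_lo, j_hi + 1) * pitch
        ys = np.arange(i_lo, i_hi + 1) * pitch
        gx = np.exp(-0.5 * ((xs - x) / sigma) ** 2)
        gy = np.exp(-0.5 * ((ys - y) / sigma) ** 2)
        amp = total * pitch**2 / (2.0 * np.pi * sigma**2)
        img[i_lo : i_hi + 1, j_lo : j_hi + 1] += amp * np.outer(gy, gx)
    return img


def render_spots(
    shape: tuple[int, int],
    pixel_pitch_nm: float,
    xy_nm: np.ndarray,
    fwhm_nm,
    total_photons,
    psf_fwhm_nm: float = 0.0,
    background: float = 0.0,
) -> np.ndarray:
    """Render isotropic Gaussian spots of known FWHM onto a grid (no noise).

    With ``psf_fwhm_nm`` > 0 the spots are analytically convolved with a
    Gaussian PSF, so their rendered width is sqrt(fwhm² + psf²).  Useful
    for constructing exactly known test images.
    """
    xy = np.atleast_2d(np.asarray(xy_nm, dtype=float))
    n = len(xy)
    fwhm = np.broadcast_to(np.asarray(fwhm_nm, dtype=float), (n,))
    photons = np.broadcast_to(np.asarray(total_photons, dtype=float), (n,))
    psf = max(psf_fwhm_nm, 1e-9)
    return _render(
        shape, pixel_pitch_nm, xy, fwhm, photons, psf, 1.0, background
    )


def generate_sheet(spec: SyntheticSpec) -> tuple[SheetImage, GroundTruth]:
    """Simulate one dual-channel membrane sheet and its ground truth.

    Centers are drawn in a field padded by 3× the mean cluster FWHM and
    then cropped, so intensity near the field border is unbiased; the
    returned ground truth lists only clusters whose centers fall inside
    the field.  Per-stage random substreams are derived deterministically
    from ``spec.seed``, so a fixed seed reproduces the sheet bit for bit.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_place1, rng_place2, rng_marks1, rng_marks2, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    pitch = spec.pixel_pitch_nm
    nx = max(int(round(spec.field_width_um * 1000.0 / pitch)), 2)
    ny = max(int(round(spec.field_height_um * 1000.0 / pitch)), 2)
    w_nm, h_nm = (nx - 1) * pitch, (ny - 1) * pitch
    pad = 3.0 * spec.cluster_fwhm_mean_nm
    lo = np.array([-pad, -pad])
    hi = np.array([w_nm + pad, h_nm + pad])

    xy1 = _poisson_centers(rng_place1, spec.density_ch1, lo, hi, spec.max_clusters)
    xy1 = _hardcore_thin(xy1, spec.min_separation_nm, rng_place1)
    if spec.coupling == "independent":
        xy2 = _poisson_centers(rng_place2, spec.density_ch2, lo, hi, spec.max_clusters)
        xy2 = _hardcore_thin(xy2, spec.min_separation_nm, rng_place2)
        parent = None
    elif spec.coupling == "co_centered":
        xy2 = xy1.copy()
        parent = np.arange(len(xy1))
    else:  # offset
        d = np.abs(rng_place2.normal(spec.offset_mean_nm, spec.offset_sd_nm, len(xy1)))
        theta = rng_place2.uniform(0.0, 2.0 * np.pi, len(xy1))
        xy2 = xy1 + np.column_stack([d * np.cos(theta), d * np.sin(theta)])
        parent = np.arange(len(xy1))

    ch1, ch2 = spec.channel_names
    tables: dict[str, np.ndarray] = {}
    grids: dict[str, np.ndarray] = {}
    for name, xy, rng_marks, sample in (
        (ch1, xy1, rng_marks1, spec.fwhm_sample_ch1),
        (ch2, xy2, rng_marks2, spec.fwhm_sample_ch2),
    ):
        fwhm = _draw_fwhm(
            rng_marks, len(xy), spec.cluster_fwhm_mean_nm, spec.cluster_fwhm_sd_nm, sample
        )
        mol = 1 + rng_marks.poisson(spec.molecules_per_cluster_mean - 1.0, size=len(xy))
        grid = _render(
            (ny, nx),
            pitch,
            xy,
            fwhm,
            mol,
            spec.psf_fwhm_nm,
            spec.photons_per_molecule,
            spec.background_level,
        )
        if spec.shot_noise:
            grid = rng_noise.poisson(grid).astype(float)
        grids[name] = grid
        inside = (
            (xy[:, 0] >= 0.0)
            & (xy[:, 0] <= w_nm)
            & (xy[:, 1] >= 0.0)
            & (xy[:, 1] <= h_nm)
        )
        tables[name] = _truth_table(xy[inside], fwhm[inside], mol[inside])

    image = SheetImage(
        channels=grids,
        pixel_pitch_nm=pitch,
        image_id=f"synthetic-seed{spec.seed}",
    )
    truth = GroundTruth(
        channels=tables,
        field_area_um2=w_nm * h_nm / 1e6,
        field_size_nm=(w_nm, h_nm),
    )
    return image, truth


def cluster_map_from_truth(truth: GroundTruth, channel: str):
    """Build a ClusterMap directly from simulator ground truth.

    The map is flagged ``source="truth"`` so null comparisons that require
    detection-pipeline provenance will refuse it unless explicitly allowed.
    """
    from .detect import Cluster, ClusterMap

    t = truth.channels[channel]
    area = truth.field_area_um2
    if truth.field_size_nm is not None:
        field_size = truth.field_size_nm
    else:
        side = 1000.0 * np.sqrt(area)
        field_size = (side, side)
    clusters = [
        Cluster(
            x_nm=float(r["x_nm"]),
            y_nm=float(r["y_nm"]),
            peak=float(r["molecules"]),
            channel=channel,
            fwhm_nm=float(r["fwhm_nm"]),
        )
        for r in t
    ]
    return ClusterMap(
        clusters=clusters,
        analyzed_area_um2=area,
        channel=channel,
        image_id="truth",
        source="truth",
        field_size_nm=field_size,
    )


def truth_nn_distances(truth: GroundTruth, channel: str) -> np.ndarray:
    """Same-channel nearest-neighbor distances (nm) between true centers.

    Returns an empty array when the channel holds fewer than two clusters.
    This is the image-free oracle for the spatial statistics: it sees the
    simulator's exact coordinates, bypassing detection entirely.
    """
    xy = truth.centers_nm(channel)
    if len(xy) < 2:
        return np.empty(0)
    from scipy.spatial import cKDTree

    d, _ = cKDTree(xy).query(xy, k=2)
    return d[:, 1]
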