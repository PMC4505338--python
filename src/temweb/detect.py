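"""Cluster detection and morphometry on membrane-sheet images.

Clusters are diffraction-limited spots (~90-170 nm FWHM after convolution
with a ~50 nm STED point-spread function) sitting on a roughly uniform
background.  Detection is deliberately simple and transparent: a robust
background-relative intensity threshold followed by connected-component
blob detection and intensity-weighted centroids.  Sizes are measured as
the full width at half maximum (FWHM) of orthogonal line profiles through
the peak; per-cluster masks at the 50 %-of-peak contour give area and
circularity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours

__all__ = [
    "SheetImage",
    "Cluster",
    "ClusterMap",
    "CensoredSizeError",
    "exclude_edges",
    "background_stats",
    "annotate_clusters",
    "measure_fwhm",
    "segment_masks",
    "measure_clusters",
    "cluster_density",
    "boundary_distance_nm",
]

GAUSS_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


class CensoredSizeError(RuntimeError):
    """The intensity profile never falls below half maximum inside the mask."""


@dataclass
class SheetImage:
    """A membrane sheet: one 2D photon-count grid per channel plus a mask.

    Coordinates are in nm with the origin at the top-left pixel center,
    x rightward (columns) and y downward (rows); pixel (i, j) covers a
    ``pixel_pitch_nm`` square centered on (j * pitch, i * pitch).
    """

    channels: dict[str, np.ndarray]
    pixel_pitch_nm: float
    mask: np.ndarray | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_pitch_nm <= 0:
            raise ValueError("pixel_pitch_nm must be > 0")
        if not self.channels:
            raise ValueError("SheetImage needs at least one channel")
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.mask is None:
            self.mask = np.ones(first, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != first:
                raise ValueError("mask shape does not match channels")
        if not self.mask.any():
            raise ValueError("sheet mask is empty")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def mask_area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_pitch_nm**2 / 1e6

    @property
    def field_size_nm(self) -> tuple[float, float]:
        ny, nx = self.shape
        return ((nx - 1) * self.pixel_pitch_nm, (ny - 1) * self.pixel_pitch_nm)

    def channel(self, name: str) -> np.ndarray:
        try:
            return np.asarray(self.channels[name], dtype=float)
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in image (have {sorted(self.channels)})"
            ) from None


@dataclass
class Cluster:
    """A single annotated nanocluster."""

    x_nm: float
    y_nm: float
    peak: float
    channel: str
    n_pixels: int = 0
    fwhm_nm: float = float("nan")
    area_um2: float = float("nan")
    circularity: float = float("nan")


@dataclass
class ClusterMap:
    """All clusters of one channel of one sheet, plus the analyzed area."""

    clusters: list[Cluster]
    analyzed_area_um2: float
    channel: str
    image_id: str = ""
    source: str = "pipeline"  # "truth" when built from simulator ground truth
    field_size_nm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.analyzed_area_um2 <= 0:
            raise ValueError("analyzed area must be > 0")

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def density_per_um2(self) -> float:
        return len(self.clusters) / self.analyzed_area_um2

    def centers_nm(self) -> np.ndarray:
        """(n, 2) array of cluster centers, columns (x, y) in nm."""
        if not self.clusters:
            return np.empty((0, 2))
        return np.array([[c.x_nm, c.y_nm] for c in self.clusters])

    def fwhms_nm(self) -> np.ndarray:
        return np.array([c.fwhm_nm for c in self.clusters])

    def to_records(self) -> list[dict]:
        return [
            {
                "image_id": self.image_id,
                "channel": c.channel,
                "x_nm": c.x_nm,
                "y_nm": c.y_nm,
                "peak": c.peak,
                "fwhm_nm": c.fwhm_nm,
                "area_um2": c.area_um2,
                "circularity": c.circularity,
            }
            for c in self.clusters
        ]


def boundary_distance_nm(mask: np.ndarray, pixel_pitch_nm: float) -> np.ndarray:
    """Distance (nm) from each pixel to the nearest outside-mask pixel.

    The region outside the image counts as outside the mask, so the field
    border is treated like a mask edge.
    """
    padded = np.pad(np.asarray(mask, dtype=bool), 1, constant_values=False)
    return ndimage.distance_transform_edt(padded)[1:-1, 1:-1] * pixel_pitch_nm


def exclude_edges(image: SheetImage, margin_nm: float) -> SheetImage:
    """Erode the analyzable mask by ``margin_nm`` (sheet edges are unreliable).

    The erosion uses a square structuring element (Chebyshev metric), so a
    margin of m nm removes an m-wide band along straight mask edges.
    """
    if margin_nm < 0:
        raise ValueError("margin must be >= 0")
    margin_px = int(round(margin_nm / image.pixel_pitch_nm))
    if margin_px == 0:
        return image
    size = 2 * margin_px + 1
    new_mask = ndimage.minimum_filter(
        image.mask, size=size, mode="constant", cval=False
    )
    if not new_mask.any():
        raise ValueError(
            f"edge margin of {margin_nm:g} nm leaves no analyzable pixels"
        )
    return replace(image, mask=new_mask)


def background_stats(image: SheetImage, channel: str) -> tuple[float, float]:
    """Robust background (median, SD) from mask pixels.

    The spread is a MAD-based SD estimated from the pixels at or below the
    median, so bright clusters (a few percent of pixels) cannot inflate it.
    """
    vals = image.channel(channel)[image.mask]
    med = float(np.median(vals))
    lower = vals[vals <= med]
    sd = 1.4826 * float(np.median(med - lower))
    return med, sd


def annotate_clusters(
    image: SheetImage,
    channel: str,
    offset_k: float = 3.0,
    min_pixels: int = 9,
) -> ClusterMap:
    """Threshold + blob detection: annotate cluster centers on one channel.

    Pixels brighter than ``background median + offset_k * robust SD`` inside
    the mask are grouped into 8-connected components; components with fewer
    than ``min_pixels`` pixels are discarded; each surviving blob yields one
    :class:`Cluster` at its intensity-weighted (background-subtracted)
    centroid.  Overlapping blobs merge into a single detection; no watershed
    splitting is attempted.
    """
    img = image.channel(channel)
    med, sd = background_stats(image, channel)
    threshold = med + offset_k * sd
    above = (img > threshold) & image.mask
    if above.sum() == image.mask.sum():
        raise ValueError(
            "degenerate threshold: every mask pixel is above background"
        )
    labels, n_blobs = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    pitch = image.pixel_pitch_nm
    clusters: list[Cluster] = []
    if n_blobs:
        counts = np.bincount(labels.ravel())[1:]
        weights = np.clip(img - med, 0.0, None)
        # intensity-weighted centroids of all blobs at once
        wsum = ndimage.sum_labels(weights, labels, index=np.arange(1, n_blobs + 1))
        yy, xx = np.indices(img.shape)
        cy = ndimage.sum_labels(weights * yy, labels, np.arange(1, n_blobs + 1))
        cx = ndimage.sum_labels(weights * xx, labels, np.arange(1, n_blobs + 1))
        peaks = ndimage.maximum(img, labels, np.arange(1, n_blobs + 1))
        for k in range(n_blobs):
            if counts[k] < min_pixels or wsum[k] <= 0:
                continue
            x_nm = float(cx[k] / wsum[k] * pitch)
            y_nm = float(cy[k] / wsum[k] * pitch)
            i, j = int(round(y_nm / pitch)), int(round(x_nm / pitch))
            ny, nx = img.shape
            if not image.mask[min(max(i, 0), ny - 1), min(max(j, 0), nx - 1)]:
                continue
            clusters.append(
                Cluster(
                    x_nm=x_nm,
                    y_nm=y_nm,
                    peak=float(peaks[k]),
                    channel=channel,
                    n_pixels=int(counts[k]),
                )
            )
    return ClusterMap(
        clusters=clusters,
        analyzed_area_um2=image.mask_area_um2,
        channel=channel,
        image_id=image.image_id,
        field_size_nm=image.field_size_nm,
    )


def _half_crossings(profile: np.ndarray, j0: int, half: float) -> tuple[float, float]:
    """Walk outward from index j0; return interpolated half-max crossings."""
    left = None
    for j in range(j0, 0, -1):
        if profile[j - 1] < half <= profile[j]:
            frac = (profile[j] - half) / (profile[j] - profile[j - 1])
            left = j - frac
            break
        if np.isnan(profile[j - 1]):
            break
    right = None
    n = len(profile)
    for j in range(j0, n - 1):
        if profile[j + 1] < half <= profile[j]:
            frac = (profile[j] - half) / (profile[j] - profile[j + 1])
            right = j + frac
            break
        if np.isnan(profile[j + 1]):
            break
    if left is None or right is None:
        raise CensoredSizeError(
            "intensity profile does not fall below half maximum inside the mask"
        )
    return left, right


def measure_fwhm(image: SheetImage, cluster: Cluster, search_px: int = 2) -> float:
    """FWHM (nm) of a cluster from two orthogonal profiles through its peak.

    The image is first smoothed with a 3×3 boxcar: measuring on the raw
    pixels would let the noise-inflated maximum set the half-max level and
    bias the width low by up to ~20% at realistic photon counts.  The peak
    is located within a small window around the annotated center, the
    background (mask median) is subtracted, and each half-maximum crossing
    is found by linear interpolation along the smoothed row and column
    through the peak.  The known smoothing variance (pitch²·(3²−1)/12 per
    axis) is then removed analytically, so Gaussian spots are recovered
    without bias.  The reported size is the mean of the two widths; note it
    still contains the instrument PSF (measured ≈ sqrt(true² + psf²) for
    Gaussian spots).
    """
    img = image.channel(cluster.channel)
    med, _ = background_stats(image, cluster.channel)
    smooth = ndimage.uniform_filter(img, size=3, mode="nearest")
    ny, nx = img.shape
    pitch = image.pixel_pitch_nm
    i0 = min(max(int(round(cluster.y_nm / pitch)), 0), ny - 1)
    j0 = min(max(int(round(cluster.x_nm / pitch)), 0), nx - 1)
    window = smooth[
        max(i0 - search_px, 0) : i0 + search_px + 1,
        max(j0 - search_px, 0) : j0 + search_px + 1,
    ]
    di, dj = np.unravel_index(np.argmax(window), window.shape)
    i0 = max(i0 - search_px, 0) + int(di)
    j0 = max(j0 - search_px, 0) + int(dj)
    peak = smooth[i0, j0] - med
    if peak <= 0:
        raise CensoredSizeError("cluster peak is not above local background")
    half = peak / 2.0

    row = np.where(image.mask[i0, :], smooth[i0, :] - med, np.nan)
    col = np.where(image.mask[:, j0], smooth[:, j0] - med, np.nan)
    lx, rx = _half_crossings(row, j0, half)
    ly, ry = _half_crossings(col, i0, half)
    w_smoothed = ((rx - lx) + (ry - ly)) / 2.0 * pitch
    kernel_var = pitch**2 * (3**2 - 1) / 12.0  # boxcar-3 variance per axis
    w_sq = w_smoothed**2 - GAUSS_FWHM_PER_SIGMA**2 * kernel_var
    if w_sq <= 0:
        raise CensoredSizeError(
            "profile narrower than the smoothing kernel; size unresolvable"
        )
    return float(np.sqrt(w_sq))


def segment_masks(
    image: SheetImage,
    channel: str,
    cluster_map: ClusterMap | None = None,
    offset_k: float = 3.0,
    min_pixels: int = 9,
) -> list[tuple[float, float]]:
    """Per-cluster (area in μm², circularity) from 50 %-of-peak masks.

    Each detected blob is re-thresholded locally at half its peak above
    background (the FWHM contour), the connected region containing the peak
    is kept, and circularity = 4π·area / perimeter² (Crofton perimeter) is
    clipped to [0, 1].
    """
    if cluster_map is None:
        cluster_map = annotate_clusters(image, channel, offset_k, min_pixels)
    img = image.channel(channel)
    med, _ = background_stats(image, channel)
    pitch = image.pixel_pitch_nm
    ny, nx = img.shape
    out: list[tuple[float, float]] = []
    for c in cluster_map.clusters:
        i0 = min(max(int(round(c.y_nm / pitch)), 0), ny - 1)
        j0 = min(max(int(round(c.x_nm / pitch)), 0), nx - 1)
        # grow a window until the 50%-of-peak region no longer touches it
        half_r = 8
        while True:
            sl = (
                slice(max(i0 - half_r, 0), min(i0 + half_r + 1, ny)),
                slice(max(j0 - half_r, 0), min(j0 + half_r + 1, nx)),
            )
            patch = img[sl]
            local_thr = med + 0.5 * (patch.max() - med)
            region = patch > local_thr
            labels, _ = ndimage.label(region, structure=np.ones((3, 3), dtype=int))
            lab = labels[i0 - sl[0].start, j0 - sl[1].start]
            if lab == 0:
                # peak pixel below local threshold (flat blob): use whole region
                blob = region
            else:
                blob = labels == lab
            touches = (
                (blob[0, :].any() and sl[0].start > 0)
                or (blob[-1, :].any() and sl[0].stop < ny)
                or (blob[:, 0].any() and sl[1].start > 0)
                or (blob[:, -1].any() and sl[1].stop < nx)
            )
            if not touches or half_r > max(ny, nx):
                break
            half_r *= 2
        area_px = int(blob.sum())
        area_um2 = area_px * pitch**2 / 1e6
        perim_px = _traced_perimeter(blob)
        circ = 1.0 if perim_px == 0 else min(1.0, 4.0 * np.pi * area_px / perim_px**2)
        out.append((area_um2, float(circ)))
    return out


def _traced_perimeter(blob: np.ndarray) -> float:
    """Boundary length (px) of a binary blob from its traced 0.5-level
    contour.

    The raw marching-squares polygon overestimates smooth boundaries by
    ~7% (staircase effect), so the closed contour is smoothed with a short
    moving average along its arc before measuring; this recovers disc and
    ellipse perimeters to ~1% without visibly shrinking corners of
    elongated shapes.
    """
    padded = np.pad(blob.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return 0.0
    longest = max(contours, key=len)[:-1]  # drop duplicated closing vertex
    if len(longest) < 3:
        return float(len(longest))
    smooth = np.column_stack(
        [
            ndimage.uniform_filter1d(longest[:, 0], 5, mode="wrap"),
            ndimage.uniform_filter1d(longest[:, 1], 5, mode="wrap"),
        ]
    )
    closed = np.vstack([smooth, smooth[:1]])
    return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))


def measure_clusters(
    image: SheetImage,
    channel: str,
    offset_k: float = 3.0,
    min_pixels: int = 9,
) -> ClusterMap:
    """Detect clusters and fill in FWHM, area and circularity for each.

    Clusters whose profile is censored (never drops below half max inside
    the mask) keep ``fwhm_nm = nan`` rather than aborting the whole sheet.
    """
    cmap = annotate_clusters(image, channel, offset_k, min_pixels)
    shapes = segment_masks(image, channel, cmap)
    for c, (area, circ) in zip(cmap.clusters, shapes):
        c.area_um2 = area
        c.circularity = circ
        try:
            c.fwhm_nm = measure_fwhm(image, c)
        except CensoredSizeError:
            c.fwhm_nm = float("nan")
    return cmap


def cluster_density(cluster_map: ClusterMap) -> float:
    """Clusters per μm² of analyzed membrane."""
    return cluster_map.density_per_um2
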