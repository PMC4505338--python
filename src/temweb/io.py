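"""File interchange: multi-page TIFF images, CSV tables, JSON sidecars.

Images travel as 16-bit grayscale TIFF, one page per channel; masks as a
single-page TIFF of 0/1.  All tabular outputs are plain CSV and all
metadata JSON, so every artifact is inspectable with standard tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detect import Cluster, ClusterMap, SheetImage
from .synth import GroundTruth, SyntheticSpec, _TRUTH_DTYPE

__all__ = [
    "read_sheet_tiff",
    "write_sheet_tiff",
    "write_mask_tiff",
    "write_truth_csv",
    "read_truth_csv",
    "write_clusters_csv",
    "read_cluster_maps",
    "write_summary_csv",
    "save_synthetic",
]


def read_sheet_tiff(
    path,
    pixel_pitch_nm: float = 20.0,
    channel_names: list[str] | None = None,
    mask_path=None,
    image_id: str | None = None,
) -> SheetImage:
    """Read a multi-page grayscale TIFF as a SheetImage (one page = one
    channel).  The mask defaults to all-true; a mask TIFF (nonzero =
    analyzable) can be supplied."""
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except Exception as e:  # noqa: BLE001 - surface the path in the message
        raise IOError(f"cannot read TIFF {path}: {e}") from e
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise IOError(f"{path}: expected 2D pages, got shape {pages.shape}")
    if channel_names is None:
        channel_names = [f"ch{i + 1}" for i in range(len(pages))]
    if len(channel_names) != len(pages):
        raise ValueError(
            f"{len(channel_names)} channel names for {len(pages)} pages"
        )
    mask = None
    if mask_path is not None:
        mask = tifffile.imread(Path(mask_path)) > 0
    return SheetImage(
        channels={n: pages[i].astype(float) for i, n in enumerate(channel_names)},
        pixel_pitch_nm=pixel_pitch_nm,
        mask=mask,
        image_id=image_id or path.stem,
    )


def write_sheet_tiff(image: SheetImage, path) -> None:
    """Write a SheetImage as a 16-bit multi-page TIFF (counts clipped to
    the uint16 range)."""
    stack = np.stack(
        [
            np.clip(np.round(np.asarray(a, dtype=float)), 0, 65535).astype(np.uint16)
            for a in image.channels.values()
        ]
    )
    tifffile.imwrite(Path(path), stack)


def write_mask_tiff(mask: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), mask.astype(np.uint8))


def write_truth_csv(truth: GroundTruth, path) -> None:
    pd.DataFrame(truth.to_records()).to_csv(Path(path), index=False)


def read_truth_csv(path, field_area_um2: float, field_size_nm=None) -> GroundTruth:
    df = pd.read_csv(Path(path))
    channels = {}
    for ch, g in df.groupby("channel"):
        t = np.empty(len(g), dtype=_TRUTH_DTYPE)
        t["x_nm"] = g["x_nm"].to_numpy()
        t["y_nm"] = g["y_nm"].to_numpy()
        t["fwhm_nm"] = g["fwhm_nm"].to_numpy()
        t["molecules"] = g["molecules"].to_numpy()
        channels[str(ch)] = t
    return GroundTruth(
        channels=channels, field_area_um2=field_area_um2, field_size_nm=field_size_nm
    )


def write_clusters_csv(maps: list[ClusterMap], path) -> None:
    """Per-cluster table plus the per-map analyzed area (needed to rebuild
    densities when reading back)."""
    rows = []
    for m in maps:
        w, h = m.field_size_nm if m.field_size_nm is not None else (np.nan, np.nan)
        extra = {
            "analyzed_area_um2": m.analyzed_area_um2,
            "field_w_nm": w,
            "field_h_nm": h,
        }
        for rec in m.to_records():
            rows.append(rec | extra)
        if not m.clusters:
            rows.append({"image_id": m.image_id, "channel": m.channel} | extra)
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_cluster_maps(path) -> list[ClusterMap]:
    df = pd.read_csv(Path(path))
    maps = []
    for (image_id, channel), g in df.groupby(["image_id", "channel"], sort=False):
        clusters = [
            Cluster(
                x_nm=r.x_nm,
                y_nm=r.y_nm,
                peak=getattr(r, "peak", 0.0),
                channel=str(channel),
                fwhm_nm=getattr(r, "fwhm_nm", float("nan")),
                area_um2=getattr(r, "area_um2", float("nan")),
                circularity=getattr(r, "circularity", float("nan")),
            )
            for r in g.itertuples()
            if np.isfinite(getattr(r, "x_nm", float("nan")))
        ]
        field = None
        if "field_w_nm" in g and np.isfinite(g["field_w_nm"].iloc[0]):
            field = (float(g["field_w_nm"].iloc[0]), float(g["field_h_nm"].iloc[0]))
        maps.append(
            ClusterMap(
                clusters=clusters,
                analyzed_area_um2=float(g["analyzed_area_um2"].iloc[0]),
                channel=str(channel),
                image_id=str(image_id),
                field_size_nm=field,
            )
        )
    return maps


def write_summary_csv(maps: list[ClusterMap], path) -> None:
    rows = [
        {
            "image_id": m.image_id,
            "channel": m.channel,
            "n_clusters": len(m),
            "area_um2": m.analyzed_area_um2,
            "density_per_um2": m.density_per_um2,
        }
        for m in maps
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def save_synthetic(
    image: SheetImage, truth: GroundTruth, spec: SyntheticSpec, prefix
) -> dict[str, Path]:
    """Write image TIFF + ground-truth CSV + a JSON sidecar echoing the
    full generator spec and seed; returns the written paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": prefix.with_suffix(".tif"),
        "truth": Path(str(prefix) + "_truth.csv"),
        "spec": Path(str(prefix) + "_spec.json"),
    }
    write_sheet_tiff(image, paths["image"])
    write_truth_csv(truth, paths["truth"])
    with open(paths["spec"], "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2, sort_keys=True)
    return paths
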