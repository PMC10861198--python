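"""Nuclear segmentation from the nuclear-stain channel.

Foreground requires a pixel to pass BOTH a global Otsu threshold and a
sliding-window local Otsu threshold (the conservative intersection, which
suppresses large dim autofluorescent regions).  Connected components are
8-connected, hole-filled, then filtered on area and mean intensity.

Coordinate convention (used package-wide): centroids are Cartesian
micrometres with the origin at the image's lower-left corner, x rightward
and y upward (image row 0 is the top); orientations are axial degrees
counterclockwise from +x.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import rank, threshold_otsu
from skimage.measure import label as sk_label

from .axial import wrap_axial

log = logging.getLogger(__name__)

__all__ = ["NucleusRecord", "segment_nuclei", "records_from_labels", "records_to_frame",
           "write_records", "read_records"]


@dataclass
class NucleusRecord:
    """One segmented nucleus."""

    id: int
    centroid: tuple[float, float]  # (x, y) micrometres, y-up
    pixel_mask: tuple[np.ndarray, np.ndarray]  # (rows, cols) index arrays
    area: float  # square micrometres
    mean_intensity: float
    orientation: float  # axial degrees in (-90, 90], CCW from +x

    def __post_init__(self):
        if self.area <= 0:
            raise ValueError("area must be > 0")
        if not -90.0 < self.orientation <= 90.0:
            raise ValueError("orientation must be in (-90, 90]")


def _mask_orientation(rows: np.ndarray, cols: np.ndarray) -> float:
    """Long-axis direction of a pixel set, axial degrees CCW from +x (y-up)."""
    x = cols.astype(float)
    y = -rows.astype(float)  # y-up; offset irrelevant for central moments
    mu_xx = np.var(x)
    mu_yy = np.var(y)
    mu_xy = np.mean((x - x.mean()) * (y - y.mean()))
    theta = 0.5 * np.degrees(np.arctan2(2.0 * mu_xy, mu_xx - mu_yy))
    return wrap_axial(theta)


def _measure_components(labels: np.ndarray, image: np.ndarray, pixel_size: float):
    h = labels.shape[0]
    records = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rows, cols = np.nonzero(labels == lab)
        n_px = rows.size
        cx = cols.mean() * pixel_size
        cy = (h - 1 - rows.mean()) * pixel_size
        records.append(
            NucleusRecord(
                id=int(lab),
                centroid=(float(cx), float(cy)),
                pixel_mask=(rows, cols),
                area=float(n_px * pixel_size**2),
                mean_intensity=float(image[rows, cols].mean()),
                orientation=_mask_orientation(rows, cols),
            )
        )
    return records


def segment_nuclei(
    image: np.ndarray,
    pixel_size: float,
    min_area: float = 20.0,
    max_area: float = 400.0,
    min_mean_intensity: float = 0.0,
    local_block: int = 64,
):
    """Segment nuclei; returns ``(records, label_image)``.

    ``min_area``/``max_area`` are in square micrometres; components outside
    the range or with mean intensity below ``min_mean_intensity`` are
    discarded.  A constant image yields an empty result with a warning.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be single-channel 2-D")
    if np.any(image < 0):
        raise ValueError("image must be non-negative")
    if not min_area < max_area:
        raise ValueError("min_area must be < max_area")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")

    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        log.warning("constant image: Otsu threshold undefined, returning no nuclei")
        return [], np.zeros(image.shape, dtype=np.int32)

    global_thr = threshold_otsu(image)

    # Sliding local Otsu on an 8-bit rescale of the image.
    u8 = np.round((image - lo) / (hi - lo) * 255.0).astype(np.uint8)
    footprint = np.ones((local_block, local_block), dtype=bool)
    local_thr = rank.otsu(u8, footprint)
    foreground = (image > global_thr) & (u8 > local_thr)

    foreground = ndimage.binary_fill_holes(foreground)
    labels = sk_label(foreground, connectivity=2)

    records = _measure_components(labels, image, pixel_size)
    kept = [
        r
        for r in records
        if min_area <= r.area <= max_area and r.mean_intensity >= min_mean_intensity
    ]
    log.info("segmentation: %d components, %d kept after filters", len(records), len(kept))

    out_labels = np.zeros(image.shape, dtype=np.int32)
    final = []
    for new_id, rec in enumerate(sorted(kept, key=lambda r: r.id), start=1):
        rows, cols = rec.pixel_mask
        out_labels[rows, cols] = new_id
        rec.id = new_id
        final.append(rec)
    return final, out_labels


def records_from_labels(labels: np.ndarray, image: np.ndarray, pixel_size: float):
    """Measure :class:`NucleusRecord` objects from a ground-truth label image."""
    return _measure_components(np.asarray(labels), np.asarray(image, dtype=float), pixel_size)


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nucleus_id": [r.id for r in records],
            "x_um": [r.centroid[0] for r in records],
            "y_um": [r.centroid[1] for r in records],
            "area_um2": [r.area for r in records],
            "mean_intensity": [r.mean_intensity for r in records],
            "orientation_deg": [r.orientation for r in records],
        }
    )


def write_records(records, labels: np.ndarray, prefix) -> None:
    """Write the label image (16-bit TIFF) and the record table (CSV)."""
    prefix = str(prefix)
    tifffile.imwrite(prefix + "_labels.tif", labels.astype(np.uint16))
    records_to_frame(records).to_csv(prefix + "_records.csv", index=False)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
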