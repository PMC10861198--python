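"""Per-nucleus feature extraction in four groups.

The catalog covers the four feature families used for nuclear state
classification: nuclear morphology, boundary characteristics, global
intensity profile and chromatin texture.  Texture features are gray-level
co-occurrence statistics on a per-nucleus min-max quantization to 64
levels (1-px offsets at 0/45/90/135 degrees, averaged), plus chromatin
focus counts from a white-top-hat at the chromatin length scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.measure import find_contours, perimeter_crofton, regionprops
from skimage.morphology import convex_hull_image, disk, white_tophat

log = logging.getLogger(__name__)

__all__ = ["FeatureTable", "compute_features", "FEATURE_CATALOG", "DEGENERATE_MIN_PIXELS"]

#: Nuclei smaller than this (pixels) are flagged degenerate and excluded
#: from classifier training.
DEGENERATE_MIN_PIXELS = 16

_N_GLCM_LEVELS = 64
_GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))  # 0, 45, 90, 135 deg

FEATURE_CATALOG: tuple[tuple[str, str], ...] = (
    ("morphology", "area"),
    ("morphology", "perimeter"),
    ("morphology", "aspect_ratio"),
    ("morphology", "eccentricity"),
    ("morphology", "solidity"),
    ("morphology", "extent"),
    ("morphology", "equivalent_diameter"),
    ("boundary", "circularity"),
    ("boundary", "radial_dist_cv"),
    ("boundary", "concave_count"),
    ("intensity", "mean"),
    ("intensity", "sd"),
    ("intensity", "skewness"),
    ("intensity", "kurtosis"),
    ("intensity", "entropy"),
    ("intensity", "p10_p90_ratio"),
    ("intensity", "high_fraction"),
    ("texture", "glcm_contrast"),
    ("texture", "glcm_correlation"),
    ("texture", "glcm_homogeneity"),
    ("texture", "glcm_energy"),
    ("texture", "glcm_entropy"),
    ("texture", "focus_count"),
    ("texture", "focus_area_fraction"),
)


@dataclass
class FeatureTable:
    """Feature matrix with group-tagged columns and per-row provenance.

    ``data`` is indexed by nucleus id with a two-level column index
    ``(group, feature)``.  ``condition``, ``image_id`` and ``degenerate``
    are aligned Series.
    """

    data: pd.DataFrame
    condition: pd.Series
    image_id: pd.Series
    degenerate: pd.Series

    def __post_init__(self):
        names = [f for _, f in self.data.columns]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")

    @property
    def groups(self) -> dict[str, str]:
        """Map feature name -> group."""
        return {f: g for g, f in self.data.columns}

    def feature_matrix(self, include_degenerate: bool = False) -> pd.DataFrame:
        """Flat-column feature matrix, degenerate rows dropped by default."""
        df = self.data.copy()
        df.columns = [f for _, f in df.columns]
        if not include_degenerate:
            df = df.loc[~self.degenerate]
        return df

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out[("meta", "condition")] = self.condition
        out[("meta", "image_id")] = self.image_id
        out[("meta", "degenerate")] = self.degenerate
        out.to_csv(path, index_label="nucleus_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        raw = pd.read_csv(path, header=[0, 1], index_col=0)
        meta = raw["meta"]
        data = raw.drop(columns="meta", level=0)
        return cls(
            data=data,
            condition=meta["condition"],
            image_id=meta["image_id"],
            degenerate=meta["degenerate"].astype(bool),
        )

    @classmethod
    def concat(cls, tables) -> "FeatureTable":
        tables = list(tables)
        data = pd.concat([t.data for t in tables], ignore_index=True)
        return cls(
            data=data,
            condition=pd.concat([t.condition for t in tables], ignore_index=True),
            image_id=pd.concat([t.image_id for t in tables], ignore_index=True),
            degenerate=pd.concat([t.degenerate for t in tables], ignore_index=True),
        )


def _masked_glcm_features(quantized: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Co-occurrence features restricted to pixel pairs inside the mask."""
    feats = {k: [] for k in ("contrast", "correlation", "homogeneity", "energy", "entropy")}
    i_idx = np.arange(_N_GLCM_LEVELS, dtype=float)
    for dr, dc in _GLCM_OFFSETS:
        a_r = slice(max(dr, 0), quantized.shape[0] + min(dr, 0))
        a_c = slice(max(dc, 0), quantized.shape[1] + min(dc, 0))
        b_r = slice(max(-dr, 0), quantized.shape[0] + min(-dr, 0))
        b_c = slice(max(-dc, 0), quantized.shape[1] + min(-dc, 0))
        valid = mask[a_r, a_c] & mask[b_r, b_c]
        ia = quantized[a_r, a_c][valid]
        ib = quantized[b_r, b_c][valid]
        if ia.size == 0:
            continue
        counts = np.zeros((_N_GLCM_LEVELS, _N_GLCM_LEVELS))
        np.add.at(counts, (ia, ib), 1.0)
        counts = counts + counts.T  # symmetric
        p = counts / counts.sum()
        pi = p.sum(axis=1)
        mu = float(np.sum(i_idx * pi))
        var = float(np.sum((i_idx - mu) ** 2 * pi))
        diff2 = (i_idx[:, None] - i_idx[None, :]) ** 2
        feats["contrast"].append(float(np.sum(p * diff2)))
        if var > 0:
            cov = float(np.sum(p * np.outer(i_idx - mu, i_idx - mu)))
            feats["correlation"].append(cov / var)
        else:
            feats["correlation"].append(1.0)  # flat nucleus: degenerate value
        feats["homogeneity"].append(float(np.sum(p / (1.0 + diff2))))
        feats["energy"].append(float(np.sqrt(np.sum(p**2))))
        nz = p[p > 0]
        feats["entropy"].append(float(-np.sum(nz * np.log2(nz))))
    if not feats["contrast"]:
        return {"contrast": 0.0, "correlation": 1.0, "homogeneity": 1.0, "energy": 1.0, "entropy": 0.0}
    return {k: float(np.mean(v)) for k, v in feats.items()}


def _boundary_features(mask: np.ndarray, perimeter_px: float, contour: np.ndarray) -> dict[str, float]:
    area_px = float(mask.sum())
    circ = 4.0 * np.pi * area_px / perimeter_px**2 if perimeter_px > 0 else 0.0
    rows, cols = np.nonzero(mask)
    cr, cc = rows.mean(), cols.mean()
    radial = np.hypot(contour[:, 0] - cr, contour[:, 1] - cc)
    radial_cv = float(radial.std() / radial.mean()) if radial.mean() > 0 else 0.0
    # Concave indentations: components of hull-minus-mask with non-trivial area.
    hull = convex_hull_image(mask)
    defects = hull & ~mask
    lab, n = ndimage.label(defects)
    sizes = ndimage.sum_labels(defects, lab, index=np.arange(1, n + 1)) if n else []
    concave = int(np.sum(np.asarray(sizes) >= 2))
    return {"circularity": min(circ, 1.0), "radial_dist_cv": radial_cv, "concave_count": float(concave)}


def _contour_and_perimeter(mask: np.ndarray):
    """Outer contour (for radial statistics) and Crofton perimeter.

    The marching-squares arc length overestimates the perimeter of
    digitized convex shapes by several percent; the 4-direction Crofton
    estimate is unbiased on disks and keeps circularity of a perfect disk
    near 1.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    contour = max(contours, key=len) - 1.0
    perimeter = float(perimeter_crofton(mask, directions=4))
    return contour, perimeter


def _nucleus_features(crop: np.ndarray, mask: np.ndarray, pixel_size: float,
                      texture_scale_px: int) -> dict[tuple[str, str], float]:
    pixels = crop[mask]
    area_um2 = float(mask.sum()) * pixel_size**2

    props = regionprops(mask.astype(np.uint8))[0]
    minor = props.axis_minor_length
    aspect = float(props.axis_major_length / minor) if minor > 0 else 1.0
    contour, perimeter_px = _contour_and_perimeter(mask)

    mean = float(pixels.mean())
    sd = float(pixels.std())
    if sd > 0:
        skew = float(stats.skew(pixels))
        kurt = float(stats.kurtosis(pixels))
        hist, _ = np.histogram(pixels, bins=_N_GLCM_LEVELS)
        p = hist / hist.sum()
        nz = p[p > 0]
        ent = float(-np.sum(nz * np.log2(nz)))
        p10, p90 = np.percentile(pixels, [10, 90])
        ratio = float(p10 / p90) if p90 > 0 else 1.0
        high = float(np.mean(pixels > mean + sd))
    else:
        skew, kurt, ent, ratio, high = 0.0, 0.0, 0.0, 1.0, 0.0

    # Per-nucleus min-max quantization to 64 levels.
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi > lo:
        q = np.clip(((crop - lo) / (hi - lo) * (_N_GLCM_LEVELS - 1)), 0, _N_GLCM_LEVELS - 1)
        q = np.round(q).astype(np.intp)
    else:
        q = np.zeros_like(crop, dtype=np.intp)
    glcm = _masked_glcm_features(q, mask)

    # Chromatin foci: white-top-hat at the chromatin scale, Otsu inside the mask.
    tophat = white_tophat(crop, disk(texture_scale_px))
    th_vals = tophat[mask]
    focus_count, focus_frac = 0.0, 0.0
    if th_vals.max() > th_vals.min():
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(th_vals)
        foci = (tophat > thr) & mask
        _, n_foci = ndimage.label(foci)
        focus_count = float(n_foci)
        focus_frac = float(foci.sum() / mask.sum())

    bnd = _boundary_features(mask, perimeter_px, contour)
    return {
        ("morphology", "area"): area_um2,
        ("morphology", "perimeter"): perimeter_px * pixel_size,
        ("morphology", "aspect_ratio"): aspect,
        ("morphology", "eccentricity"): float(props.eccentricity),
        ("morphology", "solidity"): float(props.solidity),
        ("morphology", "extent"): float(props.extent),
        ("morphology", "equivalent_diameter"): 2.0 * np.sqrt(area_um2 / np.pi),
        ("boundary", "circularity"): bnd["circularity"],
        ("boundary", "radial_dist_cv"): bnd["radial_dist_cv"],
        ("boundary", "concave_count"): bnd["concave_count"],
        ("intensity", "mean"): mean,
        ("intensity", "sd"): sd,
        ("intensity", "skewness"): skew,
        ("intensity", "kurtosis"): kurt,
        ("intensity", "entropy"): ent,
        ("intensity", "p10_p90_ratio"): ratio,
        ("intensity", "high_fraction"): high,
        ("texture", "glcm_contrast"): glcm["contrast"],
        ("texture", "glcm_correlation"): glcm["correlation"],
        ("texture", "glcm_homogeneity"): glcm["homogeneity"],
        ("texture", "glcm_energy"): glcm["energy"],
        ("texture", "glcm_entropy"): glcm["entropy"],
        ("texture", "focus_count"): focus_count,
        ("texture", "focus_area_fraction"): focus_frac,
    }


def compute_features(
    image: np.ndarray,
    records,
    pixel_size: float,
    condition: str = "",
    image_id: str = "",
    texture_scale_um: float = 1.0,
) -> FeatureTable:
    """Compute the full feature catalog for every nucleus record.

    Nuclei smaller than :data:`DEGENERATE_MIN_PIXELS` pixels still get a
    row but are flagged ``degenerate``.
    """
    image = np.asarray(image, dtype=float)
    texture_scale_px = max(int(round(texture_scale_um / pixel_size)), 1)
    rows_out, ids, degen = [], [], []
    for rec in records:
        rows, cols = rec.pixel_mask
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        crop = image[r0:r1, c0:c1]
        mask = np.zeros(crop.shape, dtype=bool)
        mask[rows - r0, cols - c0] = True
        rows_out.append(_nucleus_features(crop, mask, pixel_size, texture_scale_px))
        ids.append(rec.id)
        degen.append(rows.size < DEGENERATE_MIN_PIXELS)

    data = pd.DataFrame(rows_out, index=ids)
    data.columns = pd.MultiIndex.from_tuples(data.columns, names=["group", "feature"])
    data = data[[c for c in FEATURE_CATALOG]]
    n_deg = int(np.sum(degen))
    if n_deg:
        log.warning("%d nuclei below %d px flagged degenerate", n_deg, DEGENERATE_MIN_PIXELS)
    n = len(ids)
    return FeatureTable(
        data=data,
        condition=pd.Series([condition] * n, index=ids),
        image_id=pd.Series([image_id] * n, index=ids),
        degenerate=pd.Series(degen, index=ids),
    )
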