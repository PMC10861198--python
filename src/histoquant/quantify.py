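"""ROI intensity fold changes, delta-delta-Ct expression and group tests.

Fold changes normalize background-subtracted ROI means per channel by the
mean of the reference condition, so the reference condition's mean fold
change is 1 by construction.  Relative qPCR expression uses the classic
``2**(-ddCt)`` rule against a housekeeping gene.  Group comparisons wrap
the standard scipy tests and attach the figure star convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import polygon as draw_polygon

log = logging.getLogger(__name__)

__all__ = [
    "RoiMeasurement",
    "measure_roi",
    "intensity_fold_change",
    "ddct_fold_change",
    "compare_groups",
    "significance_stars",
    "read_roi_polygons",
]

_TESTS = ("mann_whitney", "tukey_hsd", "paired_t", "anova")


@dataclass
class RoiMeasurement:
    """Mean intensity of one ROI in one channel of one image."""

    image_id: str
    channel: str
    condition: str
    mean_intensity: float
    background: float = 0.0
    roi: np.ndarray | None = None  # polygon vertices (x, y) in micrometres

    def __post_init__(self):
        if self.mean_intensity < 0:
            raise ValueError("mean intensity must be >= 0")
        if self.roi is not None:
            v = np.asarray(self.roi, dtype=float)
            if v.ndim != 2 or v.shape[0] < 3:
                raise ValueError("ROI polygon needs >= 3 vertices")
            x, y = v[:, 0], v[:, 1]
            area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
            if area <= 0:
                raise ValueError("ROI polygon is degenerate (zero area)")


def measure_roi(image: np.ndarray, polygon_um: np.ndarray, pixel_size: float) -> float:
    """Mean intensity inside a polygon given as (x, y) vertices in um (y-up)."""
    image = np.asarray(image, dtype=float)
    v = np.asarray(polygon_um, dtype=float)
    h = image.shape[0]
    rows = h - 1 - v[:, 1] / pixel_size
    cols = v[:, 0] / pixel_size
    rr, cc = draw_polygon(rows, cols, shape=image.shape)
    if rr.size == 0:
        raise ValueError("ROI covers no pixels")
    return float(image[rr, cc].mean())


def intensity_fold_change(measurements, reference_condition: str) -> pd.DataFrame:
    """Per-measurement fold change vs the reference condition's channel mean.

    Each measurement is background-subtracted first.  Raises if a channel
    has no reference measurements or a non-positive reference mean.
    """
    rows = [
        {
            "image_id": m.image_id,
            "channel": m.channel,
            "condition": m.condition,
            "net_intensity": m.mean_intensity - m.background,
        }
        for m in measurements
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no measurements")
    out = []
    for channel, grp in df.groupby("channel", sort=False):
        ref = grp.loc[grp.condition == reference_condition, "net_intensity"]
        if ref.empty:
            raise ValueError(f"channel '{channel}' has no reference measurements")
        if (grp.condition != reference_condition).sum() == 0:
            raise ValueError(f"channel '{channel}' has no non-reference measurements")
        ref_mean = float(ref.mean())
        if ref_mean <= 0:
            raise ValueError(
                f"reference mean for channel '{channel}' is {ref_mean:.3g} after "
                "background subtraction"
            )
        g = grp.copy()
        g["fold_change"] = g.net_intensity / ref_mean
        out.append(g)
    return pd.concat(out, ignore_index=True)


def ddct_fold_change(records: pd.DataFrame, reference_condition: str = "reference") -> pd.DataFrame:
    """Per-sample relative expression ``2**(-ddCt)``.

    ``records`` needs columns ``sample``, ``condition``, ``ct_target``,
    ``ct_housekeeping`` (an optional ``gene`` column is handled per gene).
    ``dCt = ct_target - ct_housekeeping``; ``ddCt`` subtracts the mean dCt
    of the reference condition.  Rows with missing housekeeping Ct are
    skipped with a warning; Ct values must lie in (0, 45).
    """
    df = records.copy()
    missing = df["ct_housekeeping"].isna() | df["ct_target"].isna()
    if missing.any():
        log.warning("skipping %d records with missing Ct values", int(missing.sum()))
        df = df.loc[~missing]
    for col in ("ct_target", "ct_housekeeping"):
        bad = (df[col] <= 0) | (df[col] >= 45)
        if bad.any():
            raise ValueError(f"{col} values must lie in (0, 45)")
    if "gene" not in df.columns:
        df = df.assign(gene="target")
    out = []
    for gene, grp in df.groupby("gene", sort=False):
        dct = grp.ct_target - grp.ct_housekeeping
        ref = dct[grp.condition == reference_condition]
        if ref.empty:
            raise ValueError(f"gene '{gene}': reference condition has no records")
        ddct = dct - ref.mean()
        g = grp.assign(dct=dct, ddct=ddct, fold_change=2.0 ** (-ddct))
        out.append(g)
    return pd.concat(out, ignore_index=True)


def significance_stars(p: float) -> str:
    """Figure star convention: * < 0.05, ** < 0.01, *** < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(values_by_group: dict, test: str) -> pd.DataFrame:
    """Run a named group-comparison test and tabulate statistic/p/stars.

    ``mann_whitney`` and ``paired_t`` need exactly 2 groups; ``anova``
    accepts >= 2; ``tukey_hsd`` reports every pairwise comparison.  Groups
    with fewer than 3 values are flagged ``reliable=False`` but still
    reported.
    """
    if test not in _TESTS:
        raise ValueError(f"test must be one of {_TESTS}")
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[k], dtype=float) for k in names]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    reliable = all(len(g) >= 3 for g in groups)
    if not reliable:
        log.warning("a group has n < 3: results flagged unreliable")
    ns = {k: len(v) for k, v in zip(names, groups)}

    rows = []
    if test == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney requires exactly 2 groups")
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        rows.append((f"{names[0]} vs {names[1]}", float(res.statistic), float(res.pvalue)))
    elif test == "paired_t":
        if len(groups) != 2:
            raise ValueError("paired_t requires exactly 2 groups")
        if len(groups[0]) != len(groups[1]):
            raise ValueError("paired_t requires equal-length groups")
        d = groups[0] - groups[1]
        if np.allclose(d, 0):
            rows.append((f"{names[0]} vs {names[1]}", 0.0, 1.0))
        else:
            res = stats.ttest_rel(groups[0], groups[1])
            rows.append((f"{names[0]} vs {names[1]}", float(res.statistic), float(res.pvalue)))
    elif test == "anova":
        res = stats.f_oneway(*groups)
        rows.append(("anova", float(res.statistic), float(res.pvalue)))
    else:  # tukey_hsd
        res = stats.tukey_hsd(*groups)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                rows.append(
                    (f"{names[i]} vs {names[j]}", float(res.statistic[i, j]),
                     float(res.pvalue[i, j]))
                )

    return pd.DataFrame(
        {
            "comparison": [r[0] for r in rows],
            "statistic": [r[1] for r in rows],
            "pvalue": [r[2] for r in rows],
            "stars": [significance_stars(r[2]) for r in rows],
            "n": [json.dumps(ns)] * len(rows),
            "reliable": [reliable] * len(rows),
        }
    )


def read_roi_polygons(path) -> dict:
    """Read ROI polygons from GeoJSON-style JSON or a vertex-list CSV.

    JSON: ``{"rois": [{"name": ..., "vertices": [[x, y], ...]}, ...]}``
    (micrometres).  CSV needs columns ``roi``, ``x_um``, ``y_um``.
    Returns a mapping name -> (n, 2) vertex array.
    """
    path = str(path)
    if path.endswith(".json") or path.endswith(".geojson"):
        with open(path) as fh:
            payload = json.load(fh)
        return {r["name"]: np.asarray(r["vertices"], dtype=float) for r in payload["rois"]}
    df = pd.read_csv(path, comment="#")
    return {
        str(name): grp[["x_um", "y_um"]].to_numpy(dtype=float)
        for name, grp in df.groupby("roi", sort=False)
    }
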