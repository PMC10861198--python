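"""Internuclear pairwise distances, dispersion and density-based clustering.

The IPD matrix holds exact Euclidean distances between nuclear centroids
in micrometres; it is symmetric with a zero diagonal.  The spreading
statistic is the sample standard deviation of the strict upper triangle.
Spatial clustering uses the hierarchical density-based method
(epsilon-free) on jointly min-max normalized centroid coordinates plus
either the state score or the full feature set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

from .axial import mean_pairwise_axial_difference

log = logging.getLogger(__name__)

__all__ = [
    "IPDMatrix",
    "ClusterAssignment",
    "compute_ipd_matrix",
    "ipd_dispersion",
    "cluster_nuclei",
    "cluster_angular_difference",
]


@dataclass
class IPDMatrix:
    """Symmetric internuclear distance matrix (micrometres) with id order."""

    ids: list
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape must match id count")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise ValueError("IPD matrix must be symmetric, non-negative, zero-diagonal")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "IPDMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=list(df.index), matrix=df.to_numpy(dtype=float))


@dataclass
class ClusterAssignment:
    """Per-nucleus cluster labels (-1 = noise) and per-cluster statistics."""

    labels: np.ndarray
    table: pd.DataFrame  # columns: cluster, n, mean_score, mean_angular_diff_deg


def _extract_xy_ids(records):
    """Accept a NucleusRecord list or a DataFrame with x_um/y_um columns."""
    if isinstance(records, pd.DataFrame):
        ids = list(records["nucleus_id"]) if "nucleus_id" in records else list(records.index)
        xy = records[["x_um", "y_um"]].to_numpy(dtype=float)
        orient = records["orientation_deg"].to_numpy(dtype=float) if "orientation_deg" in records else None
    else:
        ids = [r.id for r in records]
        xy = np.array([r.centroid for r in records], dtype=float)
        orient = np.array([r.orientation for r in records], dtype=float)
    return ids, xy, orient


def compute_ipd_matrix(records) -> IPDMatrix:
    """All-pairs Euclidean centroid distances, ordered as the input ids."""
    ids, xy, _ = _extract_xy_ids(records)
    if len(ids) < 2:
        raise ValueError("need at least 2 records")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate nucleus ids")
    dx = xy[:, None, 0] - xy[None, :, 0]
    dy = xy[:, None, 1] - xy[None, :, 1]
    # Explicit multiplies: every op is correctly rounded, so the result is
    # bit-identical to the naive per-pair formula.
    matrix = np.sqrt(dx * dx + dy * dy)
    np.fill_diagonal(matrix, 0.0)
    return IPDMatrix(ids=ids, matrix=matrix)


def ipd_dispersion(matrix: IPDMatrix) -> float:
    """Sample SD (n-1 denominator) of the strict upper-triangle distances."""
    n = len(matrix.ids)
    if n < 2:
        raise ValueError("need at least 2 nuclei")
    iu = np.triu_indices(n, k=1)
    d = matrix.matrix[iu]
    if d.size == 1:
        log.info("only one distance: dispersion reported as 0")
        return 0.0
    return float(np.std(d, ddof=1))


def _minmax_columns(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return (X - lo) / rng


def cluster_nuclei(
    records,
    scores=None,
    feature_set: str = "xy+score",
    min_cluster_size: int = 5,
    features=None,
    extent: float | tuple[float, float] | None = None,
    allow_single_cluster: bool = True,
    cluster_selection_epsilon: float | None = None,
) -> ClusterAssignment:
    """Density-based clustering of nuclei on normalized coordinates + state.

    ``feature_set`` selects the columns joined to the centroid coordinates:
    ``"xy+score"`` (default; the normalized state score) or
    ``"xy+features"`` (the full feature matrix from ``features``).  Every
    column is normalized to [0, 1] before clustering: when ``extent`` (the
    image width/height in micrometres) is given, coordinates are divided by
    it — so a spatially tight group stays tight — and a merge radius of
    0.05 normalized units is applied by default; without ``extent`` each
    column is min-max scaled over the data.  Noise nuclei get label -1 and
    are excluded from cluster statistics.
    """
    ids, xy, orient = _extract_xy_ids(records)
    n = len(ids)
    if feature_set not in ("xy+score", "xy+features"):
        raise ValueError("feature_set must be 'xy+score' or 'xy+features'")
    if scores is None:
        if isinstance(records, pd.DataFrame) and "score" in records:
            scores = records["score"].to_numpy(dtype=float)
        else:
            raise ValueError("scores are required")
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != n:
        raise ValueError("scores must align with records")

    if feature_set == "xy+score":
        other = np.clip(scores, 0.0, 1.0)[:, None]
    else:
        if features is None:
            raise ValueError("feature_set='xy+features' requires a FeatureTable")
        F = features.feature_matrix(include_degenerate=True).to_numpy(dtype=float)
        if F.shape[0] != n:
            raise ValueError("feature table must align with records")
        other = _minmax_columns(F)

    if extent is not None:
        wh = np.broadcast_to(np.asarray(extent, dtype=float), (2,))
        if np.any(wh <= 0):
            raise ValueError("extent must be positive")
        X = np.column_stack([xy / wh, other])
        eps = 0.05 if cluster_selection_epsilon is None else cluster_selection_epsilon
    else:
        X = np.column_stack([_minmax_columns(xy), other])
        eps = 0.0 if cluster_selection_epsilon is None else cluster_selection_epsilon

    if min_cluster_size > n:
        labels = np.full(n, -1, dtype=int)
    else:
        labels = HDBSCAN(
            min_cluster_size=min_cluster_size,
            allow_single_cluster=allow_single_cluster,
            cluster_selection_epsilon=eps,
            copy=True,
        ).fit_predict(X)

    rows = []
    for lab in sorted(set(labels) - {-1}):
        members = labels == lab
        if orient is not None and members.sum() >= 2:
            ang = mean_pairwise_axial_difference(orient[members])
        else:
            ang = np.nan
        rows.append(
            {
                "cluster": int(lab),
                "n": int(members.sum()),
                "mean_score": float(scores[members].mean()),
                "mean_angular_diff_deg": ang,
            }
        )
    if not rows:
        log.warning("all nuclei labeled noise: empty cluster table")
    table = pd.DataFrame(rows, columns=["cluster", "n", "mean_score", "mean_angular_diff_deg"])
    return ClusterAssignment(labels=labels, table=table)


def cluster_angular_difference(assignment: ClusterAssignment, records) -> pd.Series:
    """Mean pairwise axial angular difference per non-noise cluster.

    Singleton clusters get NaN (statistic undefined).
    """
    _, _, orient = _extract_xy_ids(records)
    if orient is None:
        raise ValueError("records carry no orientations")
    out = {}
    for lab in sorted(set(assignment.labels) - {-1}):
        members = assignment.labels == lab
        if members.sum() < 2:
            out[int(lab)] = np.nan
        else:
            out[int(lab)] = mean_pairwise_axial_difference(orient[members])
    return pd.Series(out, name="mean_angular_diff_deg", dtype=float)
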