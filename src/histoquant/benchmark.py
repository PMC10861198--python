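"""Ground-truth-driven helpers for validating stages on synthetic scenes."""

from __future__ import annotations

import numpy as np

from .morphometrics import FeatureTable, compute_features
from .segmentation import records_from_labels, segment_nuclei
from .synthetic import SyntheticScene

__all__ = ["scene_feature_table", "match_detections"]


def scene_feature_table(
    scene: SyntheticScene,
    use_segmentation: bool = False,
    image_id: str = "",
    **segmentation_kwargs,
) -> FeatureTable:
    """Feature table for a synthetic scene, labeled by true population tag.

    With ``use_segmentation`` the nuclei are re-detected from the rendered
    image; otherwise the ground-truth masks are measured directly.  In the
    segmentation path each detection inherits the population tag of the
    ground-truth nucleus it overlaps most.
    """
    if use_segmentation:
        records, _ = segment_nuclei(scene.image, scene.pixel_size, **segmentation_kwargs)
    else:
        records = records_from_labels(scene.labels, scene.image, scene.pixel_size)
    table = compute_features(scene.image, records, scene.pixel_size, image_id=image_id)
    tag_by_id = scene.truth.set_index("nucleus_id")["population"]
    conditions = []
    for rec in records:
        gt = scene.labels[rec.pixel_mask]
        gt = gt[gt > 0]
        if gt.size:
            conditions.append(str(tag_by_id.loc[int(np.bincount(gt).argmax())]))
        else:
            conditions.append("unmatched")
    table.condition = table.condition.copy()
    table.condition[:] = conditions
    return table


def match_detections(records, scene: SyntheticScene, min_overlap: float = 0.5):
    """Count detections overlapping ground truth.

    Returns ``(n_true_positive_nuclei, n_false_positive_records)`` where a
    record is a false positive if fewer than ``min_overlap`` of its pixels
    lie on any ground-truth nucleus, and a ground-truth nucleus counts as
    detected if some record claims it as its majority overlap.
    """
    detected = set()
    false_pos = 0
    for rec in records:
        gt = scene.labels[rec.pixel_mask]
        frac_on = float((gt > 0).mean())
        if frac_on < min_overlap:
            false_pos += 1
            continue
        hit = gt[gt > 0]
        detected.add(int(np.bincount(hit).argmax()))
    return len(detected), false_pos
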