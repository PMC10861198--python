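"""End-to-end analysis pipelines and run configuration handling.

Two entry points mirror the two tissue experiments: the rejuvenation
pipeline (segment -> features -> LDA score -> IPD/dispersion -> spatial
clusters per condition) and the wound pipeline (orientation field ->
alignment histogram/width -> HSB map -> ROI fold changes).  Every run
serializes its configuration, stamps a config hash into each output and
writes a machine-readable summary JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import fibers, quantify, scoring, segmentation, spatial, synthetic
from .morphometrics import FeatureTable, compute_features

log = logging.getLogger(__name__)

__all__ = [
    "PipelineError",
    "config_hash",
    "load_config",
    "default_rejuvenation_config",
    "default_wound_config",
    "run_rejuvenation_analysis",
    "run_wound_analysis",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for the abort message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def default_rejuvenation_config() -> dict:
    return {
        "seed": 0,
        "pixel_size": 0.5,
        "image_size": 512,
        "use_ground_truth_masks": False,
        "conditions": {
            "old": {
                "synthetic": {
                    "population": {"mean_area": 70.0, "texture_contrast": 0.2},
                    "n": 80,
                    "dispersion": 45.0,
                }
            },
            "pr": {
                "synthetic": {
                    "population": {"mean_area": 85.0, "texture_contrast": 0.5},
                    "n": 80,
                    "dispersion": 60.0,
                }
            },
        },
        "segmentation": {
            "min_area": 20.0,
            "max_area": 400.0,
            "min_mean_intensity": 0.0,
            "local_block": 64,
        },
        "scoring": {"train_fraction": 0.75, "balance": True, "seed": 0},
        "clustering": {"min_cluster_size": 5, "feature_set": "xy+score"},
    }


def default_wound_config() -> dict:
    return {
        "seed": 0,
        "pixel_size": 1.0,
        "sigma": 2.0,
        "bins": 36,
        "weight": "coherency*energy",
        "reference_angle": 0.0,
        "reference_condition": "old",
        "conditions": {
            "old": {"synthetic": {"mean_angle": 0.0, "concentration": 0.0, "image_size": 512}},
            "pr": {"synthetic": {"mean_angle": 0.0, "concentration": 20.0, "image_size": 512}},
        },
    }


def _write_csv(df: pd.DataFrame, path: Path, chash: str, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, **kwargs)


def _validate(config: dict, required: tuple, pipeline: str) -> None:
    for key in required:
        if key not in config:
            raise PipelineError("validate", f"{pipeline} config is missing '{key}'")
    conditions = config["conditions"]
    if not isinstance(conditions, dict) or not conditions:
        raise PipelineError("validate", "conditions must be a non-empty mapping")
    for name, spec in conditions.items():
        if not isinstance(spec, dict) or not ({"synthetic", "image"} & set(spec)):
            raise PipelineError(
                "validate", f"condition '{name}' needs a 'synthetic' block or an 'image' path"
            )
    if "seed" not in config:
        raise PipelineError("validate", "an explicit seed is required (no wall-clock seeding)")


def _condition_records(name, spec, config, outdir, chash):
    """Produce (records, records_frame, image) for one condition."""
    px = config["pixel_size"]
    if "synthetic" in spec:
        syn = spec["synthetic"]
        pop = synthetic.PopulationParams(**syn.get("population", {}))
        scene = synthetic.generate_nuclei_scene(
            pop,
            pop,
            n_per_pop=max(int(syn.get("n", 80)) // 2, 1),
            dispersion=float(syn.get("dispersion", 45.0)),
            image_size=int(syn.get("image_size", config.get("image_size", 512))),
            pixel_size=px,
            seed=int(config["seed"]) + sum(map(ord, name)),
        )
        image = scene.image
        gt_labels = scene.labels
    else:
        image = tifffile.imread(spec["image"]).astype(float)
        gt_labels = None

    if config.get("use_ground_truth_masks") and gt_labels is not None:
        records = segmentation.records_from_labels(gt_labels, image, px)
        labels = gt_labels
    else:
        records, labels = segmentation.segment_nuclei(image, px, **config["segmentation"])
    if not records:
        raise PipelineError("segment", f"condition '{name}': no nuclei found")
    tifffile.imwrite(outdir / f"labels_{name}.tif", labels.astype(np.uint16))
    frame = segmentation.records_to_frame(records)
    _write_csv(frame, outdir / f"records_{name}.csv", chash, index=False)
    log.info("condition %s: %d nuclei", name, len(records))
    return records, frame, image


def run_rejuvenation_analysis(config: dict, outdir) -> dict:
    """Segment, score and spatially characterize two implanted conditions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _validate(config, ("pixel_size", "conditions", "segmentation", "scoring", "clustering"),
              "rejuvenation")
    if len(config["conditions"]) != 2:
        raise PipelineError("validate", "rejuvenation analysis needs exactly 2 conditions")
    chash = config_hash(config)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)

    per_condition = {}
    tables = []
    for name, spec in config["conditions"].items():
        try:
            records, frame, image = _condition_records(name, spec, config, outdir, chash)
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001 - abort with stage context
            raise PipelineError("segment", f"condition '{name}': {e}") from e
        try:
            table = compute_features(image, records, config["pixel_size"],
                                     condition=name, image_id=name)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("features", f"condition '{name}': {e}") from e
        per_condition[name] = {
            "records": records,
            "frame": frame,
            "extent": (image.shape[1] * config["pixel_size"], image.shape[0] * config["pixel_size"]),
        }
        tables.append(table)

    features = FeatureTable.concat(tables)
    _write_csv(features.data.assign(condition=features.condition.to_numpy()),
               outdir / "features.csv", chash)

    try:
        score_set = scoring.train_score_lda(features, seed=int(config["scoring"].get("seed", config["seed"])),
                                            train_fraction=float(config["scoring"]["train_fraction"]),
                                            balance=bool(config["scoring"]["balance"]))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("score", str(e)) from e
    _write_csv(score_set.table, outdir / "scores.csv", chash)
    scoring.write_model(score_set, outdir / "model.json")

    fig, ax = plt.subplots(figsize=(5, 3.5))
    summary = {
        "config_hash": chash,
        "test_accuracy": score_set.test_accuracy,
        "conditions": {},
    }
    for name in config["conditions"]:
        info = per_condition[name]
        mask = (score_set.table.label == name) & score_set.table.score.notna()
        scores_c = score_set.table.loc[mask, "score"].to_numpy()
        ax.hist(scores_c, bins=25, range=(0, 1), density=True, alpha=0.6, label=name)

        try:
            ipd = spatial.compute_ipd_matrix(info["frame"])
            dispersion = spatial.ipd_dispersion(ipd)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("ipd", f"condition '{name}': {e}") from e
        ipd.to_csv(outdir / f"ipd_{name}.csv")

        # Scores align positionally: the same record list produced the features.
        df = info["frame"].copy()
        df["score"] = score_set.table.loc[score_set.table.label == name, "score"].to_numpy()
        df_clusterable = df.loc[df.score.notna()]
        try:
            assignment = spatial.cluster_nuclei(
                df_clusterable,
                feature_set=config["clustering"]["feature_set"],
                min_cluster_size=int(config["clustering"]["min_cluster_size"]),
                extent=info["extent"],
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("cluster", f"condition '{name}': {e}") from e
        _write_csv(assignment.table, outdir / f"clusters_{name}.csv", chash, index=False)

        cfig, cax = plt.subplots(figsize=(4.5, 4.5))
        cax.scatter(df_clusterable.x_um, df_clusterable.y_um, c=assignment.labels,
                    cmap="tab20", s=8)
        cax.set_xlabel("x (um)")
        cax.set_ylabel("y (um)")
        cax.set_title(f"{name}: spatial clusters")
        cfig.savefig(outdir / f"cluster_map_{name}.png", dpi=120)
        plt.close(cfig)

        summary["conditions"][name] = {
            "n_nuclei": int(len(info["records"])),
            "ipd_dispersion_um": float(dispersion),
            "n_clusters": int(len(assignment.table)),
            "noise_fraction": float(np.mean(assignment.labels == -1)),
            "mean_score": float(np.nanmean(scores_c)) if scores_c.size else None,
            "mean_cluster_score": (
                float(assignment.table.mean_score.mean()) if len(assignment.table) else None
            ),
            "mean_cluster_angular_diff_deg": (
                float(assignment.table.mean_angular_diff_deg.mean())
                if assignment.table.mean_angular_diff_deg.notna().any()
                else None
            ),
        }

    ax.set_xlabel("normalized state score")
    ax.set_ylabel("density")
    ax.legend()
    fig.savefig(outdir / "score_histogram.png", dpi=120)
    plt.close(fig)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def run_wound_analysis(config: dict, outdir) -> dict:
    """Fiber-alignment analysis per condition plus optional ROI fold changes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _validate(config, ("pixel_size", "sigma", "bins", "conditions"), "wound")
    chash = config_hash(config)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)

    if "reference_angle" in config and config["reference_angle"] is not None:
        reference = float(config["reference_angle"])
    else:
        log.info("no wound reference angle given: histograms use absolute angles")
        reference = 0.0

    summary = {"config_hash": chash, "conditions": {}}
    for name, spec in config["conditions"].items():
        try:
            if "synthetic" in spec:
                syn = spec["synthetic"]
                image = synthetic.generate_fiber_field(
                    mean_angle=float(syn.get("mean_angle", 0.0)),
                    concentration=float(syn.get("concentration", 0.0)),
                    image_size=int(syn.get("image_size", 512)),
                    seed=int(config["seed"]) + sum(map(ord, name)),
                )
            else:
                image = tifffile.imread(spec["image"]).astype(float)
            field = fibers.compute_orientation_field(
                image, sigma=float(config["sigma"]), pixel_size=float(config["pixel_size"])
            )
            hist = fibers.orientation_histogram(
                field,
                reference_angle=reference,
                n_bins=int(config["bins"]),
                weight=config.get("weight", "coherency*energy"),
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("fibers", f"condition '{name}': {e}") from e
        fibers.write_field(field, outdir / f"field_{name}.tif")
        hist.to_csv(outdir / f"histogram_{name}.csv")
        rgb = fibers.render_hsb_map(field, image)
        plt.imsave(outdir / f"hsb_{name}.png", np.clip(rgb, 0, 1))
        summary["conditions"][name] = {
            "mean_orientation_deg": hist.mean_deg,
            "width_deg": hist.width_deg,
            "mean_coherency": float(field.coherency.mean()),
        }
        log.info("condition %s: width %.2f deg", name, hist.width_deg)

    if config.get("intensity_csv"):
        try:
            df = pd.read_csv(config["intensity_csv"], comment="#")
            measurements = [
                quantify.RoiMeasurement(
                    image_id=str(r.image_id),
                    channel=str(r.channel),
                    condition=str(r.condition),
                    mean_intensity=float(r.mean_intensity),
                    background=float(getattr(r, "background", 0.0)),
                )
                for r in df.itertuples()
            ]
            folds = quantify.intensity_fold_change(
                measurements, config.get("reference_condition", "old")
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError("quantify", str(e)) from e
        _write_csv(folds, outdir / "fold_changes.csv", chash, index=False)
        summary["fold_changes"] = {
            f"{ch}/{cond}": float(g.fold_change.mean())
            for (ch, cond), g in folds.groupby(["channel", "condition"])
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
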