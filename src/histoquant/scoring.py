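"""Two-class LDA cell-state scoring.

Trains a linear discriminant on the nuclear feature table (closed form:
class means and pooled within-class covariance, shrunk toward its
diagonal), projects every nucleus onto the first discriminant axis and
min-max normalizes the projection to a [0, 1] score.  75/25 train/test
splitting and optional majority-class downsampling are seeded and
bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import ledoit_wolf

from .morphometrics import FeatureTable

log = logging.getLogger(__name__)

__all__ = ["LdaModel", "ScoreSet", "train_score_lda", "rank_feature_groups",
           "write_scores", "write_model", "read_model"]


@dataclass
class LdaModel:
    """Exported discriminant: works on standardized features.

    ``raw = (x - mean) / sd @ coef + intercept``; positive raw projections
    predict ``classes[1]``.
    """

    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    means: np.ndarray
    sds: np.ndarray
    classes: tuple[str, str]
    shrinkage: float

    def project(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.means) / self.sds
        return Xs @ self.coef + self.intercept


@dataclass
class ScoreSet:
    """Per-nucleus scores plus the trained model and its test accuracy."""

    table: pd.DataFrame  # columns: image_id, label, raw, score, split
    model: LdaModel
    test_accuracy: float
    seed: int
    dropped_features: list[str] = field(default_factory=list)
    feature_groups: dict[str, str] = field(default_factory=dict)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def train_score_lda(
    features: FeatureTable,
    label_column: str = "condition",
    train_fraction: float = 0.75,
    balance: bool = True,
    shrinkage: str | float = "auto",
    seed: int = 0,
) -> ScoreSet:
    """Train the discriminant and score every non-degenerate nucleus.

    Exactly two condition labels are required, each with at least 20
    non-degenerate nuclei.  With ``balance`` the majority class is randomly
    downsampled to the minority count before the split; left-out majority
    nuclei are still scored (split tag ``unused``).  Zero-variance features
    are dropped with a warning.
    """
    if label_column != "condition":
        raise ValueError("only the 'condition' label column is supported")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    X_all = features.feature_matrix(include_degenerate=True)
    labels = features.condition.to_numpy()
    degen = features.degenerate.to_numpy()
    classes = sorted(pd.unique(labels[~degen]))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 condition labels, got {classes}")
    for c in classes:
        n_c = int(np.sum((labels == c) & ~degen))
        if n_c < 20:
            raise ValueError(f"need >= 20 non-degenerate nuclei per label; '{c}' has {n_c}")

    rng = np.random.default_rng(seed)
    usable = np.flatnonzero(~degen)
    idx_by_class = {c: usable[labels[usable] == c] for c in classes}
    if balance:
        n_min = min(len(v) for v in idx_by_class.values())
        for c in classes:
            if len(idx_by_class[c]) > n_min:
                keep = rng.choice(len(idx_by_class[c]), size=n_min, replace=False)
                idx_by_class[c] = idx_by_class[c][np.sort(keep)]

    train_idx, test_idx = [], []
    for c in classes:
        idx = idx_by_class[c].copy()
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    train_idx = np.sort(np.array(train_idx))
    test_idx = np.sort(np.array(test_idx))

    X = X_all.to_numpy(dtype=float)
    Xtr = X[train_idx]
    ytr = labels[train_idx]

    means = Xtr.mean(axis=0)
    sds = Xtr.std(axis=0)
    keep_cols = sds > 0
    dropped = [n for n, k in zip(X_all.columns, keep_cols) if not k]
    if dropped:
        log.warning("dropping %d zero-variance features: %s", len(dropped), dropped)
    names = [n for n, k in zip(X_all.columns, keep_cols) if k]
    means, sds = means[keep_cols], sds[keep_cols]
    Xtr_s = (Xtr[:, keep_cols] - means) / sds

    mu = {c: Xtr_s[ytr == c].mean(axis=0) for c in classes}
    centered = np.vstack([Xtr_s[ytr == c] - mu[c] for c in classes])
    if shrinkage == "auto":
        cov, gamma = ledoit_wolf(centered, assume_centered=True)
        gamma = float(gamma)
        pooled = centered.T @ centered / max(len(centered) - 2, 1)
        cov = (1.0 - gamma) * pooled + gamma * np.diag(np.diag(pooled))
    else:
        gamma = float(shrinkage)
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("shrinkage must be in [0, 1] or 'auto'")
        pooled = centered.T @ centered / max(len(centered) - 2, 1)
        cov = (1.0 - gamma) * pooled + gamma * np.diag(np.diag(pooled))

    diff = mu[classes[1]] - mu[classes[0]]
    coef = np.linalg.solve(cov, diff)
    intercept = float(-0.5 * (mu[classes[0]] + mu[classes[1]]) @ coef)

    model = LdaModel(
        feature_names=list(names),
        coef=coef,
        intercept=intercept,
        means=means,
        sds=sds,
        classes=(str(classes[0]), str(classes[1])),
        shrinkage=gamma,
    )

    scored_idx = np.flatnonzero(~degen)
    raw = model.project(X[scored_idx][:, keep_cols])
    score = _minmax(raw)

    split = np.full(len(labels), "excluded", dtype=object)
    split[scored_idx] = "unused"
    split[train_idx] = "train"
    split[test_idx] = "test"

    pred_test = np.where(model.project(X[test_idx][:, keep_cols]) > 0, classes[1], classes[0])
    test_accuracy = float(np.mean(pred_test == labels[test_idx]))

    raw_full = np.full(len(labels), np.nan)
    raw_full[scored_idx] = raw
    score_full = np.full(len(labels), np.nan)
    score_full[scored_idx] = score
    table = pd.DataFrame(
        {
            "image_id": features.image_id.to_numpy(),
            "label": labels,
            "raw": raw_full,
            "score": score_full,
            "split": split,
        },
        index=X_all.index,
    )
    table.index.name = "nucleus_id"
    log.info(
        "LDA: %d train / %d test nuclei, test accuracy %.3f (shrinkage %.3f)",
        len(train_idx), len(test_idx), test_accuracy, gamma,
    )
    return ScoreSet(
        table=table,
        model=model,
        test_accuracy=test_accuracy,
        seed=seed,
        dropped_features=[str(d) for d in dropped],
        feature_groups=features.groups,
    )


def rank_feature_groups(score_set: ScoreSet, top_k: int) -> pd.DataFrame:
    """Features ranked by |standardized coefficient|, descending.

    Ties break lexicographically on the feature name.  ``top_k`` larger
    than the feature count returns everything (logged).
    """
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    model = score_set.model
    n = len(model.feature_names)
    if top_k > n:
        log.warning("top_k=%d exceeds %d features; returning all", top_k, n)
        top_k = n
    df = pd.DataFrame(
        {
            "feature": model.feature_names,
            "group": [score_set.feature_groups.get(f, "") for f in model.feature_names],
            "coefficient": model.coef,
        }
    )
    df = df.reindex(
        df.assign(absc=df.coefficient.abs())
        .sort_values(["absc", "feature"], ascending=[False, True])
        .index
    ).reset_index(drop=True)
    return df.head(top_k)


def write_scores(score_set: ScoreSet, path) -> None:
    score_set.table.to_csv(path)


def write_model(score_set: ScoreSet, path) -> None:
    model = score_set.model
    payload = {
        "feature_names": model.feature_names,
        "coefficients": model.coef.tolist(),
        "intercept": model.intercept,
        "standardization_means": model.means.tolist(),
        "standardization_sds": model.sds.tolist(),
        "classes": list(model.classes),
        "shrinkage": model.shrinkage,
        "seed": score_set.seed,
        "test_accuracy": score_set.test_accuracy,
        "dropped_features": score_set.dropped_features,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_model(path) -> LdaModel:
    with open(path) as fh:
        d = json.load(fh)
    return LdaModel(
        feature_names=d["feature_names"],
        coef=np.asarray(d["coefficients"]),
        intercept=d["intercept"],
        means=np.asarray(d["standardization_means"]),
        sds=np.asarray(d["standardization_sds"]),
        classes=tuple(d["classes"]),
        shrinkage=d["shrinkage"],
    )
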