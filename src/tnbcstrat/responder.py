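"""Predicted response to anti-CTLA-4 therapy from immune-score features.

A linear support vector classifier (standardized features, C = 1) is
trained on a labeled immune-score table and applied to new cohorts; the
enrichment of predicted responders across CTLA-4 clusters is then tested
with Fisher's exact test and BH adjustment.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import stats as st

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass
class ResponderModel:
    """A fitted responder classifier plus the metadata needed to apply it."""

    pipeline: Pipeline
    feature_names: list[str]
    classes: list[str]
    cv_accuracy: float
    n_train: int
    seed: int
    version: int = MODEL_FORMAT_VERSION

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "ResponderModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if model.version != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model version {model.version}")
        return model


def train_responder(features: pd.DataFrame, labels: pd.Series, seed: int = 0) -> ResponderModel:
    """Fit the linear-SVM responder model with 5-fold cross-validation.

    ``features`` is samples x immune-score features; ``labels`` holds two
    classes (e.g. responder / non-responder). Features are standardized
    inside the pipeline, so predictions are invariant to affine rescaling
    of any input feature.
    """
    labels = labels.reindex(features.index)
    classes = sorted(labels.dropna().unique())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    if len(features) < 10:
        raise ValueError("need at least 10 training samples")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="linear", C=1.0)),
    ])
    X = features.to_numpy(dtype=float)
    y = labels.to_numpy()
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    cv_acc = float(cross_val_score(pipe, X, y, cv=cv, scoring="accuracy").mean())
    pipe.fit(X, y)
    logger.info("responder SVM: n=%d, 5-fold CV accuracy %.3f", len(y), cv_acc)
    return ResponderModel(
        pipeline=pipe,
        feature_names=list(features.columns),
        classes=list(classes),
        cv_accuracy=cv_acc,
        n_train=len(y),
        seed=seed,
    )


def predict_responders(model: ResponderModel, features: pd.DataFrame) -> pd.Series:
    """Hard responder/non-responder calls for new samples."""
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise ValueError(f"missing feature(s): {missing}")
    X = features[model.feature_names].to_numpy(dtype=float)
    return pd.Series(model.pipeline.predict(X), index=features.index, name="predicted_response")


def responder_enrichment(
    labels: pd.Series,
    clusters: pd.DataFrame,
    axis: str = "erk",
    contrasts: list[tuple[str, str]] = (("HH", "HL"),),
    positive_class: str | None = None,
) -> pd.DataFrame:
    """Fisher exact enrichment of responders across cluster pairs.

    For each (cluster A, cluster B) contrast a 2x2 responder-by-cluster
    table is tested; p-values are BH-adjusted across contrasts. Responder
    proportions are reported as exact count ratios.
    """
    cluster_labels = clusters[f"{axis}_cluster"].reindex(labels.index)
    if positive_class is None:
        positive_class = sorted(labels.dropna().unique())[-1]
    rows = []
    for a, b in contrasts:
        in_a = cluster_labels == a
        in_b = cluster_labels == b
        if not in_a.any() or not in_b.any():
            logger.warning("contrast (%s, %s) skipped: empty cluster", a, b)
            continue
        ra = int((labels[in_a] == positive_class).sum())
        rb = int((labels[in_b] == positive_class).sum())
        na, nb = int(in_a.sum()), int(in_b.sum())
        table = [[ra, na - ra], [rb, nb - rb]]
        rows.append({
            "cluster_a": a, "cluster_b": b,
            "responders_a": ra, "n_a": na, "prop_a": ra / na,
            "responders_b": rb, "n_b": nb, "prop_b": rb / nb,
            "p": st.fisher_exact(table),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = st.bh_adjust(out["p"].to_numpy())
    return out
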