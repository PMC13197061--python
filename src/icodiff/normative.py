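"""ROI abnormality scoring against personalized reference sets.

A test subject is compared, region by region, against N reference feature
maps (either diffusion-model pseudo-healthy reconstructions or age-matched
real "template" subjects): the abnormal score for ROI ``i`` is the z-score of
the subject's ROI-mean feature value under the reference set's ROI-mean
distribution,

    Z_i = (x_i - mean_j x_{i,j}) / std_j x_{i,j},

computed on cortical thickness by default (atrophy biomarker).  The
per-subject vector of ROI scores feeds a linear SVM for group classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .geometry import Parcellation

__all__ = [
    "AbnormalScoreTable",
    "roi_means",
    "abnormal_scores",
    "template_reference",
    "classification_eval",
]


@dataclass
class AbnormalScoreTable:
    """Per-ROI abnormality z-scores for one subject."""

    subject_id: str
    z: np.ndarray
    n_reference: int
    channel: str = "ct"
    degenerate_rois: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "roi": np.arange(len(self.z)),
                "z": self.z,
            }
        )


def roi_means(values: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Unweighted mean of a per-vertex map within each ROI.

    Empty ROIs yield NaN (undefined-mean sentinel).  ``values`` may be
    ``(V,)`` or stacked ``(N, V)``.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = parcellation.labels
    if values.shape[-1] != labels.shape[0]:
        raise ValueError("map and parcellation disagree on vertex count")
    counts = np.bincount(labels, minlength=parcellation.n_rois).astype(np.float64)
    single = values.ndim == 1
    if single:
        values = values[None]
    sums = np.stack(
        [np.bincount(labels, weights=row, minlength=parcellation.n_rois) for row in values]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    return means[0] if single else means


def abnormal_scores(
    subject_map: np.ndarray,
    sample_maps: np.ndarray,
    parcellation: Parcellation,
    subject_id: str = "subject",
    ddof: int = 1,
    channel: str = "ct",
) -> AbnormalScoreTable:
    """Per-ROI abnormality z-scores of a subject against N reference maps.

    The standard deviation uses the unbiased (N-1) denominator by default
    (material at N=10; configurable through ``ddof``).  ROIs where the
    reference spread is zero receive a signed-infinity sentinel and are
    recorded in ``degenerate_rois``.
    """
    sample_maps = np.asarray(sample_maps, dtype=np.float64)
    if sample_maps.ndim != 2 or sample_maps.shape[0] < 2:
        raise ValueError("need at least 2 reference maps (N >= 2)")
    x = roi_means(subject_map, parcellation)
    xs = roi_means(sample_maps, parcellation)
    mu = xs.mean(axis=0)
    sd = xs.std(axis=0, ddof=ddof)

    degenerate = np.flatnonzero(sd == 0.0).tolist()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mu) / sd
    for i in degenerate:
        z[i] = np.sign(x[i] - mu[i]) * np.inf if x[i] != mu[i] else 0.0
    return AbnormalScoreTable(
        subject_id=subject_id,
        z=z,
        n_reference=sample_maps.shape[0],
        channel=channel,
        degenerate_rois=degenerate,
    )


def template_reference(ages: np.ndarray, test_age: float, k: int = 10) -> np.ndarray:
    """Indices of the ``k`` cohort members with ages closest to ``test_age``.

    Ties in age distance break toward the smaller index (subject-id order).
    """
    ages = np.asarray(ages, dtype=np.float64)
    if ages.shape[0] < k:
        raise ValueError("cohort smaller than k")
    dist = np.abs(ages - test_age)
    return np.lexsort((np.arange(ages.shape[0]), dist))[:k]


def classification_eval(
    score_vectors: np.ndarray,
    group_labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    kernel: str = "linear",
) -> dict:
    """Stratified k-fold SVM classification of per-subject ROI score vectors.

    Returns fold-averaged accuracy, precision and recall (positive class =
    the lexicographically larger label).  Degenerate (non-finite) features
    must be excluded by the caller.
    """
    X = np.asarray(score_vectors, dtype=np.float64)
    y = np.asarray(group_labels)
    classes = np.unique(y)
    if classes.shape[0] < 2:
        raise ValueError("need at least two classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("score vectors contain non-finite entries")
    pos = classes[-1]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, precs, recs = [], [], []
    for train_idx, test_idx in skf.split(X, y):
        clf = SVC(kernel=kernel, random_state=seed)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        accs.append(accuracy_score(y[test_idx], pred))
        precs.append(precision_score(y[test_idx], pred, pos_label=pos, zero_division=0))
        recs.append(recall_score(y[test_idx], pred, pos_label=pos, zero_division=0))
    return {
        "accuracy": float(np.mean(accs)),
        "precision": float(np.mean(precs)),
        "recall": float(np.mean(recs)),
        "folds": folds,
        "seed": seed,
    }
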