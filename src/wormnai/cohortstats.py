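"""Cohort-level discrimination between cancer and control subjects.

Given per-subject (CI, NAI) summaries, this module classifies subjects by
the sign of an index, computes confusion metrics (sensitivity,
specificity, accuracy), sweeps ROC curves with their AUC, and performs a
two-variable PCA of (CI, NAI) on the raw covariance, reporting how much
of the first component each index carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .indices import SubjectRecord

POSITIVE = "cancer"
NEGATIVE = "control"


@dataclass
class DiscriminationReport:
    """Summary of a two-group discrimination analysis."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc_ci: float | None = None
    auc_nai: float | None = None
    auc_pc1: float | None = None
    pc1_variance_fraction: float | None = None
    pc1_loading_fraction_nai: float | None = None
    predictions: pd.DataFrame | None = field(default=None, repr=False)

    def to_series(self) -> pd.Series:
        d = {
            k: getattr(self, k)
            for k in (
                "sensitivity",
                "specificity",
                "accuracy",
                "auc_ci",
                "auc_nai",
                "auc_pc1",
                "pc1_variance_fraction",
                "pc1_loading_fraction_nai",
            )
        }
        return pd.Series(d, dtype=float)


def _index_values(records: Sequence[SubjectRecord], index: str) -> np.ndarray:
    try:
        vals = np.array(
            [getattr(r, {"nai": "nai_mean", "ci": "ci_mean"}[index]) for r in records],
            dtype=float,
        )
    except KeyError as exc:
        raise ValueError(f"unknown index {index!r} (use 'nai' or 'ci')") from exc
    if np.isnan(vals).any():
        raise ValueError(f"missing {index} values in subject records")
    return vals


def classify_by_sign(
    scores: np.ndarray | Sequence[float], threshold: float = 0.0
) -> list[str]:
    """Predict cancer for scores strictly above the threshold.

    Ties at the threshold go to control, so an uninformative zero index
    never inflates sensitivity.
    """
    return [POSITIVE if s > threshold else NEGATIVE for s in np.asarray(scores, float)]


def confusion_metrics(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) for two-class labels.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy the
    proportion of true positives and true negatives among all cases.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label lists differ in length")
    classes = set(t) | set(p)
    if not classes <= {POSITIVE, NEGATIVE}:
        raise ValueError(f"labels must be {{{POSITIVE!r}, {NEGATIVE!r}}}, got {classes}")
    tp = int(np.sum((t == POSITIVE) & (p == POSITIVE)))
    fn = int(np.sum((t == POSITIVE) & (p == NEGATIVE)))
    tn = int(np.sum((t == NEGATIVE) & (p == NEGATIVE)))
    fp = int(np.sum((t == NEGATIVE) & (p == POSITIVE)))
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present in true_labels")
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    return sensitivity, specificity, accuracy


def roc_curve(
    scores: Sequence[float], true_labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC sweep over all distinct score thresholds.

    Returns (fpr, tpr, thresholds, auc). The trapezoid AUC equals the
    Mann-Whitney probability that a random cancer subject scores above a
    random control subject (ties counted half).
    """
    t = np.asarray(true_labels)
    if len(set(t)) < 2:
        raise ValueError("ROC needs at least one subject of each class")
    y = (t == POSITIVE).astype(int)
    fpr, tpr, thr = _skm.roc_curve(y, np.asarray(scores, float))
    return fpr, tpr, thr, float(_skm.auc(fpr, tpr))


def pca_two_vars(
    ci: Sequence[float],
    nai: Sequence[float],
    groups: Sequence[str] | None = None,
    standardize: bool = False,
) -> dict:
    """Eigendecomposition of the 2x2 covariance of (CI, NAI).

    Both indices already live on the same [-1, 1] scale, so the raw
    covariance is decomposed by default; ``standardize=True`` switches to
    the correlation matrix. Returns components (rows = PCs, columns =
    (ci, nai)), variance fractions, the NAI share of PC1's absolute
    loadings, and per-subject PC scores. When group labels are given the
    PC1 sign is fixed so the cancer-group mean score is positive.
    """
    x = np.column_stack([np.asarray(ci, float), np.asarray(nai, float)])
    if x.shape[0] < 3:
        raise ValueError("PCA needs at least 3 subjects")
    centered = x - x.mean(axis=0)
    cov = np.cov(centered, rowvar=False, ddof=1)
    if standardize:
        sd = np.sqrt(np.diag(cov))
        if np.any(sd == 0):
            raise ValueError("a variable with zero variance cannot be standardized")
        cov = cov / np.outer(sd, sd)
        centered = centered / sd
    if not np.any(cov):
        raise ValueError("covariance matrix is zero; PCA undefined")
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    components = evecs.T  # rows are PCs
    scores = centered @ evecs
    if groups is not None:
        g = np.asarray(groups)
        for k in range(2):
            if scores[g == POSITIVE, k].mean() < 0:
                components[k] *= -1
                scores[:, k] *= -1
    var_frac = evals / evals.sum()
    load = np.abs(components[0])
    return {
        "components": components,
        "explained_variance": evals,
        "variance_fractions": var_frac,
        "loading_fraction_nai": float(load[1] / load.sum()),
        "scores": scores,
    }


def discriminate(records: Sequence[SubjectRecord]) -> DiscriminationReport:
    """Full discrimination analysis on a cohort of subject records.

    Sign-classifies by NAI at threshold 0, computes confusion metrics,
    ROC/AUC for CI, NAI and PC1, and the two-variable PCA summary.
    """
    true = [r.group for r in records]
    nai = _index_values(records, "nai")
    have_ci = not np.isnan([r.ci_mean for r in records]).any()
    predicted = classify_by_sign(nai)
    sens, spec, acc = confusion_metrics(true, predicted)
    report = DiscriminationReport(sensitivity=sens, specificity=spec, accuracy=acc)
    *_, report.auc_nai = roc_curve(nai, true)
    pred_df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": true,
            "nai": nai,
            "predicted": predicted,
        }
    )
    if have_ci:
        ci = _index_values(records, "ci")
        *_, report.auc_ci = roc_curve(ci, true)
        pca = pca_two_vars(ci, nai, groups=true)
        report.pc1_variance_fraction = float(pca["variance_fractions"][0])
        report.pc1_loading_fraction_nai = pca["loading_fraction_nai"]
        *_, report.auc_pc1 = roc_curve(pca["scores"][:, 0], true)
        pred_df["ci"] = ci
        pred_df["pc1"] = pca["scores"][:, 0]
    report.predictions = pred_df
    return report
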