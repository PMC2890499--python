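"""Differential expression screening and leave-one-out classification.

Gene panels (e.g. the top high-traffic genes of a disease network) are
screened for differential expression between two clinical classes with
two-sample t tests, and evaluated as classifier inputs with a linear
maximum-margin classifier (linear SVM, C = 1) under leave-one-out
cross-validation. Features are z-scored inside each training fold only,
so no statistic of the held-out sample leaks into preprocessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .stats import StatResult, two_sample_t

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ClassificationResult",
    "differential_expression",
    "loo_linear_classify",
    "load_expression",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a binary class label per sample."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    labels: dict[str, str]  # sample -> class name

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols")
        unlabeled = set(self.values.columns) - set(self.labels)
        if unlabeled:
            raise ValueError(f"unlabeled samples: {sorted(unlabeled)[:5]}")
        if len(self.classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {self.classes}")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted({self.labels[s] for s in self.values.columns}))

    def class_columns(self, cls: str) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == cls]


@dataclass
class ClassificationResult:
    panel: list[str]
    accuracy: float
    auc: float
    predictions: pd.DataFrame = field(repr=False)  # sample, true, predicted, decision


def differential_expression(
    matrix: ExpressionMatrix,
    panel: Sequence[str],
    alpha: float = 0.05,
    variance_rule: str = "pooled",
    positive_class: str | None = None,
) -> pd.DataFrame:
    """Per-gene two-sample t test between the two classes.

    Positive t means higher mean in ``positive_class`` (default: first
    class alphabetically). Panel genes absent from the matrix yield NA
    rows (the screen continues); present genes are flagged ``NS`` when
    p > alpha.
    """
    cls = matrix.classes
    pos = positive_class or cls[0]
    neg = cls[1] if pos == cls[0] else cls[0]
    xcols, ycols = matrix.class_columns(pos), matrix.class_columns(neg)
    if len(xcols) < 2 or len(ycols) < 2:
        raise ValueError("each class needs >= 2 samples")
    rows = []
    for gene in panel:
        if gene not in matrix.values.index:
            logger.info("panel gene %s absent from matrix: NA", gene)
            rows.append({"gene": gene, "t": np.nan, "p": np.nan, "flag": "NA"})
            continue
        res = two_sample_t(matrix.values.loc[gene, xcols],
                           matrix.values.loc[gene, ycols], variance_rule)
        rows.append({"gene": gene, "t": res.value, "p": res.p,
                     "flag": "sig" if res.p <= alpha else "NS"})
    return pd.DataFrame(rows)


def loo_linear_classify(
    matrix: ExpressionMatrix,
    panel: Sequence[str],
    c: float = 1.0,
    positive_class: str | None = None,
) -> ClassificationResult:
    """Leave-one-out evaluation of a linear SVM on a gene panel.

    For every sample, the classifier is trained on all the others —
    features standardized with training-fold statistics only — and the
    held-out sample is predicted. Accuracy is the fraction of correct
    held-out predictions; the AUC is computed from the held-out decision
    values. Deterministic for fixed inputs.
    """
    present = [g for g in panel if g in matrix.values.index]
    if not present:
        raise ValueError("no panel gene present in the expression matrix")
    absent = [g for g in panel if g not in matrix.values.index]
    if absent:
        logger.warning("panel genes absent from matrix: %s", ", ".join(absent))
    x = matrix.values.loc[present].to_numpy(dtype=float).T  # samples x genes
    samples = list(matrix.values.columns)
    if len(samples) < 4:
        raise ValueError("need >= 4 samples for leave-one-out")
    cls = matrix.classes
    pos = positive_class or cls[1]
    y = np.array([1 if matrix.labels[s] == pos else 0 for s in samples])
    if y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("each class needs >= 2 samples")
    preds, decisions = [], []
    for i in range(len(samples)):
        train = np.ones(len(samples), dtype=bool)
        train[i] = False
        if len(np.unique(y[train])) < 2:
            raise ValueError("training fold with a single class")
        model = make_pipeline(StandardScaler(), SVC(kernel="linear", C=c))
        model.fit(x[train], y[train])
        preds.append(int(model.predict(x[i:i + 1])[0]))
        decisions.append(float(model.decision_function(x[i:i + 1])[0]))
    preds = np.array(preds)
    accuracy = float((preds == y).mean())
    auc = float(roc_auc_score(y, decisions))
    table = pd.DataFrame({"sample": samples, "true": y, "predicted": preds,
                          "decision": decisions})
    return ClassificationResult(panel=present, accuracy=accuracy, auc=auc,
                                predictions=table)


def load_expression(expr_path: str | Path, labels_path: str | Path) -> ExpressionMatrix:
    """Expression TSV (first column gene symbol, header = sample ids) plus
    a labels TSV of (sample, class) rows."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    values.index = values.index.astype(str).str.strip().str.upper()
    lab = pd.read_csv(labels_path, sep="\t", header=None, names=["sample", "class"],
                      comment="#", dtype=str)
    labels = dict(zip(lab["sample"].str.strip(), lab["class"].str.strip()))
    return ExpressionMatrix(values=values, labels=labels)
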