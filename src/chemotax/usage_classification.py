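"""Classification of plants by economic use from metabolite-group features.

Plants carry one use label from {E: edible, M: medicinal, L: landscaping
(forestry/ornamental), T: timber, P: poisonous, W: wild/unused}.  Plants
labelled both edible and medicinal ("E/M") are treated as medicinal, and
W plants are excluded from classification.  Each plant's binary
metabolite-group membership vector is the feature row for a soft-margin
support vector machine with a radial-basis kernel at library defaults.

Evaluation follows the confusion-matrix convention in which a row is an
actual class and a column a predicted class.  The per-class *recognition
rate* is the row-normalised diagonal (percent) and *accuracy* the
trace over the total (percent).  The default evaluation mode is
resubstitution (predicting the training set); stratified k-fold
cross-validation is available and gives the honest generalisation
estimate, at the price of not being the classical resubstitution table.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

VALID_USES = {"E", "M", "L", "T", "P", "W", "E/M"}


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Read ``plant_id<TAB>use`` rows with uses in {E,M,L,T,P,W,E/M}."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            if lineno == 1 and parts[0] == "plant_id":
                continue
            if parts[1] not in VALID_USES:
                raise ValueError(f"{path}:{lineno}: unknown use label {parts[1]!r}")
            out[parts[0]] = parts[1]
    return out


def build_dataset(M, labels: Mapping[str, str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Feature matrix X, label list y, and the retained plant ids.

    Rows of X are group-membership vectors; E/M collapses to M and W
    plants are dropped.  A plant without a label is an error.
    """
    df = M.df if hasattr(M, "df") else M
    missing = [p for p in df.index if p not in labels]
    if missing:
        raise ValueError(f"no usage label for plant {missing[0]!r}")
    plants = [p for p in df.index if labels[p] != "W"]
    y = ["M" if labels[p] == "E/M" else labels[p] for p in plants]
    X = df.loc[plants].to_numpy(dtype=float)
    return X, y, plants


def train_and_predict(
    X: np.ndarray,
    y: Sequence[str],
    mode: str = "resubstitution",
    n_folds: int = 5,
    seed: int = 0,
) -> list[str]:
    """Fit the RBF SVM at default parameters and predict labels.

    ``mode="resubstitution"`` predicts the training set itself;
    ``mode="k-fold"`` returns out-of-fold predictions from stratified
    cross-validation (shuffled with ``seed``).
    """
    if len(set(y)) < 2:
        raise ValueError("need at least 2 classes")
    clf = SVC()
    if mode == "resubstitution":
        clf.fit(X, list(y))
        return list(clf.predict(X))
    if mode == "k-fold":
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return list(cross_val_predict(clf, X, list(y), cv=cv))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ConfusionMatrix:
    """Counts[actual][predicted] over an ordered class list."""

    classes: list[str]
    counts: np.ndarray  # shape (k, k), rows = actual

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts shape does not match class list")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sum(self, cls: str) -> int:
        return int(self.counts[self.classes.index(cls)].sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="actual\\predicted")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy())


def confusion(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    classes: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Actual x predicted counts.

    Default class order is by descending actual class size (ties
    alphabetical); pass ``classes`` explicitly to fix another order.
    """
    if len(y_true) != len(y_pred):
        raise ValueError("label lists differ in length")
    if classes is None:
        sizes: dict[str, int] = {}
        for t in y_true:
            sizes[t] = sizes.get(t, 0) + 1
        classes = sorted(sizes, key=lambda c: (-sizes[c], c))
    classes = list(classes)
    idx = {c: i for i, c in enumerate(classes)}
    bad = [l for l in list(y_true) + list(y_pred) if l not in idx]
    if bad:
        raise ValueError(f"label {bad[0]!r} outside the class list {classes}")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(classes, counts)


def recognition_rate(cm: ConfusionMatrix, cls: str) -> float:
    """Percent of class members predicted correctly (row-normalised diagonal)."""
    i = cm.classes.index(cls)
    row = cm.counts[i].sum()
    if row == 0:
        raise ValueError(f"class {cls!r} has no instances")
    return 100.0 * cm.counts[i, i] / row


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent of all instances predicted correctly (trace over total)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(cm.counts) / cm.total


def round_rate(value: float, ndigits: int = 1) -> float:
    """Round half-up to ``ndigits`` decimals (57.15 -> 57.2)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
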