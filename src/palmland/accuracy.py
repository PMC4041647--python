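"""Error-matrix accuracy assessment: confusion matrices, overall accuracy
and Cohen's kappa, as used to evaluate categorical maps and classifiers.

Orientation convention: rows are the reference labels, columns the
predicted labels (overall accuracy and kappa are orientation-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "overall_accuracy",
    "cohens_kappa",
    "kappa_quality",
]


@dataclass
class ConfusionMatrix:
    """k x k count matrix; rows = reference class, columns = predicted."""

    counts: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} labels"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("confusion matrix must contain at least one count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.labels, name="reference"),
                            columns=pd.Index(self.labels, name="predicted"))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), tuple(df.index))


def confusion_matrix(reference, predicted) -> ConfusionMatrix:
    """Cross-tabulate reference vs predicted label sequences.

    Classes are the sorted union of the labels observed in either sequence.

    Raises
    ------
    ValueError
        On length mismatch or empty input.
    """
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    if len(reference) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(reference)} reference vs {len(predicted)} predicted"
        )
    if len(reference) == 0:
        raise ValueError("label sequences are empty")
    labels = tuple(sorted(set(reference.tolist()) | set(predicted.tolist())))
    lut = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    for r, p in zip(reference.tolist(), predicted.tolist()):
        counts[lut[r], lut[p]] += 1
    return ConfusionMatrix(counts, labels)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over total: the fraction of agreeing pairs."""
    return float(np.trace(cm.counts) / cm.total)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_e is the expected agreement under independent margins,
    sum_i row_i * col_i / total**2.  A degenerate matrix whose margins put
    all mass on one class (p_e = 1) has kappa 1 under perfect agreement and
    is undefined otherwise.

    Raises
    ------
    ValueError
        If p_e = 1 with imperfect agreement.
    """
    n = cm.total
    p_o = float(np.trace(cm.counts)) / n
    rows = cm.counts.sum(axis=1)
    cols = cm.counts.sum(axis=0)
    p_e = float(np.sum(rows * cols)) / (n * n)
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("kappa undefined: degenerate margins with imperfect agreement")
    return (p_o - p_e) / (1.0 - p_e)


def kappa_quality(kappa: float, scale: str = "landis_koch") -> str:
    """Verbal quality of a kappa value on a published scale (metadata only).

    ``landis_koch``: the Landis & Koch (1977) bands; ``monserud``: the
    Monserud & Leemans (1992) map-agreement bands.
    """
    if scale == "landis_koch":
        bands = [(-1.0, "poor"), (0.0, "slight"), (0.2, "fair"),
                 (0.4, "moderate"), (0.6, "substantial"), (0.8, "almost perfect")]
    elif scale == "monserud":
        bands = [(-1.0, "no agreement"), (0.05, "very poor"), (0.2, "poor"),
                 (0.4, "fair"), (0.55, "good"), (0.7, "very good"),
                 (0.85, "excellent"), (0.99, "perfect")]
    else:
        raise ValueError(f"unknown kappa scale: {scale}")
    label = bands[0][1]
    for cut, name in bands:
        if kappa >= cut:
            label = name
    return label
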