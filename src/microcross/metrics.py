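"""Performance measures: rank-based AUC, AUC-PR, MCC and confusion counts."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

POSITIVE = "case"


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == POSITIVE]
    neg = scores[labels != POSITIVE]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to score predictions")
    return pos, neg


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a random case outscores a random control,
    with half credit for ties.  ``labels`` are 'case'/'control' strings.
    """
    pos, neg = _split(scores, labels)
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def secondary_metrics(scores, labels, threshold: float = 0.5):
    """AUC-PR (step-interpolated), MCC and confusion counts at ``threshold``.

    MCC is defined as 0 whenever a marginal of the confusion matrix is 0.
    Returns (auc_pr, mcc, tp, fp, tn, fn).
    """
    pos, neg = _split(scores, labels)
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    s = np.concatenate([pos, neg])
    auc_pr = float(average_precision_score(y, s))

    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else float((tp * tn - fp * fn) / np.sqrt(denom))
    return auc_pr, mcc, tp, fp, tn, fn


@dataclass
class EvalRecord:
    """One (design, training set, test cohort) evaluation row."""

    design: str  # intra | cross | lodo | ccm | scm
    train_id: str
    test_cohort: str
    n_train: int
    auc: float
    auc_pr: float
    mcc: float
    tp: int
    fp: int
    tn: int
    fn: int
    tag: Optional[str] = None  # e.g. CCM subset size or SCM grid point

    def __post_init__(self) -> None:
        if self.design not in ("intra", "cross", "lodo", "ccm", "scm"):
            raise ValueError(f"unknown design {self.design!r}")
        if not (0.0 <= self.auc <= 1.0 and 0.0 <= self.auc_pr <= 1.0):
            raise ValueError("AUC and AUC-PR must lie in [0, 1]")
        if not -1.0 <= self.mcc <= 1.0:
            raise ValueError("MCC must lie in [-1, 1]")


def evaluate(design, train_id, test_cohort, n_train, scores, labels,
             threshold: float = 0.5, tag: str | None = None) -> EvalRecord:
    """Build an EvalRecord from raw scores and labels."""
    auc_pr, mcc, tp, fp, tn, fn = secondary_metrics(scores, labels, threshold)
    return EvalRecord(
        design=design, train_id=train_id, test_cohort=test_cohort,
        n_train=int(n_train), auc=auc(scores, labels), auc_pr=auc_pr, mcc=mcc,
        tp=tp, fp=fp, tn=tn, fn=fn, tag=tag,
    )


def records_to_frame(records: Iterable[EvalRecord]) -> pd.DataFrame:
    """Tidy one-row-per-evaluation DataFrame (the on-disk EvalRecord dialect)."""
    return pd.DataFrame([asdict(r) for r in records])
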