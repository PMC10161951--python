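"""Log-std feature normalization with frozen parameters, and SMOTE balancing.

Normalization follows the log.std convention used by microbiome
classification toolkits: log10 after a pseudocount, then per-feature z-score
standardization with a quantile floor on the standard deviation.  Parameters
are learned once on training data and reapplied frozen to external cohorts,
with features absent from a test table zero-filled in raw abundance space
before the transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .util import logger


@dataclass
class NormalizationParams:
    """Frozen per-feature log-std parameters (train-time state)."""

    log_n0: float
    means: pd.Series  # indexed by feature
    sds: pd.Series  # floored at the sd_min_q quantile of all feature sds
    features: list[str]

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in normalization parameters")
        if (self.sds <= 0).any():
            raise ValueError("floored standard deviations must be positive")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "log_n0": self.log_n0,
            "features": self.features,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        payload = json.loads(Path(path).read_text())
        feats = payload["features"]
        return cls(
            log_n0=payload["log_n0"],
            means=pd.Series(payload["means"], index=feats),
            sds=pd.Series(payload["sds"], index=feats),
            features=feats,
        )


def log_std_fit(table: pd.DataFrame, log_n0: float = 1e-6,
                sd_min_q: float = 0.1) -> NormalizationParams:
    """Learn log-std parameters on a training table (taxa x samples).

    Per entry: log10(x + log_n0); per feature: mean and sd (ddof=1), with the
    sd floored at the ``sd_min_q`` quantile of all feature sds so constant
    features stay finite under the transform.
    """
    if table.shape[1] < 2:
        raise ValueError("log_std_fit needs at least two samples (sd undefined)")
    vals = table.to_numpy(dtype=float)
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("relative abundances must lie in [0, 1]")
    logged = np.log10(vals + log_n0)
    means = logged.mean(axis=1)
    sds = logged.std(axis=1, ddof=1)
    floor = float(np.quantile(sds, sd_min_q))
    if floor <= 0:
        positive = sds[sds > 0]
        if len(positive) == 0:
            raise ValueError("all features constant; normalization undefined")
        floor = float(positive.min())
    sds = np.maximum(sds, floor)
    features = list(table.index)
    return NormalizationParams(
        log_n0=log_n0,
        means=pd.Series(means, index=features),
        sds=pd.Series(sds, index=features),
        features=features,
    )


def log_std_apply(table: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Apply frozen parameters; returns samples x features matrix.

    Features missing from ``table`` enter as raw zeros (the external
    validation zero-fill contract); extra taxa are ignored.  Column order is
    the params' training feature list.
    """
    aligned = table.reindex(params.features, fill_value=0.0)
    logged = np.log10(aligned.to_numpy(dtype=float) + params.log_n0)
    z = (logged - params.means.to_numpy()[:, None]) / params.sds.to_numpy()[:, None]
    return pd.DataFrame(z.T, index=list(table.columns), columns=params.features)


@dataclass
class SmoteConfig:
    """Balancing rule for imbalanced cohorts.

    Oversampling triggers when majority/minority >= ``trigger_ratio``; each
    minority sample then contributes ``max(3, round(majority/(2*minority)))``
    synthetic points, each a uniform convex combination of the sample and one
    of its ``k`` nearest minority neighbors.
    """

    k: int = 5
    trigger_ratio: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.trigger_ratio <= 1:
            raise ValueError("trigger_ratio must exceed 1")


def dup_size(n_majority: int, n_minority: int) -> int:
    """Synthetic points per minority sample: max(3, majority/(2*minority))."""
    return max(3, int(round(n_majority / (2.0 * n_minority))))


def smote_balance(matrix: pd.DataFrame, labels: pd.Series,
                  config: SmoteConfig | None = None) -> tuple[pd.DataFrame, pd.Series]:
    """SMOTE oversampling of the minority class (samples x features input).

    Returns the input unchanged when the class ratio is below the trigger.
    Original rows are preserved verbatim; synthetic rows are appended with
    ids ``smote_<i>``.  Deterministic under ``config.seed``.
    """
    config = config or SmoteConfig()
    labels = pd.Series(np.asarray(labels), index=matrix.index)
    counts = labels.value_counts()
    if len(counts) != 2:
        raise ValueError("smote_balance needs exactly two classes")
    minority_label = counts.idxmin()
    n_min, n_maj = int(counts.min()), int(counts.max())
    if n_maj / n_min < config.trigger_ratio:
        return matrix, labels
    if n_min < 2:
        raise ValueError("minority class of size 1 cannot be oversampled")

    k = config.k
    if n_min < k + 1:
        k = n_min - 1
        logger.info("SMOTE: minority class smaller than k+1; reducing k to %d", k)

    minority = matrix[labels == minority_label].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    neighbor_idx = nn.kneighbors(minority, return_distance=False)[:, 1:]

    rng = np.random.default_rng(config.seed)
    d = dup_size(n_maj, n_min)
    synth = np.empty((n_min * d, matrix.shape[1]))
    row = 0
    for i in range(n_min):
        for _ in range(d):
            j = neighbor_idx[i, rng.integers(k)]
            gap = rng.random()
            synth[row] = minority[i] + gap * (minority[j] - minority[i])
            row += 1

    synth_ids = [f"smote_{i}" for i in range(row)]
    out = pd.concat(
        [matrix, pd.DataFrame(synth, index=synth_ids, columns=matrix.columns)]
    )
    out_labels = pd.concat(
        [labels, pd.Series([minority_label] * row, index=synth_ids)]
    )
    return out, out_labels
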