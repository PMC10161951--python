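"""The Marker Similarity Index (MSI): cross-cohort marker consistency.

MSI is an asymmetric similarity between two signed marker score vectors.
With A the reference (training-set analogue) carrying p markers, the target
B is aligned to A's taxa — markers absent from B enter with score 0, extra
markers of B are dropped — and

    MSI(A -> B) = p / sqrt(sum_i (m_i^a - m_i^b)^2).

Higher values mean more consistent markers.  With one or no reference
marker the MSI is defined as 0; identical aligned vectors (distance 0) are
flagged degenerate and floored at p / 1e-8 so downstream medians stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import MarkerSet

DEGENERATE_EPS = 1e-8


@dataclass
class MsiResult:
    reference: str
    target: str
    p: int  # reference marker count
    distance: float
    value: float
    degenerate: bool = False


def msi(reference: MarkerSet, target: MarkerSet) -> MsiResult:
    """MSI with ``reference`` defining the aligned index set (asymmetric)."""
    a = reference.scores()
    b = target.scores()
    p = len(a)
    if p <= 1:
        return MsiResult(reference.source, target.source, p, float("nan"), 0.0)
    aligned_b = b.reindex(a.index).fillna(0.0)
    dist = float(np.sqrt(np.sum((a.to_numpy() - aligned_b.to_numpy()) ** 2)))
    if dist == 0.0:
        return MsiResult(
            reference.source, target.source, p, 0.0, p / DEGENERATE_EPS, True
        )
    return MsiResult(reference.source, target.source, p, dist, p / dist)


def msi_matrix(sets: list[MarkerSet]) -> pd.DataFrame:
    """K x K MSI table; rows are the reference (training analogue).

    The diagonal is NA, never numeric.
    """
    if len(sets) < 2:
        raise ValueError("msi_matrix needs at least two marker sets")
    names = [s.source for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("marker set sources must be unique")
    out = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for ref in sets:
        for tgt in sets:
            if ref.source != tgt.source:
                out.loc[ref.source, tgt.source] = msi(ref, tgt).value
    out.index.name = "reference"
    return out
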