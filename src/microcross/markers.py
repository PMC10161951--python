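"""LEfSe-style differential-abundance marker calling with signed LDA scores.

The two-stage procedure mirrors the classic effect-size workflow for
two-class microbiome comparisons: a nonparametric rank screen (Kruskal-Wallis,
which for two classes is the Wilcoxon rank-sum test) followed by a
bootstrapped linear-discriminant effect size on profiles rescaled to sum 1e6
per sample.  Scores are reported on a log10 scale; taxa with score >= the
LDA cutoff (default 2) become markers, signed + when case-enriched and -
when control-enriched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .util import logger

LEFSE_SCALE = 1e6
RIDGE_EPS = 1e-6  # stabilizes the pooled covariance on degenerate draws


@dataclass
class Marker:
    taxon: str
    lda_score: float  # signed: + case-enriched, - control-enriched
    p_value: float

    @property
    def enriched(self) -> str:
        return "case" if self.lda_score >= 0 else "control"


@dataclass
class MarkerSet:
    """Signed markers for one cohort or pooled training set."""

    source: str
    markers: list[Marker] = field(default_factory=list)
    lda_cutoff: float = 2.0

    def __post_init__(self) -> None:
        taxa = [m.taxon for m in self.markers]
        if len(set(taxa)) != len(taxa):
            raise ValueError(f"duplicate taxa in marker set {self.source!r}")

    @property
    def taxa(self) -> list[str]:
        return [m.taxon for m in self.markers]

    def scores(self) -> pd.Series:
        return pd.Series(
            {m.taxon: m.lda_score for m in self.markers}, dtype=float
        )

    def __len__(self) -> int:
        return len(self.markers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "taxon": m.taxon,
                    "lda_score": m.lda_score,
                    "enriched": m.enriched,
                    "p_value": m.p_value,
                }
                for m in self.markers
            ],
            columns=["taxon", "lda_score", "enriched", "p_value"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, path: str | Path, source: str | None = None,
             lda_cutoff: float = 2.0) -> "MarkerSet":
        """Import any TSV with taxon + signed score columns (external tools too)."""
        frame = pd.read_csv(path, sep="\t")
        markers = [
            Marker(
                taxon=str(row["taxon"]),
                lda_score=float(row["lda_score"]),
                p_value=float(row.get("p_value", np.nan)),
            )
            for _, row in frame.iterrows()
        ]
        return cls(source or Path(path).stem, markers, lda_cutoff)


def kw_screen(table: pd.DataFrame, labels, alpha: float = 0.05) -> pd.DataFrame:
    """Per-taxon two-sided rank test of case vs control relative abundances.

    Returns a frame with columns taxon, p_value, passed (p < alpha), sorted
    in table row order.  Constant taxa get p = 1 and never pass.
    """
    labels = np.asarray(labels)
    is_case = labels == "case"
    if is_case.all() or (~is_case).all():
        raise ValueError("both classes must be present")
    vals = table.to_numpy(dtype=float)
    pvals = np.ones(len(table))
    for i in range(len(table)):
        row = vals[i]
        if np.ptp(row) == 0:
            continue
        pvals[i] = stats.mannwhitneyu(
            row[is_case], row[~is_case], alternative="two-sided"
        ).pvalue
    return pd.DataFrame(
        {"taxon": list(table.index), "p_value": pvals, "passed": pvals < alpha}
    )


def lda_effect_size(table: pd.DataFrame, labels, n_boot: int = 30,
                    subsample_frac: float = 2.0 / 3.0, seed: int = 0) -> pd.Series:
    """Bootstrapped LDA effect size per taxon (log10 scale, unsigned).

    ``table`` is taxa x samples ON THE 1e6 PER-SAMPLE SCALE (the caller
    rescales before screening).  Per bootstrap round, a balanced 2/3-per-class
    subsample (without replacement, at least 3 per class) feeds a two-class
    linear discriminant with a ridge-stabilized pooled covariance; each
    taxon's round score is the mean of (a) the absolute class-mean difference
    and (b) |unit discriminant weight x projected class-mean difference|.
    The final score is log10(1 + mean over rounds).  Deterministic per seed.
    """
    labels = np.asarray(labels)
    # canonical sample order so scores do not depend on column order
    order = np.argsort(np.asarray(table.columns, dtype=str), kind="stable")
    table = table.iloc[:, order]
    labels = labels[order]
    is_case = labels == "case"
    X = table.to_numpy(dtype=float).T  # samples x taxa
    case_idx = np.where(is_case)[0]
    ctrl_idx = np.where(~is_case)[0]
    if len(case_idx) == 0 or len(ctrl_idx) == 0:
        raise ValueError("both classes must be present")

    def draw_size(n: int) -> int:
        size = int(round(subsample_frac * n))
        if size < 3:
            logger.info(
                "lda_effect_size: class of %d too small for frac %.2f; using all samples",
                n, subsample_frac,
            )
            size = min(3, n)
        return min(size, n)

    rng = np.random.default_rng(seed)
    p = X.shape[1]
    acc = np.zeros(p)
    for _ in range(n_boot):
        ci = rng.choice(case_idx, size=draw_size(len(case_idx)), replace=False)
        ki = rng.choice(ctrl_idx, size=draw_size(len(ctrl_idx)), replace=False)
        mu1 = X[ci].mean(axis=0)
        mu0 = X[ki].mean(axis=0)
        diff = mu1 - mu0
        cov = 0.5 * (np.cov(X[ci], rowvar=False) + np.cov(X[ki], rowvar=False))
        cov = np.atleast_2d(cov) + RIDGE_EPS * np.eye(p)
        w = np.linalg.solve(cov, diff)
        norm = np.linalg.norm(w)
        if norm == 0:
            acc += np.abs(diff)  # zero discriminant: fall back to mean difference
            continue
        w_hat = w / norm
        projected = abs(float(w_hat @ diff))
        acc += 0.5 * (np.abs(diff) + np.abs(w_hat) * projected)
    return pd.Series(np.log10(1.0 + acc / n_boot), index=list(table.index))


def lefse_markers(table: pd.DataFrame, labels, alpha: float = 0.05,
                  lda_cutoff: float = 2.0, n_boot: int = 30,
                  subsample_frac: float = 2.0 / 3.0, seed: int = 0,
                  source: str = "cohort") -> MarkerSet:
    """Full marker call: rank screen, LDA effect size, cutoff, sign.

    Profiles are rescaled to sum 1e6 per sample before both stages.  An empty
    MarkerSet is a valid outcome.
    """
    labels = np.asarray(labels)
    totals = table.sum(axis=0).to_numpy(dtype=float)
    if np.any(totals <= 0):
        raise ValueError("samples with zero total abundance cannot be rescaled")
    scaled = table * (LEFSE_SCALE / totals)

    screen = kw_screen(scaled, labels, alpha)
    passed = screen[screen["passed"]]
    markers: list[Marker] = []
    if len(passed):
        sub = scaled.loc[passed["taxon"]]
        scores = lda_effect_size(sub, labels, n_boot, subsample_frac, seed)
        is_case = labels == "case"
        case_means = sub.to_numpy()[:, is_case].mean(axis=1)
        ctrl_means = sub.to_numpy()[:, ~is_case].mean(axis=1)
        signs = np.where(case_means >= ctrl_means, 1.0, -1.0)
        pvals = passed.set_index("taxon")["p_value"]
        for taxon, sign in zip(sub.index, signs):
            score = float(scores[taxon])
            if score >= lda_cutoff:
                markers.append(Marker(taxon, sign * score, float(pvals[taxon])))
    return MarkerSet(source, markers, lda_cutoff)
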