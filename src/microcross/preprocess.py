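"""Sample/feature QC, confounder detection and removal, batch correction.

QC keeps the conventions of relative-abundance pipelines: samples with two or
fewer detected taxa are removed, and taxa never reaching 0.001 relative
abundance in any sample are dropped; surviving values are NOT renormalized.

Confounders are covariates whose distribution differs between cases and
controls within a cohort (Fisher's exact test for categorical covariates,
Wilcoxon rank-sum for quantitative ones).  Their fitted contribution is
regressed out of log abundances with the label kept in the design, mirroring
limma's removeBatchEffect.  Cross-cohort batch effects are removed by a
zero-preserving empirical-Bayes location/scale correction of per-taxon
log-abundance distributions (ComBat-style shrinkage), again keeping the
label in the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .util import logger

LOG_N0 = 1e-6  # pseudocount shared with the normalization module


@dataclass
class QcReport:
    dropped_samples: list[str] = field(default_factory=list)
    dropped_taxa: list[str] = field(default_factory=list)


def qc_filter(table: pd.DataFrame) -> tuple[pd.DataFrame, QcReport]:
    """Drop samples with <=2 nonzero taxa and taxa below 0.001 everywhere.

    The two rules are iterated to a fixed point, which makes the filter
    idempotent.  Values are left untouched (no renormalization).
    """
    vals = table.to_numpy(dtype=float)
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("relative abundances must lie in [0, 1]")
    report = QcReport()
    current = table
    while True:
        low_taxa = current.max(axis=1) < 0.001
        sparse_samples = (current > 0).sum(axis=0) <= 2
        if not low_taxa.any() and not sparse_samples.any():
            break
        report.dropped_taxa.extend(current.index[low_taxa])
        report.dropped_samples.extend(current.columns[sparse_samples])
        current = current.loc[~low_taxa, ~sparse_samples]
        if current.shape[0] == 0:
            raise ValueError("all taxa removed by the <0.001 abundance filter")
        if current.shape[1] == 0:
            raise ValueError("all samples removed by the <=2 nonzero taxa filter")
    return current, report


def _covariate_columns(meta: pd.DataFrame) -> list[str]:
    return [c for c in meta.columns if c not in ("sample_id", "cohort_id", "label")]


def covariate_kind(series: pd.Series) -> str:
    """'quantitative' for numeric covariates with >2 distinct values, else 'categorical'."""
    if pd.api.types.is_numeric_dtype(series) and series.nunique() > 2:
        return "quantitative"
    return "categorical"


def detect_confounders(meta: pd.DataFrame, alpha: float = 0.05,
                       kinds: Mapping[str, str] | None = None) -> list[str]:
    """Covariates significantly associated with the label within a cohort.

    Categorical covariates: two-sided Fisher's exact test (chi-square when a
    covariate has more than two levels).  Quantitative covariates: two-sided
    Wilcoxon rank-sum.  Constant covariates are skipped with a logged note.
    Returned in metadata column order (deterministic).
    """
    labels = meta["label"].to_numpy()
    if min((labels == "case").sum(), (labels == "control").sum()) < 2:
        raise ValueError("need at least two samples per label group")
    flagged = []
    for name in _covariate_columns(meta):
        series = meta[name]
        if series.nunique(dropna=True) <= 1:
            logger.info("covariate %r constant across samples; skipped", name)
            continue
        kind = (kinds or {}).get(name) or covariate_kind(series)
        if kind == "quantitative":
            case = series[labels == "case"].astype(float)
            control = series[labels == "control"].astype(float)
            p = stats.mannwhitneyu(case, control, alternative="two-sided").pvalue
        else:
            contingency = pd.crosstab(series, meta["label"])
            if contingency.shape[0] == 2:
                p = stats.fisher_exact(contingency.to_numpy())[1]
            else:
                p = stats.chi2_contingency(contingency.to_numpy())[1]
        if p < alpha:
            flagged.append(name)
    return flagged


def _design_matrix(meta: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    """Intercept + label + covariate columns (categoricals one-hot, first level dropped)."""
    n = len(meta)
    cols = [np.ones(n), (meta["label"].to_numpy() == "case").astype(float)]
    names = ["intercept", "label"]
    for name in covariates:
        series = meta[name]
        if covariate_kind(series) == "quantitative":
            cols.append(series.to_numpy(dtype=float))
            names.append(name)
        else:
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:
                cols.append((series.astype(str) == level).astype(float).to_numpy())
                names.append(f"{name}[{level}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design; collinear covariates among {list(covariates)}"
        )
    return X


def adjust_confounders(table: pd.DataFrame, meta: pd.DataFrame,
                       covariates: Sequence[str]) -> pd.DataFrame:
    """Regress flagged covariates out of log10 abundances, keeping the label.

    Per taxon, an OLS fit of log10(x + 1e-6) on intercept + label +
    covariates; the mean-centered covariate contribution is subtracted and
    the result back-transformed and floored at 0.  Empty covariate list
    returns the table unchanged.
    """
    if not covariates:
        return table
    meta = meta.set_index("sample_id").loc[list(table.columns)].reset_index()
    X = _design_matrix(meta, covariates)
    Y = np.log10(table.to_numpy(dtype=float) + LOG_N0).T  # samples x taxa
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    nuisance = X[:, 2:] - X[:, 2:].mean(axis=0)
    adjusted_log = Y - nuisance @ beta[2:]
    out = np.power(10.0, adjusted_log).T - LOG_N0
    return pd.DataFrame(np.maximum(out, 0.0), index=table.index, columns=table.columns)


def _eb_solve(z: np.ndarray, taxon_of: np.ndarray, n_taxa: int,
              max_iter: int = 100, tol: float = 1e-5):
    """Empirical-Bayes shrinkage of per-taxon location/scale within one cohort.

    ``z`` holds standardized non-zero residuals, ``taxon_of`` their taxon
    index.  Normal prior on locations, inverse-gamma on scales; hyper-
    parameters by method of moments; joint posterior-mode iteration as in the
    standard parametric ComBat formulation.  Returns per-taxon (gamma*,
    delta2*) with NaN for taxa lacking enough observations.
    """
    gamma_hat = np.full(n_taxa, np.nan)
    delta2_hat = np.full(n_taxa, np.nan)
    counts = np.zeros(n_taxa)
    for t in range(n_taxa):
        zt = z[taxon_of == t]
        counts[t] = len(zt)
        if len(zt) >= 2:
            gamma_hat[t] = zt.mean()
            delta2_hat[t] = zt.var(ddof=1)
    ok = ~np.isnan(gamma_hat) & (delta2_hat > 0)
    if ok.sum() < 2:
        return gamma_hat, np.where(delta2_hat > 0, delta2_hat, np.nan)

    gamma_bar = gamma_hat[ok].mean()
    tau2 = gamma_hat[ok].var(ddof=1)
    m = delta2_hat[ok].mean()
    s2 = delta2_hat[ok].var(ddof=1)
    if tau2 <= 0 or s2 <= 0:
        return gamma_hat, delta2_hat
    a_prior = (2 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    g_star = gamma_hat.copy()
    d_star = delta2_hat.copy()
    n = counts
    for _ in range(max_iter):
        g_new = np.where(
            ok, (n * tau2 * gamma_hat + d_star * gamma_bar) / (n * tau2 + d_star), g_star
        )
        ssq = np.zeros(n_taxa)
        for t in np.where(ok)[0]:
            zt = z[taxon_of == t]
            ssq[t] = np.sum((zt - g_new[t]) ** 2)
        d_new = np.where(ok, (b_prior + 0.5 * ssq) / (n / 2.0 + a_prior - 1.0), d_star)
        change = np.nanmax(
            np.abs(np.concatenate([(g_new - g_star)[ok], (d_new - d_star)[ok]]))
        )
        g_star, d_star = g_new, d_new
        if change < tol:
            break
    return g_star, d_star


def adjust_batch(tables: Mapping[str, pd.DataFrame], meta: pd.DataFrame,
                 covariates: Sequence[str] = ()) -> dict[str, pd.DataFrame]:
    """Remove cross-cohort batch effects; zero-preserving, label-protected.

    Non-zero entries of each taxon are log10-transformed, residualized
    against intercept + label (+ covariates), standardized, and the
    per-cohort location/scale of the residuals is shrunk toward the grand
    parameters with empirical-Bayes priors before being removed.  Zeros stay
    zero; each sample is renormalized to sum 1.  A single cohort is returned
    unchanged.
    """
    cohorts = list(tables)
    if len(cohorts) < 2:
        return {c: t.copy() for c, t in tables.items()}

    features: list[str] = []
    for t in tables.values():
        features.extend(x for x in t.index if x not in features)
    n_taxa = len(features)

    aligned = {c: tables[c].reindex(features, fill_value=0.0) for c in cohorts}
    meta_idx = meta.set_index("sample_id")
    big = pd.concat([aligned[c] for c in cohorts], axis=1)
    samples = list(big.columns)
    labels = (meta_idx.loc[samples, "label"].to_numpy() == "case").astype(float)
    cohort_of = meta_idx.loc[samples, "cohort_id"].to_numpy()

    sub_meta = meta_idx.loc[samples].reset_index()
    X = _design_matrix(sub_meta, covariates)

    vals = big.to_numpy(dtype=float)
    nz = vals > 0
    for c in cohorts:
        if nz[:, cohort_of == c].sum() < 3:
            raise ValueError(f"cohort {c!r} has fewer than 3 non-zero observations")

    logv = np.full_like(vals, np.nan)
    logv[nz] = np.log10(vals[nz])

    # ComBat-style standardization per taxon on non-zero entries: cohort
    # indicators enter the fit (so batch shifts do not inflate the residual
    # scale), label + covariates are protected and added back, and the
    # batch-free standardized data keep the cohort location/scale effects
    # for the EB step to estimate and remove.
    Xcov = X[:, 1:]  # label + covariate columns; cohort dummies span the intercept
    cohort_index = np.array([cohorts.index(c) for c in cohort_of])
    stand_part = np.full_like(vals, np.nan)  # stand_mean + Xcov @ beta
    sigma = np.full(n_taxa, np.nan)
    for t in range(n_taxa):
        mask = nz[t]
        if mask.sum() < 3:
            continue
        present, inverse = np.unique(cohort_index[mask], return_inverse=True)
        D = np.zeros((mask.sum(), len(present)))
        D[np.arange(mask.sum()), inverse] = 1.0
        Xt = np.hstack([D, Xcov[mask]])
        yt = logv[t, mask]
        beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        alpha = beta[: len(present)]
        bcov = beta[len(present):]
        counts = D.sum(axis=0)
        stand_mean = float(np.sum(alpha * counts) / counts.sum())
        resid = yt - Xt @ beta
        sd = resid.std(ddof=1)
        if sd <= 0:
            continue
        sigma[t] = sd
        stand_part[t, mask] = stand_mean + Xcov[mask] @ bcov

    adjusted = vals.copy()
    usable = nz & ~np.isnan(stand_part)
    z = np.full_like(vals, np.nan)
    z[usable] = (logv[usable] - stand_part[usable]) / np.repeat(
        sigma[:, None], vals.shape[1], axis=1
    )[usable]

    for c in cohorts:
        cmask = cohort_of == c
        tt, ss = np.where(usable[:, cmask])
        zc = z[:, cmask][tt, ss]
        g_star, d_star = _eb_solve(zc, tt, n_taxa)
        for t in range(n_taxa):
            if np.isnan(g_star[t]) or np.isnan(d_star[t]) or d_star[t] <= 0:
                continue
            entry = usable[t] & cmask
            znew = (z[t, entry] - g_star[t]) / np.sqrt(d_star[t])
            adjusted[t, entry] = np.power(
                10.0, stand_part[t, entry] + sigma[t] * znew
            )

    adjusted[~nz] = 0.0
    totals = adjusted.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("batch adjustment produced an all-zero sample")
    adjusted /= totals[None, :]

    out_all = pd.DataFrame(adjusted, index=features, columns=samples)
    return {c: out_all.loc[:, cohort_of == c] for c in cohorts}
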