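"""Evaluation designs, sample-size extrapolation and the MSI-AUC linkage.

Four designs are orchestrated over a multi-cohort dataset:

* ``intra``/``cross``: one nested-CV model per cohort, validated internally
  (out-of-fold) and on every other cohort of the same disease;
* ``lodo``: leave-one-dataset-out — train on the pooled remaining cohorts,
  test the left-out one (requires >= 3 cohorts);
* ``ccm``: cohort-cumulation — training pools of growing cohort counts,
  tested on the excluded cohorts (requires >= 5 cohorts);
* ``scm``: sample-cumulation — balanced 1:1 case:control training subsets of
  growing size drawn from the LODO pool, tested on the left-out cohort
  (requires >= 5 cohorts; default grid 16..40 step 6, then 60..max step 20).

The sample-size extrapolation fits ordinary least squares of median external
AUC on training-set size and inverts it (with a prediction-interval CI) at a
target AUC.  The MSI-AUC linkage pairs each (train, test) cohort ordering's
Marker Similarity Index with its external validation AUC and reports a
Spearman correlation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import MultiCohortDataset
from .features import SmoteConfig
from .markers import MarkerSet, lefse_markers
from .metrics import EvalRecord, evaluate, records_to_frame
from .models import ClassifierSpec, FittedModel, nested_cv_train, predict_external
from .msi import msi, msi_matrix
from .preprocess import adjust_batch, adjust_confounders, detect_confounders, qc_filter
from .simulate import SimConfig, simulate_multicohort
from .util import derive_seed, logger

SCM_GRID_LOW = (16, 22, 28, 34, 40)
SCM_GRID_STEP_HIGH = 20


def run_single_cohort(
    dataset: MultiCohortDataset, spec: ClassifierSpec
) -> tuple[list[EvalRecord], dict[str, FittedModel]]:
    """Per-cohort nested-CV models; internal plus all-pairs external records.

    K cohorts yield K ``intra`` records (out-of-fold scores) and K*(K-1)
    ``cross`` records (each model applied to every other cohort).
    """
    records: list[EvalRecord] = []
    models: dict[str, FittedModel] = {}
    cohorts = dataset.cohort_ids
    for cohort in cohorts:
        table = dataset.tables[cohort]
        labels = dataset.labels_for(cohort)
        cspec = replace(spec, seed=derive_seed(spec.seed, f"intra-{cohort}"))
        model = nested_cv_train(table, labels, cspec)
        models[cohort] = model
        records.append(
            evaluate(
                "intra", cohort, cohort, model.n_train,
                model.oof_mean_scores().to_numpy(), model.labels.to_numpy(),
            )
        )
    for cohort in cohorts:
        for other in cohorts:
            if other == cohort:
                continue
            scores = predict_external(models[cohort], dataset.tables[other])
            records.append(
                evaluate(
                    "cross", cohort, other, models[cohort].n_train,
                    scores.to_numpy(), dataset.labels_for(other).to_numpy(),
                )
            )
    return records, models


def run_lodo(
    dataset: MultiCohortDataset, spec: ClassifierSpec
) -> tuple[list[EvalRecord], dict[str, FittedModel]]:
    """Leave-one-dataset-out: pool all but one cohort, test the left-out one."""
    cohorts = dataset.cohort_ids
    if len(cohorts) < 3:
        raise ValueError("LODO requires at least 3 cohorts")
    records: list[EvalRecord] = []
    models: dict[str, FittedModel] = {}
    for left_out in cohorts:
        train_cohorts = [c for c in cohorts if c != left_out]
        pooled, labels = dataset.pooled(train_cohorts)
        test_table = dataset.tables[left_out]
        leaked = set(pooled.columns) & set(test_table.columns)
        if leaked:
            raise RuntimeError(f"LODO leakage: {sorted(leaked)[:5]}")
        lspec = replace(spec, seed=derive_seed(spec.seed, f"lodo-{left_out}"))
        model = nested_cv_train(pooled, labels, lspec)
        models[left_out] = model
        scores = predict_external(model, test_table)
        records.append(
            evaluate(
                "lodo", "+".join(train_cohorts), left_out, model.n_train,
                scores.to_numpy(), dataset.labels_for(left_out).to_numpy(),
            )
        )
    return records, models


def run_ccm(
    dataset: MultiCohortDataset, spec: ClassifierSpec,
    draws_per_size: int = 20, seed: int = 0,
) -> list[EvalRecord]:
    """Cohort-cumulation: training pools of 2..K-1 cohorts, excluded cohorts as tests.

    All subsets are enumerated when their number is within ``draws_per_size``;
    otherwise that many are drawn without replacement under ``seed``.
    """
    cohorts = dataset.cohort_ids
    if len(cohorts) < 5:
        raise ValueError("cohort-cumulation requires at least 5 cohorts")
    rng = np.random.default_rng(seed)
    records: list[EvalRecord] = []
    for size in range(2, len(cohorts)):
        combos = list(itertools.combinations(cohorts, size))
        if len(combos) > draws_per_size:
            picked = rng.choice(len(combos), size=draws_per_size, replace=False)
            combos = [combos[i] for i in sorted(picked)]
        for subset in combos:
            pooled, labels = dataset.pooled(subset)
            sspec = replace(
                spec, seed=derive_seed(spec.seed, f"ccm-{size}-{'+'.join(subset)}")
            )
            model = nested_cv_train(pooled, labels, sspec)
            for test in cohorts:
                if test in subset:
                    continue
                scores = predict_external(model, dataset.tables[test])
                records.append(
                    evaluate(
                        "ccm", "+".join(subset), test, model.n_train,
                        scores.to_numpy(), dataset.labels_for(test).to_numpy(),
                        tag=str(size),
                    )
                )
    return records


def default_scm_grid(max_n: int) -> list[int]:
    """16..40 step 6, then 60..max step 20, capped at the balanced pool size."""
    pts = [p for p in SCM_GRID_LOW if p <= max_n]
    pts += list(range(60, max_n + 1, SCM_GRID_STEP_HIGH))
    if not pts:
        raise ValueError(f"balanced pool of {max_n} is below the smallest grid point")
    return pts


def run_scm(
    dataset: MultiCohortDataset, spec: ClassifierSpec,
    grid: Sequence[int] | None = None, draws_per_point: int = 10,
    seed: int = 0, test_cohorts: Iterable[str] | None = None,
) -> list[EvalRecord]:
    """Sample-cumulation: balanced 1:1 training draws from the LODO pool.

    Per left-out cohort and grid point n, ``draws_per_point`` subsets of n/2
    cases and n/2 controls are drawn from the pooled remaining cohorts,
    trained and tested on the left-out cohort.  Grid points exceeding the
    balanced pool are capped with a logged note.
    """
    cohorts = dataset.cohort_ids
    if len(cohorts) < 5:
        raise ValueError("sample-cumulation requires at least 5 cohorts")
    rng = np.random.default_rng(seed)
    records: list[EvalRecord] = []
    for left_out in test_cohorts or cohorts:
        train_cohorts = [c for c in cohorts if c != left_out]
        pooled, labels = dataset.pooled(train_cohorts)
        case_ids = [s for s, l in labels.items() if l == "case"]
        ctrl_ids = [s for s, l in labels.items() if l == "control"]
        max_balanced = 2 * min(len(case_ids), len(ctrl_ids))
        if grid is None:
            points = default_scm_grid(max_balanced)
        else:
            points = []
            for g in grid:
                if int(g) % 2:
                    raise ValueError("SCM grid points must be even for a 1:1 ratio")
                if g > max_balanced:
                    logger.info(
                        "SCM grid point %d exceeds balanced pool %d; capped",
                        g, max_balanced,
                    )
                    g = max_balanced - (max_balanced % 2)
                if g >= 4 and g not in points:
                    points.append(int(g))
        if sorted(points) != points:
            raise ValueError("SCM grid must be strictly increasing")
        test_table = dataset.tables[left_out]
        test_labels = dataset.labels_for(left_out).to_numpy()
        for n in points:
            for d in range(draws_per_point):
                half = n // 2
                chosen = list(rng.choice(case_ids, half, replace=False)) + list(
                    rng.choice(ctrl_ids, half, replace=False)
                )
                sub = pooled[chosen]
                sub_labels = labels.loc[chosen]
                sspec = replace(
                    spec, seed=derive_seed(spec.seed, f"scm-{left_out}-{n}-{d}")
                )
                model = nested_cv_train(sub, sub_labels, sspec)
                scores = predict_external(model, test_table)
                records.append(
                    evaluate(
                        "scm", f"{'+'.join(train_cohorts)}|n={n}|draw={d}",
                        left_out, n, scores.to_numpy(), test_labels, tag=str(n),
                    )
                )
    return records


@dataclass
class ExtrapolationResult:
    attainable: bool
    target_auc: float
    slope: float
    intercept: float
    n_required: Optional[int] = None
    ci: Optional[tuple[float, float]] = None  # 95% CI on n, prediction-interval inversion


def extrapolate_n_required(
    records: Iterable[EvalRecord], target_auc: float,
    grid_step: Optional[int] = None,
) -> ExtrapolationResult:
    """OLS of median external AUC on n_train, inverted at ``target_auc``.

    The point estimate is rounded up to the grid step (default: the smallest
    spacing between distinct training sizes); the 95% CI comes from inverting
    the regression's prediction interval.  A non-positive slope yields an
    explicitly non-attainable result instead of a fabricated number.
    """
    frame = records_to_frame(list(records))
    med = frame.groupby("n_train")["auc"].median()
    if len(med) < 3:
        raise ValueError("need at least 3 distinct training sizes")
    ns = med.index.to_numpy(dtype=float)
    aucs = med.to_numpy(dtype=float)
    X = sm.add_constant(ns)
    fit = sm.OLS(aucs, X).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    if slope <= 1e-12:  # flat or negative trend: target not attainable
        return ExtrapolationResult(False, target_auc, slope, intercept)
    step = grid_step or int(np.min(np.diff(np.sort(ns))))
    raw = (target_auc - intercept) / slope
    n_required = int(np.ceil(round(raw / step, 9)) * step)

    # CI: smallest n whose upper/lower prediction bound reaches the target.
    span = np.linspace(0.0, max(raw * 3.0, ns.max() * 3.0) + 10 * step, 4001)
    pred = fit.get_prediction(sm.add_constant(span)).summary_frame(alpha=0.05)

    def first_crossing(bound: np.ndarray) -> float:
        hits = np.nonzero(bound >= target_auc)[0]
        if len(hits) == 0:
            return float("inf")
        i = hits[0]
        if i == 0 or bound[i] == bound[i - 1]:
            return float(span[i])
        frac = (target_auc - bound[i - 1]) / (bound[i] - bound[i - 1])
        return float(span[i - 1] + frac * (span[i] - span[i - 1]))

    ci_lo = first_crossing(pred["obs_ci_upper"].to_numpy())
    ci_hi = first_crossing(pred["obs_ci_lower"].to_numpy())
    if ci_lo == float("inf"):
        ci_lo = 0.0
    ci_lo = min(ci_lo, float(n_required))
    ci_hi = max(ci_hi, float(n_required))
    return ExtrapolationResult(
        True, target_auc, slope, intercept, n_required, (ci_lo, ci_hi)
    )


def correlate_msi_auc(
    msi_table: pd.DataFrame, records: Iterable[EvalRecord]
) -> tuple[float, float]:
    """Spearman correlation of pairwise MSI vs external AUC.

    Pairs are matched by (reference = training cohort, target = test cohort)
    over ``cross`` records.  Requires >= 4 matched pairs.
    """
    xs, ys = [], []
    for rec in records:
        if rec.design != "cross":
            continue
        if rec.train_id in msi_table.index and rec.test_cohort in msi_table.columns:
            val = msi_table.loc[rec.train_id, rec.test_cohort]
            if not np.isnan(val):
                xs.append(float(val))
                ys.append(rec.auc)
    return spearman_pairs(xs, ys)


def spearman_pairs(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rank correlation with p-value."""
    if len(x) < 4:
        raise ValueError("need at least 4 pairs for a Spearman correlation")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def lodo_marker_sets(
    tables: dict[str, pd.DataFrame], metadata: pd.DataFrame,
    alpha: float = 0.05, lda_cutoff: float = 2.0, seed: int = 0,
) -> list[tuple[MarkerSet, MarkerSet]]:
    """Marker sets under the LODO organization: (pooled reference, left-out target).

    Mirrors the combined-cohort marker analysis: for each cohort, markers of
    the pooled remaining cohorts are the reference and the left-out cohort's
    markers the target.
    """
    dataset = MultiCohortDataset(tables, metadata)
    out = []
    for left_out in dataset.cohort_ids:
        others = [c for c in dataset.cohort_ids if c != left_out]
        pooled, labels = dataset.pooled(others)
        ref = lefse_markers(
            pooled, labels.to_numpy(), alpha, lda_cutoff,
            seed=derive_seed(seed, f"lodo-ref-{left_out}"),
            source=f"pool-not-{left_out}",
        )
        tgt = lefse_markers(
            dataset.tables[left_out], dataset.labels_for(left_out).to_numpy(),
            alpha, lda_cutoff, seed=derive_seed(seed, f"lodo-tgt-{left_out}"),
            source=left_out,
        )
        out.append((ref, tgt))
    return out


@dataclass
class ExperimentConfig:
    """One full experiment: simulation, preprocessing and chosen designs."""

    sim: SimConfig = field(default_factory=SimConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    designs: tuple[str, ...] = ("intra", "cross", "lodo")
    alpha: float = 0.05
    lda_cutoff: float = 2.0
    apply_qc: bool = True
    apply_batch_correction: bool = True
    ccm_draws_per_size: int = 20
    scm_draws_per_point: int = 10
    scm_grid: Optional[tuple[int, ...]] = None


@dataclass
class ExperimentResult:
    records: pd.DataFrame
    msi: pd.DataFrame
    marker_sets: list[MarkerSet]
    msi_auc: Optional[tuple[float, float]]
    dataset: MultiCohortDataset


def prepare_dataset(
    dataset: MultiCohortDataset, alpha: float = 0.05,
    apply_qc: bool = True, apply_batch_correction: bool = True,
) -> tuple[MultiCohortDataset, dict[str, pd.DataFrame]]:
    """QC, per-cohort confounder removal, cross-cohort batch correction.

    Returns the modeling dataset (confounder- and batch-adjusted) plus the
    confounder-adjusted-only tables used for marker calling.
    """
    meta = dataset.metadata
    tables_adj: dict[str, pd.DataFrame] = {}
    kept_samples: list[str] = []
    for cohort, table in dataset.tables.items():
        if apply_qc:
            table, report = qc_filter(table)
            if report.dropped_samples:
                logger.info(
                    "%s: QC dropped %d samples", cohort, len(report.dropped_samples)
                )
        sub_meta = meta[meta["sample_id"].isin(table.columns)]
        sub_meta = sub_meta[sub_meta["cohort_id"] == cohort]
        confs = detect_confounders(sub_meta, alpha) if len(sub_meta.columns) > 3 else []
        if confs:
            logger.info("%s: adjusting confounders %s", cohort, confs)
            table = adjust_confounders(table, sub_meta, confs)
        tables_adj[cohort] = table
        kept_samples.extend(table.columns)
    meta_kept = meta[meta["sample_id"].isin(kept_samples)].reset_index(drop=True)

    if apply_batch_correction and len(tables_adj) >= 2:
        tables_model = adjust_batch(tables_adj, meta_kept)
    else:
        tables_model = dict(tables_adj)
    return MultiCohortDataset(tables_model, meta_kept), tables_adj


def run_experiment(
    config: ExperimentConfig, seed: int, outdir: str | Path | None = None
) -> ExperimentResult:
    """Simulate, preprocess, evaluate the requested designs, call markers,
    compute the MSI matrix and its linkage to external AUC; optionally write
    tidy TSVs.  Byte-identical outputs under a fixed seed."""
    sim = replace(config.sim, seed=derive_seed(seed, "simulate"))
    dataset, _truth = simulate_multicohort(sim)
    model_ds, tables_lefse = prepare_dataset(
        dataset, config.alpha, config.apply_qc, config.apply_batch_correction
    )
    spec = replace(config.classifier, seed=derive_seed(seed, "classifier"))
    # combined-cohort designs conventionally use 10-fold CV on the pool
    pooled_spec = replace(spec, outer_folds=max(spec.outer_folds, 10))

    records: list[EvalRecord] = []
    if "intra" in config.designs or "cross" in config.designs:
        recs, _ = run_single_cohort(model_ds, spec)
        records.extend(recs)
    if "lodo" in config.designs:
        recs, _ = run_lodo(model_ds, pooled_spec)
        records.extend(recs)
    if "ccm" in config.designs:
        records.extend(
            run_ccm(model_ds, pooled_spec, config.ccm_draws_per_size,
                    derive_seed(seed, "ccm"))
        )
    if "scm" in config.designs:
        records.extend(
            run_scm(
                model_ds, pooled_spec, config.scm_grid, config.scm_draws_per_point,
                derive_seed(seed, "scm"),
            )
        )

    marker_sets = []
    meta_idx = model_ds.metadata.set_index("sample_id")
    for cohort, table in tables_lefse.items():
        labels = meta_idx.loc[list(table.columns), "label"].to_numpy()
        marker_sets.append(
            lefse_markers(
                table, labels, config.alpha, config.lda_cutoff,
                seed=derive_seed(seed, f"lefse-{cohort}"), source=cohort,
            )
        )
    msi_table = msi_matrix(marker_sets) if len(marker_sets) >= 2 else pd.DataFrame()

    linkage = None
    cross = [r for r in records if r.design == "cross"]
    if len(cross) >= 4 and not msi_table.empty:
        try:
            linkage = correlate_msi_auc(msi_table, cross)
        except ValueError:
            linkage = None

    frame = records_to_frame(records)
    result = ExperimentResult(frame, msi_table, marker_sets, linkage, model_ds)
    if outdir is not None:
        write_report(result, outdir)
    return result


def write_report(result: ExperimentResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(
        outdir / "records.tsv", sep="\t", index=False, float_format="%.10g"
    )
    if not result.msi.empty:
        result.msi.to_csv(outdir / "msi_matrix.tsv", sep="\t", float_format="%.10g")
    markers_dir = outdir / "markers"
    markers_dir.mkdir(exist_ok=True)
    for ms in result.marker_sets:
        ms.write(markers_dir / f"{ms.source}.tsv")
    summary = (
        result.records.groupby("design")[["auc", "auc_pr", "mcc"]]
        .describe(percentiles=[0.25, 0.5, 0.75])
        .round(6)
    )
    summary.columns = ["_".join(c) for c in summary.columns]
    summary.to_csv(outdir / "summary.tsv", sep="\t", float_format="%.10g")
    if result.msi_auc is not None:
        pd.DataFrame(
            [{"spearman_r": result.msi_auc[0], "p_value": result.msi_auc[1]}]
        ).to_csv(outdir / "msi_auc_correlation.tsv", sep="\t", index=False,
                 float_format="%.10g")
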