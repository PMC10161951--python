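"""Nested cross-validated classifiers with frozen normalization.

Training follows the leak-free nested design standard in microbiome
classification: stratified outer folds (with repeats), hyperparameters
chosen per outer split by an inner grid-searched cross-validation run only
on the outer-training portion, and normalization / SMOTE / feature selection
all fitted inside the outer-training portion.  External prediction maps a
test cohort onto the training feature list (raw zero-fill for absent taxa),
applies each fold's frozen normalization, and averages the fold models'
scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .features import (
    NormalizationParams,
    SmoteConfig,
    log_std_apply,
    log_std_fit,
    smote_balance,
)
from .metrics import auc
from .util import derive_seed, logger

ALGORITHMS = ("lasso", "enet", "ridge", "random_forest")
TOP_N_CHOICES = (11, 15, 20, 25, 30, 35, 40)


@dataclass
class ClassifierSpec:
    """Algorithm choice, hyperparameter grid and nested-CV design.

    ``c_grid`` holds inverse regularization strengths for the linear
    algorithms, ordered weakest-C first so ties in inner AUC resolve toward
    stronger regularization.  ``outer_folds`` defaults to 5 (intra-cohort
    design); combined-cohort designs pass 10.
    """

    algorithm: str = "lasso"
    c_grid: tuple[float, ...] = tuple(np.logspace(-3.0, 3.0, 20))
    l1_ratio_grid: tuple[float, ...] = (0.2, 0.5, 0.8)
    rf_n_estimators: int = 200
    rf_max_features_grid: tuple = ("sqrt", 0.3)
    outer_folds: int = 5
    inner_folds: int = 5
    repeats: int = 3
    top_n: Optional[int] = None  # None = all features
    smote_mode: str = "fold"  # fold | cohort | off
    smote_k: int = 5
    log_n0: float = 1e-6
    sd_min_q: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.c_grid:
            raise ValueError("hyperparameter grid must be non-empty")
        if self.smote_mode not in ("fold", "cohort", "off"):
            raise ValueError("smote_mode must be fold, cohort or off")

    def grid(self) -> list[dict]:
        """Candidate hyperparameter settings, strongest regularization first."""
        if self.algorithm == "lasso" or self.algorithm == "ridge":
            return [{"C": c} for c in sorted(self.c_grid)]
        if self.algorithm == "enet":
            return [
                {"C": c, "l1_ratio": r}
                for c in sorted(self.c_grid)
                for r in self.l1_ratio_grid
            ]
        return [
            {"n_estimators": self.rf_n_estimators, "max_features": mf}
            for mf in self.rf_max_features_grid
        ]


def make_estimator(spec: ClassifierSpec, params: dict, seed: int):
    if spec.algorithm == "lasso":
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=params["C"],
            max_iter=2000, random_state=seed,
        )
    if spec.algorithm == "ridge":
        return LogisticRegression(
            l1_ratio=0.0, solver="liblinear", C=params["C"],
            max_iter=2000, random_state=seed,
        )
    if spec.algorithm == "enet":
        return LogisticRegression(
            l1_ratio=params["l1_ratio"], solver="saga", C=params["C"],
            max_iter=2000, tol=1e-3, random_state=seed,
        )
    return RandomForestClassifier(
        n_estimators=params["n_estimators"], max_features=params["max_features"],
        random_state=seed, n_jobs=1,
    )


@dataclass
class FoldModel:
    estimator: object
    normalization: NormalizationParams
    features: list[str]
    hyperparams: dict
    repeat: int
    fold: int


@dataclass
class FittedModel:
    """All fold models plus out-of-fold bookkeeping for one training set."""

    folds: list[FoldModel]
    oof_scores: pd.DataFrame  # samples x repeats
    labels: pd.Series
    spec: ClassifierSpec
    feature_list: list[str]
    normalization: NormalizationParams  # fitted on the full training table
    audit: list[dict] = field(default_factory=list)
    n_train: int = 0

    def internal_auc(self) -> float:
        """Mean over repeats of the out-of-fold AUC."""
        vals = [
            auc(self.oof_scores[r].to_numpy(), self.labels.to_numpy())
            for r in self.oof_scores.columns
        ]
        return float(np.mean(vals))

    def oof_mean_scores(self) -> pd.Series:
        return self.oof_scores.mean(axis=1)

    def save(self, outdir: str | Path) -> None:
        """Serialize a linear-model bundle: coefficients TSV + params JSON."""
        if self.spec.algorithm == "random_forest":
            raise NotImplementedError("only linear model bundles serialize to TSV")
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, fm in enumerate(self.folds):
            fm.normalization.to_json(outdir / f"fold_{i:03d}.norm.json")
            for feat, coef in zip(fm.features, fm.estimator.coef_[0]):
                rows.append({"fold": i, "feature": feat, "coef": coef})
            rows.append(
                {"fold": i, "feature": "__intercept__",
                 "coef": float(fm.estimator.intercept_[0])}
            )
        pd.DataFrame(rows).to_csv(
            outdir / "coefficients.tsv", sep="\t", index=False, float_format="%.12g"
        )
        meta = {
            "spec": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(self.spec).items()},
            "feature_list": self.feature_list,
            "n_train": self.n_train,
            "fold_hyperparams": [fm.hyperparams for fm in self.folds],
            "fold_design": [[fm.repeat, fm.fold] for fm in self.folds],
        }
        (outdir / "model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, indir: str | Path) -> "FittedModel":
        indir = Path(indir)
        meta = json.loads((indir / "model.json").read_text())
        raw_spec = meta["spec"]
        for key in ("c_grid", "l1_ratio_grid", "rf_max_features_grid"):
            raw_spec[key] = tuple(raw_spec[key])
        spec = ClassifierSpec(**raw_spec)
        coefs = pd.read_csv(indir / "coefficients.tsv", sep="\t")
        folds = []
        for i, (hyper, (rep, fold)) in enumerate(
            zip(meta["fold_hyperparams"], meta["fold_design"])
        ):
            params = NormalizationParams.from_json(indir / f"fold_{i:03d}.norm.json")
            sub = coefs[coefs["fold"] == i].set_index("feature")["coef"]
            feats = [f for f in sub.index if f != "__intercept__"]
            est = make_estimator(spec, _first_params(spec, hyper), seed=0)
            est.classes_ = np.array([False, True])
            est.coef_ = sub.loc[feats].to_numpy()[None, :]
            est.intercept_ = np.array([sub["__intercept__"]])
            est.n_features_in_ = len(feats)
            folds.append(FoldModel(est, params, feats, hyper, rep, fold))
        full_norm = folds[0].normalization
        empty = pd.DataFrame(index=pd.Index([], name="sample"))
        return cls(
            folds=folds, oof_scores=empty, labels=pd.Series(dtype=object),
            spec=spec, feature_list=meta["feature_list"],
            normalization=full_norm, n_train=meta["n_train"],
        )


def _first_params(spec: ClassifierSpec, hyper: dict) -> dict:
    merged = dict(spec.grid()[0])
    merged.update(hyper)
    return merged


def select_top_features(matrix: pd.DataFrame, labels, n: int) -> list[str]:
    """Top-N features by single-feature absolute AUC (inside outer-train only).

    The ranking key is max(AUC, 1-AUC), descending; ties break by
    lexicographic feature id.  With n >= the feature count the original list
    is returned unchanged.
    """
    if n <= 0:
        raise ValueError("top-N must be positive")
    feats = list(matrix.columns)
    if n >= len(feats):
        return feats
    y = np.asarray(labels)
    keys = []
    for feat in feats:
        a = auc(matrix[feat].to_numpy(), y)
        keys.append((-max(a, 1.0 - a), feat))
    keys.sort()
    return [feat for _, feat in keys[:n]]


def _safe_folds(requested: int, labels: np.ndarray) -> int:
    smallest = min((labels == "case").sum(), (labels != "case").sum())
    if smallest < 2:
        raise ValueError("need at least two samples per class for stratified folds")
    if requested > smallest:
        logger.info(
            "reducing folds from %d to %d (smallest class)", requested, smallest
        )
        return int(smallest)
    return requested


def _maybe_smote(Z: pd.DataFrame, y: pd.Series, spec: ClassifierSpec,
                 seed: int) -> tuple[pd.DataFrame, pd.Series]:
    if spec.smote_mode == "off":
        return Z, y
    return smote_balance(Z, y, SmoteConfig(k=spec.smote_k, seed=seed))


def _grid_search(Z: pd.DataFrame, y: pd.Series, spec: ClassifierSpec,
                 seed: int) -> dict:
    """Inner k-fold grid search; returns the winning hyperparameter dict.

    Ties in mean inner AUC resolve to the earlier grid entry, i.e. stronger
    regularization.
    """
    grid = spec.grid()
    if len(grid) == 1:
        return grid[0]
    yarr = y.to_numpy()
    n_splits = _safe_folds(spec.inner_folds, yarr)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % 2**31)
    splits = list(skf.split(np.zeros(len(yarr)), yarr))
    best_params, best_score = grid[0], -np.inf
    for params in grid:
        scores = []
        for j, (tr, te) in enumerate(splits):
            Ztr, ytr = _maybe_smote(
                Z.iloc[tr], y.iloc[tr], spec, derive_seed(seed, f"inner-smote-{j}")
            )
            est = make_estimator(spec, params, derive_seed(seed, f"inner-fit-{j}"))
            est.fit(Ztr.to_numpy(), ytr.to_numpy() == "case")
            s = est.predict_proba(Z.iloc[te].to_numpy())[:, 1]
            scores.append(auc(s, yarr[te]))
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_score, best_params = mean_score, params
    return best_params


def nested_cv_train(table: pd.DataFrame, labels, spec: ClassifierSpec) -> FittedModel:
    """Train with repeated stratified nested CV on one (possibly pooled) table.

    ``table`` is taxa x samples raw relative abundance; ``labels`` aligns to
    its columns.  In the default ``smote_mode='fold'`` balancing happens only
    inside training portions; ``'cohort'`` reproduces whole-cohort balancing
    before splitting (leaky, kept for comparability with published practice).
    """
    labels = pd.Series(np.asarray(labels), index=list(table.columns))
    sample_ids = list(table.columns)

    full_norm = log_std_fit(table, spec.log_n0, spec.sd_min_q)

    if spec.smote_mode == "cohort":
        Zfull = log_std_apply(table, full_norm)
        Zdata, ydata = smote_balance(
            Zfull, labels, SmoteConfig(k=spec.smote_k, seed=derive_seed(spec.seed, "cohort-smote"))
        )
    else:
        Zdata, ydata = None, labels

    yarr = ydata.to_numpy() if Zdata is not None else labels.to_numpy()
    n_splits = _safe_folds(spec.outer_folds, yarr)

    oof = pd.DataFrame(np.nan, index=sample_ids, columns=range(spec.repeats))
    folds: list[FoldModel] = []
    audit: list[dict] = []
    all_ids = list(Zdata.index) if Zdata is not None else sample_ids

    for r in range(spec.repeats):
        skf = StratifiedKFold(
            n_splits=n_splits, shuffle=True,
            random_state=derive_seed(spec.seed, f"outer-{r}"),
        )
        for f, (tr, te) in enumerate(skf.split(np.zeros(len(yarr)), yarr)):
            fold_seed = derive_seed(spec.seed, f"fold-{r}-{f}")
            tr_ids = [all_ids[i] for i in tr]
            te_ids = [all_ids[i] for i in te]
            if Zdata is not None:
                Ztr, ytr = Zdata.iloc[tr], ydata.iloc[tr]
                norm = full_norm
            else:
                train_tab = table.iloc[:, tr]
                norm = log_std_fit(train_tab, spec.log_n0, spec.sd_min_q)
                Ztr = log_std_apply(train_tab, norm)
                ytr = labels.iloc[tr]

            feats = (
                select_top_features(Ztr, ytr, spec.top_n)
                if spec.top_n is not None
                else list(Ztr.columns)
            )
            Ztr = Ztr[feats]

            best = _grid_search(Ztr, ytr, spec, fold_seed)
            if spec.smote_mode == "fold":
                Zfit, yfit = _maybe_smote(Ztr, ytr, spec, derive_seed(fold_seed, "fit-smote"))
            else:
                Zfit, yfit = Ztr, ytr
            est = make_estimator(spec, best, derive_seed(fold_seed, "fit"))
            est.fit(Zfit.to_numpy(), yfit.to_numpy() == "case")

            if Zdata is not None:
                Zte = Zdata.iloc[te][feats]
            else:
                Zte = log_std_apply(table.iloc[:, te], norm)[feats]
            scores = est.predict_proba(Zte.to_numpy())[:, 1]
            for sid, s in zip(te_ids, scores):
                if sid in oof.index:
                    oof.loc[sid, r] = s

            folds.append(FoldModel(est, norm, feats, best, r, f))
            audit.append({
                "repeat": r, "fold": f,
                "train_index": tr_ids, "test_index": te_ids,
                "hyperparams": best,
            })

    if oof.isna().any().any():
        raise RuntimeError("out-of-fold bookkeeping failed: missing scores")
    return FittedModel(
        folds=folds, oof_scores=oof, labels=labels, spec=spec,
        feature_list=list(table.index), normalization=full_norm,
        audit=audit, n_train=len(sample_ids),
    )


def predict_external(model: FittedModel, table: pd.DataFrame) -> pd.Series:
    """Score an external cohort: raw zero-fill, frozen per-fold normalization,
    fold-model score averaging."""
    train_feats = set(model.feature_list)
    overlap = train_feats & set(table.index)
    if not overlap:
        raise ValueError("no overlap between training and test features")
    frac = len(overlap) / len(train_feats)
    if frac < 0.5:
        warnings.warn(
            f"only {frac:.0%} of training features present in the test table",
            stacklevel=2,
        )
    acc = np.zeros(table.shape[1])
    for fm in model.folds:
        Z = log_std_apply(table, fm.normalization)[fm.features]
        acc += fm.estimator.predict_proba(Z.to_numpy())[:, 1]
    return pd.Series(acc / len(model.folds), index=list(table.columns))
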