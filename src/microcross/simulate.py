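"""Synthetic multi-cohort case-control microbiome data with known ground truth.

The generator emulates the structure of curated multi-cohort gut-microbiome
case-control collections: several cohorts of the same disease, compositional
sparse relative-abundance profiles, per-cohort batch shifts, and a set of
disease marker taxa whose cross-cohort consistency is a single tunable knob
(``consistency_rho``).

Generative model (all shifts in log2 space):

* each taxon has a global baseline log2 abundance drawn N(0, ``base_sd``),
  giving heavy-tailed, rank-realistic lognormal profiles;
* each cohort adds a per-taxon batch shift drawn N(0, ``batch_sd``);
* each sample adds i.i.d. noise N(0, ``sample_sd``) per taxon;
* in case samples, each marker taxon is multiplied by ``2**(sign*effect_size)``;
* entries drop to exact zero with probability ``zero_prob`` (detection limit),
  then each sample is closed to sum 1.

A fraction ``consistency_rho`` of the ``n_markers`` markers is shared by all
cohorts with a fixed direction; the remainder is drawn independently per
cohort (disjoint from the shared set) with per-cohort directions, so
``consistency_rho`` maps directly onto downstream cross-cohort statistics
(external-validation AUC, the Marker Similarity Index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .data import MultiCohortDataset
from .util import logger


@dataclass
class ConfounderSpec:
    """One optional covariate confounded with the label.

    A ``categorical`` covariate is binary; its level-1 probability differs
    between cases and controls according to ``odds_ratio`` (base rate 0.5 in
    controls), and level-1 samples get ``effect_size`` log2 units added to
    ``n_taxa`` affected taxa (disjoint from marker taxa).  A ``quantitative``
    covariate is standard normal plus ``label_shift`` in cases, and the
    affected taxa shift by ``effect_size * value`` log2 units.
    """

    name: str
    kind: str = "categorical"  # or "quantitative"
    n_taxa: int = 10
    effect_size: float = 1.0
    odds_ratio: float = 3.0
    label_shift: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "quantitative"):
            raise ValueError(f"unknown confounder kind {self.kind!r}")
        if self.n_taxa <= 0 or self.effect_size < 0:
            raise ValueError("confounder n_taxa must be positive, effect_size >= 0")


@dataclass
class SimConfig:
    """Study conditions for the multi-cohort simulation.

    Defaults follow the cohort structure of curated disease collections:
    median case/control group sizes of 48/47 per cohort, a few hundred taxa
    after filtering, and a handful of true markers with a 4-fold (2 log2
    units) case shift.
    """

    n_cohorts: int = 5
    n_case: int = 48
    n_control: int = 47
    n_taxa: int = 150
    n_markers: int = 25
    effect_size: float = 4.0
    consistency_rho: float = 1.0
    batch_sd: float = 1.0
    zero_prob: float = 0.3
    base_sd: float = 2.0
    sample_sd: float = 1.5
    confounder_spec: Optional[ConfounderSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_cohorts, self.n_case, self.n_control, self.n_taxa, self.n_markers)
        if any(int(c) != c or c <= 0 for c in counts):
            raise ValueError("cohort, sample, taxon and marker counts must be positive integers")
        if self.n_markers > self.n_taxa:
            raise ValueError(
                f"n_markers ({self.n_markers}) exceeds n_taxa ({self.n_taxa})"
            )
        if not 0.0 <= self.consistency_rho <= 1.0:
            raise ValueError("consistency_rho must lie in [0, 1]")
        if not 0.0 <= self.zero_prob < 1.0:
            raise ValueError("zero_prob must lie in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.batch_sd < 0 or self.base_sd <= 0 or self.sample_sd < 0:
            raise ValueError("standard deviations must be non-negative (base_sd > 0)")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        conf = raw.pop("confounder_spec", None)
        cfg = cls(**raw)
        if conf is not None:
            cfg.confounder_spec = ConfounderSpec(**conf)
        return cfg


@dataclass
class CohortTruth:
    """Simulation ground truth: per-cohort markers, directions, batch shifts."""

    markers: dict[str, dict[str, int]]  # cohort -> taxon -> +1 (case) / -1 (control)
    batch_shifts: pd.DataFrame  # taxa x cohorts, log2 units
    confounder_taxa: list[str] = field(default_factory=list)

    def marker_sets_identical(self) -> bool:
        items = [tuple(sorted(m.items())) for m in self.markers.values()]
        return len(set(items)) <= 1

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = [
            {"cohort_id": cohort, "taxon": taxon, "direction": sign}
            for cohort, markers in self.markers.items()
            for taxon, sign in sorted(markers.items())
        ]
        pd.DataFrame(rows, columns=["cohort_id", "taxon", "direction"]).to_csv(
            outdir / "truth_markers.tsv", sep="\t", index=False
        )
        shifts = self.batch_shifts.copy()
        shifts.index.name = "taxon"
        shifts.to_csv(outdir / "truth_batch_shifts.tsv", sep="\t", float_format="%.10g")


def simulate_multicohort(config: SimConfig) -> tuple[MultiCohortDataset, CohortTruth]:
    """Generate one multi-cohort case-control dataset plus its ground truth.

    Bit-reproducible from ``config.seed``.  Raises if the configuration can
    produce empty samples (``zero_prob`` too high for ``n_taxa``).
    """
    rng = np.random.default_rng(config.seed)
    taxa = [f"taxon_{i:04d}" for i in range(config.n_taxa)]
    cohorts = [f"cohort_{k:02d}" for k in range(config.n_cohorts)]

    base_mu = rng.normal(0.0, config.base_sd, config.n_taxa)

    # Markers are drawn from the detectable (upper 60% baseline abundance)
    # taxa: real curated markers are taxa that survive detection limits, and
    # this keeps the injected signal comparable across seeds.
    detectable = np.where(base_mu >= np.quantile(base_mu, 0.4))[0]
    if config.n_markers > len(detectable):
        raise ValueError(
            f"n_markers ({config.n_markers}) exceeds detectable taxa "
            f"({len(detectable)}); increase n_taxa"
        )
    # Shared markers carry one global direction; the per-cohort remainder is
    # drawn from the non-shared pool with per-cohort directions.
    n_shared = int(round(config.consistency_rho * config.n_markers))
    order = detectable[rng.permutation(len(detectable))]
    shared_idx = order[:n_shared]
    pool = order[n_shared:]
    shared_signs = rng.choice([-1, 1], size=n_shared)

    markers: dict[str, dict[str, int]] = {}
    marker_idx: dict[str, np.ndarray] = {}
    marker_signs: dict[str, np.ndarray] = {}
    for cohort in cohorts:
        n_specific = config.n_markers - n_shared
        if n_specific > len(pool):
            raise ValueError(
                "not enough non-shared taxa for cohort-specific markers; "
                "increase n_taxa or consistency_rho"
            )
        specific = rng.choice(pool, size=n_specific, replace=False)
        specific_signs = rng.choice([-1, 1], size=n_specific)
        idx = np.concatenate([shared_idx, specific]).astype(int)
        signs = np.concatenate([shared_signs, specific_signs]).astype(int)
        marker_idx[cohort] = idx
        marker_signs[cohort] = signs
        markers[cohort] = {taxa[i]: int(s) for i, s in zip(idx, signs)}

    batch = pd.DataFrame(
        rng.normal(0.0, config.batch_sd, (config.n_taxa, config.n_cohorts)),
        index=taxa,
        columns=cohorts,
    )

    conf = config.confounder_spec
    conf_taxa_idx = np.array([], dtype=int)
    if conf is not None:
        used = set()
        for idx in marker_idx.values():
            used.update(idx.tolist())
        free = np.array([i for i in range(config.n_taxa) if i not in used])
        if len(free) < conf.n_taxa:
            raise ValueError("not enough marker-free taxa for the confounder")
        conf_taxa_idx = rng.choice(free, size=conf.n_taxa, replace=False)

    tables: dict[str, pd.DataFrame] = {}
    meta_rows: list[dict] = []
    for cohort in cohorts:
        n = config.n_case + config.n_control
        labels = np.array(["case"] * config.n_case + ["control"] * config.n_control)
        is_case = labels == "case"
        log2 = (
            base_mu[None, :]
            + batch[cohort].to_numpy()[None, :]
            + rng.normal(0.0, config.sample_sd, (n, config.n_taxa))
        )
        idx, signs = marker_idx[cohort], marker_signs[cohort]
        log2[np.ix_(is_case, idx)] += signs[None, :] * config.effect_size

        cov_values = None
        if conf is not None:
            if conf.kind == "categorical":
                p_control = 0.5
                odds = conf.odds_ratio * p_control / (1 - p_control)
                p_case = odds / (1 + odds)
                probs = np.where(is_case, p_case, p_control)
                cov_values = (rng.random(n) < probs).astype(int)
                log2[:, conf_taxa_idx] += conf.effect_size * cov_values[:, None]
            else:
                cov_values = rng.normal(0.0, 1.0, n) + conf.label_shift * is_case
                log2[:, conf_taxa_idx] += conf.effect_size * cov_values[:, None]

        abund = np.exp2(log2)
        abund[rng.random((n, config.n_taxa)) < config.zero_prob] = 0.0
        totals = abund.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError(
                "degenerate config: zero_prob produced all-zero samples; "
                "lower zero_prob or raise n_taxa"
            )
        abund /= totals[:, None]

        sample_ids = [f"{cohort}_s{i:03d}" for i in range(n)]
        tables[cohort] = pd.DataFrame(
            abund.T, index=pd.Index(taxa, name="taxon"), columns=sample_ids
        )
        for i, sid in enumerate(sample_ids):
            row = {"sample_id": sid, "cohort_id": cohort, "label": labels[i]}
            if cov_values is not None:
                row[conf.name] = cov_values[i]
            meta_rows.append(row)

    metadata = pd.DataFrame(meta_rows)
    truth = CohortTruth(
        markers=markers,
        batch_shifts=batch,
        confounder_taxa=[taxa[i] for i in conf_taxa_idx],
    )
    logger.debug(
        "simulated %d cohorts x %d samples, %d taxa, %d markers (%d shared)",
        config.n_cohorts, config.n_case + config.n_control,
        config.n_taxa, config.n_markers, n_shared,
    )
    return MultiCohortDataset(tables, metadata), truth
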