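"""In-memory containers and the TSV dialects used throughout the pipeline.

Abundance tables are pandas DataFrames with taxa as rows and samples as
columns (values are per-sample relative abundances in [0, 1]); on disk the
first column is ``taxon``.  Sample metadata is a DataFrame with one row per
sample and the mandatory columns ``sample_id``, ``cohort_id`` and ``label``
(``case``/``control``); any further columns are covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

LABELS = ("case", "control")


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a taxa x samples abundance TSV (first column ``taxon``)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = "taxon"
    return table


def write_abundance(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out.index.name = "taxon"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort_id": str})
    _check_metadata(meta)
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _check_metadata(meta: pd.DataFrame) -> None:
    required = {"sample_id", "cohort_id", "label"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dupes[:5]}")
    bad = set(meta["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"labels must be in {LABELS}; found {sorted(bad)}")


def union_features(tables: Iterable[pd.DataFrame]) -> list[str]:
    """Union taxon universe across tables, first-seen order."""
    seen: dict[str, None] = {}
    for table in tables:
        for taxon in table.index:
            seen.setdefault(taxon, None)
    return list(seen)


def align_to_features(table: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Map a table onto ``features``: zero-fill absences, drop extras."""
    return table.reindex(features, fill_value=0.0)


@dataclass
class MultiCohortDataset:
    """Per-cohort abundance tables plus one metadata frame covering them all."""

    tables: dict[str, pd.DataFrame]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        _check_metadata(self.metadata)
        meta_ids = set(self.metadata["sample_id"])
        for cohort, table in self.tables.items():
            absent = [s for s in table.columns if s not in meta_ids]
            if absent:
                raise ValueError(
                    f"cohort {cohort!r}: abundance columns without metadata rows: {absent[:5]}"
                )

    @property
    def cohort_ids(self) -> list[str]:
        return list(self.tables)

    def labels_for(self, cohort: str) -> pd.Series:
        """Label series aligned to the cohort table's sample columns."""
        meta = self.metadata.set_index("sample_id")
        return meta.loc[list(self.tables[cohort].columns), "label"]

    def pooled(self, cohorts: Iterable[str]) -> tuple[pd.DataFrame, pd.Series]:
        """Pool cohorts on their union taxon space (zero-filled absences)."""
        cohorts = list(cohorts)
        tables = [self.tables[c] for c in cohorts]
        features = union_features(tables)
        pooled = pd.concat(
            [align_to_features(t, features) for t in tables], axis=1
        )
        if pooled.columns.duplicated().any():
            raise ValueError("pooled cohorts share sample ids")
        meta = self.metadata.set_index("sample_id")
        labels = meta.loc[list(pooled.columns), "label"]
        return pooled, labels

    def subset(self, cohorts: Iterable[str]) -> "MultiCohortDataset":
        cohorts = list(cohorts)
        meta = self.metadata[self.metadata["cohort_id"].isin(cohorts)].reset_index(
            drop=True
        )
        return MultiCohortDataset({c: self.tables[c] for c in cohorts}, meta)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cohort, table in self.tables.items():
            write_abundance(table, outdir / f"abundance_{cohort}.tsv")
        write_metadata(self.metadata, outdir / "metadata.tsv")

    @classmethod
    def read(cls, indir: str | Path) -> "MultiCohortDataset":
        indir = Path(indir)
        meta = read_metadata(indir / "metadata.tsv")
        tables = {}
        for path in sorted(indir.glob("abundance_*.tsv")):
            cohort = path.stem[len("abundance_") :]
            tables[cohort] = read_abundance(path)
        if not tables:
            raise FileNotFoundError(f"no abundance_*.tsv files under {indir}")
        return cls(tables, meta)
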