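"""QC filters, confounder detection/removal, batch correction contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from microcross.preprocess import (
    adjust_batch,
    adjust_confounders,
    detect_confounders,
    qc_filter,
)
from microcross.simulate import SimConfig, simulate_multicohort


def _table(values, taxa=None, samples=None):
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=taxa, columns=samples)


class TestQcFilter:
    def test_sample_with_two_nonzero_taxa_dropped(self):
        table = _table(
            [[0.5, 0.3, 0.2], [0.5, 0.0, 0.3], [0.0, 0.7, 0.5], [0.0, 0.0, 0.0]]
        )
        out, report = qc_filter(table)
        assert "s1" in report.dropped_samples  # exactly 2 nonzero taxa
        assert "s0" in report.dropped_samples
        assert "s1" not in out.columns

    def test_taxon_below_threshold_everywhere_dropped(self):
        table = _table([[0.4] * 4, [0.3] * 4, [0.3] * 4, [5e-4] * 4])
        out, report = qc_filter(table)
        assert report.dropped_taxa == ["t3"]
        assert "t3" not in out.index

    def test_passing_table_unchanged_and_idempotent(self, tiny_dataset):
        table = tiny_dataset.tables["cohort_00"]
        once, _ = qc_filter(table)
        twice, report2 = qc_filter(once)
        pd.testing.assert_frame_equal(once, twice)
        assert not report2.dropped_samples and not report2.dropped_taxa

    def test_no_renormalization(self):
        table = _table([[0.4] * 4, [0.3] * 4, [0.2] * 4, [5e-4] * 4])
        out, _ = qc_filter(table)
        np.testing.assert_allclose(out.sum(axis=0), 0.9, atol=1e-12)

    def test_everything_filtered_raises(self):
        with pytest.raises(ValueError, match="filter"):
            qc_filter(_table([[5e-4] * 3, [2e-4] * 3]))


def _meta(n_case=40, n_control=40, **covs):
    rows = []
    for i in range(n_case + n_control):
        row = {
            "sample_id": f"s{i}",
            "cohort_id": "c0",
            "label": "case" if i < n_case else "control",
        }
        for name, values in covs.items():
            row[name] = values[i]
        rows.append(row)
    return pd.DataFrame(rows)


class TestDetectConfounders:
    def test_identical_quantitative_distributions_not_flagged(self):
        age = list(range(40)) + list(range(40))
        assert detect_confounders(_meta(age=age)) == []

    def test_fisher_2x2_flagged_matches_hypergeometric_tail(self):
        # counts [[30,10],[10,30]]: covariate level 1 in 30/40 cases, 10/40 controls
        sex = [1] * 30 + [0] * 10 + [1] * 10 + [0] * 30
        flagged = detect_confounders(_meta(sex=sex), alpha=0.05)
        assert flagged == ["sex"]
        # independent oracle: two-sided Fisher p as sum of hypergeometric
        # probabilities no larger than the observed table's
        rv = hypergeom(80, 40, 40)  # N, K (level-1 total), n (cases)
        p_obs = rv.pmf(30)
        p_two = sum(rv.pmf(k) for k in range(41) if rv.pmf(k) <= p_obs + 1e-12)
        assert p_two < 0.05

    def test_no_covariates_empty_list(self):
        assert detect_confounders(_meta()) == []

    def test_constant_covariate_skipped(self):
        assert detect_confounders(_meta(site=[1] * 80)) == []

    def test_type_one_error_controlled_on_null_covariates(self):
        rng = np.random.default_rng(0)
        flags = 0
        n_sims = 200
        for _ in range(n_sims):
            cov = rng.normal(size=40)
            flags += bool(detect_confounders(_meta(20, 20, x=list(cov))))
        rate = flags / n_sims
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert rate <= 0.05 + 3 * se


class TestAdjustConfounders:
    def _setup(self, noise=0.0, cov_label_corr=True):
        rng = np.random.default_rng(4)
        n = 60
        label = np.array(["case"] * 30 + ["control"] * 30)
        if cov_label_corr:
            cov = rng.normal(size=n) + (label == "case") * 1.0
        else:
            cov = rng.normal(size=n)
        log_ab = -3 + 0.8 * (label == "case") + 0.5 * cov
        if noise:
            log_ab = log_ab + rng.normal(0, noise, n)
        table = _table(np.power(10.0, log_ab)[None, :],
                       taxa=["t0"], samples=[f"s{i}" for i in range(n)])
        meta = pd.DataFrame({
            "sample_id": table.columns, "cohort_id": "c0", "label": label,
            "cov": cov,
        })
        return table, meta

    def test_adjusted_covariate_slope_vanishes(self):
        table, meta = self._setup(noise=0.0)
        out = adjust_confounders(table, meta, ["cov"])
        y = np.log10(out.to_numpy()[0] + 1e-6)
        X = np.column_stack([
            np.ones(len(y)), (meta.label == "case").astype(float), meta["cov"],
        ])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert abs(beta[2]) < 1e-6

    def test_label_contrast_preserved_when_covariate_orthogonal(self):
        table, meta = self._setup(noise=0.0, cov_label_corr=False)
        before = np.log10(table.to_numpy()[0] + 1e-6)
        out = adjust_confounders(table, meta, ["cov"])
        after = np.log10(out.to_numpy()[0] + 1e-6)
        case = (meta.label == "case").to_numpy()

        def contrast(v):
            return v[case].mean() - v[~case].mean()

        # OLS with the covariate in the design removes its contribution but
        # keeps the label term; with an orthogonal covariate the contrast
        # estimate is unchanged up to the covariate's sample correlation
        assert abs(contrast(after) - 0.8) < 0.05

    def test_empty_covariates_identity(self, tiny_dataset):
        table = tiny_dataset.tables["cohort_00"]
        out = adjust_confounders(table, tiny_dataset.metadata, [])
        pd.testing.assert_frame_equal(out, table)

    def test_collinear_covariates_rejected(self):
        table, meta = self._setup()
        meta["cov2"] = meta["cov"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            adjust_confounders(table, meta, ["cov", "cov2"])


def _two_cohort_shift(shift=1.0, n=40, sd=0.1, seed=0):
    """Two cohorts; taxon t0 carries a constant log10 shift in cohort c1."""
    rng = np.random.default_rng(seed)
    tables, rows = {}, []
    for ci, cohort in enumerate(["c0", "c1"]):
        log_ab = np.stack([
            rng.normal(-2 + (shift if ci else 0.0), sd, n),
            rng.normal(-1.5, sd, n),
            rng.normal(-2.5, sd, n),
        ])
        ab = np.power(10.0, log_ab)
        samples = [f"{cohort}_s{j}" for j in range(n)]
        tables[cohort] = pd.DataFrame(
            ab / ab.sum(axis=0), index=["t0", "t1", "t2"], columns=samples
        )
        for j, s in enumerate(samples):
            rows.append({
                "sample_id": s, "cohort_id": cohort,
                "label": "case" if j < n // 2 else "control",
            })
    return tables, pd.DataFrame(rows)


class TestAdjustBatch:
    def test_constant_shift_removed(self):
        tables, meta = _two_cohort_shift(shift=1.0)
        out = adjust_batch(tables, meta)

        def mean_log(t):
            row = t.loc["t0"].to_numpy()
            return np.log10(row[row > 0]).mean()

        gap_before = abs(mean_log(tables["c1"]) - mean_log(tables["c0"]))
        gap_after = abs(mean_log(out["c1"]) - mean_log(out["c0"]))
        assert gap_before > 0.5
        assert gap_after < 0.05

    def test_zeros_preserved_and_renormalized(self, tiny_dataset):
        out = adjust_batch(tiny_dataset.tables, tiny_dataset.metadata)
        for cohort, table in out.items():
            orig = tiny_dataset.tables[cohort]
            assert ((orig == 0) == (table == 0)).all().all()
            np.testing.assert_allclose(table.sum(axis=0), 1.0, atol=1e-9)

    def test_single_cohort_unchanged(self, tiny_dataset):
        cohort = "cohort_00"
        out = adjust_batch(
            {cohort: tiny_dataset.tables[cohort]}, tiny_dataset.metadata
        )
        pd.testing.assert_frame_equal(out[cohort], tiny_dataset.tables[cohort])

    def test_between_cohort_variance_reduced(self):
        cfg = SimConfig(n_cohorts=3, n_case=20, n_control=20, n_taxa=60,
                        batch_sd=1.0, seed=13)
        ds, _ = simulate_multicohort(cfg)
        out = adjust_batch(ds.tables, ds.metadata)

        def cohort_dispersion(tables):
            total = 0.0
            taxa = next(iter(tables.values())).index
            for t in taxa:
                means = []
                for table in tables.values():
                    row = table.loc[t].to_numpy()
                    if (row > 0).sum() >= 2:
                        means.append(np.log10(row[row > 0]).mean())
                if len(means) == len(tables):
                    total += np.var(means)
            return total

        assert cohort_dispersion(out) < cohort_dispersion(ds.tables) + 1e-6
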