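"""Design orchestration: record bookkeeping, eligibility, extrapolation,
Spearman linkage and the end-to-end experiment runner."""

import numpy as np
import pandas as pd
import pytest

from microcross.harness import (
    ExperimentConfig,
    correlate_msi_auc,
    default_scm_grid,
    extrapolate_n_required,
    lodo_marker_sets,
    prepare_dataset,
    run_ccm,
    run_experiment,
    run_lodo,
    run_scm,
    run_single_cohort,
    spearman_pairs,
)
from microcross.metrics import EvalRecord, records_to_frame
from microcross.models import ClassifierSpec
from microcross.msi import msi, msi_matrix
from microcross.simulate import SimConfig, simulate_multicohort


def _rec(design, train, test, n, auc_value, tag=None):
    return EvalRecord(design, train, test, n, auc_value, 0.5, 0.0,
                      1, 1, 1, 1, tag=tag)


class TestSingleCohortAndLodo:
    def test_record_combinatorics(self, tiny_prepared, light_spec):
        mds, _ = tiny_prepared
        records, _ = run_single_cohort(mds, light_spec)
        frame = records_to_frame(records)
        assert (frame.design == "intra").sum() == 3
        assert (frame.design == "cross").sum() == 6

    def test_lodo_counts_and_leakage_audit(self, tiny_prepared, light_spec):
        mds, _ = tiny_prepared
        records, models = run_lodo(mds, light_spec)
        assert len(records) == 3
        for rec in records:
            trained_on = rec.train_id.split("+")
            assert rec.test_cohort not in trained_on
            assert len(trained_on) == 2
        for left_out, model in models.items():
            test_samples = set(mds.tables[left_out].columns)
            for entry in model.audit:
                assert not test_samples & set(entry["train_index"])

    def test_lodo_requires_three_cohorts(self, tiny_prepared, light_spec):
        mds, _ = tiny_prepared
        with pytest.raises(ValueError, match="3 cohorts"):
            run_lodo(mds.subset(["cohort_00", "cohort_01"]), light_spec)


@pytest.fixture(scope="module")
def five_cohorts():
    cfg = SimConfig(n_cohorts=5, n_case=16, n_control=16, n_taxa=60,
                    n_markers=12, seed=29)
    ds, _ = simulate_multicohort(cfg)
    mds, _ = prepare_dataset(ds)
    return mds


class TestCcmScm:
    def test_eligibility_rules(self, tiny_prepared, light_spec):
        mds, _ = tiny_prepared
        with pytest.raises(ValueError, match="5 cohorts"):
            run_ccm(mds, light_spec)
        with pytest.raises(ValueError, match="5 cohorts"):
            run_scm(mds, light_spec)

    def test_ccm_enumerates_subsets_deterministically(self, five_cohorts):
        spec = ClassifierSpec(repeats=1, c_grid=(0.1, 1.0), outer_folds=5, seed=3)
        r1 = run_ccm(five_cohorts, spec, draws_per_size=3, seed=17)
        r2 = run_ccm(five_cohorts, spec, draws_per_size=3, seed=17)
        f1, f2 = records_to_frame(r1), records_to_frame(r2)
        pd.testing.assert_frame_equal(f1, f2)
        # size 4 has C(5,4)=5 subsets > 3 draws -> exactly 3 drawn
        assert f1[f1.tag == "4"].train_id.nunique() == 3

    def test_scm_balanced_draws_and_grid(self, five_cohorts):
        spec = ClassifierSpec(repeats=1, c_grid=(0.1, 1.0), outer_folds=5, seed=3)
        records = run_scm(five_cohorts, spec, grid=(16, 22), draws_per_point=2,
                          seed=5, test_cohorts=["cohort_00"])
        frame = records_to_frame(records)
        assert sorted(frame.n_train.unique()) == [16, 22]
        assert len(frame) == 4
        for rec in records:
            assert rec.n_train % 2 == 0  # 1:1 case:control by construction

    def test_default_grid_layout(self):
        assert default_scm_grid(100) == [16, 22, 28, 34, 40, 60, 80, 100]
        assert default_scm_grid(45) == [16, 22, 28, 34, 40]
        with pytest.raises(ValueError):
            default_scm_grid(10)


class TestExtrapolation:
    def test_closed_form_ols_example(self):
        records = [
            _rec("scm", "p", "t", n, a)
            for n, a in ((100, 0.55), (200, 0.60), (300, 0.65))
        ]
        res = extrapolate_n_required(records, target_auc=0.70)
        assert res.attainable
        assert res.slope == pytest.approx(5e-4, abs=1e-12)
        assert res.intercept == pytest.approx(0.50, abs=1e-12)
        assert res.n_required == 400
        assert res.ci[0] <= 400 <= res.ci[1]

    def test_flat_trend_not_attainable(self):
        records = [
            _rec("scm", "p", "t", n, 0.6) for n in (100, 200, 300)
        ]
        res = extrapolate_n_required(records, target_auc=0.70)
        assert not res.attainable
        assert res.n_required is None

    def test_ci_contains_point_estimate_with_noise(self):
        rng = np.random.default_rng(0)
        records = [
            _rec("scm", "p", "t", n, 0.5 + 4e-4 * n + rng.normal(0, 0.01))
            for n in (50, 100, 150, 200, 250, 300)
        ]
        res = extrapolate_n_required(records, target_auc=0.70)
        assert res.attainable
        assert res.ci[0] <= res.n_required
        assert res.ci[1] >= res.n_required

    def test_needs_three_grid_points(self):
        records = [_rec("scm", "p", "t", n, 0.5) for n in (100, 200)]
        with pytest.raises(ValueError):
            extrapolate_n_required(records, 0.7)


class TestSpearmanLinkage:
    def test_monotone_pairs(self):
        assert spearman_pairs([1, 2, 3, 4], [10, 20, 30, 40])[0] == 1.0
        assert spearman_pairs([1, 2, 3, 4], [4, 3, 2, 1])[0] == -1.0

    def test_hand_rank_example(self):
        r, _ = spearman_pairs([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_pairs([1, 2, 3], [1, 2, 3])

    def test_pairs_matched_by_train_test(self):
        table = pd.DataFrame(
            [[np.nan, 4.0, 1.0], [2.0, np.nan, 3.0], [0.5, 1.5, np.nan]],
            index=list("ABC"), columns=list("ABC"),
        )
        records = [
            _rec("cross", a, b, 10, v)
            for a, b, v in (("A", "B", 0.9), ("A", "C", 0.55), ("B", "A", 0.7),
                            ("B", "C", 0.8), ("C", "A", 0.5), ("C", "B", 0.6))
        ]
        r, p = correlate_msi_auc(table, records)
        msis = [4.0, 1.0, 2.0, 3.0, 0.5, 1.5]
        aucs = [0.9, 0.55, 0.7, 0.8, 0.5, 0.6]
        assert r == pytest.approx(spearman_pairs(msis, aucs)[0], abs=1e-12)


class TestExperimentRunner:
    def test_end_to_end_outputs(self, tmp_path):
        cfg = ExperimentConfig(
            sim=SimConfig(n_cohorts=3, n_case=16, n_control=16, n_taxa=60,
                          n_markers=12),
            classifier=ClassifierSpec(repeats=1, c_grid=(0.1, 1.0)),
            designs=("intra", "cross"),
        )
        result = run_experiment(cfg, seed=5, outdir=tmp_path)
        assert (tmp_path / "records.tsv").exists()
        assert (tmp_path / "msi_matrix.tsv").exists()
        assert set(result.records.design) == {"intra", "cross"}
        assert result.msi.shape == (3, 3)

    def test_lodo_organization_raises_marker_consistency(self):
        """Pooled-reference MSI exceeds the intra-organization median on
        partially consistent cohorts."""
        cfg = SimConfig(n_cohorts=3, n_case=30, n_control=30, n_taxa=80,
                        n_markers=15, consistency_rho=0.5, seed=37)
        ds, _ = simulate_multicohort(cfg)
        _, lefse_tabs = prepare_dataset(ds)
        from microcross.markers import lefse_markers

        sets = []
        for c, tab in lefse_tabs.items():
            sets.append(
                lefse_markers(tab, ds.labels_for(c).to_numpy(), seed=1, source=c)
            )
        intra = msi_matrix(sets)
        intra_vals = intra.to_numpy()[~np.isnan(intra.to_numpy())]
        lodo_vals = [
            msi(ref, tgt).value
            for ref, tgt in lodo_marker_sets(lefse_tabs, ds.metadata, seed=1)
        ]
        assert np.median(lodo_vals) > np.median(intra_vals)
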