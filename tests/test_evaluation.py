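"""Fold construction, accuracy aggregation, ranking, ensemble, summary t."""

import numpy as np
import pandas as pd
import pytest

from csecnn.cnn import desk_scale_spec
from csecnn.evaluation import (
    _fold_split,
    accuracy_ci,
    binomial_chance_band,
    ensemble_predict,
    make_folds,
    rank_rois,
    run_full_cv,
    run_seed_roi_cv,
    summary_t_test,
)
from csecnn.volumes import fit_reference_stats
from csecnn import io


def manifest_of(ns, si, sa):
    rows = [
        {"subject_id": f"sub-{i:03d}", "group": g, "binary_target": 0 if g == "NS" else 1}
        for i, g in enumerate(["NS"] * ns + ["SI"] * si + ["SA"] * sa, start=1)
    ]
    return pd.DataFrame(rows)


class TestFolds:
    def test_study_cohort_fold_sizes(self):
        folds = make_folds(manifest_of(35, 26, 22), k=6, seed=0)
        assert sorted(folds.sizes()) == [13, 14, 14, 14, 14, 14]

    def test_each_stratum_in_every_fold(self):
        manifest = manifest_of(35, 26, 22)
        folds = make_folds(manifest, k=6, seed=3)
        groups = dict(zip(manifest.subject_id, manifest.group))
        for f in range(1, 7):
            present = {groups[sid] for sid in folds.fold_members(f)}
            assert present == {"NS", "SI", "SA"}

    def test_six_subjects_six_folds(self):
        folds = make_folds(manifest_of(2, 2, 2), k=6, seed=0)
        assert folds.sizes() == [1] * 6

    def test_every_subject_tested_exactly_once(self):
        manifest = manifest_of(10, 6, 5)
        folds = make_folds(manifest, k=4, seed=1)
        tested = [sid for f in range(1, 5) for sid in _fold_split(folds, f)[0]]
        assert sorted(tested) == sorted(manifest.subject_id)

    def test_validation_fold_rotates(self):
        folds = make_folds(manifest_of(6, 6, 6), k=3, seed=0)
        for f in range(1, 4):
            test, val, train = _fold_split(folds, f)
            assert set(test).isdisjoint(val)
            assert set(test).isdisjoint(train) and set(val).isdisjoint(train)
            assert len(test) + len(val) + len(train) == 18

    def test_deterministic(self):
        m = manifest_of(9, 5, 4)
        assert make_folds(m, 3, seed=5).mapping == make_folds(m, 3, seed=5).mapping

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            make_folds(manifest_of(2, 1, 1), k=6)


class TestAccuracyCI:
    def test_zero_spread(self):
        assert accuracy_ci([0.8, 0.8, 0.8]) == pytest.approx((0.8, 0.8, 0.8))

    def test_two_fold_mean(self):
        mean, lo, hi = accuracy_ci([1.0, 0.5])
        assert mean == pytest.approx(0.75)
        assert lo == 0.0 and hi == 1.0  # clamped t-interval at k = 2

    def test_width_shrinks_with_k(self):
        narrow = accuracy_ci([0.7, 0.8] * 6)
        wide = accuracy_ci([0.7, 0.8])
        assert (narrow[2] - narrow[1]) < (wide[2] - wide[1])

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            accuracy_ci([0.8])


class TestRanking:
    def report_of(self, rows):
        return pd.DataFrame([
            {
                "roi_label": roi,
                **{f"acc_fold{i+1}": a for i, a in enumerate(accs)},
                "mean_accuracy": np.mean(accs),
            }
            for roi, accs in rows.items()
        ])

    def test_above_threshold_sorted(self):
        above, _ = rank_rois(self.report_of({1: [0.8, 0.8], 2: [0.6, 0.6], 3: [0.9, 0.9]}))
        assert above == [3, 1]

    def test_above_but_not_reliable(self):
        report = self.report_of({7: [0.8, 0.8, 0.7]})
        above, reliable = rank_rois(report)
        assert above == [7] and reliable == []

    def test_empty_above_set_allowed(self):
        above, reliable = rank_rois(self.report_of({1: [0.5, 0.5]}))
        assert above == [] and reliable == []


class TestEnsemble:
    @pytest.mark.parametrize(
        "votes,expected", [([1, 1, 0], 1), ([0, 0, 0, 1], 0), ([0, 1], 1)]
    )
    def test_majority_with_tie_to_suicidality(self, votes, expected):
        assert ensemble_predict(votes) == expected

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError):
            ensemble_predict([])


class TestSummaryT:
    def test_identical_groups(self):
        assert summary_t_test(5, 1, 10, 5, 1, 10) == 0.0

    def test_antisymmetric(self):
        t1 = summary_t_test(7.9, 2.9, 35, 9.2, 3.6, 48)
        t2 = summary_t_test(9.2, 3.6, 48, 7.9, 2.9, 35)
        assert t1 == pytest.approx(-t2)

    def test_zero_variance_unequal_means(self):
        assert summary_t_test(1, 0, 5, 2, 0, 5) == -np.inf

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            summary_t_test(1, 1, 1, 2, 1, 10)


def test_chance_band_contains_half():
    lo, hi = binomial_chance_band(48, 0.5)
    assert lo < 0.5 < hi and 0.3 < lo and hi < 0.7


class TestCrossValidationDrivers:
    def test_seed_roi_cv_returns_k_accuracies(self, tiny_cohort):
        manifest, _, atlas, matrices = tiny_cohort
        folds = make_folds(manifest, k=3, seed=7)
        result = run_seed_roi_cv(
            matrices, manifest, folds, atlas, seed_roi=1,
            spec=desk_scale_spec(atlas.data.shape),
            max_epochs=10, early_stop_patience=10, seed=7,
        )
        assert len(result["fold_accuracies"]) == 3
        assert all(0 <= a <= 1 for a in result["fold_accuracies"])
        assert sorted(result["predictions"]) == sorted(manifest.subject_id)

    def test_missing_matrices_rejected(self, tiny_cohort):
        manifest, _, atlas, matrices = tiny_cohort
        folds = make_folds(manifest, k=3, seed=7)
        partial = dict(list(matrices.items())[:-1])
        with pytest.raises(ValueError, match="without CSE matrices"):
            run_seed_roi_cv(partial, manifest, folds, atlas, seed_roi=1)

    def test_reference_statistics_exclude_test_fold(self, tiny_cohort):
        """Leakage audit: per-fold reference stats ignore test-fold data."""
        manifest, _, atlas, matrices = tiny_cohort
        groups = dict(zip(manifest.subject_id, manifest.group))
        folds = make_folds(manifest, k=3, seed=7)
        for f in range(1, 4):
            test, _, train = _fold_split(folds, f)
            ref_ids = [sid for sid in train if groups[sid] == "NS"]
            assert set(ref_ids).isdisjoint(test)
            before = fit_reference_stats(
                [matrices[sid] for sid in ref_ids], ref_ids
            ).content_hash()
            perturbed = {
                sid: m for sid, m in matrices.items()
            }
            import copy

            for sid in test:
                perturbed[sid] = copy.deepcopy(matrices[sid])
                perturbed[sid].values[:] += 99.0
            after = fit_reference_stats(
                [perturbed[sid] for sid in ref_ids], ref_ids
            ).content_hash()
            assert before == after

    def test_full_cv_report_shape_and_roundtrip(self, tiny_cohort, tmp_path):
        manifest, _, atlas, matrices = tiny_cohort
        folds = make_folds(manifest, k=3, seed=7)
        result = run_full_cv(
            matrices, manifest, folds, atlas, reduced=True,
            max_epochs=8, early_stop_patience=8, seed=7,
        )
        report = result["report"]
        assert len(report) == len(atlas.labels)
        assert {"mean_accuracy", "ci_low", "ci_high", "above_threshold",
                "reliable", "pooled_accuracy"} <= set(report.columns)
        assert ((report.ci_low <= report.mean_accuracy)
                & (report.mean_accuracy <= report.ci_high)).all()
        assert set(result["ensemble"]) == set(manifest.subject_id)
        io.write_report(report, tmp_path / "report.tsv", {"k": 3})
        back = io.read_report(tmp_path / "report.tsv")
        pd.testing.assert_frame_equal(report, back)
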