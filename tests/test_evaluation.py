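"""Split construction, leakage guards, metrics and majority voting."""

import numpy as np
import pandas as pd
import pytest

from endotex import (CLASSES, SplitLeakageError, SynthConfig,
                     confusion_matrix, evaluate, frames_to_manifest,
                     generate_frames, kfold_cross_sample, repeated_runs,
                     split_cross_sample, split_cross_subject,
                     subject_majority_label, validate_split)


@pytest.fixture(scope="module")
def cohort_manifest():
    """Unequal cohort (9 healthy, 13 cancer, 16 inflammation subjects)."""
    cfg = SynthConfig(
        n_subjects_per_class={"healthy": 9, "cancer": 13, "inflammation": 16},
        frames_per_subject=4, artifact_fraction=0.0, seed=8)
    return frames_to_manifest(generate_frames(cfg))


@pytest.fixture(scope="module")
def small_manifest():
    cfg = SynthConfig(n_subjects_per_class=3, frames_per_subject=20,
                      artifact_fraction=0.0, seed=9)
    return frames_to_manifest(generate_frames(cfg))


TABLE_COUNTS = {"healthy": (5, 1, 3), "cancer": (7, 2, 4),
                "inflammation": (7, 2, 7)}


class TestCrossSubjectSplit:
    def test_study_layout_counts(self, cohort_manifest):
        """The published cohort layout (5/7/7 train, 1/2/2 val, 3/4/7 test)."""
        out = split_cross_subject(cohort_manifest, TABLE_COUNTS, seed=0)
        for split, col in zip(("train", "val", "test"), range(3)):
            got = out[out["split"] == split].groupby(
                "class_label")["subject_id"].nunique()
            for cls, counts in TABLE_COUNTS.items():
                assert got[cls] == counts[col]

    def test_subject_sets_disjoint(self, cohort_manifest):
        out = split_cross_subject(cohort_manifest, TABLE_COUNTS, seed=1)
        for a, b in (("train", "test"), ("train", "val"), ("val", "test")):
            sa = set(out.loc[out["split"] == a, "subject_id"])
            sb = set(out.loc[out["split"] == b, "subject_id"])
            assert not (sa & sb)

    def test_frames_follow_their_subject(self, cohort_manifest):
        out = split_cross_subject(cohort_manifest, TABLE_COUNTS, seed=2)
        assert (out.groupby("subject_id")["split"].nunique() == 1).all()

    def test_reseeding_rotates_subjects(self, cohort_manifest):
        outs = [split_cross_subject(cohort_manifest, TABLE_COUNTS, seed=s)
                for s in range(4)]
        test_sets = [frozenset(o.loc[o["split"] == "test", "subject_id"])
                     for o in outs]
        assert len(set(test_sets)) > 1  # assignments differ across seeds
        for o in outs:  # counts stay fixed
            assert (o["split"] == "test").sum() == (
                outs[0]["split"] == "test").sum()

    def test_insufficient_subjects_rejected(self, small_manifest):
        with pytest.raises(ValueError):
            split_cross_subject(small_manifest, {"healthy": (3, 1, 1)})


class TestCrossSampleSplit:
    def test_split_arithmetic_180_frames(self, small_manifest):
        out = split_cross_sample(small_manifest, 0.75, seed=0)
        assert (out["split"] == "train").sum() == 135
        assert (out["split"] == "test").sum() == 45

    def test_class_proportions_preserved(self, small_manifest):
        out = split_cross_sample(small_manifest, 0.75, seed=3)
        per_class = out[out["split"] == "test"].groupby(
            "class_label").size()
        expected = small_manifest.groupby("class_label").size() * 0.25
        assert (abs(per_class - expected) <= 1).all()

    def test_degenerate_fraction_rejected(self, small_manifest):
        for frac in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                split_cross_sample(small_manifest, frac)


class TestKFold:
    def test_partition_property(self, small_manifest):
        out = kfold_cross_sample(small_manifest, k=7, seed=0)
        assert set(out["fold"]) == set(range(7))
        assert len(out) == len(small_manifest)  # each frame exactly one fold

    def test_fold_sizes_balanced_within_class(self, small_manifest):
        out = kfold_cross_sample(small_manifest, k=7, seed=1)
        for _, g in out.groupby("class_label"):
            sizes = g.groupby("fold").size()
            assert sizes.max() - sizes.min() <= 1

    def test_leave_one_out_limit(self):
        manifest = pd.DataFrame({
            "path": [""] * 6, "subject_id": ["s"] * 6,
            "class_label": ["healthy", "cancer", "inflammation"] * 2,
            "frame_index": range(6), "is_artifact": [False] * 6,
        })
        out = kfold_cross_sample(manifest, k=2, seed=0)
        assert set(out["fold"]) == {0, 1}

    def test_k_exceeding_class_size_rejected(self, small_manifest):
        with pytest.raises(ValueError):
            kfold_cross_sample(small_manifest, k=61)


class TestLeakageGuard:
    def test_subject_leakage_detected(self, small_manifest):
        out = split_cross_sample(small_manifest, 0.75, seed=0)
        # cross-sample splits legitimately mix subjects across splits,
        # which the cross-subject guard must flag
        with pytest.raises(SplitLeakageError):
            validate_split(out, mode="cross_subject")

    def test_frame_leakage_detected(self, small_manifest):
        out = split_cross_sample(small_manifest, 0.75, seed=0)
        dup = out.iloc[[0]].copy()
        dup["split"] = "test" if out.iloc[0]["split"] == "train" else "train"
        with pytest.raises(SplitLeakageError):
            validate_split(pd.concat([out, dup]), mode="cross_sample")

    def test_clean_splits_pass(self, cohort_manifest):
        out = split_cross_subject(cohort_manifest, TABLE_COUNTS, seed=0)
        validate_split(out, mode="cross_subject")
        out2 = split_cross_sample(cohort_manifest, 0.75, seed=0)
        validate_split(out2, mode="cross_sample")


class TestEvaluate:
    def test_perfect_predictor(self):
        y = ["healthy", "cancer", "inflammation", "cancer"]
        rep = evaluate(y, y)
        assert rep.accuracy == 100.0
        conf = rep.confusion.to_numpy()
        assert np.trace(conf) == 4 and conf.sum() == 4

    def test_constant_predictor_scores_prevalence(self):
        y_true = ["cancer"] * 6 + ["healthy"] * 3 + ["inflammation"] * 1
        rep = evaluate(y_true, ["cancer"] * 10)
        assert rep.accuracy == pytest.approx(60.0)

    def test_confusion_orientation_rows_predicted(self):
        rep = evaluate(["healthy"], ["cancer"])
        assert rep.confusion.loc["cancer", "healthy"] == 1
        assert rep.confusion.loc["healthy", "cancer"] == 0

    def test_accuracy_consistent_with_confusion(self, rng):
        y_true = rng.choice(CLASSES, 50)
        y_pred = rng.choice(CLASSES, 50)
        rep = evaluate(y_true, y_pred)
        conf = rep.confusion.to_numpy()
        assert rep.accuracy == pytest.approx(100.0 * np.trace(conf)
                                             / conf.sum())
        # column sums equal true-class counts
        for j, cls in enumerate(CLASSES):
            assert conf[:, j].sum() == (y_true == cls).sum()

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])


class TestMajorityVote:
    def test_strict_majority(self):
        got = subject_majority_label({"m1": ["cancer", "cancer", "healthy"]})
        assert got == {"m1": "cancer"}

    def test_unanimous(self):
        assert subject_majority_label({"m": ["healthy"] * 5}) == {
            "m": "healthy"}

    def test_tie_breaks_by_severity(self):
        assert subject_majority_label(
            {"m": ["cancer", "healthy"]}) == {"m": "cancer"}
        assert subject_majority_label(
            {"m": ["inflammation", "healthy"]}) == {"m": "inflammation"}

    def test_dataframe_input(self):
        df = pd.DataFrame({"subject_id": ["a", "a", "b"],
                           "predicted": ["cancer", "cancer", "healthy"]})
        assert subject_majority_label(df) == {"a": "cancer", "b": "healthy"}

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            subject_majority_label({"m": []})


class TestRepeatedRuns:
    def test_deterministic_pipeline_has_zero_sd(self):
        accs, mean, sd = repeated_runs(lambda seed: 93.5, n_runs=5,
                                       base_seed=1)
        assert mean == pytest.approx(93.5) and sd == 0.0

    def test_two_run_sd_identity(self):
        values = iter([90.0, 96.0])
        accs, mean, sd = repeated_runs(lambda seed: next(values), n_runs=2,
                                       base_seed=0)
        assert sd == pytest.approx(abs(accs[0] - accs[1]) / np.sqrt(2))

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            repeated_runs(lambda s: 1.0, n_runs=1)
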