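"""Random-template validation protocol, F1 arithmetic, recall tables."""

import numpy as np
import pytest
from sklearn.metrics import f1_score as sklearn_f1

import repcount as rc
from repcount.classification import MERGED_CLASSES

from conftest import make_segment
from test_classification import dtw_by_path_enumeration

CHEST = rc.WearPosition.CHEST


class TestF1PerClass:
    def test_identity_confusion_is_perfect(self):
        np.testing.assert_allclose(rc.f1_per_class(np.eye(4) * 5), 1.0)

    def test_hand_computed_two_class_example(self):
        f1 = rc.f1_per_class(np.array([[8, 2], [3, 7]]))
        p0, r0 = 8 / 11, 8 / 10
        assert f1[0] == pytest.approx(2 * p0 * r0 / (p0 + r0))
        assert f1[0] == pytest.approx(0.7619, abs=1e-4)

    def test_absent_and_never_predicted_class_scores_zero(self):
        conf = np.array([[5, 0], [0, 0]])
        f1 = rc.f1_per_class(conf)
        assert f1[1] == 0.0

    def test_matches_sklearn_on_random_labels(self):
        rng = np.random.default_rng(17)
        true = rng.integers(0, 4, size=300)
        pred = rng.integers(0, 4, size=300)
        conf = np.zeros((4, 4), dtype=int)
        for a, b in zip(true, pred):
            conf[a, b] += 1
        np.testing.assert_allclose(
            rc.f1_per_class(conf),
            sklearn_f1(true, pred, average=None, zero_division=0),
            atol=1e-12,
        )

    def test_non_square_rejected(self):
        with pytest.raises(rc.InvalidInputError):
            rc.f1_per_class(np.ones((2, 3)))


def perfectly_separable_pool(chest_registry, copies=3):
    pool = []
    for tpl in chest_registry:
        for _ in range(copies):
            pool.append(
                make_segment(tpl.data, label=tpl.template_class.value)
            )
    return pool


class TestRandomTemplateValidation:
    def test_perfect_separability_gives_accuracy_one_sd_zero(self, chest_registry):
        pool = perfectly_separable_pool(chest_registry)
        report = rc.random_template_validation(
            pool, rc.ValidationConfig(position=CHEST, n_iterations=10, seed=0)
        )
        assert report.mean_accuracy == 1.0
        assert report.sd_accuracy == 0.0
        assert report.min_accuracy == report.max_accuracy == 1.0

    def test_single_iteration_matches_bruteforce_dtw_argmin(self):
        # tiny hand-built pool, scored independently by path enumeration
        rng = np.random.default_rng(5)
        pool = []
        for tc in MERGED_CLASSES:
            for _ in range(2):
                n = int(rng.integers(3, 7))
                pool.append(
                    make_segment(rng.normal(size=(n, 3)), label=tc.value)
                )
        config = rc.ValidationConfig(position=CHEST, n_iterations=1, seed=11)
        report = rc.random_template_validation(pool, config)
        (drawn,) = report.template_indices
        templates = {
            tc: pool[i].data for tc, i in zip(MERGED_CLASSES, drawn)
        }
        correct = total = 0
        for i, seg in enumerate(pool):
            if i in drawn:
                continue
            scores = {
                tc: dtw_by_path_enumeration(seg.data, data)
                for tc, data in templates.items()
            }
            predicted = min(MERGED_CLASSES, key=lambda tc: scores[tc])
            correct += predicted.value == seg.label
            total += 1
        assert report.per_iteration_accuracy[0] == pytest.approx(correct / total)

    def test_template_never_in_its_own_test_set(self, chest_registry):
        pool = perfectly_separable_pool(chest_registry, copies=2)
        report = rc.random_template_validation(
            pool, rc.ValidationConfig(position=CHEST, n_iterations=20, seed=3)
        )
        tested_per_iteration = len(pool) - len(MERGED_CLASSES)
        assert int(report.confusion.values.sum()) == 20 * tested_per_iteration

    def test_seed_determinism(self, chest_registry):
        pool = perfectly_separable_pool(chest_registry)
        config = rc.ValidationConfig(position=CHEST, n_iterations=5, seed=42)
        r1 = rc.random_template_validation(pool, config)
        r2 = rc.random_template_validation(pool, config)
        np.testing.assert_array_equal(
            r1.per_iteration_accuracy, r2.per_iteration_accuracy
        )
        assert r1.template_indices == r2.template_indices

    def test_accuracy_aggregation_conventions(self, chest_registry):
        pool = perfectly_separable_pool(chest_registry)
        # corrupt one label so accuracy varies across iterations
        pool[1] = make_segment(pool[1].data, label="walking")
        report = rc.random_template_validation(
            pool, rc.ValidationConfig(position=CHEST, n_iterations=12, seed=9)
        )
        acc = report.per_iteration_accuracy
        assert report.mean_accuracy == pytest.approx(acc.mean(), abs=1e-12)
        assert report.sd_accuracy == pytest.approx(np.std(acc, ddof=1), abs=1e-12)
        assert report.min_accuracy <= report.mean_accuracy <= report.max_accuracy

    def test_thin_class_named_in_error(self, chest_registry):
        pool = perfectly_separable_pool(chest_registry)
        pool = [s for s in pool if s.label != "sit_up"][:13] + [
            s for s in pool if s.label == "sit_up"
        ][:1]
        with pytest.raises(rc.ConfigurationError, match="sit_up"):
            rc.random_template_validation(
                pool, rc.ValidationConfig(position=CHEST, n_iterations=2, seed=0)
            )

    def test_unlabeled_pool_rejected(self, chest_registry):
        pool = perfectly_separable_pool(chest_registry)
        pool[0] = make_segment(pool[0].data, label=None)
        with pytest.raises(rc.ConfigurationError):
            rc.random_template_validation(
                pool, rc.ValidationConfig(position=CHEST, n_iterations=1, seed=0)
            )


class TestBuildLabeledPool:
    def test_keeps_one_segment_per_cycle_and_labels_it(self):
        series, truth = rc.generate_exercise(
            rc.DEFAULT_SPECS[rc.ExerciseLabel.PUSH_UP],
            rc.DEFAULT_TRANSFORMS[CHEST],
            10,
            seed=31,
        )
        env = rc.short_term_energy(rc.compute_magnitude(series))
        peaks = rc.detect_peaks(env, min_height_frac=0.05)
        segments = rc.extract_segments(series, peaks)
        pool = rc.build_labeled_pool(segments, truth)
        assert 8 <= len(pool) <= 10
        assert all(s.label == "push_up" for s in pool)

    def test_sit_up_pool_keeps_only_wakeup_spans(self):
        series, truth = rc.generate_exercise(
            rc.DEFAULT_SPECS[rc.ExerciseLabel.SIT_UP],
            rc.DEFAULT_TRANSFORMS[CHEST],
            12,
            seed=32,
        )
        env = rc.short_term_energy(rc.compute_magnitude(series))
        peaks = rc.detect_peaks(env, min_height_frac=0.05)
        segments = rc.extract_segments(series, peaks)
        pool = rc.build_labeled_pool(segments, truth)
        # one wake-up per cycle at most, far fewer than the ~3x sub-segments
        assert len(pool) <= 12 < len(segments)
        wake_ms = rc.DEFAULT_SPECS[rc.ExerciseLabel.SIT_UP].base_period_s * 0.34 * 1000
        for seg in pool:
            assert seg.label == "sit_up"
            assert seg.duration_ms < 2 * wake_ms

    def test_side_labels_at_wrist(self):
        series, truth = rc.generate_exercise(
            rc.DEFAULT_SPECS[rc.ExerciseLabel.RUNNING],
            rc.DEFAULT_TRANSFORMS[rc.WearPosition.WRIST],
            10,
            seed=33,
        )
        env = rc.short_term_energy(rc.compute_magnitude(series))
        peaks = rc.detect_peaks(env, min_height_frac=0.05)
        segments = rc.extract_segments(series, peaks)
        pool = rc.build_labeled_pool(segments, truth)
        assert set(s.label for s in pool) <= {"running_right", "running_left"}
        assert len(set(s.label for s in pool)) == 2


class TestSegmentationRecallTable:
    def test_single_entry_total(self):
        table = rc.segmentation_recall_table({"chest": {"running": (1.0, 10)}})
        assert table.loc["chest", "total"] == 1.0

    def test_weighted_total(self):
        table = rc.segmentation_recall_table(
            {"chest": {"running": (1.0, 10), "walking": (0.5, 30)}}
        )
        assert table.loc["chest", "total"] == pytest.approx(0.625)

    def test_out_of_range_recall_rejected(self):
        with pytest.raises(rc.InvalidInputError):
            rc.segmentation_recall_table({"chest": {"running": (1.2, 10)}})

    def test_full_shape_from_all_positions(self):
        recalls = {
            pos: {label: (0.9, 10) for label in rc.ExerciseLabel}
            for pos in rc.WearPosition
        }
        table = rc.segmentation_recall_table(recalls)
        assert table.shape == (4, 6)
        assert ((table >= 0) & (table <= 1)).all().all()
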