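"""DTW against exhaustive path enumeration; registries and argmin classification."""

import json

import numpy as np
import pytest

import repcount as rc
from repcount.classification import MERGED_CLASSES, SIDE_SPLIT_CLASSES

from conftest import make_segment


def dtw_by_path_enumeration(s, t):
    """Minimum accumulated cost over explicitly enumerated monotone warping
    paths — exponential, usable only for tiny sequences."""
    s = np.atleast_2d(np.asarray(s, dtype=float))
    t = np.atleast_2d(np.asarray(t, dtype=float))
    n, m = len(s), len(t)

    def cost(i, j):
        return float(np.linalg.norm(s[i] - t[j]))

    best = [np.inf]

    def walk(i, j, acc):
        acc += cost(i, j)
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], acc)
            return
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def random_pair(rng):
    n, m = rng.integers(1, 7, size=2)
    return rng.normal(size=(n, 3)), rng.normal(size=(m, 3))


class TestDtwDistance:
    def test_self_distance_is_zero(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=(17, 3))
        assert rc.dtw_distance(s, s) == 0.0

    def test_single_cell_euclidean(self):
        assert rc.dtw_distance([[0, 0, 0]], [[3, 4, 0]]) == pytest.approx(5.0)

    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            s, t = random_pair(rng)
            assert rc.dtw_distance(s, t) == pytest.approx(
                dtw_by_path_enumeration(s, t), abs=1e-9
            )

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            s, t = random_pair(rng)
            assert rc.dtw_distance(s, t) == pytest.approx(rc.dtw_distance(t, s))

    def test_diagonal_is_admissible_upper_bound(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=(30, 3))
        t = rng.normal(size=(30, 3))
        diagonal = float(np.linalg.norm(s - t, axis=1).sum())
        assert rc.dtw_distance(s, t) <= diagonal + 1e-12

    def test_normalized_mode_divides_by_total_length(self):
        rng = np.random.default_rng(4)
        s, t = rng.normal(size=(5, 3)), rng.normal(size=(8, 3))
        raw = rc.dtw_distance(s, t)
        assert rc.dtw_distance(s, t, normalize=True) == pytest.approx(raw / 13)

    def test_empty_sequence_rejected(self):
        with pytest.raises(rc.InvalidInputError):
            rc.dtw_distance(np.empty((0, 3)), np.ones((3, 3)))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(rc.InvalidInputError):
            rc.dtw_distance(np.ones((3, 2)), np.ones((3, 3)))


class TestMergeClass:
    @pytest.mark.parametrize(
        "tc,label",
        [
            (rc.TemplateClass.RUNNING_LEFT, rc.ExerciseLabel.RUNNING),
            (rc.TemplateClass.RUNNING_RIGHT, rc.ExerciseLabel.RUNNING),
            (rc.TemplateClass.WALKING_RIGHT, rc.ExerciseLabel.WALKING),
            (rc.TemplateClass.WALKING_LEFT, rc.ExerciseLabel.WALKING),
            (rc.TemplateClass.JUMPING, rc.ExerciseLabel.JUMPING),
            (rc.TemplateClass.PUSH_UP, rc.ExerciseLabel.PUSH_UP),
            (rc.TemplateClass.SIT_UP, rc.ExerciseLabel.SIT_UP),
        ],
    )
    def test_mapping(self, tc, label):
        assert rc.merge_class(tc) is label


def template(tc, position, n=10, seed=0):
    rng = np.random.default_rng(seed + hash(tc) % 1000)
    return rc.Template(
        template_class=tc, position=position, fs=100.0, data=rng.normal(size=(n, 3))
    )


class TestBuildRegistry:
    def test_wrist_registry_has_seven(self):
        templates = [template(tc, rc.WearPosition.WRIST) for tc in SIDE_SPLIT_CLASSES]
        registry = rc.build_registry(templates, rc.WearPosition.WRIST)
        assert len(registry) == 7

    def test_chest_registry_has_five(self):
        templates = [template(tc, rc.WearPosition.CHEST) for tc in MERGED_CLASSES]
        assert len(rc.build_registry(templates, rc.WearPosition.CHEST)) == 5

    def test_missing_class_named_in_error(self):
        templates = [
            template(tc, rc.WearPosition.WRIST)
            for tc in SIDE_SPLIT_CLASSES
            if tc is not rc.TemplateClass.WALKING_LEFT
        ]
        with pytest.raises(rc.ConfigurationError, match="walking_left"):
            rc.build_registry(templates, rc.WearPosition.WRIST)

    def test_duplicate_class_rejected(self):
        templates = [template(tc, rc.WearPosition.CHEST) for tc in MERGED_CLASSES]
        templates.append(template(rc.TemplateClass.JUMPING, rc.WearPosition.CHEST))
        with pytest.raises(rc.ConfigurationError, match="duplicate"):
            rc.build_registry(templates, rc.WearPosition.CHEST)

    def test_side_split_class_rejected_at_chest(self):
        templates = [template(tc, rc.WearPosition.CHEST) for tc in MERGED_CLASSES]
        templates[0] = template(rc.TemplateClass.RUNNING_RIGHT, rc.WearPosition.CHEST)
        with pytest.raises(rc.ConfigurationError):
            rc.build_registry(templates, rc.WearPosition.CHEST)


class TestClassifySegment:
    def test_identical_to_template_scores_zero(self, chest_registry):
        tpl = chest_registry.get(rc.TemplateClass.PUSH_UP)
        seg = make_segment(tpl.data)
        result = rc.classify_segment(seg, chest_registry)
        assert result.template_class is rc.TemplateClass.PUSH_UP
        assert result.score == 0.0
        assert result.score == min(result.all_scores.values())

    def test_single_template_registry_always_wins(self):
        tpl = template(rc.TemplateClass.JUMPING, rc.WearPosition.CHEST, n=8)
        registry = rc.Registry(position=rc.WearPosition.CHEST, templates=(tpl,))
        seg = make_segment(np.random.default_rng(1).normal(size=(20, 3)))
        result = rc.classify_segment(seg, registry)
        assert result.template_class is rc.TemplateClass.JUMPING
        assert result.score > 0

    def test_tie_broken_by_canonical_order(self):
        # two templates equidistant from an all-zero query: mirror images
        data = np.random.default_rng(2).normal(size=(6, 3))
        t1 = rc.Template(rc.TemplateClass.RUNNING, rc.WearPosition.CHEST, 100.0, data)
        t2 = rc.Template(rc.TemplateClass.WALKING, rc.WearPosition.CHEST, 100.0, -data)
        registry = rc.Registry(position=rc.WearPosition.CHEST, templates=(t1, t2))
        seg = make_segment(np.zeros((4, 3)))
        result = rc.classify_segment(seg, registry)
        scores = list(result.all_scores.values())
        assert scores[0] == pytest.approx(scores[1])
        assert result.template_class is rc.TemplateClass.RUNNING

    def test_empty_registry_rejected(self):
        registry = rc.Registry(position=rc.WearPosition.CHEST, templates=())
        with pytest.raises(rc.ConfigurationError):
            rc.classify_segment(make_segment(np.zeros((4, 3))), registry)

    def test_position_mismatch_rejected(self, chest_registry):
        seg = make_segment(np.zeros((4, 3)), position="wrist")
        with pytest.raises(rc.ConfigurationError, match="position"):
            rc.classify_segment(seg, chest_registry)

    def test_rejection_threshold_marks_far_segments(self, chest_registry):
        rng = np.random.default_rng(3)
        seg = make_segment(rng.normal(size=(40, 3)) * 5.0)
        accepted = rc.classify_segment(seg, chest_registry)
        rejected = rc.classify_segment(seg, chest_registry, reject_threshold=1e-6)
        assert not accepted.rejected
        assert rejected.rejected
        assert rejected.template_class is accepted.template_class

    def test_query_resampled_on_fs_mismatch(self, chest_registry):
        tpl = chest_registry.get(rc.TemplateClass.WALKING)
        # same waveform recorded at twice the rate
        dense = np.repeat(tpl.data, 2, axis=0)
        seg = make_segment(dense, fs=200.0)
        result = rc.classify_segment(seg, chest_registry)
        assert result.label is rc.ExerciseLabel.WALKING

    def test_time_stretched_query_keeps_its_class(self, chest_registry):
        # DTW robustness to execution speed: 2x-length resampled queries
        for tpl in chest_registry:
            n = len(tpl.data)
            t_old = np.arange(n)
            t_new = np.linspace(0, n - 1, 2 * n)
            stretched = np.column_stack(
                [np.interp(t_new, t_old, tpl.data[:, k]) for k in range(3)]
            )
            result = rc.classify_segment(make_segment(stretched), chest_registry)
            assert result.template_class is tpl.template_class


class TestTemplateStore:
    def test_round_trip_is_bit_exact(self, tmp_path, template_bank):
        for position, registry in template_bank.items():
            path = tmp_path / f"{position.value}.json"
            rc.save_registry(registry, path)
            loaded = rc.load_registry(path)
            assert loaded.position == registry.position
            for a, b in zip(registry, loaded):
                assert a.template_class == b.template_class
                np.testing.assert_array_equal(a.data, b.data)

    def test_unsupported_schema_version_rejected(self, tmp_path, template_bank):
        path = tmp_path / "reg.json"
        rc.save_registry(template_bank[rc.WearPosition.CHEST], path)
        payload = json.loads(path.read_text())
        payload["schema_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(rc.InvalidInputError, match="schema"):
            rc.load_registry(path)
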