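"""Pattern preparation and between-subject classification."""

import numpy as np
import pytest

from conftest import TEST_DIMS, planted_example_set
from fairmirror.config import SimConfig, default_signal_spec
from fairmirror.mvpa import (
    CVFolds,
    ExampleSet,
    PatternExample,
    SearchlightSpec,
    balance_and_average,
    build_example_set,
    center_pattern,
    classify_fold,
    loso_folds,
    roi_accuracy,
    role_difference_images,
    searchlight_accuracy_map,
    searchlight_offsets,
    within_subject_accuracy,
)
from fairmirror.simulate import (
    make_block_schedule,
    make_signal_templates,
    simulate_subject_betas,
)


class TestCenterPattern:
    def test_constant_volume_becomes_zero_in_mask(self):
        vol = np.full((4, 4, 2), 7.0)
        mask = np.ones_like(vol, dtype=bool)
        np.testing.assert_allclose(center_pattern(vol, mask), 0.0)

    def test_idempotent_on_zero_mean(self):
        rng = np.random.default_rng(0)
        vol = rng.standard_normal((4, 4, 2))
        mask = np.ones_like(vol, dtype=bool)
        once = center_pattern(vol, mask)
        np.testing.assert_allclose(center_pattern(once, mask), once, atol=1e-12)

    def test_hand_example_and_out_of_mask_untouched(self):
        vol = np.zeros((4, 1, 1))
        vol[:, 0, 0] = [1, 2, 3, 6]
        mask = np.ones_like(vol, dtype=bool)
        mask[3] = False  # out of mask
        out = center_pattern(vol, mask)
        np.testing.assert_allclose(out[:3, 0, 0], [-1, 0, 1])
        assert out[3, 0, 0] == 6

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            center_pattern(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool))


@pytest.fixture(scope="module")
def betas(assignment):
    config = SimConfig(n_runs=3, blocks_per_run=8, volume_dims=(6, 6, 4),
                       error_rate=0.0)
    spec = default_signal_spec(config, noise_sd=0.0, subject_offset_sd=0.0,
                               smooth_fwhm_mm=0.0)
    tpl = make_signal_templates(config, spec, seed=1)
    schedule = make_block_schedule(config, assignment, seed=2)
    return simulate_subject_betas(schedule, tpl, spec, seed=3), tpl


class TestBalanceAndAverage:
    def test_equal_groups_are_plain_means(self, betas):
        b, tpl = betas
        flagged = sum(not blk.is_analyzable for blk in b.schedule.blocks)
        averages, retained = balance_and_average(b, ("stim_type",), seed=0)
        sizes = {k: len(v) for k, v in retained.items()}
        assert sizes[("action",)] == sizes[("control",)]
        total_analyzable = len(b.schedule.analyzable_indices())
        assert sum(sizes.values()) <= total_analyzable

    def test_larger_group_subsampled_to_smaller(self, assignment):
        config = SimConfig(n_runs=3, blocks_per_run=8, n_oddballs=2,
                           volume_dims=(4, 4, 2), error_rate=0.0)
        spec = default_signal_spec(config, noise_sd=0.0, subject_offset_sd=0.0,
                                   smooth_fwhm_mm=0.0)
        tpl = make_signal_templates(config, spec, seed=1)
        schedule = make_block_schedule(config, assignment, seed=5)
        b = simulate_subject_betas(schedule, tpl, spec, seed=3)
        averages, retained = balance_and_average(b, ("stim_type",), seed=0)
        sizes = [len(v) for v in retained.values()]
        assert len(set(sizes)) == 1  # balanced by subsampling
        assert sizes[0] == min(
            sum(blk.stim_type == s and blk.is_analyzable for blk in schedule.blocks)
            for s in ("action", "control")
        )

    def test_deterministic_given_seed(self, betas):
        b, _ = betas
        _, r1 = balance_and_average(b, ("modality", "stim_type", "role"), seed=9)
        _, r2 = balance_and_average(b, ("modality", "stim_type", "role"), seed=9)
        assert r1 == r2

    def test_noise_free_averages_equal_templates(self, betas):
        b, tpl = betas
        averages, _ = balance_and_average(b, ("modality", "stim_type", "role"), seed=0)
        identity = b.schedule.assignment.role_to_identity
        for (modality, stim, role), vol in averages.items():
            np.testing.assert_allclose(
                vol, tpl.volumes[(modality, stim, role, identity[role])], atol=1e-12
            )


class TestRoleDifferenceImages:
    def test_equal_action_control_gives_zero(self):
        vol = np.random.default_rng(0).standard_normal((4, 4, 2))
        averages = {
            ("visual", s, r): vol for s in ("action", "control") for r in ("fair", "unfair")
        }
        diffs = role_difference_images(averages)
        np.testing.assert_allclose(diffs["fair"], 0)
        np.testing.assert_allclose(diffs["unfair"], 0)

    def test_linearity_under_scaling(self):
        rng = np.random.default_rng(1)
        averages = {
            ("visual", s, r): rng.standard_normal((4, 4, 2))
            for s in ("action", "control")
            for r in ("fair", "unfair")
        }
        scaled = {k: 2 * v for k, v in averages.items()}
        d1 = role_difference_images(averages)
        d2 = role_difference_images(scaled)
        for role in ("fair", "unfair"):
            np.testing.assert_allclose(d2[role], 2 * d1[role])

    def test_noise_free_difference_is_shared_offset_plus_role_pattern(self):
        config = SimConfig(volume_dims=(12, 12, 8))
        spec = default_signal_spec(config, confound_pattern_amplitude=0.0)
        tpl = make_signal_templates(config, spec, seed=2)
        averages = {
            ("visual", s, r): tpl.volumes[("visual", s, r, "A" if r == "fair" else "B")]
            for s in ("action", "control")
            for r in ("fair", "unfair")
        }
        diffs = role_difference_images(averages)
        base = spec.shared_amplitude * spec.shared_region
        np.testing.assert_allclose(
            diffs["fair"], base + spec.role_pattern_amplitude * tpl.role_pattern,
            atol=1e-12,
        )
        np.testing.assert_allclose(
            diffs["unfair"], base - spec.role_pattern_amplitude * tpl.role_pattern,
            atol=1e-12,
        )

    def test_missing_condition_raises(self):
        with pytest.raises(KeyError):
            role_difference_images({("visual", "action", "fair"): np.zeros((2, 2, 2))})


class TestSearchlightOffsets:
    def test_radius_zero_is_origin_only(self):
        offsets = searchlight_offsets(0)
        assert offsets.shape == (1, 3)
        assert tuple(offsets[0]) == (0, 0, 0)

    def test_radius_one_has_seven_offsets(self):
        assert len(searchlight_offsets(1)) == 7

    @pytest.mark.parametrize("radius", range(6))
    def test_matches_exhaustive_lattice_enumeration(self, radius):
        expected = sorted(
            (i, j, k)
            for i in range(-radius, radius + 1)
            for j in range(-radius, radius + 1)
            for k in range(-radius, radius + 1)
            if i * i + j * j + k * k <= radius * radius
        )
        got = sorted(map(tuple, searchlight_offsets(radius)))
        assert got == expected

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            searchlight_offsets(-1)


class TestLosoFolds:
    def test_fifteen_subjects_fifteen_folds(self):
        folds = loso_folds([f"sub-{i:02d}" for i in range(15)])
        assert len(folds) == 15

    def test_two_subjects_two_folds(self):
        assert len(loso_folds(["a", "b"])) == 2

    def test_test_sets_partition_subjects(self):
        ids = [f"s{i}" for i in range(9)]
        folds = loso_folds(ids)
        tested = [s for _, test in folds.folds for s in test]
        assert sorted(tested) == sorted(ids)
        for train, test in folds.folds:
            assert set(train) | set(test) == set(ids)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loso_folds(["only"])


def _tiny_set(vectors_by_subject_label, n_voxels):
    examples = tuple(
        PatternExample(subject_id=s, label=lab, vector=np.asarray(v, float))
        for (s, lab), v in vectors_by_subject_label.items()
    )
    return ExampleSet(
        examples=examples,
        voxel_indices=np.arange(n_voxels),
        class_labels=("fair", "unfair"),
    )


class TestClassifyFold:
    def test_separable_training_set_classifies_itself(self):
        train = _tiny_set(
            {("s1", "fair"): [1, 1], ("s1", "unfair"): [-1, -1],
             ("s2", "fair"): [1.2, 0.8], ("s2", "unfair"): [-0.8, -1.2]},
            2,
        )
        pred = classify_fold(train, train)
        assert pred == [ex.label for ex in train.examples]

    def test_exact_tie_goes_to_lexicographically_first_class(self):
        train = _tiny_set(
            {("s1", "fair"): [1, 0], ("s1", "unfair"): [-1, 0]}, 2
        )
        test = _tiny_set({("t1", "fair"): [0, 1], ("t1", "unfair"): [0, -1]}, 2)
        pred = classify_fold(train, test)
        # both test vectors are orthogonal to the discriminant: decision 0
        assert pred == ["fair", "fair"]

    def test_matches_sklearn_svc_on_random_problems(self):
        # dual-route check: the low-level solver must reproduce
        # SVC(kernel='linear') everywhere except exact decision ties,
        # where our documented rule picks the lexicographically first class
        from sklearn.svm import SVC

        from fairmirror.mvpa import _fit_predict

        rng = np.random.default_rng(21)
        for trial in range(100):
            n, d = int(rng.integers(4, 30)) * 2, int(rng.integers(2, 40))
            C = float(rng.choice([0.1, 1.0, 10.0]))
            X = rng.standard_normal((n, d))
            y = rng.permutation([0.0, 1.0] * (n // 2))
            Xte = rng.standard_normal((8, d))
            mine = _fit_predict(X, y, Xte, C)
            clf = SVC(kernel="linear", C=C).fit(X, y)
            ref = clf.predict(Xte)
            ties = np.abs(clf.decision_function(Xte)) < 1e-9
            np.testing.assert_array_equal(mine[~ties], ref[~ties])
            np.testing.assert_array_equal(mine[ties], 0.0)

    def test_single_class_training_rejected(self):
        from fairmirror.mvpa import _fit_predict

        with pytest.raises(ValueError, match="both classes"):
            _fit_predict(np.ones((4, 3)), np.zeros(4), np.ones((1, 3)), 1.0)
        # and the ExampleSet contract refuses unbalanced class membership
        with pytest.raises(ValueError, match="equally many"):
            _tiny_set({("s1", "fair"): [1, 0], ("s2", "fair"): [2, 0]}, 2)

    def test_planted_pattern_generalizes_to_held_out_subject(self):
        examples, spec, _ = planted_example_set(
            n_subjects=8, role_amp=3.0, noise_sd=0.3, seed=4
        )
        folds = loso_folds(examples.subject_ids)
        acc = roi_accuracy(examples, folds, spec.role_pattern_region)
        assert acc == 1.0


class TestRoiAccuracy:
    def test_accuracy_is_multiple_of_one_thirtieth(self):
        examples, spec, _ = planted_example_set(n_subjects=15, role_amp=0.3,
                                                noise_sd=1.0, seed=6)
        folds = loso_folds(examples.subject_ids)
        acc = roi_accuracy(examples, folds, spec.role_pattern_region)
        assert (acc * 30) == pytest.approx(round(acc * 30), abs=1e-9)

    def test_invariant_to_subject_ordering(self):
        examples, spec, _ = planted_example_set(n_subjects=8, seed=8)
        folds = loso_folds(examples.subject_ids)
        reversed_set = ExampleSet(
            examples=tuple(reversed(examples.examples)),
            voxel_indices=examples.voxel_indices,
            class_labels=examples.class_labels,
            dims=examples.dims,
        )
        a = roi_accuracy(examples, folds, spec.role_pattern_region)
        b = roi_accuracy(reversed_set, folds, spec.role_pattern_region)
        assert a == b

    def test_invariant_to_common_rescaling(self):
        examples, spec, _ = planted_example_set(n_subjects=8, role_amp=2.0,
                                                noise_sd=0.5, seed=9)
        folds = loso_folds(examples.subject_ids)
        scaled = ExampleSet(
            examples=tuple(
                PatternExample(e.subject_id, e.label, e.vector * 3.7, e.chunk)
                for e in examples.examples
            ),
            voxel_indices=examples.voxel_indices,
            class_labels=examples.class_labels,
            dims=examples.dims,
        )
        assert roi_accuracy(examples, folds, spec.role_pattern_region) == roi_accuracy(
            scaled, folds, spec.role_pattern_region
        )

    def test_empty_roi_rejected(self):
        examples, _, sim = planted_example_set(n_subjects=4, seed=10)
        folds = loso_folds(examples.subject_ids)
        with pytest.raises(ValueError):
            roi_accuracy(examples, folds, np.zeros(sim.volume_dims, bool))


class TestSearchlight:
    def test_radius_zero_equals_single_voxel_classification(self):
        examples, spec, sim = planted_example_set(n_subjects=6, seed=12)
        folds = loso_folds(examples.subject_ids)
        mask = np.zeros(sim.volume_dims, bool)
        mask[5, 5, 4] = mask[6, 3, 2] = True
        sl = searchlight_accuracy_map(
            examples, SearchlightSpec(radius_voxels=0), folds, mask
        )
        for voxel in [(5, 5, 4), (6, 3, 2)]:
            single = np.zeros(sim.volume_dims, bool)
            single[voxel] = True
            assert sl.values[voxel] == roi_accuracy(examples, folds, single)

    def test_constant_data_yields_degenerate_chance_accuracy(self):
        n_vox = 4 * 4 * 2
        examples = ExampleSet(
            examples=tuple(
                PatternExample(f"s{i}", lab, np.ones(n_vox))
                for i in range(4)
                for lab in ("fair", "unfair")
            ),
            voxel_indices=np.arange(n_vox),
            class_labels=("fair", "unfair"),
            dims=(4, 4, 2),
        )
        folds = loso_folds(examples.subject_ids)
        mask = np.ones((4, 4, 2), bool)
        sl = searchlight_accuracy_map(
            examples, SearchlightSpec(radius_voxels=1), folds, mask
        )
        # identical patterns for both classes: the tie rule always predicts
        # the lexicographically first class, so accuracy is exactly 1/2
        np.testing.assert_allclose(sl.values[mask], 0.5)

    def test_planted_region_has_higher_accuracy_than_outside(self):
        examples, spec, sim = planted_example_set(n_subjects=10, role_amp=1.0,
                                                  noise_sd=1.0, seed=13)
        folds = loso_folds(examples.subject_ids)
        mask = np.ones(sim.volume_dims, bool)
        sl = searchlight_accuracy_map(
            examples, SearchlightSpec(radius_voxels=2), folds, mask
        )
        inside = sl.values[spec.role_pattern_region].mean()
        outside = np.nanmean(sl.values[~spec.role_pattern_region])
        assert inside - outside > 0.2


class TestWithinSubjectLeakage:
    def test_confound_only_data_leaks_within_subject(self):
        examples, spec, _ = planted_example_set(
            n_subjects=6, role_amp=0.0, conf_amp=2.0, noise_sd=0.5, seed=14,
            chunked=True,
        )
        acc = within_subject_accuracy(examples)
        assert acc > 0.5

    def test_unchunked_set_rejected(self):
        examples, _, _ = planted_example_set(n_subjects=4, seed=15)
        with pytest.raises(ValueError):
            within_subject_accuracy(examples)


class TestExampleSetInvariants:
    def test_unbalanced_subject_contribution_rejected(self):
        with pytest.raises(ValueError, match="equally many"):
            ExampleSet(
                examples=(
                    PatternExample("s1", "fair", np.zeros(3)),
                    PatternExample("s1", "unfair", np.zeros(3)),
                    PatternExample("s2", "fair", np.zeros(3)),
                ),
                voxel_indices=np.arange(3),
                class_labels=("fair", "unfair"),
            )

    def test_non_finite_vector_rejected(self):
        with pytest.raises(ValueError):
            PatternExample("s", "fair", np.array([1.0, np.nan]))

    def test_asymmetric_offsets_rejected(self):
        with pytest.raises(ValueError):
            SearchlightSpec(offsets=np.array([[0, 0, 0], [1, 0, 0]]))
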