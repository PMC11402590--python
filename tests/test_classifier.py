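import numpy as np
import pytest

from wriststep.classifier import (
    TrainConfig,
    augment_epoch,
    class_weights,
    extract_features,
    grouped_stratified_kfold,
    label_epochs_from_steps,
    predict_epochs,
    train_classifier,
    _rotation_matrix,
)
from wriststep.signal_io import AccelRecording, EpochSet, epoch_split
from wriststep.synthetic import GaitProfile, simulate_participant


def epoch_set_for(n_epochs=6, rate=25.0, seed=0, labels=None, groups=None):
    rng = np.random.default_rng(seed)
    epochs = rng.normal(0, 0.2, (n_epochs, int(10 * rate), 3))
    return EpochSet(
        epochs=epochs,
        epoch_length_s=10.0,
        sample_rate_hz=rate,
        labels=labels,
        group_ids=groups,
    )


class TestLabelRule:
    @pytest.mark.parametrize("n_steps,expected", [(0, 0), (3, 0), (4, 1), (9, 1)])
    def test_at_least_four_steps_defines_walking(self, n_steps, expected):
        es = epoch_set_for(n_epochs=1)
        steps = np.linspace(1.0, 9.0, n_steps) if n_steps else np.empty(0)
        assert label_epochs_from_steps(steps, es)[0] == expected

    def test_half_open_epoch_windows(self):
        es = epoch_set_for(n_epochs=2)
        # 4 steps exactly at the boundary belong to the second epoch
        steps = np.array([10.0, 11.0, 12.0, 13.0])
        np.testing.assert_array_equal(label_epochs_from_steps(steps, es), [0, 1])


class TestAugmentation:
    def test_norms_preserved(self, rng):
        epoch = rng.normal(0, 1, (250, 3))
        out = augment_epoch(epoch, rng)
        np.testing.assert_allclose(
            np.linalg.norm(out, axis=1), np.linalg.norm(epoch, axis=1), atol=1e-9
        )

    def test_quarter_turn_about_z(self):
        R = _rotation_matrix(np.array([0.0, 0.0, 1.0]), np.pi / 2)
        np.testing.assert_allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_vm_features_invariant_under_augmentation(self, rng):
        epoch = rng.normal(0, 0.5, (250, 3)) + [0, 0, 1]
        f0 = extract_features(epoch, 25.0)
        f1 = extract_features(augment_epoch(epoch, rng), 25.0)
        np.testing.assert_allclose(f0, f1, atol=1e-7)


class TestFeatures:
    def test_zero_epoch_degenerates_cleanly(self):
        f = extract_features(np.zeros((250, 3)), 25.0)
        assert np.all(np.isfinite(f))
        names_idx = {"vm_sd": 1, "dom_freq_hz": 5}
        assert f[names_idx["vm_sd"]] == 0.0
        assert f[names_idx["dom_freq_hz"]] == 0.0

    def test_dominant_frequency_of_pure_tone(self):
        t = np.arange(250) / 25.0
        vm_target = 0.3 * np.sin(2 * np.pi * 2.0 * t)  # 2 Hz VM oscillation
        epoch = np.column_stack([np.zeros_like(t), np.zeros_like(t), 1.0 + vm_target])
        f = extract_features(epoch, 25.0)
        assert f[5] == pytest.approx(2.0, abs=0.11)


class TestClassWeights:
    def test_already_at_target_balance_gives_equal_weights(self):
        labels = np.array([1] * 10 + [0] * 90)
        w = class_weights(labels)
        assert w[0] == pytest.approx(w[1]) == pytest.approx(1.0)

    def test_balanced_data_reweighted_one_to_nine(self):
        labels = np.array([1] * 50 + [0] * 50)
        w = class_weights(labels)
        assert w[1] / w[0] == pytest.approx(1 / 9)

    def test_duplicating_non_walk_epochs_keeps_loss_ratio(self):
        labels = np.array([1] * 20 + [0] * 80)
        w1 = class_weights(labels)
        labels2 = np.array([1] * 20 + [0] * 160)
        w2 = class_weights(labels2)
        # total weighted mass ratio walk:non-walk stays 10:90
        r1 = (20 * w1[1]) / (80 * w1[0])
        r2 = (20 * w2[1]) / (160 * w2[0])
        assert r1 == pytest.approx(r2) == pytest.approx(1 / 9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights(np.zeros(10, int))


def _toy_cohort_epochs(n_participants=6, seed=3):
    """Per-participant recordings mixing clean walking and sedentary time."""
    all_es = []
    for i in range(n_participants):
        rec = simulate_participant(
            [
                ("sedentary", None, 60.0),
                ("walk", GaitProfile(cadence_spm=100 + 2 * i), 60.0),
                ("fidget", None, 60.0),
            ],
            25.0,
            seed=seed + i,
            participant_id=f"T{i}",
        )
        es = rec.epoch_set
        all_es.append(es)
    return EpochSet(
        epochs=np.concatenate([e.epochs for e in all_es]),
        epoch_length_s=10.0,
        sample_rate_hz=25.0,
        labels=np.concatenate([e.labels for e in all_es]),
        group_ids=np.concatenate([e.group_ids for e in all_es]),
    )


@pytest.fixture(scope="module")
def cohort_epochs():
    return _toy_cohort_epochs()


class TestTrainPredict:
    @pytest.mark.parametrize("backend", ["logistic", "sgd"])
    def test_separable_features_reach_high_kappa(self, cohort_epochs, backend):
        from wriststep.evaluation import classification_metrics

        model = train_classifier(
            cohort_epochs, TrainConfig(seed=5), backend=backend
        )
        rep = classification_metrics(model.val_true, model.val_pred)
        assert rep.cohens_kappa >= 0.9

    def test_validation_predictions_recorded(self, cohort_epochs):
        model = train_classifier(cohort_epochs, TrainConfig(seed=5))
        assert model.val_true.shape == model.val_pred.shape
        assert set(model.val_groups.tolist()) < set(cohort_epochs.group_ids.tolist())

    def test_prediction_is_deterministic_and_normalised(self, cohort_epochs):
        model = train_classifier(cohort_epochs, TrainConfig(seed=5))
        p1, h1 = predict_epochs(model, cohort_epochs)
        p2, h2 = predict_epochs(model, cohort_epochs)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(h1, h2)
        assert np.all((p1 >= 0) & (p1 <= 1))
        np.testing.assert_array_equal(h1, (p1 >= 0.5).astype(int))

    def test_single_class_training_fails(self):
        es = epoch_set_for(
            n_epochs=8,
            labels=np.zeros(8, int),
            groups=np.array(["a"] * 4 + ["b"] * 4, dtype=object),
        )
        with pytest.raises(ValueError):
            train_classifier(es, TrainConfig(seed=0))


class TestGroupedStratifiedKFold:
    def _epoch_set(self, walk_fractions, epochs_per_participant=20):
        labels, groups = [], []
        for i, f in enumerate(walk_fractions):
            n_walk = int(round(f * epochs_per_participant))
            labels += [1] * n_walk + [0] * (epochs_per_participant - n_walk)
            groups += [f"G{i}"] * epochs_per_participant
        n = len(labels)
        return EpochSet(
            epochs=np.zeros((n, 250, 3)),
            epoch_length_s=10.0,
            sample_rate_hz=25.0,
            labels=np.array(labels),
            group_ids=np.array(groups, dtype=object),
        )

    def test_one_participant_per_fold_when_k_equals_n(self, rng):
        es = self._epoch_set([0.2] * 10)
        folds = grouped_stratified_kfold(es, k=10, rng=rng)
        for g in set(es.group_ids.tolist()):
            assert len(set(folds[es.group_ids == g].tolist())) == 1
        assert sorted(set(folds.tolist())) == list(range(10))

    def test_grouping_invariant_and_partition(self, rng):
        es = self._epoch_set([0.1, 0.5] * 8)
        folds = grouped_stratified_kfold(es, k=4, rng=rng)
        per_fold_groups = [
            set(es.group_ids[folds == f].tolist()) for f in range(4)
        ]
        for a in range(4):
            for b in range(a + 1, 4):
                assert not (per_fold_groups[a] & per_fold_groups[b])
        assert set().union(*per_fold_groups) == set(es.group_ids.tolist())

    def test_greedy_balance_on_alternating_cohort(self, rng):
        es = self._epoch_set([0.1, 0.5] * 10)
        folds = grouped_stratified_kfold(es, k=5, rng=rng)
        global_frac = es.labels.mean()
        for f in range(5):
            frac = es.labels[folds == f].mean()
            assert abs(frac - global_frac) <= 0.1

    def test_too_few_participants_rejected(self, rng):
        es = self._epoch_set([0.2] * 3)
        with pytest.raises(ValueError):
            grouped_stratified_kfold(es, k=10, rng=rng)
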