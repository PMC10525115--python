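"""Split plans, the training loop, and cross-validation aggregation."""

import numpy as np
import pandas as pd
import pytest

from voicescreen.evaluate import (
    SplitPlan,
    TrainConfig,
    aggregate_reports,
    early_stop_epoch,
    make_splits,
    predict_scores,
    train,
)
from voicescreen.metrics import MetricsReport
from voicescreen.models import MissingBackboneError, ModelSpec, SmallCNN, build_model


def _image_index(n):
    """Balanced image-level index frame."""
    return pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "group": ["AD" if i % 2 else "control" for i in range(n)],
        }
    )


def _participant_index(n_participants, images_per=1):
    rows = []
    for i in range(n_participants):
        for j in range(images_per):
            rows.append(
                {
                    "participant_id": f"P{i:03d}",
                    "group": "AD" if i % 2 else "control",
                }
            )
    return pd.DataFrame(rows)


class TestMakeSplits:
    def test_image_level_holdout_640_train(self):
        """8:1:1 over 800 images leaves 640 for training."""
        plan = make_splits(_image_index(800), SplitPlan(unit="image", seed=0))
        counts = pd.Series(plan.assignments).value_counts()
        assert counts["train"] == 640
        assert counts["val"] == 80
        assert counts["test"] == 80

    def test_participant_kfold_sixteen_per_fold(self):
        plan = make_splits(
            _participant_index(80),
            SplitPlan(mode="kfold", k=5, unit="participant", seed=1),
        )
        assert len(plan.fold_assignments) == 5
        all_test = []
        for fold in plan.fold_assignments:
            test_units = [u for u, part in fold.items() if part == "test"]
            assert len(test_units) == 16
            all_test += test_units
        # folds are disjoint and cover every participant
        assert sorted(all_test) == sorted(set(all_test))
        assert len(all_test) == 80

    def test_stratification(self):
        plan = make_splits(_participant_index(80), SplitPlan(seed=3))
        df = _participant_index(80).drop_duplicates("participant_id")
        df["part"] = df["participant_id"].map(plan.assignments)
        test = df[df.part == "test"]
        assert (test.group == "AD").sum() == 4  # balanced 8-participant test set

    def test_same_seed_same_assignment(self):
        a = make_splits(_participant_index(40), SplitPlan(seed=7))
        b = make_splits(_participant_index(40), SplitPlan(seed=7))
        assert a.assignments == b.assignments

    def test_too_few_units_for_kfold(self):
        with pytest.raises(ValueError):
            make_splits(_participant_index(6), SplitPlan(mode="kfold", k=5))

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            SplitPlan(mode="bogus")
        with pytest.raises(ValueError):
            SplitPlan(ratios=(0.5, 0.2, 0.2))

    def test_participant_never_straddles_partitions(self):
        """Subject-wise split keeps all of a speaker's images together."""
        index = _participant_index(20, images_per=10)
        plan = make_splits(index, SplitPlan(unit="participant", seed=2))
        member = index["participant_id"].map(plan.assignments)
        per_part = member.groupby(index["participant_id"]).nunique()
        assert (per_part == 1).all()


class TestEarlyStop:
    @pytest.mark.parametrize(
        "losses,patience,expected",
        [
            ([1.0, 0.9, 0.91, 0.92, 0.93], 3, 5),
            ([1.0, 0.9, 0.8, 0.7], 3, 4),        # keeps improving -> runs out
            ([1.0, 1.1, 1.2, 1.3, 0.5], 3, 4),    # stops before the rebound
            ([0.5], 3, 1),
        ],
    )
    def test_patience_arithmetic(self, losses, patience, expected):
        assert early_stop_epoch(losses, patience) == expected


def _toy_data(n=12, seed=0):
    """Tiny images whose mean intensity separates the classes."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for i in range(n):
        label = i % 2
        base = 60 if label == 0 else 190
        images.append(
            np.clip(rng.normal(base, 12, size=(32, 60)), 0, 255).astype(np.uint8)
        )
        labels.append(label)
    return images, np.asarray(labels)


class TestTrain:
    def test_max_epochs_one(self):
        images, labels = _toy_data()
        model = SmallCNN(input_size=(16, 30), seed=0)
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=1, early_stop_patience=1,
                          seed=0)
        _, history = train(model, cfg, images, labels, images, labels)
        assert len(history["val_loss"]) == 1

    def test_config_rejects_nonpositive_settings(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)

    def test_separable_toy_problem_converges(self):
        images, labels = _toy_data(16)
        model = SmallCNN(input_size=(16, 30), seed=0)
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=40, seed=0)
        model, history = train(model, cfg, images, labels, images, labels)
        scores = predict_scores(model, images)
        assert (((scores >= 0.5).astype(int)) == labels).mean() >= 0.95
        assert history["val_loss"][-1] <= history["val_loss"][0]

    def test_empty_set_rejected(self):
        model = SmallCNN(seed=0)
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=2, early_stop_patience=1)
        with pytest.raises(ValueError):
            train(model, cfg, [], np.array([]), [], np.array([]))

    def test_unfitted_model_cannot_score(self):
        model = SmallCNN(seed=0)
        with pytest.raises(RuntimeError):
            model.predict_proba([np.zeros((312, 599), np.uint8)])

    def test_scores_deterministic_and_bounded(self):
        images, labels = _toy_data(8)
        model = SmallCNN(input_size=(16, 30), seed=1)
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=5, seed=1)
        model, _ = train(model, cfg, images, labels, images, labels)
        s1 = predict_scores(model, images)
        s2 = predict_scores(model, images)
        np.testing.assert_array_equal(s1, s2)
        assert np.all((s1 >= 0) & (s1 <= 1))
        # duplicate image gets an identical score
        s_dup = predict_scores(model, [images[0], images[0]])
        assert s_dup[0] == s_dup[1]

    def test_empty_scores_for_empty_set(self):
        images, labels = _toy_data(8)
        model = SmallCNN(input_size=(16, 30), seed=0)
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=2, seed=0)
        model, _ = train(model, cfg, images, labels, images, labels)
        assert predict_scores(model, []).size == 0


class TestAggregation:
    def test_unweighted_mean(self):
        reports = [
            MetricsReport(tp=8, fn=2, fp=1, tn=9, auc=0.9),
            MetricsReport(tp=6, fn=4, fp=3, tn=7, auc=0.7),
        ]
        panel = aggregate_reports(reports)
        assert panel["sensitivity"] == pytest.approx((0.8 + 0.6) / 2)
        assert panel["auc"] == pytest.approx(0.8)

    def test_identical_folds_zero_variance(self):
        r = MetricsReport(tp=5, fn=0, fp=0, tn=5, auc=1.0)
        panel = aggregate_reports([r, r, r])
        assert panel["accuracy"] == 1.0


class TestBackbones:
    def test_unregistered_backbone_raises(self):
        with pytest.raises(MissingBackboneError):
            build_model(ModelSpec(architecture="densenet121", channels=3))

    def test_registry_pluggable(self):
        from voicescreen.models import register_backbone

        sentinel = object()
        register_backbone("vgg19", lambda spec, seed: sentinel)
        try:
            assert build_model(ModelSpec(architecture="vgg19", channels=3)) is sentinel
        finally:
            from voicescreen import models as m

            m._BACKBONES.pop("vgg19", None)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(architecture="alexnet")
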