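"""Model assembly, the training loop, and evaluation metrics."""

import numpy as np
import pytest

from mfnet import nn
from mfnet.model_training import (EvalReport, ModelConfig, TrainConfig,
                                  build_mfnet, desk_model_config,
                                  desk_train_config, evaluate,
                                  evaluate_split, prepare_features, train)
from mfnet.skeleton_core import SkeletonSequence, ValidationError
from mfnet.synthetic_actions import generate, two_class_spec
from mfnet.tcn_backbone import count_block_parameters, verify_parameter_count


def _random_batch(rng, n, length=16):
    return {
        "body": rng.normal(size=(n, length, 20, 3)),
        "part": rng.normal(size=(n, length, 5, 9)),
        "joint": rng.normal(size=(n, length, 160)),
        "velocity": rng.normal(size=(n, length, 20, 3)),
        "acceleration": rng.normal(size=(n, length, 20, 3)),
    }


class TestBuildMfnet:
    def test_probabilities_sum_to_one(self, rng):
        model = build_mfnet(5, desk_model_config(5, sequence_length=16))
        model.eval()
        probs = model.forward(_random_batch(rng, 2))
        assert probs.shape == (2, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_untrained_model_is_at_chance(self, rng):
        model = build_mfnet(4, desk_model_config(4, sequence_length=16))
        model.eval()
        n = 200
        labels = rng.integers(0, 4, size=n)
        preds = model.predict(_random_batch(rng, n))
        acc = (preds == labels).mean()
        assert abs(acc - 0.25) < 0.12  # binomial noise around chance

    def test_untrained_loss_near_log_n_classes(self, rng):
        # batch statistics, as the first training step sees them
        model = build_mfnet(5, desk_model_config(5, sequence_length=16,
                                                  dropout=0.0))
        logits = model.logits(_random_batch(rng, 32))
        loss = nn.cross_entropy(logits, rng.integers(0, 5, size=32))
        assert abs(loss.data - np.log(5)) < 0.25

    def test_stream_block_parameters_match_analytic(self):
        model = build_mfnet(3, desk_model_config(3))
        for net in model.stream_nets:
            for block in net.blocks:
                assert verify_parameter_count(block) == \
                    count_block_parameters(block.cfg)

    def test_invalid_configs(self):
        with pytest.raises(ValidationError):
            ModelConfig(n_classes=1)
        with pytest.raises(ValidationError):
            ModelConfig(n_classes=3, streams=("body", "bogus"))
        with pytest.raises(ValidationError):
            ModelConfig(n_classes=3, fusion="average")
        with pytest.raises(ValidationError):
            build_mfnet(4, ModelConfig(n_classes=3))


class TestTrainConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            TrainConfig(train_frac=0.5, val_frac=0.1, test_frac=0.3)

    def test_defaults_follow_reference_protocol(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 1e-5
        assert cfg.weight_decay == 5e-4
        assert cfg.batch_size == 256
        assert cfg.dropout == 0.5
        assert (cfg.train_frac, cfg.val_frac, cfg.test_frac) == (0.6, 0.1, 0.3)


class TestTrain:
    def test_separable_two_class_learns(self, two_class_dataset):
        """On the linearly separable fixture the trained model must beat
        0.95 validation accuracy (the centroid oracle already does)."""
        sequences, labels = two_class_dataset
        model = build_mfnet(2, desk_model_config(2), seed=5)
        cfg = desk_train_config(seed=5, max_epochs=25)
        model, history, (tr, va, te) = train(model, sequences, labels, cfg)
        assert max(history.val_acc) >= 0.95
        report = evaluate_split(model, sequences, labels, te)
        assert report.accuracy >= 0.95

    def test_overfit_tiny_set_monotone_loss(self):
        """With dropout off, full-batch updates and lr 1e-3 the network
        memorizes 20 samples; loss decreases over the first epochs."""
        sequences, manifest = generate(two_class_spec(seed=7, n_per_class=10))
        labels = manifest.labels()
        model = build_mfnet(2, desk_model_config(2, dropout=0.0), seed=7)
        cfg = desk_train_config(seed=7, max_epochs=6)
        cfg.batch_size = 20
        cfg.train_frac, cfg.val_frac, cfg.test_frac = 0.8, 0.1, 0.1
        model, history, _ = train(model, sequences, labels, cfg)
        losses = history.train_loss[:4]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_empty_dataset_rejected(self):
        model = build_mfnet(2, desk_model_config(2))
        with pytest.raises(ValidationError):
            train(model, [], [])

    def test_split_too_small_rejected(self, rng):
        seqs = [SkeletonSequence(rng.normal(size=(8, 20, 3)))
                for _ in range(3)]
        model = build_mfnet(2, desk_model_config(2))
        with pytest.raises(ValidationError):
            train(model, seqs, [0, 1, 0], desk_train_config())


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        model = build_mfnet(2, desk_model_config(2, sequence_length=8))
        model.eval()
        feats = _random_batch(rng, 10, length=8)
        labels = model.predict(feats)  # evaluate against its own output
        report = evaluate(model, feats, labels)
        assert report.accuracy == 1.0
        present = [c for c in range(2) if (labels == c).sum()]
        assert all(report.f1[c] == 1.0 for c in present)

    def test_all_one_class_confusion(self):
        """Predicting a single class on a balanced 2-class set: accuracy
        one half, macro F1 = (2/3 + 0)/2 = 1/3."""
        from sklearn.metrics import precision_recall_fscore_support
        labels = np.array([0, 0, 1, 1])
        preds = np.zeros(4, dtype=int)
        prec, rec, f1, _ = precision_recall_fscore_support(
            labels, preds, labels=[0, 1], zero_division=0)
        assert (preds == labels).mean() == 0.5
        assert np.isclose(f1.mean(), 1 / 3)

    def test_report_json_round_trip(self):
        report = EvalReport(accuracy=0.9, precision=[1.0, 0.8],
                            recall=[0.9, 0.9], f1=[0.95, 0.85],
                            macro_precision=0.9, macro_recall=0.9,
                            macro_f1=0.9, confusion=[[9, 1], [0, 10]])
        assert EvalReport.from_json(report.to_json()) == report

    def test_missing_class_flagged(self, rng):
        model = build_mfnet(3, desk_model_config(3, sequence_length=8))
        feats = _random_batch(rng, 6, length=8)
        labels = np.array([0, 0, 1, 1, 0, 1])  # class 2 absent
        report = evaluate(model, feats, labels)
        assert report.missing_classes == [2]


class TestDeterminism:
    def test_same_seed_same_history(self, two_class_dataset):
        sequences, labels = two_class_dataset

        def run():
            model = build_mfnet(2, desk_model_config(2), seed=11)
            cfg = desk_train_config(seed=11, max_epochs=4)
            _, history, _ = train(model, sequences, labels, cfg)
            return history

        h1, h2 = run(), run()
        assert h1.train_loss == h2.train_loss
        assert h1.val_acc == h2.val_acc
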