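"""Tests for dataset splitting, the training loops and the grid search.

Training runs here use deliberately tiny datasets and miniature model
configs so the whole file stays fast; the full-scale surrogate benchmarks
live in the acceptance suite.
"""

import numpy as np
import pytest

from lfianet import synthdata as sd, training as tr
from lfianet.models import ClassifierConfig, SegmenterConfig

TINY_CLF = ClassifierConfig(conv_channels=(4, 4, 8, 8, 12, 12, 16),
                            expansion_channels=32)
TINY_SEG = SegmenterConfig(encoder_features=(4, 6, 8, 8))


@pytest.fixture(scope="module")
def tiny_dataset():
    return sd.generate_dataset(sd.SynthConfig(counts=(12, 12, 12, 16), seed=21))


@pytest.fixture(scope="module")
def tiny_class4():
    return sd.generate_dataset(sd.SynthConfig(counts=(0, 0, 0, 48), seed=22))


class TestSplitDataset:
    def test_split_sizes_and_union(self, tiny_dataset):
        train, val = tr.split_dataset(tiny_dataset, 0.8, seed=1)
        assert len(train) + len(val) == len(tiny_dataset)
        # per-class rounding: 10+10+10+13 train of 52 (4,100 would give 3,280/820)
        assert len(train) == 43 and len(val) == 9
        ids = {id(t) for t in train} | {id(t) for t in val}
        assert ids == {id(t) for t in tiny_dataset}

    def test_stratification_preserves_class_shares(self, tiny_dataset):
        train, val = tr.split_dataset(tiny_dataset, 0.75, seed=3)
        for label, count in ((1, 12), (2, 12), (3, 12), (4, 16)):
            n_train = sum(1 for t in train if t.label == label)
            assert n_train == round(0.75 * count)

    def test_same_seed_same_split(self, tiny_dataset):
        a_train, _ = tr.split_dataset(tiny_dataset, 0.8, seed=9)
        b_train, _ = tr.split_dataset(tiny_dataset, 0.8, seed=9)
        assert [id(t) for t in a_train] == [id(t) for t in b_train]

    def test_degenerate_split_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            tr.split_dataset(tiny_dataset, 0.99, seed=0)  # empty validation class


@pytest.fixture(scope="module")
def classifier_tiny_run(tiny_dataset):
    train, val = tr.split_dataset(tiny_dataset, 0.8, seed=5)
    cfg = tr.TrainConfig(epochs=8, seed=5)
    model, hist = tr.train_classifier(train, val, cfg, model_config=TINY_CLF)
    return model, hist, train, val


@pytest.fixture(scope="module")
def segmenter_tiny_run(tiny_class4):
    train, val = tr.split_dataset(tiny_class4, 0.8, seed=6)
    cfg = tr.TrainConfig(loss="WBCE+DSC", epochs=6, seed=6)
    model, hist = tr.train_segmenter(train, val, cfg, model_config=TINY_SEG)
    return model, hist, val


class TestTrainClassifier:
    @pytest.fixture
    def run(self, classifier_tiny_run):
        return classifier_tiny_run

    def test_history_length_matches_epochs(self, run):
        _, hist, _, _ = run
        assert len(hist.train_loss) == len(hist.val_metric) == 8

    def test_loss_decreases(self, run):
        _, hist, _, _ = run
        assert min(hist.train_loss[-3:]) < hist.train_loss[0]
        assert np.all(np.isfinite(hist.train_loss))

    def test_best_checkpoint_equals_history_max(self, run):
        _, hist, _, _ = run
        assert hist.best_metric == max(hist.val_metric)

    def test_bitwise_reproducibility(self, tiny_dataset, run):
        model_a, hist_a, _, _ = run
        train, val = tr.split_dataset(tiny_dataset, 0.8, seed=5)
        cfg = tr.TrainConfig(epochs=8, seed=5)
        model_b, hist_b = tr.train_classifier(train, val, cfg, model_config=TINY_CLF)
        assert hist_a.train_loss == hist_b.train_loss
        assert hist_a.val_metric == hist_b.val_metric
        for pa, pb in zip(model_a.params(), model_b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)


class TestTrainSegmenter:
    @pytest.fixture
    def run(self, segmenter_tiny_run):
        return segmenter_tiny_run

    def test_history_and_finiteness(self, run):
        _, hist, _ = run
        assert len(hist.val_metric) == 6
        assert np.all(np.isfinite(hist.train_loss))
        assert np.all(np.isfinite(hist.val_loss))

    def test_best_checkpoint_is_max_iou(self, run):
        _, hist, _ = run
        assert hist.best_metric == max(hist.val_metric)
        assert hist.val_metric[hist.best_epoch] == hist.best_metric

    def test_iou_improves_over_training(self, run):
        _, hist, _ = run
        assert hist.val_metric[-1] > hist.val_metric[0]

    def test_evaluate_report_fields(self, run):
        model, _, val = run
        report = tr.evaluate(model, val, cutoff=0.6)
        assert set(report) == {"iou", "dice", "recall", "precision"}
        assert all(0 <= v <= 1 for v in report.values())

    def test_data_driven_weight_mode_runs(self, tiny_class4):
        train, val = tr.split_dataset(tiny_class4, 0.8, seed=6)
        cfg = tr.TrainConfig(loss="WBCE", epochs=2, seed=6, weight_mode="data")
        _, hist = tr.train_segmenter(train, val, cfg, model_config=TINY_SEG)
        assert np.all(np.isfinite(hist.train_loss))


class TestLossOrdering:
    def test_combined_loss_beats_dsc_alone_as_tendency(self):
        """WBCE+DSC should reach a better best-validation IoU than DSC alone
        on a majority of paired seeds (the combined-loss advantage)."""
        model_cfg = SegmenterConfig(encoder_features=(8, 16, 16, 32))
        wins = 0
        for seed in (1, 2, 3):
            dataset = sd.generate_dataset(sd.SynthConfig(counts=(0, 0, 0, 120),
                                                         seed=seed))
            train, val = tr.split_dataset(dataset, 0.8, seed=seed)
            best = {}
            for tag in ("WBCE+DSC", "DSC"):
                cfg = tr.TrainConfig(loss=tag, epochs=20, seed=seed)
                _, hist = tr.train_segmenter(train, val, cfg,
                                             model_config=model_cfg)
                best[tag] = hist.best_metric
            wins += best["WBCE+DSC"] >= best["DSC"]
        assert wins >= 2


class TestEvaluateClassifier:
    def test_oracle_model_scores_perfectly(self, tiny_dataset):
        _, val = tr.split_dataset(tiny_dataset, 0.8, seed=5)
        labels = np.array([t.label for t in val])

        class Oracle(tr.PeakClassifier):
            def forward(self, x, training=False):
                out = np.zeros((len(x), 4), dtype=np.float32)
                out[np.arange(len(x)), labels[:len(x)] - 1] = 1.0
                return out

        report = tr.evaluate(Oracle(TINY_CLF, seed=0), val)
        assert report["accuracy"] == 1.0
        confusion = np.array(report["confusion"])
        assert confusion.sum() == len(val)
        assert np.all(confusion == np.diag(np.diag(confusion)))


class TestGridSearch:
    def test_reduced_grid_complete_and_reproducible(self, tiny_class4):
        train, val = tr.split_dataset(tiny_class4, 0.8, seed=6)
        cfg = tr.TrainConfig(loss="WBCE+DSC", epochs=3, seed=6)
        grid = tr.grid_search(train, val, weight_ratios=((0.6, 0.4), (0.5, 0.5)),
                              cutoffs=(0.5, 0.6), config=cfg, model_config=TINY_SEG)
        assert grid.shape == (2, 2)
        assert grid.notna().all().all()
        assert ((grid >= 0) & (grid <= 1)).all().all()
        # a cell must equal an independent single run with the same seed
        model, _ = tr.train_segmenter(train, val, cfg, model_config=TINY_SEG)
        independent = tr.evaluate(model, val, cutoff=0.6)["iou"]
        assert grid.loc["0.6:0.4", "cutoff=0.6"] == pytest.approx(independent,
                                                                  abs=1e-12)
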