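"""Training pipeline, Model/Results interface, config, CLI."""

import numpy as np
import pytest
from click.testing import CliRunner

import noduleseg as ns
from noduleseg.cli import main as cli_main
from noduleseg.model import evaluate, train
from noduleseg.networks import NetworkSpec
from noduleseg.nn import Tensor
from noduleseg.phantom import DatasetSplit


def tiny_split(n=4, seed=2):
    samples = ns.synth_dataset(n, seed=seed)
    return DatasetSplit(samples, [], 0.0, seed)


class _OracleNet:
    """Test double that predicts saturated logits of a fixed mask stack."""

    spec = NetworkSpec()

    def __init__(self, masks):
        self.masks = np.stack(masks).astype(np.float32)[..., None]
        self.i = 0

    def __call__(self, x):
        out = self.masks[self.i:self.i + len(x.data)]
        self.i += len(x.data)
        return Tensor(out * 0.98 + 0.01)


class TestTrain:
    def test_zero_epochs_leaves_weights_untouched(self):
        cfg = ns.TrainConfig(epochs=0, val_fraction=0.0, seed=1)
        net = ns.build_segmenter(seed=1)
        before = [p.data.copy() for p in net.parameters()]
        net, log = train(net, tiny_split(), cfg)
        assert log.rows == []
        for p, b in zip(net.parameters(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_log_rows_match_epochs_and_loss_decreases(self):
        cfg = ns.TrainConfig(epochs=3, val_fraction=0.0, seed=1,
                             batch_size=4)
        net, log = train(ns.build_segmenter(seed=1), tiny_split(), cfg)
        assert len(log.rows) == 3
        assert log.train_losses[-1] < log.train_losses[0]
        assert all(np.isfinite(v) for v in log.train_losses)

    def test_same_seed_same_losses(self):
        cfg = ns.TrainConfig(epochs=2, val_fraction=0.0, seed=7,
                             batch_size=4)
        _, log1 = train(ns.build_segmenter(seed=7), tiny_split(), cfg)
        _, log2 = train(ns.build_segmenter(seed=7), tiny_split(), cfg)
        assert log1.train_losses == log2.train_losses

    def test_validation_carveout_tracked(self):
        cfg = ns.TrainConfig(epochs=2, val_fraction=0.25, seed=3,
                             batch_size=4)
        _, log = train(ns.build_segmenter(seed=3), tiny_split(8, seed=3),
                       cfg)
        assert all(v is not None and np.isfinite(v)
                   for v in log.val_losses)
        assert log.best_epoch is not None and log.best_weights is not None

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(ns.build_segmenter(), DatasetSplit([], [], 0.0, 0),
                  ns.TrainConfig(epochs=1))


class TestEvaluate:
    def test_ground_truth_as_prediction_scores_one(self, small_dataset):
        net = _OracleNet([s.mask for s in small_dataset])
        rep = evaluate(net, small_dataset)
        for k in ("dsc", "iou", "sensitivity", "precision"):
            assert rep["macro"][k] == 1.0

    def test_all_background_prediction_scores_zero_dsc(self, small_dataset):
        net = _OracleNet([np.zeros_like(s.mask) for s in small_dataset])
        rep = evaluate(net, small_dataset)
        assert rep["macro"]["dsc"] == 0.0

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError):
            evaluate(ns.build_segmenter(), [])


class TestModelInterface:
    def test_from_phantom_pipeline_counts(self):
        model = ns.SegmentationModel.from_phantom(n=10, seed=1)
        assert len(model.train_samples) == 16   # 10 -> 20 -> 16/4
        assert len(model.test_samples) == 4

    def test_fit_returns_results_with_summary(self):
        model = ns.SegmentationModel.from_phantom(
            n=4, seed=5, train_config=ns.TrainConfig(
                epochs=1, batch_size=8, val_fraction=0.0, seed=5))
        fit = model.fit()
        assert fit.n_params == 891_713
        text = fit.summary()
        assert "891,713" in text
        assert "test dsc" in text
        rep = fit.evaluate()
        assert 0.0 <= rep["macro"]["dsc"] <= 1.0

    def test_predict_shapes(self):
        model = ns.SegmentationModel.from_phantom(
            n=4, seed=5, train_config=ns.TrainConfig(
                epochs=0, val_fraction=0.0))
        fit = model.fit()
        prob = fit.predict(np.zeros((64, 64), np.float32))
        assert prob.shape == (64, 64)
        mask = fit.predict_mask(np.zeros((64, 64), np.float32))
        assert set(np.unique(mask)) <= {0, 1}


class TestConfig:
    def test_defaults_follow_recipe(self):
        cfg = ns.TrainConfig()
        assert (cfg.batch_size, cfg.epochs) == (32, 200)
        assert (cfg.beta1, cfg.beta2) == (0.99, 0.999)
        assert cfg.learning_rate == 1e-3 and cfg.weight_decay == 5e-4

    def test_yaml_roundtrip(self, tmp_path):
        cfg = {"train": ns.TrainConfig(epochs=5).to_dict()}
        p = ns.save_config(cfg, tmp_path / "run.yaml")
        assert ns.load_config(p) == cfg
        p = ns.save_config(cfg, tmp_path / "run.json")
        assert ns.load_config(p) == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError):
            ns.TrainConfig.from_dict({"momentum": 0.9})
        with pytest.raises(ValueError):
            ns.TrainConfig(epochs=-1)


class TestCli:
    def test_generate_is_byte_reproducible(self, tmp_path):
        runner = CliRunner()
        for d in ("a", "b"):
            res = runner.invoke(cli_main, [
                "generate", "--n", "4", "--seed", "1",
                "--out-dir", str(tmp_path / d)])
            assert res.exit_code == 0, res.output
        for rel in sorted(p.relative_to(tmp_path / "a")
                          for p in (tmp_path / "a").rglob("*") if p.is_file()):
            assert (tmp_path / "a" / rel).read_bytes() == \
                (tmp_path / "b" / rel).read_bytes()

    def test_inspect_expect_params(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["inspect", "--expect-params",
                                       "891713"])
        assert res.exit_code == 0, res.output
        assert "891,713" in res.output
        res = runner.invoke(cli_main, ["inspect", "--expect-params", "1"])
        assert res.exit_code == 1

    def test_costs_calculator(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["costs", "--hi", "16", "--wi", "16",
                                       "--di", "64", "--dj", "64", "--f",
                                       "3"])
        assert res.exit_code == 0
        assert "9,437,184" in res.output
        assert "1,196,032" in res.output

    def test_unknown_subcommand_exits_2(self):
        res = CliRunner().invoke(cli_main, ["segmentate"])
        assert res.exit_code == 2

    def test_train_writes_outputs(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "train", "--n", "4", "--seed", "3", "--epochs", "1",
            "--out-dir", str(tmp_path / "run")])
        assert res.exit_code == 0, res.output
        for name in ("checkpoint.npz", "runlog.csv", "config.yaml",
                     "metrics.json"):
            assert (tmp_path / "run" / name).exists()
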