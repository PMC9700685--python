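"""Model/Results interface tying data, network, training and evaluation.

:class:`SegmentationModel` is constructed from data (lists of
:class:`~noduleseg.phantom.PatchSample`) plus a network spec and training
config; :meth:`SegmentationModel.fit` runs minibatch Adam on pixelwise
binary cross-entropy and returns a :class:`SegmentationFit` carrying the
trained network, the per-epoch run log and evaluation helpers, with a
``summary()`` table.  The functional core (:func:`train`,
:func:`evaluate`) is exposed for script use.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .config import TrainConfig
from .metrics import batch_report
from .networks import (NetworkSpec, PyramidAttentionNet, binarize,
                       build_segmenter, count_trainable_parameters, forward)
from .nn import Adam, Tensor
from .nn.ops import bce_with_logits

__all__ = ["RunLog", "train", "evaluate", "SegmentationModel",
           "SegmentationFit", "samples_to_arrays"]


def samples_to_arrays(samples):
    """Stack PatchSamples into (N,64,64,1) float32 image/mask arrays."""
    x = np.stack([s.image for s in samples])[..., None].astype(np.float32)
    y = np.stack([s.mask for s in samples])[..., None].astype(np.float32)
    return x, y


@dataclass
class RunLog:
    """Per-epoch training record plus run metadata."""

    rows: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    best_epoch: int | None = None
    best_weights: list | None = None

    def append(self, epoch, train_loss, val_loss, wall_time):
        if not np.isfinite(train_loss):
            raise RuntimeError(
                f"training diverged: loss={train_loss} at epoch {epoch}")
        self.rows.append({"epoch": epoch, "train_loss": float(train_loss),
                          "val_loss": val_loss, "wall_time": wall_time})

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.rows,
                            columns=["epoch", "train_loss", "val_loss",
                                     "wall_time"])

    @property
    def train_losses(self):
        return [r["train_loss"] for r in self.rows]

    @property
    def val_losses(self):
        return [r["val_loss"] for r in self.rows]


def _epoch_loss(net, x, y, batch_size):
    """Mean BCE over a dataset in inference mode (no gradient tape)."""
    total, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        loss = bce_with_logits(net.logits(Tensor(xb)), yb)
        total += float(loss.data) * len(xb)
        n += len(xb)
    return total / n


def train(net, split, cfg: TrainConfig | None = None):
    """Minibatch-Adam training of ``net`` on ``split.train``.

    A validation subset of ``cfg.val_fraction`` of the training samples
    (seeded carve-out) is tracked each epoch; the best-validation weights
    are retained on the returned RunLog's ``best_weights``.  Returns
    ``(net, RunLog)``; fully reproducible from ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    train_samples = list(split.train)
    if not train_samples:
        raise ValueError("training set is empty")

    rng = np.random.default_rng(cfg.seed)
    n_val = round(cfg.val_fraction * len(train_samples))
    order = rng.permutation(len(train_samples))
    val_samples = [train_samples[i] for i in order[:n_val]]
    fit_samples = [train_samples[i] for i in order[n_val:]]
    if not fit_samples:
        raise ValueError("val_fraction leaves no training samples")

    x, y = samples_to_arrays(fit_samples)
    xv, yv = (samples_to_arrays(val_samples) if val_samples else (None, None))

    opt = Adam(net.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1,
               beta2=cfg.beta2, weight_decay=cfg.weight_decay,
               decoupled=cfg.decoupled_weight_decay)
    log = RunLog(config=cfg.to_dict())
    best_val = np.inf

    t0 = time.time()
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(x))
        running, seen = 0.0, 0
        for i in range(0, len(x), cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            opt.zero_grad()
            loss = bce_with_logits(net.logits(Tensor(x[idx])), y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: loss={float(loss.data)} "
                    f"at epoch {epoch}")
            loss.backward()
            opt.step()
            running += float(loss.data) * len(idx)
            seen += len(idx)
        val_loss = (_epoch_loss(net, xv, yv, cfg.batch_size)
                    if xv is not None else None)
        log.append(epoch, running / seen, val_loss, time.time() - t0)
        if val_loss is not None and val_loss < best_val:
            best_val = val_loss
            log.best_epoch = epoch
            log.best_weights = [p.data.copy() for p in net.parameters()]
    return net, log


def evaluate(net, samples, threshold: float = 0.5, batch_size: int = 32):
    """Forward → binarize → batch_report on a list of PatchSamples."""
    if not samples:
        raise ValueError("no samples to evaluate")
    x, _ = samples_to_arrays(samples)
    preds = []
    for i in range(0, len(x), batch_size):
        preds.append(forward(net, x[i:i + batch_size]))
    pred = binarize(np.concatenate(preds)[..., 0], threshold)
    pairs = [(s.mask, pred[i]) for i, s in enumerate(samples)]
    report = batch_report(pairs)
    report["ids"] = [s.id for s in samples]
    return report


class SegmentationModel:
    """Segmentation experiment: data + network spec + training recipe.

    Parameters
    ----------
    train_samples, test_samples : lists of PatchSample
    network_spec : NetworkSpec, default the calibrated 891,713-parameter
        configuration
    train_config : TrainConfig, default the published recipe
    """

    def __init__(self, train_samples, test_samples=None,
                 network_spec: NetworkSpec | None = None,
                 train_config: TrainConfig | None = None):
        self.train_samples = list(train_samples)
        self.test_samples = list(test_samples or [])
        self.spec = network_spec or NetworkSpec()
        self.config = train_config or TrainConfig()

    @classmethod
    def from_phantom(cls, n: int = 100, seed: int = 0,
                     train_fraction: float = 0.8, augment: bool = True,
                     **kwargs) -> "SegmentationModel":
        """Build a model on a freshly generated phantom dataset.

        Mirrors the published data pipeline: generate, horizontally flip
        (before the split, so counts double), then split.
        """
        from .phantom import flip_augment, split_dataset, synth_dataset
        samples = synth_dataset(n, seed=seed)
        if augment:
            samples = flip_augment(samples)
        split = split_dataset(samples, train_fraction, seed=seed)
        return cls(split.train, split.test, **kwargs)

    def fit(self, epochs: int | None = None, seed: int | None = None,
            init_seed: int | None = None) -> "SegmentationFit":
        cfg = self.config
        if epochs is not None or seed is not None:
            d = cfg.to_dict()
            if epochs is not None:
                d["epochs"] = epochs
            if seed is not None:
                d["seed"] = seed
            cfg = TrainConfig.from_dict(d)
        net = build_segmenter(self.spec,
                              seed=cfg.seed if init_seed is None else init_seed)
        from .phantom import DatasetSplit
        split = DatasetSplit(self.train_samples, self.test_samples, 0.0,
                             cfg.seed)
        net, log = train(net, split, cfg)
        return SegmentationFit(self, net, log, cfg)


class SegmentationFit:
    """Results of a training run: trained network, log, evaluation."""

    def __init__(self, model: SegmentationModel, network: PyramidAttentionNet,
                 log: RunLog, config: TrainConfig):
        self.model = model
        self.network = network
        self.log = log
        self.config = config

    @property
    def n_params(self) -> int:
        return count_trainable_parameters(self.network)

    def predict(self, patches) -> np.ndarray:
        return forward(self.network, patches)

    def predict_mask(self, patches, threshold: float | None = None):
        t = self.config.threshold if threshold is None else threshold
        return binarize(self.predict(patches), t)

    def evaluate(self, samples=None, threshold: float | None = None):
        samples = samples if samples is not None else self.model.test_samples
        t = self.config.threshold if threshold is None else threshold
        return evaluate(self.network, samples, threshold=t,
                        batch_size=self.config.batch_size)

    def summary(self) -> str:
        lines = [
            "Nodule segmentation fit",
            "=" * 52,
            f"trainable parameters   {self.n_params:>12,}",
            f"training samples       {len(self.model.train_samples):>12}",
            f"test samples           {len(self.model.test_samples):>12}",
            f"epochs run             {len(self.log.rows):>12}",
        ]
        if self.log.rows:
            lines.append(f"final train BCE        "
                         f"{self.log.train_losses[-1]:>12.4f}")
            if self.log.val_losses[-1] is not None:
                lines.append(f"final val BCE          "
                             f"{self.log.val_losses[-1]:>12.4f}")
        if self.model.test_samples:
            rep = self.evaluate()
            for k in ("dsc", "iou", "sensitivity", "precision"):
                lines.append(f"test {k:<18}{rep['macro'][k]:>12.4f}")
        return "\n".join(lines)
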