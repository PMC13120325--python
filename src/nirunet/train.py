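"""Training loop for the reconstruction network.

Minimizes the pixelwise mean squared error between the network output and
the paired clean target (the same :func:`nirunet.quality_metrics.mse`
definition used for evaluation) with Adam.  All randomness — weight
initialization and per-epoch shuffling — derives from ``TrainConfig.seed``,
so identical configurations produce identical loss histories.  The returned
checkpoint holds the parameters of the epoch with the best validation loss.
"""

from __future__ import annotations

import dataclasses
import json
import time
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_utils, quality_metrics
from .errors import ConfigurationError, TrainingDivergenceError
from .nn import Adam
from .phantom_sim import DatasetManifest
from .unet import UNet, UNetConfig, build_unet, get_config

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 25
    learning_rate: float = 0.001
    optimizer: str = "adam"
    loss: str = "mse"
    epochs: int = 100
    seed: int = 0
    checkpoint_policy: str = "best_val"

    def __post_init__(self):
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.optimizer != "adam" or self.loss != "mse":
            raise ConfigurationError("only adam/mse are supported")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class Checkpoint:
    """Best-validation-loss snapshot of a training run."""

    state: dict[str, np.ndarray]
    config: UNetConfig
    train_config: TrainConfig
    history: dict[str, list[float]]
    seed: int
    best_epoch: int

    def restore(self) -> UNet:
        model = build_unet(self.config, seed=self.seed)
        model.load_state_dict(self.state)
        return model

    def save(self, path) -> None:
        """Write a ``.npz`` parameter archive plus a ``.json`` sidecar."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), **self.state)
        sidecar = {
            "config": self.config.to_dict(),
            "train_config": self.train_config.to_dict(),
            "history": self.history,
            "seed": self.seed,
            "best_epoch": self.best_epoch,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "Checkpoint":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as arch:
            state = {k: arch[k].copy() for k in arch.files}
        return cls(state=state,
                   config=UNetConfig.from_dict(sidecar["config"]),
                   train_config=TrainConfig.from_dict(sidecar["train_config"]),
                   history=sidecar["history"], seed=sidecar["seed"],
                   best_epoch=sidecar["best_epoch"])


def load_split(manifest: DatasetManifest, split: str
               ) -> tuple[np.ndarray, np.ndarray]:
    """Load one split as (captured, target) float32 stacks, (N, H, W)."""
    pairs = manifest.paths(split)
    targets = np.stack([io_utils.read_image(t) for t, _ in pairs])
    captured = np.stack([io_utils.read_image(c) for _, c in pairs])
    return captured.astype(np.float32), targets.astype(np.float32)


def _batches(n: int, batch_size: int, rng: np.random.Generator | None):
    order = np.arange(n) if rng is None else rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def evaluate_loss(model: UNet, x: np.ndarray, y: np.ndarray,
                  batch_size: int = 25) -> float:
    """Mean MSE of the model over a set, in evaluation mode."""
    total, count = 0.0, 0
    for idx in _batches(len(x), batch_size, None):
        pred = model.forward(x[idx], train=False)
        total += quality_metrics.mse(y[idx], pred) * len(idx)
        count += len(idx)
    return total / count


def train_arrays(model: UNet, x_train: np.ndarray, y_train: np.ndarray,
                 x_val: np.ndarray, y_val: np.ndarray,
                 tcfg: TrainConfig,
                 time_budget_s: float | None = None) -> Checkpoint:
    """Core loop over in-memory arrays; see :func:`train`.

    ``time_budget_s`` optionally bounds wall-clock time: after each epoch
    the loop stops early if another epoch would not fit in the budget.
    Useful for fixed-runtime benchmark harnesses; the history records how
    many epochs actually ran.
    """
    if len(x_train) == 0 or len(x_val) == 0:
        raise ConfigurationError("train and validation splits must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence(tcfg.seed).spawn(1)[0])
    opt = Adam(lr=tcfg.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val, best_epoch, best_state = np.inf, -1, None
    t_start = time.perf_counter()

    for epoch in range(tcfg.epochs):
        t0 = time.perf_counter()
        epoch_loss, n_seen = 0.0, 0
        for idx in _batches(len(x_train), tcfg.batch_size, rng):
            xb, yb = x_train[idx], y_train[idx]
            pred = model.forward(xb, train=True)
            loss = quality_metrics.mse(yb, pred)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(epoch)
            grad = (2.0 / pred.size) * (pred - yb)
            model.backward(grad.astype(np.float32))
            opt.step(model.parameters(), model.gradients())
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        train_loss = epoch_loss / n_seen
        val_loss = evaluate_loss(model, x_val, y_val, tcfg.batch_size)
        if not np.isfinite(val_loss):
            raise TrainingDivergenceError(epoch)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        epoch_time = time.perf_counter() - t0
        log.info("epoch %d: train %.3g  val %.3g  (%.1fs)", epoch,
                 train_loss, val_loss, epoch_time)
        if time_budget_s is not None:
            elapsed = time.perf_counter() - t_start
            if elapsed + epoch_time > time_budget_s:
                log.info("stopping after epoch %d: next epoch would exceed "
                         "the %.0fs budget", epoch, time_budget_s)
                break

    model.load_state_dict(best_state)
    return Checkpoint(state=best_state, config=model.config,
                      train_config=tcfg, history=history, seed=tcfg.seed,
                      best_epoch=best_epoch)


def train(config: UNetConfig | str, tcfg: TrainConfig,
          manifest: DatasetManifest) -> Checkpoint:
    """Train a variant on a simulated dataset manifest.

    Captured images are the inputs, paired targets the outputs; the
    checkpoint snapshots the epoch with the lowest validation MSE.
    """
    if isinstance(config, str):
        config = get_config(config)
    x_train, y_train = load_split(manifest, "train")
    x_val, y_val = load_split(manifest, "val")
    model = build_unet(config, seed=tcfg.seed)
    return train_arrays(model, x_train, y_train, x_val, y_val, tcfg)


def reconstruct_batch(model: UNet, captured: np.ndarray,
                      batch_size: int = 16) -> np.ndarray:
    """Evaluation-mode reconstruction of a stack of captured images."""
    captured = np.asarray(captured, dtype=np.float32)
    out = [model.forward(captured[i:i + batch_size], train=False)
           for i in range(0, len(captured), batch_size)]
    return np.concatenate(out, axis=0)
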