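"""Training procedures: single-task and alternate-batch multi-task.

Weights are initialized with the Glorot uniform scheme (each weight tensor
uniform on +/- sqrt(6 / (fan_in + fan_out)), biases zero) and optimized
with Adam (lr 1e-4, beta 0.9/0.999, eps 1e-8 by default, batch size 128).
Early stopping monitors the validation loss and the returned parameters are
the snapshot from the best validation epoch.

The multi-task loop interleaves one batch from each task — classification
first — updating the shared layers plus only the active task's head; the
inactive head is untouched bit-for-bit because gradients exist only for
parameters the backward pass reached and Adam only steps parameters that
received a gradient.  An epoch ends when the larger stream is exhausted;
the smaller stream recycles (reshuffled).  Each task keeps its own best
validation epoch and parameter snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import CLASSIFICATION, REGRESSION, PLIModel
from .objectives import LabeledBatch, bce_loss, mse_l2_loss

__all__ = [
    "TrainConfig",
    "TrainLog",
    "Adam",
    "init_parameters",
    "train_single_task",
    "train_multi_task",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 128
    optimizer: str = "adam"
    init: str = "glorot_uniform"
    max_epochs: int = 30
    patience: int = 3
    seed: int = 0
    l2_lambda: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.init != "glorot_uniform":
            raise ValueError("only glorot_uniform initialization is supported")
        if self.patience < 0 or self.max_epochs < 1:
            raise ValueError("patience must be >= 0 and max_epochs >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainLog:
    """Per-epoch losses per task plus the selected (best-validation) epoch."""

    rows: list = field(default_factory=list)
    selected_epoch: dict = field(default_factory=dict)

    def record(self, epoch: int, task: str, train_loss: float, val_loss: float) -> None:
        self.rows.append({"epoch": epoch, "task": task,
                          "train_loss": float(train_loss), "val_loss": float(val_loss)})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["epoch", "task", "train_loss", "val_loss"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def val_losses(self, task: str) -> list[float]:
        return [r["val_loss"] for r in self.rows if r["task"] == task]


def init_parameters(model: PLIModel, config: TrainConfig | int) -> dict:
    """Glorot-uniform weights, zero biases, reproducible under the seed."""
    seed = config.seed if isinstance(config, TrainConfig) else int(config)
    rng = np.random.default_rng(seed)
    params: dict = {}
    for name, (shape, fan_in, fan_out) in sorted(model.param_specs().items()):
        if fan_in == 0 and fan_out == 0:  # bias
            params[name] = np.zeros(shape)
        else:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            params[name] = rng.uniform(-limit, limit, size=shape)
    return params


class Adam:
    """Adam with per-parameter step counters: parameters that receive no
    gradient in a step are left untouched (moments included), which is what
    makes branch isolation in alternate-batch training exact."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t: dict = {}

    def update(self, params: dict, grads: dict) -> None:
        for key, g in grads.items():
            m = self.m.get(key)
            if m is None:
                m = np.zeros_like(params[key])
                self.m[key] = m
                self.v[key] = np.zeros_like(params[key])
                self.t[key] = 0
            v = self.v[key]
            self.t[key] += 1
            t = self.t[key]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1 ** t)
            vhat = v / (1 - self.beta2 ** t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _task_step(model: PLIModel, params: dict, opt: Adam, batch: LabeledBatch,
               lam: float, rng: np.random.Generator) -> float:
    """One gradient step on one batch; returns the batch training loss."""
    n = len(batch)
    preds, cache = model.forward(batch.Xp, batch.Xl, params, batch.task,
                                 training=True, rng=rng, with_cache=True)
    if batch.task == CLASSIFICATION:
        loss = bce_loss(preds, batch.y)
        graw = (preds - batch.y) / n  # combined sigmoid + mean-BCE gradient
    else:
        loss = mse_l2_loss(preds, batch.y,
                           weights=model.regression_weight_sqnorm(params), lam=lam)
        graw = 2.0 * (preds - batch.y) / n
    grads = model.backward(graw, cache, params)
    if batch.task == REGRESSION and lam > 0:
        key = f"head/{REGRESSION}/W"
        grads[key] = grads[key] + 2.0 * lam * params[key]
    opt.update(params, grads)
    return loss


def _val_loss(model: PLIModel, params: dict, val: LabeledBatch) -> float:
    """Validation loss: plain BCE / MSE (no regularizer, dropout off)."""
    preds = model.predict(val.Xp, val.Xl, params, val.task)
    if val.task == CLASSIFICATION:
        return bce_loss(preds, val.y)
    return mse_l2_loss(preds, val.y)


def train_single_task(
    data: LabeledBatch,
    val: LabeledBatch,
    model: PLIModel,
    config: TrainConfig,
    params: dict | None = None,
) -> tuple[dict, TrainLog]:
    """Adam on shuffled batches with early stopping on the validation loss.

    Stops once the validation loss has failed to improve for more than
    ``patience`` consecutive epochs; returns the parameters of the best
    epoch and the full log.
    """
    if len(data) == 0:
        raise ValueError("training data is empty")
    if data.task != val.task:
        raise ValueError("training and validation tasks differ")
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = init_parameters(model, config)
    else:
        params = PLIModel.copy_params(params)
    opt = Adam(config.learning_rate, config.adam_beta1, config.adam_beta2, config.adam_eps)
    log = TrainLog()
    best = np.inf
    best_params = PLIModel.copy_params(params)
    bad = 0
    n = len(data)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = data.subset(order[start : start + config.batch_size])
            losses.append(_task_step(model, params, opt, batch, config.l2_lambda, rng))
        vloss = _val_loss(model, params, val)
        log.record(epoch, data.task, np.mean(losses), vloss)
        if vloss < best:
            best = vloss
            best_params = PLIModel.copy_params(params)
            log.selected_epoch[data.task] = epoch
            bad = 0
        else:
            bad += 1
            if bad > config.patience:
                break
    return best_params, log


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    return [order[s : s + batch_size] for s in range(0, n, batch_size)]


def train_multi_task(
    class_data: LabeledBatch,
    regr_data: LabeledBatch,
    val_class: LabeledBatch,
    val_regr: LabeledBatch,
    model: PLIModel,
    config: TrainConfig,
    params: dict | None = None,
) -> tuple[dict, TrainLog]:
    """Alternate-batch multi-task training.

    Batches alternate strictly classification, regression, ... within an
    epoch; each step updates the shared layers plus the active task's head
    only.  Per-task validation losses are tracked independently and the
    returned dict maps each task to its best-epoch parameter snapshot
    (``result["classification"]``, ``result["regression"]``); the log
    records both curves.  Training stops when both tasks have gone more
    than ``patience`` epochs without improvement, or at ``max_epochs``.
    """
    if len(class_data) == 0 or len(regr_data) == 0:
        raise ValueError("both task streams must be non-empty")
    if val_class is None or val_regr is None or len(val_class) == 0 or len(val_regr) == 0:
        raise ValueError("each task needs a non-empty validation set")
    if class_data.task != CLASSIFICATION or regr_data.task != REGRESSION:
        raise ValueError("class_data must be classification and regr_data regression")
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = init_parameters(model, config)
    else:
        params = PLIModel.copy_params(params)
    opt = Adam(config.learning_rate, config.adam_beta1, config.adam_beta2, config.adam_eps)
    log = TrainLog()
    best = {CLASSIFICATION: np.inf, REGRESSION: np.inf}
    best_params = {CLASSIFICATION: PLIModel.copy_params(params),
                   REGRESSION: PLIModel.copy_params(params)}
    bad = {CLASSIFICATION: 0, REGRESSION: 0}
    vals = {CLASSIFICATION: val_class, REGRESSION: val_regr}
    for epoch in range(1, config.max_epochs + 1):
        bc = _batches(len(class_data), config.batch_size, rng)
        br = _batches(len(regr_data), config.batch_size, rng)
        n_steps = max(len(bc), len(br))
        # the smaller stream recycles, reshuffled, until the larger runs out
        while len(bc) < n_steps:
            bc += _batches(len(class_data), config.batch_size, rng)
        while len(br) < n_steps:
            br += _batches(len(regr_data), config.batch_size, rng)
        losses = {CLASSIFICATION: [], REGRESSION: []}
        for step in range(n_steps):  # classification first in every pair
            batch = class_data.subset(bc[step])
            losses[CLASSIFICATION].append(
                _task_step(model, params, opt, batch, config.l2_lambda, rng))
            batch = regr_data.subset(br[step])
            losses[REGRESSION].append(
                _task_step(model, params, opt, batch, config.l2_lambda, rng))
        for task in (CLASSIFICATION, REGRESSION):
            vloss = _val_loss(model, params, vals[task])
            log.record(epoch, task, np.mean(losses[task]), vloss)
            if vloss < best[task]:
                best[task] = vloss
                best_params[task] = PLIModel.copy_params(params)
                log.selected_epoch[task] = epoch
                bad[task] = 0
            else:
                bad[task] += 1
        if all(bad[t] > config.patience for t in bad):
            break
    return best_params, log
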