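"""Multi-task regression training and the two transfer-learning schemes.

RMSprop with L2 weight decay, MSE over observed (non-missing) labels,
and a plateau learning-rate schedule: after 3 consecutive epochs without
a strict improvement of the running-best training loss the rate is
multiplied by 1/3 and the non-improvement counter resets.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .networks import ArchitectureSpec, IModuleSpec, build_i_head
from .nn import Dense, Parameter, SequentialNet

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "RMSprop",
    "PlateauSchedule",
    "schedule_lrs",
    "lr_schedule_step",
    "masked_mse",
    "standardize_labels",
    "train",
    "freeze_and_extend",
    "fine_tune",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 10
    lr: float = 1e-2
    decay_factor: float = 1.0 / 3.0
    patience: int = 3
    l2: float = 1e-6
    seed: int = 0
    rmsprop_alpha: float = 0.99
    rmsprop_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")
        if not 0.0 < self.decay_factor < 1.0:
            raise ValueError("decay factor must be in (0, 1)")


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.loss)

    def __post_init__(self) -> None:
        if len(self.loss) != len(self.lr):
            raise ValueError("loss and lr traces must have equal length")


class RMSprop:
    """RMSprop with additive L2 weight decay; skips frozen parameters."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float,
        alpha: float = 0.99,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.weight_decay = weight_decay
        self._sq = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, sq in zip(self.params, self._sq):
            if not p.trainable:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            sq *= self.alpha
            sq += (1.0 - self.alpha) * g * g
            p.value -= self.lr * g / (np.sqrt(sq) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class PlateauSchedule:
    """Running-best plateau detector driving the LR decay."""

    def __init__(self, lr: float, factor: float = 1.0 / 3.0, patience: int = 3):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.best = np.inf
        self.bad = 0

    def step(self, loss: float) -> float:
        """Record one finished epoch's loss; return the LR for the next epoch."""
        if loss < self.best:
            self.best = loss
            self.bad = 0
        else:
            self.bad += 1
            if self.bad >= self.patience:
                self.lr *= self.factor
                self.bad = 0
        return self.lr


def schedule_lrs(
    loss_trace, lr0: float = 1e-2, factor: float = 1.0 / 3.0, patience: int = 3
) -> list[float]:
    """Learning rate in effect during each epoch of ``loss_trace``."""
    sched = PlateauSchedule(lr0, factor, patience)
    lrs = []
    for loss in loss_trace:
        lrs.append(sched.lr)
        sched.step(loss)
    return lrs


def lr_schedule_step(loss_trace, current_lr: float, factor: float = 1.0 / 3.0,
                     patience: int = 3) -> float:
    """Next-epoch LR after replaying a loss trace from ``current_lr``'s start.

    Functional view of :class:`PlateauSchedule`: decays once per run of
    ``patience`` consecutive epochs that fail to strictly improve the
    running best, with the counter resetting after each decay event.
    """
    if len(loss_trace) == 0:
        raise ValueError("loss trace is empty")
    sched = PlateauSchedule(current_lr, factor, patience)
    for loss in loss_trace:
        sched.step(loss)
    return sched.lr


def masked_mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """MSE over observed entries; NaN targets are excluded from loss and grad."""
    observed = ~np.isnan(target)
    n = int(observed.sum())
    if n == 0:
        return 0.0, np.zeros_like(pred)
    diff = np.where(observed, pred - np.nan_to_num(target), 0.0)
    loss = float((diff**2).sum() / n)
    return loss, 2.0 * diff / n


def standardize_labels(
    y: np.ndarray, fit_rows: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-task z-scoring (NaN-aware), fitted on ``fit_rows``.

    Returns ``(standardized, mean, std)``; zero-variance tasks keep
    scale 1 to avoid blowing up.
    """
    fit = y if fit_rows is None else y[fit_rows]
    mean = np.nanmean(fit, axis=0)
    std = np.nanstd(fit, axis=0)
    std = np.where(std > 0, std, 1.0)
    return (y - mean) / std, mean, std


def train(
    model: SequentialNet,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    task_names: list[str] | None = None,
) -> tuple[SequentialNet, TrainingHistory]:
    """Train ``model`` in place for ``cfg.epochs`` epochs.

    ``y`` may contain NaN for missing (sample, task) labels; those cells
    are excluded from the loss through a mask. Raises if any task has no
    observed label at all.
    """
    if x.shape[0] != y.shape[0]:
        raise ValueError("input and label sample counts differ")
    all_missing = np.isnan(y).all(axis=0)
    if all_missing.any():
        idx = int(np.flatnonzero(all_missing)[0])
        name = task_names[idx] if task_names else f"task#{idx}"
        raise ValueError(f"task {name} has no observed labels")

    opt = RMSprop(
        model.params(),
        lr=cfg.lr,
        alpha=cfg.rmsprop_alpha,
        eps=cfg.rmsprop_eps,
        weight_decay=cfg.l2,
    )
    sched = PlateauSchedule(cfg.lr, cfg.decay_factor, cfg.patience)
    rng = np.random.default_rng(cfg.seed)
    history = TrainingHistory()
    n = x.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_obs = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            pred = model.forward(xb)
            loss, grad = masked_mse(pred, yb)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            batch_obs = int((~np.isnan(yb)).sum())
            epoch_loss += loss * batch_obs
            n_obs += batch_obs
        epoch_loss /= max(n_obs, 1)
        history.loss.append(epoch_loss)
        history.lr.append(opt.lr)
        opt.lr = sched.step(epoch_loss)
    return model, history


def freeze_and_extend(model: SequentialNet, head: IModuleSpec, seed: int = 0) -> SequentialNet:
    """Frozen-feature-extractor transfer learning.

    The pretrained body is frozen (gradients identically zero from here
    on), the task-specific output layer is dropped, and a fresh head is
    attached on the latent representation. Only the head is trainable.
    """
    if model.latent_dim != head.d_in:
        raise ValueError(
            f"head expects d_in={head.d_in} but model latent is {model.latent_dim}"
        )
    body = copy.deepcopy(model.layers[: model.latent_index])
    for layer in body:
        for p in layer.params():
            p.trainable = False
            p.zero_grad()
    rng = np.random.default_rng(seed)
    new_head = build_i_head(head, rng)
    return SequentialNet(
        body + new_head.layers,
        latent_index=len(body),
        latent_dim=model.latent_dim,
        input_kind=model.input_kind,
    )


def fine_tune(
    model: SequentialNet,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    task_names: list[str] | None = None,
) -> tuple[SequentialNet, TrainingHistory]:
    """Warm-start transfer learning: pretrained weights as initialisation.

    A deep copy of ``model`` gets a fresh output layer sized to the new
    task count; every weight is trainable and training runs for
    ``cfg.epochs`` epochs (0 leaves the copy untouched after re-init).
    """
    tuned = copy.deepcopy(model)
    for p in tuned.params():
        p.trainable = True
    last = tuned.layers[-1]
    if not isinstance(last, Dense):
        raise ValueError("expected the final layer to be a dense output map")
    if model.input_kind == "tensor" and x.ndim != 3:
        raise ValueError("input-space mismatch: pretrained model expects a 3-D tensor")
    rng = np.random.default_rng(cfg.seed)
    tuned.layers[-1] = Dense(last.n_in, y.shape[1], rng, name="head.out")
    if cfg.epochs == 0:
        return tuned, TrainingHistory()
    return train(tuned, x, y, cfg, task_names=task_names)


def save_checkpoint(
    model: SequentialNet,
    path: str | Path,
    spec: ArchitectureSpec | None = None,
    cfg: TrainConfig | None = None,
    seed: int | None = None,
) -> None:
    """Write a flat parameter table (.npz) plus a JSON manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(str(path) + ".npz", **model.state_arrays())
    manifest = {
        "parameters": sorted(model.state_arrays()),
        "n_trainable": int(sum(p.size for p in model.params() if p.trainable)),
        "spec": asdict(spec) if spec is not None else None,
        "train_config": asdict(cfg) if cfg is not None else None,
        "seed": seed,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_checkpoint(model: SequentialNet, path: str | Path) -> SequentialNet:
    state = np.load(str(path) + ".npz")
    model.load_state_arrays({k: state[k] for k in state.files})
    return model
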