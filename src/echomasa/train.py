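"""Training loop: MAE loss on the key-frame mask map, AdamW, step decay.

The loss is the mean absolute error between the model's key-frame mask map
(sigmoid probabilities or the linear head's output, per ModelConfig.head)
and the binary left-ventricle mask — supervision exists only on the key
frame.  Training is fully seeded: given (seed, config, data order) two runs
produce identical loss curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import apply_augment, draw_augment_params
from .model import EchoSegModel
from .nn import AdamW, StepLR, Tensor

__all__ = ["TrainConfig", "TrainResult", "train", "mae_loss", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.99)  # short v-memory adapts through the L1 takeoff
    weight_decay: float = 0.01
    batch_size: int = 8
    epochs: int = 50
    milestones: tuple[int, ...] = (30, 45)
    lr_decay: float = 0.1
    augment: bool = True
    seed: int = 0
    max_steps: int | None = None  # optional hard cap across epochs

    def __post_init__(self):
        if self.lr <= 0 and self.lr != 0.0:
            raise ValueError("lr must be non-negative")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


@dataclass
class TrainResult:
    loss_curve: list[float] = field(default_factory=list)
    epochs_run: int = 0
    steps_run: int = 0


def mae_loss(proba_map: Tensor, masks: np.ndarray) -> Tensor:
    """Mean absolute error between the mask map and the binary mask."""
    target = Tensor(masks.astype(np.float32)[:, None])
    return (proba_map - target).abs().mean()


def train(model: EchoSegModel, items, config: TrainConfig | None = None,
          checkpoint_path=None, stop_fn=None) -> TrainResult:
    """Train on (clip_id, frame_type, clip, mask) items.

    ``stop_fn``, if given, is called after each epoch with the model and may
    return True to stop early (e.g. once a fit target is reached).
    """
    config = config or TrainConfig()
    items = list(items)
    if not items:
        raise ValueError("train: empty dataset")
    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.parameters(), lr=config.lr, betas=config.betas,
                weight_decay=config.weight_decay)
    sched = StepLR(opt, milestones=config.milestones, gamma=config.lr_decay)
    result = TrainResult()
    for epoch in range(config.epochs):
        order = rng.permutation(len(items))
        for start in range(0, len(items), config.batch_size):
            batch = [items[i] for i in order[start : start + config.batch_size]]
            clips, masks = [], []
            for _, _, clip, mask in batch:
                if config.augment:
                    clip, mask = apply_augment(clip, mask, draw_augment_params(rng))
                clips.append(clip)
                masks.append(mask)
            out = model(Tensor(np.stack(clips)))
            loss = mae_loss(model.proba_map(out), np.stack(masks))
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss ({value}) at epoch {epoch}, step {result.steps_run}; "
                    "check the learning rate and input scaling"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            result.loss_curve.append(value)
            result.steps_run += 1
            if config.max_steps is not None and result.steps_run >= config.max_steps:
                result.epochs_run = epoch + 1
                if checkpoint_path is not None:
                    save_checkpoint(model, checkpoint_path)
                return result
        sched.step_epoch()
        result.epochs_run = epoch + 1
        if checkpoint_path is not None:
            save_checkpoint(model, checkpoint_path)
        if stop_fn is not None and stop_fn(model):
            break
    return result


def save_checkpoint(model: EchoSegModel, path) -> None:
    np.savez(path, **model.state_dict())


def load_checkpoint(model: EchoSegModel, path) -> None:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
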