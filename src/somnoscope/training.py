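"""SGD training loop for the symptom classifier.

Plain momentum SGD minimizing the weighted multilabel sigmoid
cross-entropy. The L2 term of the loss is applied as its exact gradient
(2*lambda*w) to the regularized parameters, so optimizer weight_decay
stays 0 by default. All randomness (shuffling, per-epoch frame sampling)
derives from (seed, epoch), which makes runs resumable and bit-repeatable
on CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable

import numpy as np

from .loss import LossConfig, multilabel_loss, multilabel_loss_grad
from .model import TSMNet, load_checkpoint, _sigmoid

__all__ = ["TrainConfig", "train"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the SGD recipe of the
    reference training protocol: lr 2.5e-3, 120 epochs)."""

    learning_rate: float = 2.5e-3
    epochs: int = 120
    momentum: float = 0.9
    weight_decay: float = 0.0
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def train(
    model: TSMNet,
    dataset: "tuple[np.ndarray, np.ndarray] | Callable[[np.random.Generator], tuple[np.ndarray, np.ndarray]]",
    cfg: TrainConfig,
    loss_cfg: LossConfig | None = None,
    checkpoint_path: str | Path | None = None,
    resume_from: str | Path | None = None,
    extra_meta: dict | None = None,
) -> tuple[TSMNet, list[dict]]:
    """Fit the model; returns (model, per-epoch log).

    dataset is either ``(X, Y)`` with X shaped (N, T, C, H, W) and Y a 0/1
    matrix (N, C), or a callable ``provider(rng) -> (X, Y)`` invoked once
    per epoch (used for random-in-segment frame resampling). The log
    records epoch, mean loss and training multilabel accuracy. A NaN or
    infinite loss aborts with a diagnostic rather than training onward.
    """
    loss_cfg = loss_cfg or LossConfig()
    log: list[dict] = []
    start_epoch = 0
    velocity = {name: np.zeros_like(p.value) for name, p in model.parameters()}

    if resume_from is not None:
        prev, meta = load_checkpoint(resume_from)
        model.load_state_dict(prev.state_dict())
        start_epoch = meta["epoch"]
        log = meta.get("log", [])
        import io as _io
        import zipfile as _zf

        with _zf.ZipFile(resume_from) as zf:
            if "velocity.npz" in zf.namelist():
                with np.load(_io.BytesIO(zf.read("velocity.npz"))) as data:
                    for k in data.files:
                        velocity[k] = data[k]

    provider = dataset if callable(dataset) else None

    for epoch in range(start_epoch, cfg.epochs):
        rng = np.random.default_rng([cfg.seed, epoch])
        if provider is not None:
            x_all, y_all = provider(rng)
        else:
            x_all, y_all = dataset
        n = x_all.shape[0]
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            model.zero_grad()
            logits = model.forward(xb, train=True)
            reg_params = [p.value for _, p in model.parameters() if p.regularized]
            batch_loss = multilabel_loss(logits, yb, loss_cfg, reg_params)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}: "
                    f"loss={batch_loss}, |logits|_max={np.abs(logits).max():.3g}; "
                    "lower the learning rate or check the input scaling"
                )
            dlogits = multilabel_loss_grad(logits, yb, loss_cfg)
            model.backward(dlogits.astype(logits.dtype))
            for name, p in model.parameters():
                g = p.grad.astype(np.float64)
                if p.regularized and loss_cfg.l2_coefficient > 0:
                    g = g + 2.0 * loss_cfg.l2_coefficient * p.value
                if p.regularized and cfg.weight_decay > 0:
                    g = g + cfg.weight_decay * p.value
                v = cfg.momentum * velocity[name] - cfg.learning_rate * g
                velocity[name] = v
                p.value += v.astype(p.value.dtype)
            epoch_loss += batch_loss * len(idx)
            correct += int(((_sigmoid(logits) > 0.5) == (yb > 0.5)).sum())
        entry = {
            "epoch": epoch + 1,
            "loss": epoch_loss / n,
            "train_multilabel_accuracy": correct / (n * y_all.shape[1]),
        }
        log.append(entry)
        if checkpoint_path is not None:
            _write_checkpoint(checkpoint_path, model, cfg, loss_cfg, epoch + 1, log,
                              velocity, extra_meta)
    return model, log


def _write_checkpoint(path, model, cfg, loss_cfg, epoch, log, velocity, extra_meta):
    import io
    import json
    import zipfile

    meta = {
        "backbone": asdict(model.cfg),
        "train_config": asdict(cfg),
        "loss_config": {
            "class_weights": list(map(float, loss_cfg.class_weights)),
            "l2_coefficient": loss_cfg.l2_coefficient,
        },
        "epoch": epoch,
        "seed": cfg.seed,
        "log": log,
    }
    if extra_meta:
        meta.update(extra_meta)
    buf = io.BytesIO()
    np.savez(buf, **model.state_dict())
    vbuf = io.BytesIO()
    np.savez(vbuf, **velocity)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("params.npz", buf.getvalue())
        zf.writestr("velocity.npz", vbuf.getvalue())
        zf.writestr("meta.json", json.dumps(meta, indent=2, sort_keys=True))
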