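"""Temporal-shift spatio-temporal classifier for eye/mouth anomaly symptoms.

The backbone is a residual CNN whose residual branches apply a temporal
shift before their first convolution: a fixed fraction of feature channels
is displaced one step backward in time, an equal fraction one step forward,
and the vacated boundary positions are zero-filled. The shift moves values
without mixing them, so temporal context costs no extra parameters. Frame
features are averaged over time and a 2-logit linear head scores the two
symptom classes (eye anomaly, mouth anomaly) independently through a
sigmoid — a clip may show both.

Two profiles exist: ``micro`` (three narrow TSM residual stages, trainable
from scratch on a CPU) and ``resnet50`` (standard bottleneck stage widths
with shifts in the last three stages, accepting externally supplied
pretrained weights; provided as the scale-up configuration).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn

__all__ = [
    "BackboneConfig",
    "SymptomStream",
    "TSMNet",
    "temporal_shift",
    "build_model",
    "predict_clip",
    "predict_stream",
    "save_checkpoint",
    "load_checkpoint",
]


def temporal_shift(features: np.ndarray, shift_fraction: float) -> np.ndarray:
    """Shift channel slices of a (N, T, Ch, H, W) feature map along time.

    The first ``floor(Ch * shift_fraction)`` channels take their value from
    the next frame (shift backward in time), the next slice of equal size
    from the previous frame (shift forward); remaining channels pass
    through. Boundary positions with no source frame become zero. Values
    are only moved or zeroed, never altered.
    """
    if features.ndim != 5:
        raise ValueError(f"expected (N, T, Ch, H, W), got shape {features.shape}")
    if not 0.0 < shift_fraction <= 0.5:
        raise ValueError("shift_fraction must lie in (0, 0.5]")
    ch = features.shape[2]
    fold = int(ch * shift_fraction)
    out = features.copy()
    if fold == 0:
        return out
    # backward in time: value at t comes from t+1
    out[:, :-1, :fold] = features[:, 1:, :fold]
    out[:, -1, :fold] = 0.0
    # forward in time: value at t comes from t-1
    out[:, 1:, fold : 2 * fold] = features[:, :-1, fold : 2 * fold]
    out[:, 0, fold : 2 * fold] = 0.0
    return out


def _temporal_shift_backward(dout: np.ndarray, shift_fraction: float) -> np.ndarray:
    """Gradient of temporal_shift: the index map run in reverse."""
    ch = dout.shape[2]
    fold = int(ch * shift_fraction)
    dx = dout.copy()
    if fold == 0:
        return dx
    dx[:, 1:, :fold] = dout[:, :-1, :fold]
    dx[:, 0, :fold] = 0.0
    dx[:, :-1, fold : 2 * fold] = dout[:, 1:, fold : 2 * fold]
    dx[:, -1, fold : 2 * fold] = 0.0
    return dx


@dataclass
class BackboneConfig:
    """Architecture hyperparameters.

    shift_fraction is the per-direction channel fraction moved by each
    temporal shift (1/8 forward + 1/8 backward by default). temporal_size
    is the number of frames the network consumes per clip after sampling.
    """

    profile: str = "micro"
    num_tsm_stages: int = 3
    shift_fraction: float = 0.125
    temporal_size: int = 8
    in_channels: int = 1
    num_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.shift_fraction <= 0.5:
            raise ValueError("shift_fraction must lie in (0, 0.5]")
        if self.num_tsm_stages < 1:
            raise ValueError("num_tsm_stages must be >= 1")
        if self.profile not in ("micro", "resnet50"):
            raise ValueError(f"unknown profile {self.profile!r}")


class _TSMResidualBlock(nn.Module):
    """Basic residual block with a temporal shift entering the residual branch."""

    def __init__(self, in_ch, out_ch, stride, shift_fraction, rng, dtype, shifted=True):
        self.shift_fraction = shift_fraction
        self.shifted = shifted
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(out_ch, dtype=dtype)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(out_ch, dtype=dtype)
        self.relu_out = nn.ReLU()
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng, dtype=dtype)
            self.proj_bn = nn.BatchNorm2d(out_ch, dtype=dtype)
        else:
            self.proj = None
        self.temporal_size = None  # set by the owning network each forward

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        t = self.temporal_size
        if self.shifted:
            n5 = x.reshape(x.shape[0] // t, t, *x.shape[1:])
            branch = temporal_shift(n5, self.shift_fraction).reshape(x.shape)
        else:
            branch = x
        branch = self.conv1.forward(branch, train)
        branch = self.relu1.forward(self.bn1.forward(branch, train), train)
        branch = self.bn2.forward(self.conv2.forward(branch, train), train)
        if self.proj is not None:
            shortcut = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            shortcut = x
        return self.relu_out.forward(branch + shortcut, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        dbranch = self.bn2.backward(d)
        dbranch = self.conv2.backward(dbranch)
        dbranch = self.bn1.backward(self.relu1.backward(dbranch))
        dbranch = self.conv1.backward(dbranch)
        if self.shifted:
            t = self.temporal_size
            n5 = dbranch.reshape(dbranch.shape[0] // t, t, *dbranch.shape[1:])
            dbranch = _temporal_shift_backward(n5, self.shift_fraction).reshape(
                dbranch.shape
            )
        if self.proj is not None:
            dshort = self.proj.backward(self.proj_bn.backward(d))
        else:
            dshort = d
        return dbranch + dshort


class _Bottleneck(nn.Module):
    """1-3-1 bottleneck residual unit (ResNet-50 style), optionally shifted."""

    def __init__(self, in_ch, mid_ch, stride, shift_fraction, rng, dtype, shifted):
        out_ch = mid_ch * 4
        self.shift_fraction = shift_fraction
        self.shifted = shifted
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, pad=0, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(mid_ch, dtype=dtype)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, stride=stride, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(mid_ch, dtype=dtype)
        self.relu2 = nn.ReLU()
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, pad=0, rng=rng, dtype=dtype)
        self.bn3 = nn.BatchNorm2d(out_ch, dtype=dtype)
        self.relu_out = nn.ReLU()
        if stride != 1 or in_ch != out_ch:
            self.proj = nn.Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng, dtype=dtype)
            self.proj_bn = nn.BatchNorm2d(out_ch, dtype=dtype)
        else:
            self.proj = None
        self.temporal_size = None

    def forward(self, x, train=True):
        if self.shifted:
            t = self.temporal_size
            n5 = x.reshape(x.shape[0] // t, t, *x.shape[1:])
            b = temporal_shift(n5, self.shift_fraction).reshape(x.shape)
        else:
            b = x
        b = self.relu1.forward(self.bn1.forward(self.conv1.forward(b, train), train), train)
        b = self.relu2.forward(self.bn2.forward(self.conv2.forward(b, train), train), train)
        b = self.bn3.forward(self.conv3.forward(b, train), train)
        s = self.proj_bn.forward(self.proj.forward(x, train), train) if self.proj else x
        return self.relu_out.forward(b + s, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        db = self.conv3.backward(self.bn3.backward(d))
        db = self.conv2.backward(self.bn2.backward(self.relu2.backward(db)))
        db = self.conv1.backward(self.bn1.backward(self.relu1.backward(db)))
        if self.shifted:
            t = self.temporal_size
            n5 = db.reshape(db.shape[0] // t, t, *db.shape[1:])
            db = _temporal_shift_backward(n5, self.shift_fraction).reshape(db.shape)
        ds = self.proj.backward(self.proj_bn.backward(d)) if self.proj else d
        return db + ds


class TSMNet(nn.Module):
    """Residual CNN with temporal-shift stages and a multilabel sigmoid head.

    Input: (N, T, C, H, W) clips; output: (N, num_classes) logits. Frame
    features are pooled spatially, averaged over the T frames, then scored
    by the linear head.
    """

    def __init__(self, cfg: BackboneConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dtype = np.float32
        if cfg.profile == "micro":
            widths = [8, 16, 32, 32][: cfg.num_tsm_stages + 1]
            self.stem_conv = nn.Conv2d(cfg.in_channels, widths[0], 3, stride=2, rng=rng, dtype=dtype)
            self.stem_bn = nn.BatchNorm2d(widths[0], dtype=dtype)
            self.stem_relu = nn.ReLU()
            self.pool = nn.MaxPool2d()
            blocks = []
            in_ch = widths[0]
            for k in range(cfg.num_tsm_stages):
                out_ch = widths[min(k + 1, len(widths) - 1)]
                stride = 2 if k < 2 else 1
                blocks.append(
                    _TSMResidualBlock(in_ch, out_ch, stride, cfg.shift_fraction, rng, dtype)
                )
                in_ch = out_ch
            self.blocks = blocks
            feat = in_ch
        else:  # resnet50
            self.stem_conv = nn.Conv2d(cfg.in_channels, 64, 7, stride=2, pad=3, rng=rng, dtype=dtype)
            self.stem_bn = nn.BatchNorm2d(64, dtype=dtype)
            self.stem_relu = nn.ReLU()
            self.pool = nn.MaxPool2d()
            stage_blocks = [3, 4, 6, 3]
            mids = [64, 128, 256, 512]
            blocks = []
            in_ch = 64
            for s, (nb, mid) in enumerate(zip(stage_blocks, mids)):
                # temporal shifts go in the last num_tsm_stages stages
                shifted = s >= 4 - cfg.num_tsm_stages
                for b in range(nb):
                    stride = 2 if (b == 0 and s > 0) else 1
                    blocks.append(
                        _Bottleneck(in_ch, mid, stride, cfg.shift_fraction, rng, dtype, shifted)
                    )
                    in_ch = mid * 4
            self.blocks = blocks
            feat = in_ch
        self.head = nn.Linear(feat, cfg.num_classes, rng=rng, dtype=dtype)
        self.feat_dim = feat
        self._cache = None

    def forward(self, clips: np.ndarray, train: bool = True) -> np.ndarray:
        if clips.ndim != 5:
            raise ValueError(f"expected (N, T, C, H, W), got shape {clips.shape}")
        n, t = clips.shape[:2]
        if t != self.cfg.temporal_size:
            raise ValueError(
                f"clip has {t} frames, model expects {self.cfg.temporal_size}"
            )
        x = clips.reshape(n * t, *clips.shape[2:])
        x = self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x, train), train), train)
        x = self.pool.forward(x, train)
        for blk in self.blocks:
            blk.temporal_size = t
            x = blk.forward(x, train)
        self._spatial = x.shape[2:]
        feats = nn.global_avg_pool(x)  # (N*T, F)
        feats = feats.reshape(n, t, -1).mean(axis=1)  # temporal average
        self._nt = (n, t)
        return self.head.forward(feats, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        n, t = self._nt
        dfeat = self.head.backward(dlogits)  # (N, F)
        dfeat = np.repeat(dfeat[:, None, :], t, axis=1).reshape(n * t, -1) / t
        dx = nn.global_avg_pool_backward(dfeat, self._spatial)
        for blk in reversed(self.blocks):
            dx = blk.backward(dx)
        dx = self.pool.backward(dx)
        dx = self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(dx)))
        return dx.reshape(n, t, *dx.shape[1:])

    def zero_grad(self) -> None:
        for _, p in self.parameters():
            p.zero_grad()

    # ---- state dict -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.value for name, p in self.parameters()}
        for name, mod in self._bn_modules():
            state[f"{name}.running_mean"] = mod.running_mean
            state[f"{name}.running_var"] = mod.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.parameters():
            p.value[...] = state[name]
        for name, mod in self._bn_modules():
            mod.running_mean[...] = state[f"{name}.running_mean"]
            mod.running_var[...] = state[f"{name}.running_var"]

    def _bn_modules(self):
        def walk(mod, prefix):
            for name, attr in vars(mod).items():
                q = f"{prefix}{name}"
                if isinstance(attr, nn.BatchNorm2d):
                    yield q, attr
                elif isinstance(attr, nn.Module):
                    yield from walk(attr, q + ".")
                elif isinstance(attr, list):
                    for k, item in enumerate(attr):
                        if isinstance(item, nn.Module):
                            if isinstance(item, nn.BatchNorm2d):
                                yield f"{q}.{k}", item
                            else:
                                yield from walk(item, f"{q}.{k}.")
        yield from walk(self, "")

    def load_pretrained(self, path: str | Path) -> None:
        """Optional hook: load externally supplied weights (npz state dict)."""
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def build_model(cfg: BackboneConfig) -> TSMNet:
    """Construct the classifier for a backbone configuration."""
    return TSMNet(cfg)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def predict_clip(model: TSMNet, clip: np.ndarray) -> tuple[float, float]:
    """Symptom probabilities (P_eye, P_mouth) for one preprocessed clip."""
    if clip.ndim != 4:
        raise ValueError(f"expected (T, C, H, W), got shape {clip.shape}")
    logits = model.forward(clip[None], train=False)[0]
    p = _sigmoid(logits)
    return float(p[0]), float(p[1])


@dataclass
class SymptomStream:
    """Time-ordered per-clip symptom probabilities (the probability-time curve)."""

    clip_index: np.ndarray
    time_s: np.ndarray
    p_eye: np.ndarray
    p_mouth: np.ndarray

    def __len__(self) -> int:
        return len(self.clip_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clip_index": self.clip_index,
                "time_s": self.time_s,
                "p_eye": self.p_eye,
                "p_mouth": self.p_mouth,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SymptomStream":
        return cls(
            clip_index=df["clip_index"].to_numpy(int),
            time_s=df["time_s"].to_numpy(float),
            p_eye=df["p_eye"].to_numpy(float),
            p_mouth=df["p_mouth"].to_numpy(float),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SymptomStream":
        return cls.from_frame(pd.read_csv(path, comment="#"))


def predict_stream(
    model: TSMNet,
    clips: "np.ndarray | list[np.ndarray]",
    clip_seconds: float = 0.64,
    batch_size: int = 16,
) -> SymptomStream:
    """Score a time-ordered clip sequence; one probability pair per clip.

    clip_seconds converts clip index to a time axis (clip hop duration).
    """
    clips = np.asarray(clips)
    n = len(clips)
    if n == 0:
        z = np.array([])
        return SymptomStream(z.astype(int), z, z, z)
    probs = np.empty((n, 2))
    for start in range(0, n, batch_size):
        logits = model.forward(clips[start : start + batch_size], train=False)
        probs[start : start + logits.shape[0]] = _sigmoid(logits)
    idx = np.arange(n)
    return SymptomStream(idx, idx * clip_seconds, probs[:, 0], probs[:, 1])


# ---- checkpointing -------------------------------------------------------


def save_checkpoint(path: str | Path, model: TSMNet, meta: dict) -> None:
    """Single-archive checkpoint: npz parameter blob + JSON metadata."""
    buf = io.BytesIO()
    np.savez(buf, **model.state_dict())
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("params.npz", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta, indent=2, sort_keys=True))


def load_checkpoint(path: str | Path) -> tuple[TSMNet, dict]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with np.load(io.BytesIO(zf.read("params.npz"))) as data:
            state = {k: data[k] for k in data.files}
    model = build_model(BackboneConfig(**meta["backbone"]))
    model.load_state_dict(state)
    return model, meta
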