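"""Clip preprocessing: face cropping and segment-based temporal sampling.

Coordinates are 0-based and half-open on the right/bottom throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage.transform import resize

__all__ = [
    "FaceBox",
    "NO_DETECTION",
    "SamplerConfig",
    "detect_face",
    "tsn_sample",
    "crop_and_normalize",
]


@dataclass(frozen=True)
class FaceBox:
    """Axis-aligned face region, half-open pixel coordinates."""

    x0: int
    y0: int
    x1: int
    y1: int

    def validate(self, frame_shape: tuple[int, int]) -> "FaceBox":
        h, w = frame_shape[:2]
        if not (0 <= self.x0 < self.x1 <= w and 0 <= self.y0 < self.y1 <= h):
            raise ValueError(f"{self} invalid for frame of shape {(h, w)}")
        return self


#: Sentinel returned when a detector finds no face; caller policy decides
#: whether to skip the clip or fall back to the full frame.
NO_DETECTION: FaceBox | None = None


def detect_face(
    frame: np.ndarray,
    metadata: dict | None = None,
    detector: Callable[[np.ndarray], "FaceBox | None"] | None = None,
) -> FaceBox | None:
    """Locate the face region in one frame.

    A real detector can be plugged in as ``detector`` (returning a FaceBox
    or ``NO_DETECTION``). Without one, the fallback uses the rendered face
    box from synthetic-clip metadata when present, else a centered square
    crop of side min(H, W) — deterministic and download-free.
    """
    if frame.size == 0:
        raise ValueError("empty frame")
    h, w = frame.shape[:2]
    if detector is not None:
        box = detector(frame)
        if box is NO_DETECTION:
            return NO_DETECTION
        return box.validate((h, w))
    if metadata is not None and "face_box" in metadata:
        x0, y0, x1, y1 = metadata["face_box"]
        return FaceBox(x0, y0, x1, y1).validate((h, w))
    side = min(h, w)
    x0 = (w - side) // 2
    y0 = (h - side) // 2
    return FaceBox(x0, y0, x0 + side, y0 + side)


@dataclass
class SamplerConfig:
    """Segment-based frame sampling: one frame from each of num_segments
    equal temporal spans (center at inference, random within span during
    training)."""

    num_segments: int = 8
    mode: str = "deterministic_center"
    seed: int = 0

    def __post_init__(self):
        if self.num_segments < 1:
            raise ValueError("num_segments must be >= 1")
        if self.mode not in ("deterministic_center", "random_within_segment"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")


def tsn_sample(
    total_frames: int,
    cfg: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Strictly increasing frame indices, one per temporal segment.

    Frames are partitioned into num_segments spans of near-equal length
    (the remainder goes to the leading spans). Center mode takes each
    span's middle index floor((start+end)/2); random mode draws uniformly
    within each span (from ``rng`` if given, else from cfg.seed).
    """
    k = cfg.num_segments
    if total_frames < k:
        raise ValueError(f"total_frames={total_frames} < num_segments={k}")
    base, rem = divmod(total_frames, k)
    lengths = np.full(k, base, dtype=int)
    lengths[:rem] += 1
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    ends = starts + lengths
    if cfg.mode == "deterministic_center":
        return (starts + ends) // 2
    rng = rng or np.random.default_rng(cfg.seed)
    return starts + rng.integers(0, lengths)


def crop_and_normalize(
    frames: np.ndarray,
    box: FaceBox,
    out_size: int = 64,
    stats: tuple = (0.0, 1.0),
) -> np.ndarray:
    """Crop the face box, resize bilinearly, scale to [0,1], standardize.

    frames: (T, H, W) or (T, H, W, C) uint8/float. stats is (mean, sd) per
    channel (scalars broadcast). Output is float32 (T, C, out_size,
    out_size); frame order is preserved.
    """
    if frames.ndim == 3:
        frames = frames[..., None]
    t, h, w, c = frames.shape
    box.validate((h, w))
    if box.x1 - box.x0 < 2 or box.y1 - box.y0 < 2:
        raise ValueError(f"degenerate box {box}")
    crop = frames[:, box.y0 : box.y1, box.x0 : box.x1].astype(np.float64) / 255.0
    if crop.shape[1:3] != (out_size, out_size):
        crop = resize(
            crop, (t, out_size, out_size, c), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    mean = np.asarray(stats[0], dtype=np.float64).reshape(1, 1, 1, -1)
    sd = np.asarray(stats[1], dtype=np.float64).reshape(1, 1, 1, -1)
    out = (crop - mean) / sd
    return out.transpose(0, 3, 1, 2).astype(np.float32)
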