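"""Frame/clip readers and writers, manifest helpers.

Clips travel as directories of PNG frames in lexicographic order; a video
container path is accepted when an imageio ffmpeg plugin is available.
Manifests are plain CSV (comma, UTF-8, header row).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "read_clip_source",
    "write_clip_frames",
    "read_clip_metadata",
    "load_manifest",
]

_FRAME_EXTS = (".png", ".jpg", ".jpeg")


def read_clip_source(path: str | Path) -> tuple[np.ndarray, float | None]:
    """Read an ordered frame array from a frame directory or video file.

    Returns (frames, fps): frames is (T, H, W) or (T, H, W, C) uint8; fps
    is None for frame directories (no intrinsic rate). Mixed frame sizes
    raise an IOError naming the offending file.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            f for f in path.iterdir() if f.suffix.lower() in _FRAME_EXTS
        )
        if not files:
            raise IOError(f"no frame images found in {path}")
        frames = []
        shape = None
        for f in files:
            try:
                img = iio.imread(f)
            except Exception as exc:
                raise IOError(f"unreadable frame {f}: {exc}") from exc
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise IOError(
                    f"frame {f} has shape {img.shape}, expected {shape}"
                )
            frames.append(img)
        return np.stack(frames), None
    if path.is_file():
        try:
            frames = iio.imread(path, plugin="pyav")
        except Exception:
            try:
                frames = iio.imread(path)
            except Exception as exc:
                raise IOError(
                    f"cannot decode video {path} (no usable video plugin): {exc}"
                ) from exc
        meta = {}
        try:
            meta = iio.immeta(path)
        except Exception:
            pass
        return np.asarray(frames), meta.get("fps")
    raise IOError(f"clip source {path} does not exist")


def write_clip_frames(clip_dir: str | Path, frames: np.ndarray) -> list[Path]:
    """Write frames as zero-padded PNGs (frame0000.png, ...)."""
    clip_dir = Path(clip_dir)
    clip_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, frame in enumerate(frames):
        p = clip_dir / f"frame{t:04d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def read_clip_metadata(clip_dir: str | Path) -> dict | None:
    """Load the renderer's sidecar metadata (face box etc.) if present."""
    meta_path = Path(clip_dir) / "meta.json"
    if meta_path.exists():
        return json.loads(meta_path.read_text())
    return None


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"clip_id", "subject_id", "split", "path", "label_eye", "label_mouth", "state"}
    missing = required - set(df.columns)
    if missing:
        raise IOError(f"manifest {path} missing columns {sorted(missing)}")
    return df
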