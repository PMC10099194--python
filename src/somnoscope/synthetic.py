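"""Seeded synthetic face-clip data with the temporal structure the method assumes.

Three generators cover the pipeline's inputs end to end:

* behavior scripts — episode timelines (prolonged eye closures, yawns)
  placed on a frame axis, from which per-frame and per-clip symptom labels
  and window-level fatigue states are derived;
* clip rendering — schematic grayscale faces (two eye blobs, one mouth
  blob) whose eyes collapse to thin slits during closure episodes and
  whose mouth elongates during yawns, with per-clip position jitter and
  illumination and per-frame additive noise emulating recordings made at
  different times and angles;
* symptom-score streams — (a_e, a_m) pairs drawn from the Gaussian
  class-conditional model the MAP fusion stage assumes, for testing that
  stage in isolation.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import ellipse

__all__ = [
    "EYE_CLOSURE",
    "YAWN",
    "BehaviorScript",
    "RenderParams",
    "StreamSimParams",
    "ClipSample",
    "DatasetConfig",
    "generate_behavior_script",
    "render_clip",
    "simulate_symptom_streams",
    "make_dataset",
]

EYE_CLOSURE = "eye_closure"
YAWN = "yawn"
EVENT_TYPES = (EYE_CLOSURE, YAWN)

# Episode durations in frames (25 fps), drawn uniformly: drowsy eye
# closures run ~1-3 s, yawns ~2-5 s. Both span several 16-frame clips, so
# episodes produce runs of unambiguous positive clips flanked by partially
# covered edge clips.
DEFAULT_DURATIONS = {EYE_CLOSURE: (25, 75), YAWN: (50, 125)}


@dataclass
class BehaviorScript:
    """Episode timeline: (onset, duration, type) events on a frame axis."""

    events: list[tuple[int, int, str]]
    total_frames: int

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: (e[0], e[2]))
        last_end = {t: 0 for t in EVENT_TYPES}
        for onset, dur, etype in self.events:
            if etype not in EVENT_TYPES:
                raise ValueError(f"unknown event type {etype!r}")
            if dur < 1 or onset < 0 or onset + dur > self.total_frames:
                raise ValueError(f"event ({onset}, {dur}, {etype}) outside script bounds")
            if onset < last_end[etype]:
                raise ValueError(f"overlapping {etype} events at frame {onset}")
            last_end[etype] = onset + dur

    def frame_labels(self) -> np.ndarray:
        """(total_frames, 2) 0/1 array; column 0 = eye anomaly, 1 = mouth."""
        labels = np.zeros((self.total_frames, 2), dtype=np.int8)
        col = {EYE_CLOSURE: 0, YAWN: 1}
        for onset, dur, etype in self.events:
            labels[onset : onset + dur, col[etype]] = 1
        return labels

    def window_labels(self, start: int, end: int, coverage: float = 0.5) -> tuple[int, int]:
        """Clip-level (eye, mouth) labels: 1 iff >= coverage of the window's
        frames carry that event."""
        if not 0 <= start < end <= self.total_frames:
            raise ValueError(f"window [{start}, {end}) outside script of {self.total_frames} frames")
        frac = self.frame_labels()[start:end].mean(axis=0)
        return int(frac[0] >= coverage), int(frac[1] >= coverage)

    def window_state(self, start: int, end: int, coverage: float = 0.5) -> int:
        """Fatigue state of a clip window: 1 iff the window carries either
        symptom label — the same coverage rule that defines the symptom
        labels, so the state is always recoverable from them."""
        le, lm = self.window_labels(start, end, coverage)
        return max(le, lm)


def generate_behavior_script(
    total_frames: int,
    episode_rates: dict[str, float],
    seed: int,
    durations: dict[str, tuple[int, int]] | None = None,
) -> BehaviorScript:
    """Place anomaly episodes on a frame axis, Poisson-style.

    For each event type the episode count is Poisson(rate * total_frames);
    onsets are uniform, re-drawn (up to 200 tries) if they would overlap a
    previous episode of the same type, so E[count] matches the analytic
    rate * total_frames. Eye and mouth episodes may overlap each other.
    """
    if total_frames < 16:
        raise ValueError("total_frames must be >= 16")
    for etype, rate in episode_rates.items():
        if etype not in EVENT_TYPES:
            raise ValueError(f"unknown event type {etype!r}")
        if rate < 0:
            raise ValueError("episode rates must be >= 0")
    durations = durations or DEFAULT_DURATIONS
    rng = np.random.default_rng(seed)
    events: list[tuple[int, int, str]] = []
    for etype in EVENT_TYPES:  # fixed order keeps the draw sequence stable
        rate = episode_rates.get(etype, 0.0)
        if rate == 0.0:
            continue
        count = rng.poisson(rate * total_frames)
        occupied: list[tuple[int, int]] = []
        lo, hi = durations[etype]
        for _ in range(count):
            dur = int(rng.integers(lo, hi + 1))
            dur = min(dur, total_frames)
            for _ in range(200):
                onset = int(rng.integers(0, total_frames - dur + 1))
                if all(onset + dur <= s or onset >= e for s, e in occupied):
                    occupied.append((onset, onset + dur))
                    events.append((onset, dur, etype))
                    break
            # if no free slot was found the episode is dropped (vanishingly
            # rare at the default occupancy)
    return BehaviorScript(events=events, total_frames=total_frames)


@dataclass
class RenderParams:
    """Appearance parameters for the schematic face renderer."""

    frame_height: int = 64
    frame_width: int = 64
    channels: int = 1
    face_center_jitter: int = 3
    illumination_range: tuple[float, float] = (0.7, 1.0)
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if min(self.frame_height, self.frame_width) < 32:
            raise ValueError("frame dimensions must be >= 32")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.face_center_jitter >= min(self.frame_height, self.frame_width) / 4:
            raise ValueError("face_center_jitter must be < min(frame dims)/4")
        lo, hi = self.illumination_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("illumination_range must be an ordered pair in [0, 1]")


@dataclass
class ClipSample:
    """A fixed-length frame sequence with its multilabel symptom annotation."""

    frames: np.ndarray  # (T, H, W) or (T, H, W, 3), uint8
    label_eye: int
    label_mouth: int
    face_box: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    window: tuple[int, int]
    subject_id: str = ""
    scenario: str = "synthetic"


def _draw_face(
    h: int,
    w: int,
    cy: float,
    cx: float,
    illum: float,
    eye_closed: bool,
    yawning: bool,
) -> np.ndarray:
    frame = np.full((h, w), 30.0 * illum)
    face_ry, face_rx = 0.40 * h, 0.32 * w
    rr, cc = ellipse(cy, cx, face_ry, face_rx, shape=(h, w))
    frame[rr, cc] = 175.0 * illum
    eye_dy, eye_dx = 0.14 * h, 0.13 * w
    eye_ry = 0.012 * h if eye_closed else 0.055 * h
    eye_rx = 0.075 * w
    for side in (-1, 1):
        rr, cc = ellipse(cy - eye_dy, cx + side * eye_dx, max(eye_ry, 0.5), eye_rx, shape=(h, w))
        frame[rr, cc] = 55.0 * illum
    mouth_dy = 0.22 * h
    mouth_ry = 0.13 * h if yawning else 0.03 * h
    mouth_rx = 0.07 * w if yawning else 0.11 * w
    rr, cc = ellipse(cy + mouth_dy, cx, mouth_ry, mouth_rx, shape=(h, w))
    frame[rr, cc] = 50.0 * illum
    return frame


def render_clip(
    script: BehaviorScript,
    window: tuple[int, int],
    params: RenderParams,
    label_coverage: float = 0.5,
    subject_id: str = "",
) -> ClipSample:
    """Render the frames of ``window`` as schematic face images.

    Face position jitter and illumination are drawn once per clip, pixel
    noise once per frame; the rng derives from (params.seed, window start)
    so re-rendering the same window is bit-identical while different
    windows differ.
    """
    start, end = window
    if not 0 <= start < end <= script.total_frames:
        raise ValueError(f"window {window} outside script of {script.total_frames} frames")
    h, w = params.frame_height, params.frame_width
    rng = np.random.default_rng([params.seed, start])
    j = params.face_center_jitter
    jy, jx = (rng.integers(-j, j + 1, size=2) if j > 0 else (0, 0))
    cy, cx = h / 2 + jy, w / 2 + jx
    illum = float(rng.uniform(*params.illumination_range))
    frame_labels = script.frame_labels()[start:end]
    frames = np.empty((end - start, h, w), dtype=np.float64)
    for t in range(end - start):
        img = _draw_face(h, w, cy, cx, illum, bool(frame_labels[t, 0]), bool(frame_labels[t, 1]))
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        frames[t] = img
    frames = np.clip(frames, 0, 255).astype(np.uint8)
    if params.channels == 3:
        frames = np.repeat(frames[..., None], 3, axis=-1)
    face_ry, face_rx = 0.40 * h, 0.32 * w
    box = (
        max(int(cx - face_rx) - 2, 0),
        max(int(cy - face_ry) - 2, 0),
        min(int(cx + face_rx) + 3, w),
        min(int(cy + face_ry) + 3, h),
    )
    le, lm = script.window_labels(start, end, label_coverage)
    return ClipSample(
        frames=frames,
        label_eye=le,
        label_mouth=lm,
        face_box=box,
        window=window,
        subject_id=subject_id,
    )


@dataclass
class StreamSimParams:
    """Gaussian class-conditional parameters for direct symptom-score simulation.

    mu/sigma are (2, 2) arrays indexed [attribute, state] with attribute
    0 = eye, 1 = mouth and state 0 = normal, 1 = fatigued. Defaults put the
    fatigued means well above the normal ones on the appearance-frequency
    scale while keeping the supports overlapping.
    """

    mu: np.ndarray = field(
        default_factory=lambda: np.array([[0.05, 0.55], [0.03, 0.45]])
    )
    sigma: np.ndarray = field(
        default_factory=lambda: np.array([[0.08, 0.18], [0.06, 0.16]])
    )
    prior_fatigued: float = 0.3
    n_windows: int = 1000
    seed: int = 0

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != (2, 2) or self.sigma.shape != (2, 2):
            raise ValueError("mu and sigma must be (2, 2): [attribute, state]")
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma must be > 0")
        if not 0 <= self.prior_fatigued <= 1:
            raise ValueError("prior_fatigued must be in [0, 1]")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")


def simulate_symptom_streams(params: StreamSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Draw (observations, states) from the Gaussian class-conditional model.

    Per window the state is Bernoulli(prior_fatigued) and the two scores
    are drawn independently from that state's Gaussians (untruncated —
    the model's support is the whole real line). Returns observations as
    an (n_windows, 2) float array [a_e, a_m] and states as 0/1 ints.
    """
    rng = np.random.default_rng(params.seed)
    states = (rng.random(params.n_windows) < params.prior_fatigued).astype(np.int8)
    obs = np.empty((params.n_windows, 2))
    for attr in range(2):
        obs[:, attr] = rng.normal(
            params.mu[attr, states], params.sigma[attr, states]
        )
    return obs, states


@dataclass
class DatasetConfig:
    """Layout of a synthetic cohort: subjects, clips, splits, behavior rates."""

    n_subjects: int = 10
    clips_per_subject: int = 20
    clip_len: int = 16
    splits: dict = field(default_factory=lambda: {"train": 0.5, "val": 0.2, "test": 0.3})
    episode_rates: dict = field(
        default_factory=lambda: {EYE_CLOSURE: 0.004, YAWN: 0.002}
    )
    label_coverage: float = 0.5
    render: RenderParams = field(default_factory=RenderParams)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.splits.values()) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        n_requested = sum(1 for v in self.splits.values() if v > 0)
        if self.n_subjects < 2 * n_requested:
            raise ValueError(
                f"need >= 2 subjects per requested split ({n_requested} splits, "
                f"{self.n_subjects} subjects)"
            )

    @property
    def n_clips(self) -> int:
        return self.n_subjects * self.clips_per_subject


def make_dataset(
    config: DatasetConfig,
    out_dir: str | Path,
    write_frames: bool = True,
) -> pd.DataFrame:
    """Generate a subject-disjoint synthetic cohort and its CSV manifest.

    Each subject gets one behavior script covering ``clips_per_subject``
    consecutive non-overlapping clips; clips are rendered to per-clip PNG
    directories (with a meta.json holding the rendered face box) unless
    ``write_frames`` is False. Subjects are assigned to splits before any
    clip is cut, so no subject crosses a split boundary. The manifest —
    columns (clip_id, subject_id, split, path, label_eye, label_mouth,
    state) — is written to ``out_dir/manifest.csv`` with paths relative to
    ``out_dir``, making regeneration byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    subjects = [f"s{k:03d}" for k in range(config.n_subjects)]
    perm = rng.permutation(config.n_subjects)
    split_of: dict[str, str] = {}
    pos = 0
    names = list(config.splits)
    for k, name in enumerate(names):
        cnt = round(config.splits[name] * config.n_subjects)
        if k == len(names) - 1:
            cnt = config.n_subjects - pos
        for idx in perm[pos : pos + cnt]:
            split_of[subjects[idx]] = name
        pos += cnt

    import json

    rows = []
    clip_id = 0
    for s_idx, subject in enumerate(subjects):
        total = config.clips_per_subject * config.clip_len
        script = generate_behavior_script(
            total, config.episode_rates, seed=int(rng.integers(0, 2**31))
        )
        render = RenderParams(**{**vars(config.render), "seed": int(rng.integers(0, 2**31))})
        for c in range(config.clips_per_subject):
            start = c * config.clip_len
            window = (start, start + config.clip_len)
            state = script.window_state(*window, config.label_coverage)
            rel = f"clips/{subject}/clip{c:04d}"
            if write_frames:
                sample = render_clip(
                    script, window, render, config.label_coverage, subject
                )
                clip_dir = out_dir / rel
                clip_dir.mkdir(parents=True, exist_ok=True)
                from .io import write_clip_frames

                write_clip_frames(clip_dir, sample.frames)
                (clip_dir / "meta.json").write_text(
                    json.dumps(
                        {
                            "face_box": list(sample.face_box),
                            "window": list(window),
                            "subject_id": subject,
                            "seed": render.seed,
                        },
                        sort_keys=True,
                    )
                )
                le, lm = sample.label_eye, sample.label_mouth
            else:
                le, lm = script.window_labels(*window, config.label_coverage)
            rows.append(
                {
                    "clip_id": f"c{clip_id:05d}",
                    "subject_id": subject,
                    "split": split_of[subject],
                    "path": rel,
                    "label_eye": le,
                    "label_mouth": lm,
                    "state": state,
                }
            )
            clip_id += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
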