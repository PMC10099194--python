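"""End-to-end orchestration: simulate -> train -> infer -> fuse -> evaluate.

Each stage reads and writes plain artifacts (PNG clip directories, CSV
manifests/streams/decisions, JSON models/reports) under the run's output
directory, stamped with the package version, global seed and a hash of
the full configuration, so a run is reproducible from its artifacts
alone. The command-line interface and the worked examples are thin
wrappers over these functions.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash
from .evaluation import (
    confusion_counts,
    export_probability_curve,
    metrics,
    per_subject_accuracy,
    roc_points,
)
from .fusion import (
    compute_window_scores,
    decisions_to_frame,
    fit_gnb,
    GaussianNBModel,
    infer_state,
)
from .io import load_manifest, read_clip_metadata, read_clip_source
from .loss import LossConfig, class_weights_from_labels
from .model import (
    SymptomStream,
    build_model,
    load_checkpoint,
    predict_stream,
)
from .preprocessing import crop_and_normalize, detect_face, tsn_sample
from .synthetic import make_dataset
from .training import train

__all__ = [
    "run_simulate",
    "run_train",
    "run_infer",
    "run_fit_fusion",
    "run_fuse",
    "run_evaluate",
    "run_e2e",
]


def _meta(cfg: RunConfig) -> dict:
    return {"tool_version": __version__, "seed": cfg.seed, "config_hash": config_hash(cfg)}


def _write_meta(cfg: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    from .config import _jsonable

    payload = {**_meta(cfg), "config": _jsonable(cfg)}
    (out_dir / "run_meta.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_simulate(cfg: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Generate the synthetic cohort; returns the data directory."""
    data_dir = Path(out_dir) if out_dir else Path(cfg.out_dir) / "data"
    _write_meta(cfg, data_dir)
    make_dataset(cfg.synthetic, data_dir)
    return data_dir


def _load_clips(cfg: RunConfig, data_dir: Path, manifest: pd.DataFrame) -> dict:
    """Read, face-crop and normalize-scale every clip of a manifest.

    Returns full-length preprocessed clips (N, clip_len, C, S, S) in
    [0, 1] (standardization happens later with train-split statistics)
    plus aligned labels, states and subject ids.
    """
    clips = []
    for _, row in manifest.iterrows():
        clip_dir = data_dir / row["path"]
        frames, _ = read_clip_source(clip_dir)
        box = detect_face(frames[0], metadata=read_clip_metadata(clip_dir))
        clips.append(
            crop_and_normalize(frames, box, out_size=cfg.preprocessing.out_size)
        )
    return {
        "clips": np.stack(clips),
        "labels": manifest[["label_eye", "label_mouth"]].to_numpy(int),
        "states": manifest["state"].to_numpy(int),
        "subjects": manifest["subject_id"].to_numpy(),
    }


def run_train(cfg: RunConfig, data_dir: str | Path) -> Path:
    """Train the symptom classifier on the manifest's train split."""
    data_dir = Path(data_dir)
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = load_manifest(data_dir / "manifest.csv")
    train_rows = manifest[manifest["split"] == "train"].reset_index(drop=True)
    if len(train_rows) == 0:
        raise ValueError("train split is empty")
    data = _load_clips(cfg, data_dir, train_rows)
    x_full, y = data["clips"], data["labels"]
    stats_mean = float(x_full.mean())
    stats_sd = float(x_full.std()) or 1.0
    x_full = (x_full - stats_mean) / stats_sd
    clip_len = x_full.shape[1]

    sampler = cfg.preprocessing.train_sampler
    bb = cfg.classifier.backbone
    model = build_model(bb)

    def provider(rng: np.random.Generator):
        idx = np.stack([tsn_sample(clip_len, sampler, rng) for _ in range(len(x_full))])
        return np.take_along_axis(
            x_full, idx[:, :, None, None, None], axis=1
        ), y

    weights = class_weights_from_labels(y, cap=cfg.classifier.class_weight_cap)
    loss_cfg = LossConfig(
        class_weights=weights, l2_coefficient=cfg.classifier.l2_coefficient
    )
    ckpt = run_dir / "classifier.ckpt"
    train(
        model,
        provider,
        cfg.classifier.train,
        loss_cfg,
        checkpoint_path=ckpt,
        extra_meta={
            **_meta(cfg),
            "norm_stats": [stats_mean, stats_sd],
            "clip_seconds": cfg.clip_seconds,
        },
    )
    return ckpt


def run_infer(
    cfg: RunConfig,
    checkpoint: str | Path,
    data_dir: str | Path,
    split: str = "test",
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Score every clip of a split, per subject in time order.

    Returns a stream table (subject_id, clip_index, time_s, p_eye,
    p_mouth, label_eye, label_mouth, state) and writes it as CSV when
    out_csv is given.
    """
    data_dir = Path(data_dir)
    model, meta = load_checkpoint(checkpoint)
    stats_mean, stats_sd = meta["norm_stats"]
    manifest = load_manifest(data_dir / "manifest.csv")
    rows = manifest[manifest["split"] == split].reset_index(drop=True)
    if len(rows) == 0:
        raise ValueError(f"split {split!r} is empty")
    data = _load_clips(cfg, data_dir, rows)
    x_full = (data["clips"] - stats_mean) / stats_sd
    clip_len = x_full.shape[1]
    idx = tsn_sample(clip_len, cfg.preprocessing.eval_sampler)
    x = x_full[:, idx]

    frames = []
    for subject in pd.unique(rows["subject_id"]):
        mask = (rows["subject_id"] == subject).to_numpy()
        stream = predict_stream(model, x[mask], clip_seconds=cfg.clip_seconds)
        df = stream.to_frame()
        df.insert(0, "subject_id", subject)
        df["label_eye"] = data["labels"][mask, 0]
        df["label_mouth"] = data["labels"][mask, 1]
        df["state"] = data["states"][mask]
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


def _window_truth(states: np.ndarray, w: int) -> np.ndarray:
    """Window-level fatigue truth: 1 iff >= half the window's clips are
    fatigued (majority vote, ties toward fatigued)."""
    kernel = np.ones(w)
    sums = np.convolve(states.astype(float), kernel, mode="valid")
    return (sums / w >= 0.5).astype(int)


def _stream_of(group: pd.DataFrame) -> SymptomStream:
    return SymptomStream(
        clip_index=group["clip_index"].to_numpy(int),
        time_s=group["time_s"].to_numpy(float),
        p_eye=group["p_eye"].to_numpy(float),
        p_mouth=group["p_mouth"].to_numpy(float),
    )


def run_fit_fusion(
    cfg: RunConfig, stream_table: pd.DataFrame, out_json: str | Path | None = None
) -> GaussianNBModel:
    """Fit the Gaussian naive-Bayes fusion model from labelled streams.

    Window scores are computed per subject; window states come from the
    manifest's clip-level fatigue labels by majority vote.
    """
    obs_all, truth_all = [], []
    for _, group in stream_table.groupby("subject_id", sort=True):
        if len(group) < cfg.fusion.window_clips:
            continue
        obs = compute_window_scores(_stream_of(group), cfg.fusion)
        obs_all.extend(obs)
        truth_all.append(_window_truth(group["state"].to_numpy(int), cfg.fusion.window_clips))
    if not obs_all:
        raise ValueError("no subject stream is at least one fusion window long")
    truth = np.concatenate(truth_all)
    gnb = fit_gnb(
        obs_all,
        truth,
        sigma_floor=cfg.fusion.sigma_floor,
        shared_attr_params=cfg.fusion.shared_attr_params,
    )
    gnb.meta.update(_meta(cfg))
    if out_json is not None:
        gnb.to_json(out_json)
    return gnb


def run_fuse(
    cfg: RunConfig,
    gnb: GaussianNBModel,
    stream_table: pd.DataFrame,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Windowed MAP fatigue decisions for every subject stream."""
    frames = []
    for subject, group in stream_table.groupby("subject_id", sort=True):
        if len(group) < cfg.fusion.window_clips:
            continue
        obs = compute_window_scores(_stream_of(group), cfg.fusion)
        decisions = [infer_state(gnb, o, cfg.fusion) for o in obs]
        df = decisions_to_frame(obs, decisions)
        df.insert(0, "subject_id", subject)
        df["truth"] = _window_truth(
            group["state"].to_numpy(int), cfg.fusion.window_clips
        )
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


def run_evaluate(
    cfg: RunConfig,
    stream_table: pd.DataFrame,
    decision_table: pd.DataFrame,
    out_dir: str | Path | None = None,
) -> dict:
    """Compute the full metric report (clip-level symptoms + window-level
    state), write report.json, the per-subject table and one
    probability-time curve per run directory."""
    report: dict = {"meta": _meta(cfg)}

    labels = stream_table[["label_eye", "label_mouth"]].to_numpy(int)
    probs = stream_table[["p_eye", "p_mouth"]].to_numpy(float)
    preds = (probs > 0.5).astype(int)
    clip: dict = {}
    for j, name in enumerate(("eye", "mouth")):
        c = confusion_counts(preds[:, j], labels[:, j])
        clip[name] = metrics(c).as_dict()
        if labels[:, j].min() != labels[:, j].max():
            _, _, auc = roc_points(probs[:, j], labels[:, j])
            clip[name]["roc_auc"] = auc
    clip["multilabel_accuracy"] = float((preds == labels).mean())
    clip["exact_match_accuracy"] = float((preds == labels).all(axis=1).mean())
    clip["n_clips"] = int(labels.shape[0])
    report["clip_symptoms"] = clip

    pred_state = decision_table["state"].to_numpy(int)
    truth = decision_table["truth"].to_numpy(int)
    state_counts = confusion_counts(pred_state, truth)
    report["fatigue_state"] = {
        **metrics(state_counts).as_dict(),
        "n_windows": int(truth.size),
        "constraint_fired_windows": int(decision_table["constraint_fired"].sum()),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_subject_accuracy(
            pred_state,
            truth,
            decision_table["subject_id"].to_numpy(),
            out_csv=out_dir / "per_subject_accuracy.csv",
        )
        first_subject = stream_table["subject_id"].iloc[0]
        export_probability_curve(
            _stream_of(stream_table[stream_table["subject_id"] == first_subject]),
            out_dir / "probability_curve.csv",
        )
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
    return report


def run_e2e(cfg: RunConfig) -> dict:
    """Chain simulate -> train -> infer -> fit-fusion -> fuse -> evaluate."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    _write_meta(cfg, run_dir)
    data_dir = run_simulate(cfg)
    ckpt = run_train(cfg, data_dir)
    train_streams = run_infer(cfg, ckpt, data_dir, split="train")
    val = cfg.synthetic.splits.get("val", 0)
    if val > 0:
        val_streams = run_infer(cfg, ckpt, data_dir, split="val")
        fit_streams = pd.concat([train_streams, val_streams], ignore_index=True)
    else:
        fit_streams = train_streams
    gnb = run_fit_fusion(cfg, fit_streams, out_json=run_dir / "fusion_model.json")
    test_streams = run_infer(
        cfg, ckpt, data_dir, split="test", out_csv=run_dir / "test_streams.csv"
    )
    decisions = run_fuse(cfg, gnb, test_streams, out_csv=run_dir / "decisions.csv")
    return run_evaluate(cfg, test_streams, decisions, out_dir=run_dir)
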