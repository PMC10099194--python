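"""Fatigue-state inference: constrained Gaussian naive-Bayes MAP fusion.

Windowed eye/mouth symptom scores (a_e, a_m) are fused into a binary
fatigue state s by maximum a posteriori under a naive independence
assumption:

    s* = argmax_s  P(s) * P(a_e | s) * P(a_m | s) / P(a_e, a_m)
         subject to  a_m * a_e * (s - 1) = 0

with Gaussian class-conditionals P(a_i | s) = N(a_i; mu_is, sigma_is).
The side condition is a human-experience rule: when both symptoms are
simultaneously active (read as binarized indicators), the only admissible
state is s = 1 — a subject who keeps their eyes closed *and* yawns within
the same window is declared fatigued no matter what the data-driven
posterior says.

The window score itself is an appearance frequency: the fraction of clips
in a sliding window whose predicted symptom probability exceeds a
threshold, which averages out isolated misclassifications.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import SymptomStream

__all__ = [
    "SymptomObservation",
    "GaussianNBModel",
    "FusionConfig",
    "FatigueDecision",
    "compute_window_scores",
    "fit_gnb",
    "gnb_posterior",
    "apply_constraint",
    "infer_state",
    "decisions_to_frame",
]

_ATTRS = ("e", "m")


@dataclass(frozen=True)
class SymptomObservation:
    """One windowed symptom-score pair, the observable set {a_e, a_m}."""

    a_e: float
    a_m: float
    window: tuple[int, int] = (0, 1)

    def __post_init__(self):
        if not (np.isfinite(self.a_e) and np.isfinite(self.a_m)):
            raise ValueError("symptom scores must be finite")
        if self.window[1] <= self.window[0]:
            raise ValueError(f"empty window {self.window}")

    @property
    def scores(self) -> np.ndarray:
        return np.array([self.a_e, self.a_m])


@dataclass
class GaussianNBModel:
    """State priors and per-attribute-per-state Gaussian parameters.

    prior: (2,) over states (0 normal, 1 fatigued). mu/sigma: (2, 2)
    indexed [attribute, state], attribute 0 = eye, 1 = mouth. The evidence
    P(a_e, a_m) is never computed explicitly; posterior normalization over
    the two states realizes it.
    """

    prior: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.prior = np.asarray(self.prior, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.prior.shape != (2,) or np.any(self.prior < 0) or abs(self.prior.sum() - 1) > 1e-9:
            raise ValueError("prior must be a length-2 distribution")
        if self.mu.shape != (2, 2) or self.sigma.shape != (2, 2):
            raise ValueError("mu and sigma must be (2, 2): [attribute, state]")
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma must be > 0")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "prior": self.prior.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "attributes": list(_ATTRS),
            "states": ["normal", "fatigued"],
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GaussianNBModel":
        d = json.loads(Path(path).read_text())
        return cls(prior=d["prior"], mu=d["mu"], sigma=d["sigma"], meta=d.get("meta", {}))


@dataclass
class FusionConfig:
    """Windowing and constraint parameters.

    window_clips: W, clips per sliding window (stride 1).
    score_mode: 'appearance_frequency' (fraction of clips with p_i >
    frame_threshold) or 'mean_probability'.
    frame_threshold: tau, per-clip probability cut for frequency scoring.
    constraint_threshold: theta, score cut binarizing a_i for the
    experience constraint.
    tie_break: state returned on an exact posterior tie (0 = conservative).
    """

    window_clips: int = 4
    score_mode: str = "appearance_frequency"
    frame_threshold: float = 0.5
    constraint_threshold: float = 0.5
    tie_break: int = 0
    sigma_floor: float = 0.125
    shared_attr_params: bool = False

    def __post_init__(self):
        if self.window_clips < 1:
            raise ValueError("window_clips must be >= 1")
        if self.score_mode not in ("appearance_frequency", "mean_probability"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")
        for name in ("frame_threshold", "constraint_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.tie_break not in (0, 1):
            raise ValueError("tie_break must be 0 or 1")


@dataclass
class FatigueDecision:
    """Inferred state with its posterior and constraint bookkeeping."""

    state: int
    posterior: np.ndarray  # (P(normal | A), P(fatigued | A))
    constraint_fired: bool
    window: tuple[int, int]

    def __post_init__(self):
        self.posterior = np.asarray(self.posterior, dtype=float)
        if abs(self.posterior.sum() - 1.0) > 1e-9:
            raise ValueError("posterior must sum to 1")
        if self.constraint_fired and self.state != 1:
            raise ValueError("a fired constraint forces state 1")


def compute_window_scores(
    stream: SymptomStream, cfg: FusionConfig
) -> list[SymptomObservation]:
    """Slide a W-clip window (stride 1) over a stream; one observation each.

    appearance_frequency: a_i = fraction of the window's clips with
    p_i > frame_threshold; mean_probability: a_i = mean p_i. Either way
    the scores lie in [0, 1]. A stream of length L yields L - W + 1
    observations.
    """
    n = len(stream)
    w = cfg.window_clips
    if n == 0:
        raise ValueError("empty stream")
    if w > n:
        raise ValueError(f"window_clips={w} exceeds stream length {n}")
    p = np.column_stack([stream.p_eye, stream.p_mouth])
    if cfg.score_mode == "appearance_frequency":
        vals = (p > cfg.frame_threshold).astype(float)
    else:
        vals = p
    # sum first, divide once: keeps count/W frequencies exact dyadic ratios
    kernel = np.ones(w)
    means = np.column_stack(
        [np.convolve(vals[:, j], kernel, mode="valid") for j in range(2)]
    ) / w
    means = np.clip(means, 0.0, 1.0)
    return [
        SymptomObservation(a_e=float(means[k, 0]), a_m=float(means[k, 1]), window=(k, k + w))
        for k in range(n - w + 1)
    ]


def fit_gnb(
    observations: "list[SymptomObservation] | np.ndarray",
    state_labels: np.ndarray,
    sigma_floor: float = 1e-6,
    shared_attr_params: bool = False,
) -> GaussianNBModel:
    """Fit priors and Gaussian class-conditionals from labelled windows.

    prior = empirical state frequencies; mu/sigma = per-attribute,
    per-state sample mean and population (divide-by-n) standard
    deviation, floored at sigma_floor. ``shared_attr_params`` pools the
    two attributes into a single (mu_s, sigma_s) per state — the literal
    single-index reading of the model — at the cost of collapsing the
    attribute distinction; the default keeps them separate, the standard
    Gaussian naive-Bayes parameterization.
    """
    obs = _as_array(observations)
    y = np.asarray(state_labels, dtype=int)
    if obs.shape[0] != y.shape[0]:
        raise ValueError("observations and state_labels differ in length")
    counts = np.bincount(y, minlength=2)
    if np.any(counts < 2):
        raise ValueError(
            f"need >= 2 observations per state, got counts {counts.tolist()}"
        )
    prior = counts / counts.sum()
    mu = np.empty((2, 2))
    sigma = np.empty((2, 2))
    floored = []
    for s in (0, 1):
        block = obs[y == s]
        if shared_attr_params:
            mu[:, s] = block.mean()
            sigma[:, s] = block.std()
        else:
            mu[:, s] = block.mean(axis=0)
            sigma[:, s] = block.std(axis=0)
        for i in (0, 1):
            if sigma[i, s] < sigma_floor:
                if sigma[i, s] < 1e-12:
                    floored.append((_ATTRS[i], s))
                sigma[i, s] = sigma_floor
    if floored:
        import warnings

        warnings.warn(
            f"zero-variance attribute(s) floored at {sigma_floor}: {floored}",
            stacklevel=2,
        )
    return GaussianNBModel(
        prior=prior,
        mu=mu,
        sigma=sigma,
        meta={
            "n": int(obs.shape[0]),
            "sigma_floor": sigma_floor,
            "shared_attr_params": shared_attr_params,
        },
    )


def _as_array(observations) -> np.ndarray:
    if isinstance(observations, np.ndarray):
        return np.asarray(observations, dtype=float)
    return np.array([[o.a_e, o.a_m] for o in observations], dtype=float)


def _log_normal_pdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    return -0.5 * np.log(2.0 * np.pi * sigma**2) - (x - mu) ** 2 / (2.0 * sigma**2)


def gnb_posterior(model: GaussianNBModel, obs: SymptomObservation) -> np.ndarray:
    """Posterior (P(s=0 | a_e, a_m), P(s=1 | a_e, a_m)).

    Computed in log-space and normalized over the two states, which
    realizes the evidence denominator without ever forming it. A state
    with prior 0 keeps posterior 0 for every observation.
    """
    a = obs.scores  # (2,)
    with np.errstate(divide="ignore"):
        log_prior = np.log(model.prior)
    log_lik = _log_normal_pdf(a[:, None], model.mu, model.sigma).sum(axis=0)  # (2,)
    log_post = log_prior + log_lik
    if np.all(np.isinf(log_post)):  # both states impossible: fall back to prior
        return model.prior.copy()
    log_post -= log_post.max()
    post = np.exp(log_post)
    return post / post.sum()


def apply_constraint(
    obs: SymptomObservation, map_state: int, cfg: FusionConfig
) -> tuple[int, bool]:
    """Apply the experience rule a_m * a_e * (s - 1) = 0.

    Scores are binarized at constraint_threshold; if both indicators are
    active the product can only vanish with s = 1, so the fatigued state
    is forced regardless of the MAP argmax. constraint_fired records
    whether the rule actually overrode the MAP state.
    """
    both_active = obs.a_e > cfg.constraint_threshold and obs.a_m > cfg.constraint_threshold
    if both_active and map_state != 1:
        return 1, True
    return (1 if both_active else map_state), False


def infer_state(
    model: GaussianNBModel, obs: SymptomObservation, cfg: FusionConfig
) -> FatigueDecision:
    """MAP state for one observation, with tie-break and constraint."""
    post = gnb_posterior(model, obs)
    if post[0] == post[1]:
        map_state = cfg.tie_break
    else:
        map_state = int(post[1] > post[0])
    state, fired = apply_constraint(obs, map_state, cfg)
    return FatigueDecision(state=state, posterior=post, constraint_fired=fired, window=obs.window)


def decisions_to_frame(
    observations: list[SymptomObservation], decisions: list[FatigueDecision]
) -> pd.DataFrame:
    """Tabulate windowed decisions for CSV export."""
    return pd.DataFrame(
        {
            "window_start": [o.window[0] for o in observations],
            "window_end": [o.window[1] for o in observations],
            "a_e": [o.a_e for o in observations],
            "a_m": [o.a_m for o in observations],
            "post_normal": [d.posterior[0] for d in decisions],
            "post_fatigued": [d.posterior[1] for d in decisions],
            "state": [d.state for d in decisions],
            "constraint_fired": [d.constraint_fired for d in decisions],
        }
    )
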