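# Methods

## Problem and pipeline

The package infers a binary fatigue state from face video by composing two
stages with different epistemic roles. A discriminative stage detects
*symptoms*: short facial micro-actions — prolonged eye closure (eye
anomaly) and yawning (mouth anomaly) — at the granularity of fixed-length
clips. A generative stage then *explains* windows of symptom detections
with a two-state probabilistic model, so that every alarm decomposes into
"how often each symptom appeared" and "how probable each state makes that
pattern". Head-pose cues are deliberately excluded: they are
viewpoint-sensitive and unreliable in uncontrolled camera setups.

## Symptom classifier

Clips are face-cropped and reduced to `T = 8` frames by segment-based
sampling: the clip is split into 8 near-equal temporal spans (remainder to
the leading spans) and one frame is taken per span — the span center at
inference, a uniform draw within the span during training, a standard
train/test asymmetry that acts as temporal augmentation.

The backbone is a residual CNN whose residual branches open with a
temporal shift: with per-direction fraction `f = 1/8`, the first `⌊C/8⌋`
channels of a `(N, T, C, H, W)` feature map take their value from frame
`t+1`, the next `⌊C/8⌋` from frame `t−1`, boundary slots become zero, and
the rest pass through. The shift moves values without arithmetic, so
temporal context is free of parameters; placing it inside the residual
branch (the residual variant) keeps the identity path intact. Two profiles
share this design:

- **micro** (default): stem convolution (stride 2) + 2×2 max-pool, then
  three shifted residual stages of widths 16/32/32 with strides 2/2/1;
  global average pooling, a temporal mean, and a 2-logit linear head.
  ~37k parameters, trainable from scratch on one CPU in seconds per epoch.
- **resnet50**: standard bottleneck stage layout (3/4/6/3 blocks, widths
  256–2048) with shifts in the last three stages and a hook for loading
  externally supplied pretrained weights. This is the scale-up
  configuration for real video; nothing in this repository trains it.

The networks are implemented directly in numpy with hand-written
backpropagation (im2col convolution, batch normalization, ReLU, pooling,
linear). Correctness is established by two-sided finite-difference
gradient checks in float64 on every layer and on the full micro network;
agreement is ~1e-7 relative.

**Loss.** Weighted multilabel sigmoid cross-entropy: per class `j` the
positive term is scaled by `p_j` (default: inverse positive-class
frequency of the training manifest, capped at 10) and an L2 penalty
`λ Σ‖θ‖²` with `λ = 1e-4` covers convolution and head weights (not
BatchNorm affine parameters or biases, which standard practice leaves
unregularized). The implementation uses softplus identities
(`−log σ(x) = softplus(−x)`), exact but overflow-free. Only the positive
term carries `p_j`: the weighting sharpens recall of rare symptoms without
inflating false-alarm pressure.

**Optimization.** Momentum SGD (momentum 0.9). `TrainConfig` defaults to
the reference recipe (learning rate 2.5e-3, 120 epochs) appropriate for a
pretrained large backbone; the micro desk-scale profile instead uses
learning rate 0.02, batch size 8, 30 epochs — a from-scratch recipe for a
small normalized network on easy synthetic data, chosen once. Shuffling
and segment sampling are re-seeded per epoch from `(seed, epoch)`, which
makes training bit-reproducible on CPU and resumable from any checkpoint
without storing generator state.

## MAP fusion

Per subject, clip-level symptom probabilities form a time-ordered stream.
A sliding window of `W` clips (stride 1) is summarized by the *appearance
frequency* `a_i` = fraction of clips with `p_i > τ` (τ = 0.5); frequency,
rather than the raw probability mean, suppresses isolated
misclassifications by averaging. The fatigue state maximizes the
naive-Bayes posterior with Gaussian class-conditionals `N(a_i; μ_is,
σ_is)`, fitted as empirical state frequencies (prior) and per-attribute,
per-state sample means and population standard deviations. Posteriors are
computed in log-space and normalized over the two states, which realizes
the evidence term exactly; ties break to the normal state (conservative
alarm policy).

Two parameterization notes. First, a single-index reading of the
class-conditional parameters (one `(μ_s, σ_s)` shared by both attributes)
collapses the two-attribute model into a function of an exchangeable pair;
the default therefore keeps per-attribute parameters, with
`shared_attr_params=True` available to reproduce the shared reading.
Second, the experience constraint `a_m · a_e · (s−1) = 0` is applied to
*binarized* indicators (`a_i > θ`, θ = 0.5): the product form is only
meaningful for 0/1 values, whereas the Gaussian model treats scores as
continuous. When both indicators are active the constraint admits only
`s = 1`, so the fatigued state is forced and the decision records that the
override happened.

**Window length and variance floor.** `W` and the run-level σ floor are
not dictated by the model, so they were set by a calibration study run on
ground-truth label streams (independent of any trained classifier or test
seed), sweeping `W` and the floor over subject-block simulations of the
synthetic cohort. Two effects dominate. (1) Appearance frequencies live on
the grid `{0, 1/W, …, 1}`; a Gaussian fitted to near-constant normal-state
frequencies becomes arbitrarily tight, making a single symptomatic clip
(frequency `1/W`) look like overwhelming fatigue evidence. Flooring σ at
half the grid step, `0.5/W`, removes this failure mode and is insensitive
to the exact value across a wide plateau. (2) With the window truth
defined by majority vote over clip states, an even `W = 4` (tie counts as
fatigued) aligns the truth rule with the observable marginal frequencies
almost perfectly (Bayes accuracy 0.998 in simulation), and the floored
Gaussian model attains that ceiling. Defaults: `W = 4`, run-level
`sigma_floor = 0.125`; the bare fitting function keeps a 1e-6 floor so
degenerate inputs fail loudly rather than silently smoothing.

## Synthetic data

The generator emulates the structure the pipeline consumes, not
photorealism:

- **Behavior scripts.** Per event type, the episode count is
  Poisson(rate × frames); onsets are uniform with overlap rejection within
  a type, keeping the analytic expectation exact. Default rates 0.004
  (eye closure) and 0.002 (yawn) per frame with durations 25–75 and 50–125
  frames at a 25 fps convention — about 1–3 s closures and 2–5 s yawns,
  the physiological range for drowsy micro-sleep and yawning — yield
  roughly a third symptomatic clips.
- **Rendering.** Schematic grayscale faces (ellipse head, two eye blobs,
  one mouth blob) at 64×64: eyes collapse to slits during closures, the
  mouth elongates during yawns. Per-clip center jitter (±3 px) and
  illumination (0.7–1.0) plus per-frame Gaussian pixel noise (σ = 4)
  emulate recordings at different times and angles. The rendered face box
  is stored as clip metadata; the pluggable face detector falls back to it
  (or to a centered square) so the repository needs no detector download.
- **Labels.** A clip is positive for a symptom when ≥ 50% of its frames
  lie inside an episode of that type; a clip is *fatigued* when it carries
  either symptom label; a window is fatigued when at least half its clips
  are (ties toward fatigued). Defining the state from the symptom labels
  keeps the ground truth recoverable from what the fusion stage can
  observe.
- **Score streams.** For testing the fusion stage in isolation,
  `(a_e, a_m)` pairs are drawn directly from the Gaussian
  class-conditional model (untruncated, matching its support), with
  defaults placing fatigued means well above normal ones at overlapping
  spread.
- **Cohorts.** Subjects are assigned to splits before any clip is cut
  (subject-disjoint, emulating train/test cohorts from different
  recording campaigns); manifests regenerate byte-identically from a seed.

What passing tests on this data do and do not show: they verify the
*mechanics* — that the classifier can learn spatio-temporal symptom
patterns, that the fusion model is calibrated and constraint-dominant,
that every metric matches its independent oracle — under clean geometry
and known noise. They do not certify performance on real faces, real
illumination, occlusions (glasses, hands), head pose, or detector failure;
the symptom task here is far easier than in the wild.

## Problem sizes and reproducibility

The desk-scale study conditions are 10 subjects × 20 clips × 16 frames at
64 px (200 clips, 5/2/3 subject split), micro backbone on 8 sampled
frames, 30 training epochs — the end-to-end run takes ~30 s on one CPU.
One global seed fans out to named substreams (dataset, initialization,
training, sampling) hashed below 2³¹; artifacts carry the tool version,
seed and a hash of the scientific configuration, and two runs with one
seed produce byte-identical reports.

## Numerical choices

- Posterior agreement with the naive product-then-normalize oracle is
  ~1e-15; the log-space path exists for observations where the naive form
  underflows.
- ROC sweeps visit each distinct score once; tied scores enter en bloc and
  contribute diagonal segments, so the trapezoidal area equals the
  pairwise-comparison probability with ties at ½.
- 0/0 metric ratios (e.g., precision with no positive predictions) are
  reported as `None`/JSON `null`, never as 0.
- Appearance frequencies are computed as integer window sums divided once
  by `W`, keeping values like 3/4 exact in binary.
- Frame/pixel coordinates and windows are 0-based and half-open
  throughout.

## Known limitations

- The micro profile is a capacity floor, not a recognition model; real
  deployments need the resnet50 profile with pretrained weights and a real
  face detector behind the provided interface.
- The Gaussian class-conditional is a convenience approximation to
  bounded, gridded frequencies; it is adequate after variance flooring but
  a beta or categorical conditional would match the support.
- The naive independence assumption double-counts evidence when the same
  clips raise both symptom scores; the experience constraint mitigates
  only the co-active corner.
- Fatigue is modeled as binary; the fatigued posterior is exported as a
  continuous severity proxy but is not calibrated across subjects.
- Video-container input depends on an optional imageio ffmpeg plugin;
  directory-of-PNG is the format of record.
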