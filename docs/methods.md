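# Methods

This package predicts whether a lung nodule followed over serial CT is an
invasive adenocarcinoma (IA) or a pre-/minimally-invasive lesion (AAH, AIS,
MIA), using the *whole* irregularly sampled follow-up series rather than a
single scan. This note documents the models, the training protocol, the
synthetic cohort generator that makes everything testable without clinical
data, and the numerical choices — including what the synthetic results do
and do not say about real data.

## The prediction problem

A follow-up series is an ordered set of 2–11 CT examinations of one nodule,
with elapsed days `t_0 = 0 < t_1 < … < t_{T-1}` (consecutive scans ≥ 30 days
apart when only two exist), a voxel-level VOI mask per scan, and one
pathology label per nodule. Irregular sampling is the defining difficulty:
disease progression is a per-day process, but the observation grid is
arbitrary, so a model that ignores the time stamps conflates "grew a lot"
with "was followed for long".

## ViSTA: CNN encoder + SimTA temporal attention

**Patch encoder.** Each scan is resampled to 1 mm isotropic spacing
(trilinear; nearest-neighbour for masks), clipped to (−1000, 400) HU,
min–max normalized to (0, 1), and cropped to a 32 mm cube centred on the
VOI centroid. A four-stage 3D CNN encodes the patch: a non-overlapping
4×4×4 patchify convolution (stride 4), then three 3×3×3 stride-2
convolutions (channels 8-16-32-64), each with batch normalization and ReLU,
global average pooling, and a linear projection to D = 64 features. The
patchify stem was chosen because its im2col is a pure reshape — on a CPU
this is the difference between minutes and hours for the full benchmark —
and at these patch sizes no accuracy cost was observed relative to a
stride-2 stem.

**SimTA (Simple Temporal Attention).** At step j the attention on an
earlier step i is a causal softmax over scores

    s[j, i] = − softplus(λ) · (t_j − t_i) / τ ,   i ≤ j,

with τ = 30 days per attention unit. The weights therefore decay
exponentially with elapsed time, later steps never receive less weight than
earlier ones, rows sum to one, and only pairwise time differences matter
(predictions are invariant to shifting all dates). Attention is purely
time-driven: there are no query/key content terms, only a learned value
projection.

Each layer carries a *vector* of learnable rates λ ∈ R^D — one per feature
channel, initialized log-spaced over [0.02, 2] per unit (decay scales of
roughly two weeks to four years). One layer thus summarizes the history at
D parallel time scales, a Laplace-transform-like temporal basis from which
per-day rates are linearly decodable; with a single shared rate the scalar
λ receives almost no gradient and the model cannot separate "how much
changed" from "over how long". A scalar-rate mode (`rate_per_channel=False`)
is retained, and the public `simta_attention(times, rate, time_scale)`
helper computes the scalar-rate matrix used throughout the tests.

A SimTA layer computes `h = LN(x + Drop(A ⊙ V(x)))` followed by a
position-wise feed-forward block `h ← LN(h + Drop(FFN(h)))` with expansion
×1. Expansion ×1 (not the more common ×2) keeps the two-layer SimTA module
strictly smaller than the matched-width LSTM module (25.5k vs 33.1k
parameters at D = 64) — the attention module is meant to be the
*lightweight* alternative, and the package asserts that inequality
structurally.

**Head.** A linear-sigmoid head maps every step's representation to an IA
probability; the series-level prediction is the final step's. Per-prefix
probabilities are exposed (they are what the saliency analysis plots over a
series).

## Counterpart methods

* **1/VDT** — volume doubling time in the Schwartz exponential form
  `VDT = Δt · ln 2 / ln(v2/v1)` between the first and last scan (one value
  per nodule; first/last maximizes Δt and stability). Ranking uses 1/VDT so
  stable (1/VDT = 0) and shrinking (negative) nodules order below all
  growers. Two cutoffs: the fixed 400-day fast-growth convention
  (positive iff 0 < VDT < 400 d) and the best-Youden threshold calibrated
  on the validation split.
* **Static CNNs** — the shared backbone plus a linear-sigmoid head on a
  single patch; trained on the first scan, the last scan, or every scan as
  an independent sample (series label), evaluated on one stated scan per
  nodule.
* **CNN+LSTM** — the shared backbone feeding a single-layer LSTM
  (hidden = 64) in visit order; the time stamps are never consumed, making
  the model *interval-blind* by construction (asserted in tests: rescaling
  all dates leaves its output bit-identical, while ViSTA's changes).

## Training protocol

All networks train end-to-end with AdamW (β = (0.9, 0.99), decoupled weight
decay 0.01), cosine learning-rate decay `lr(e) = lr_min + (lr_max −
lr_min)(1 + cos(π e/E))/2` from 1e-3 to 1e-6, batch size 32 series (or
scans, for static CNNs), dropout 0.2, binary cross-entropy on the
series-level logit, global gradient-norm clipping at 5, and a 2-epoch
linear learning-rate warmup (LayerNorm/attention stacks can otherwise start
in a dead basin at the full initial rate). β₂ = 0.99, clipping and warmup
matter because a 20-epoch budget on 245 series is only ~160 updates. The
checkpoint with the best validation AUC is kept (`model_selection="final"`
is available).

Sequence models additionally receive a per-step auxiliary loss (weight 0.5)
supervising every prefix's logit with the series label. Without it the
backbone receives gradient almost exclusively through the final scan and
both sequence models underfit their own input; it is applied symmetrically
to ViSTA and CNN+LSTM so their comparison stays fair. Static CNNs have
nothing to deep-supervise and train on the plain loss.

Train-time augmentation: random cube flips (one draw per series, shared
across its scans so longitudinal comparisons stay spatially aligned) plus
additive Gaussian intensity noise (σ = 0.02 normalized units ≈ 28 HU,
fresh per scan). At cohort sizes of a few hundred series a 3D CNN otherwise
memorizes each patch's noise fingerprint within ~8 epochs and test
performance collapses; with augmentation, train AUC tracks validation.

Every run is a pure function of (config, seed): parameter init, batching,
dropout, and augmentation all derive from one root generator.

## The synthetic cohort generator

The generator renders spherical nodule phantoms — a ground-glass shell
(−600 HU) with a concentric solid core (0 HU) on uniform parenchyma
(−850 HU), Gaussian image noise σ = 30 HU — on 48³ grids at 1 mm (an
anisotropic 1×1×1.5 mm mode exercises resampling), grown over an irregular
visit schedule.

**Schedules.** Visit count uniform on 2–11. Each series draws its own
follow-up intensity (gap scale lognormal, median 45 d, σ = 1.3); gaps
scatter around it (lognormal, σ = 0.9), clipped to [30, 900] d, spans
capped at 2813 d by rejection. This
reproduces the target cohort's first-to-last span statistics (median ≈ 366
d, IQR within the reported 165–852 range) while keeping visit count a poor
proxy for elapsed time — which is what makes the time stamps genuinely
informative. Schedule parameters were calibrated once against those summary
statistics by Monte-Carlo and then frozen.

**Kinetics and label.** Volume follows `v(t) = v0 · 2^(t/dt)` (Gompertz
saturation available), v0 log-uniform on [150, 1500] mm³ — small enough to
be early lesions, large enough (radius ≥ ~3 mm) that 1 mm voxelization can
track growth. Doubling time: static with p = 0.3, fast (log-uniform
[120, 380] d) with p = 0.15, else slow ([450, 2200] d). The solid core has
a baseline fraction (uniform [0, 0.6]; stable dense nodules are deliberate
granuloma-like confusers) and a latent transformation speed: zero with
p = 0.25, invasive-fast (log-uniform [0.25, 1]/yr) with p = 0.35, else
indolent ([0.03, 0.18]/yr). A nodule is IA iff it grows fast
(dt < 400 d) or solidifies fast (> 0.2/yr), plus 5 % label noise; cohort
prevalence is fixed at 160/351 by per-class rejection so within-class
diversity is preserved. Follow-up truncates once the nodule outgrows the
renderable grid (clinically: fast growers are resected, not observed for
years), keeping labels consistent with what is rendered.

**Measurement noise.** Each rendered scan carries delineation error:
relative volume jitter (σ = 10 %) and absolute solid-fraction jitter
(σ = 0.07). This is what makes two-point VDT unreliable over short
intervals while multi-scan models can average it out.

**Why this structure.** The discriminative information was verified with
feature-oracle probes (gradient boosting on handcrafted features, measured
on large kinetics-only cohorts): static snapshot features reach AUC ≈ 0.77,
order-only serial features ≈ 0.79, time-aware features ≈ 0.87, and two-point
1/VDT ≈ 0.62 — the same qualitative ladder as the clinical study this
design emulates (60.6 / 75.9 / 78.3 / 86.4). An earlier, more naive design
(class-conditional draws, label = state not rate) was nearly solvable by
any single observable and was replaced; that analysis, not any model's test
result, drove the final parameter choices.

**What the generator does not emulate** — and hence what passing tests do
*not* show: lung anatomy (vessels, bronchi, pleura), real attenuation
texture, scanner/reconstruction effects, reader variability in VOI
delineation beyond isotropic jitter, registration error between visits, and
any biology beyond exponential growth with linear solid transformation.
Synthetic benchmark numbers characterize the *methods' relative ability to
use interval structure*, not clinical performance.

## Evaluation

AUC is the rank statistic (pairwise concordance with ties counting ½;
asserted equal to a brute-force oracle for n ≤ 50). Thresholded metrics
report the full confusion matrix; undefined ratios (zero denominators) are
reported as missing, never coerced to 0. The operating threshold is the
best-Youden cutoff (J = sensitivity + specificity − 1) on the validation
split, applied unchanged to the test split; the cutoff search scans
midpoints between adjacent distinct scores plus ±∞ and breaks ties toward
the smaller threshold (asserted equal to exhaustive search). The comparison
table carries three radiologist reference rows (senior, two juniors) as
fixed constants from the source observer study; they are reporting
references only and enter no computation.

## Scaled-down benchmark

The default study conditions are 351 series at prevalence 160/351, a
nodule-level stratified 245/37/69 train/validation/test split (largest
remainder rounding; exact when n·fraction is integral), 32³ patches, and a
20-epoch budget — sized so the full multi-seed comparison runs on one CPU
in minutes. With a 69-series test set the standard error of an AUC is
roughly 0.04–0.06, and the serial-vs-static margin in the emulated study is
itself only ~2.5 points, so single-seed orderings between adjacent methods
are noisy; the package reports multi-seed results for that reason.

At this training scale the attention model and the recurrent baseline land
close together (the attention model with distinctly lower seed-to-seed
variance), and their per-seed ordering is not reliable even across five
seeds — a known limitation of the desk-scale protocol rather than of the
data, whose feature-level ceilings clearly separate time-aware from
interval-blind reading. Users who need stable model comparisons should
average over seeds and/or raise the epoch budget.

## Numerical choices and degenerate inputs

* HU clipping implements the open intervals "(−1000, 400)"/"(0, 1)" as
  closed clipping; boundary inclusion is numerically immaterial.
* Causal masking uses additive −1e9 scores (exactly zero weight after
  softmax to float precision); softmax subtracts a detached row max.
* `v2 == v1` maps to 1/VDT = 0, VDT = +∞; shrinkage keeps its negative
  sign so ROC analysis never drops a nodule.
* Empty masks, non-positive volumes or intervals, one-class metric inputs,
  series with < 2 scans, and 2-scan series < 30 days apart raise
  `ValueError` with specific messages.
* Patch centroids round half-up (half-even rounding breaks translation
  equivariance for symmetric masks).
* LayerNorm/BatchNorm ε = 1e-5; BatchNorm keeps running statistics
  (momentum 0.1) for deterministic inference; forget-gate bias init 1.
* All network arithmetic is float32; float64 is supported end-to-end and
  used by the finite-difference gradient tests.

## Saliency

The map at time point k is |∂p/∂patch_k| of the final-step IA probability
(pre-sigmoid logit behind a flag), clipped to [0, 0.01] for display with a
colour scale fixed across a series; raw maps are kept for re-scaling.
Display uses the axial slice through the patch centre. Because attention is
causal with exponential decay, a fast-decay model provably allocates
negligible gradient mass to non-final scans (asserted numerically), and on
synthetic fast-growing series the late scans dominate the saliency mass.

## Known limitations

* The autodiff engine is minimal by design: no graph fusion, no
  mixed precision, CPU only; training scale is hundreds of series.
* Spherical two-compartment phantoms cannot probe texture-based features;
  a model relying solely on morphology cannot be distinguished here from
  one using attenuation statistics.
* The LSTM baseline shares the trainer and backbone but not the attention
  module's inductive bias; capacity is matched only approximately
  (matched widths).
* Radiologist reference values are external constants; no reader study is
  reproduced.
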