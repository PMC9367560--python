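"""Training harness and evaluation stack.

Training follows a fixed protocol: AdamW, cosine learning-rate decay from
1e-3 to 1e-6, batch size 32, weight decay 0.01, dropout 0.2, binary
cross-entropy on the series-level logit, with the checkpoint selected by
best validation AUC.  Evaluation covers threshold-free (ROC/AUC) and
thresholded metrics (accuracy, precision, sensitivity, specificity, F1),
Youden-index cutoff selection, and a comparison table against fixed
radiologist reference operating points.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score, roc_curve

from . import nn
from ._autodiff import Tensor, bce_with_logits, no_grad, stack
from .preprocess import FollowUpSeries

POSITIVE_LABEL = "IA"

#: Radiologist operating points from the source study's observer reading of
#: the 69-series test set (fixed reference constants for reporting only).
RADIOLOGIST_REFERENCE = {
    "Senior": {"accuracy": 0.855, "precision": 0.824, "sensitivity": 0.875,
               "f1": 0.848},
    "Junior 1": {"accuracy": 0.754, "precision": 0.742, "sensitivity": 0.719,
                 "f1": 0.730},
    "Junior 2": {"accuracy": 0.710, "precision": 0.731, "sensitivity": 0.594,
                 "f1": 0.655},
}


@dataclass
class TrainConfig:
    """End-to-end training protocol (defaults are the full-scale settings)."""

    epochs: int = 100
    batch_size: int = 32
    lr_max: float = 1e-3
    lr_min: float = 1e-6
    weight_decay: float = 0.01
    dropout: float = 0.2
    seed: int = 0
    model_selection: str = "best_val_auc"   # or "final"
    beta2: float = 0.99          # short schedules need a fast second moment
    grad_clip: float = 5.0       # global gradient-norm ceiling (0 disables)
    aux_step_weight: float = 0.0  # deep supervision on per-prefix logits
    #: train-time augmentation: random cube flips (shared across a series so
    #: longitudinal comparisons stay aligned) + additive intensity noise per
    #: scan.  Essential at cohort sizes where a 3D CNN can memorize every
    #: patch's noise pattern within a few epochs.
    augment: bool = True
    aug_noise_sd: float = 0.02   # in normalized intensity units (~28 HU)
    #: linear learning-rate warmup (epochs); LayerNorm/attention stacks are
    #: unstable at the full initial rate and can start in a dead basin
    warmup_epochs: float = 2.0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_min > self.lr_max:
            raise ValueError("lr_min must not exceed lr_max")


def cosine_lr(epoch: int, cfg: TrainConfig) -> float:
    """Cosine decay lr(e) = lr_min + (lr_max - lr_min) (1 + cos(pi e/E)) / 2."""
    frac = 0.5 * (1.0 + np.cos(np.pi * epoch / cfg.epochs))
    return cfg.lr_min + (cfg.lr_max - cfg.lr_min) * frac


def as_binary_labels(y) -> np.ndarray:
    """Map labels to {0, 1} with IA (or 1/True) as the positive class."""
    y = np.asarray(y)
    if y.dtype.kind in "UOS":
        return (y.astype(str) == POSITIVE_LABEL).astype(int)
    return y.astype(int)


# -- sample plumbing ---------------------------------------------------------

@dataclass
class SeriesSample:
    """One training sample: a (sub)series of patches with its binary label."""

    patches: np.ndarray          # (T, S, S, S)
    times: np.ndarray            # (T,)
    y: int


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _batch_logits(network, samples: list[SeriesSample], dtype,
                  per_step: bool = False):
    """Series-level logits for a batch, with one shared backbone pass.

    With `per_step` additionally returns every sample's per-prefix logits
    (only meaningful for networks exposing `temporal_logits`).
    """
    patches = np.concatenate([s.patches for s in samples]).astype(dtype)
    feats = network.encode(patches)
    logits, steps = [], []
    offset = 0
    for s in samples:
        t = len(s.times)
        sub = feats[offset:offset + t]
        if per_step:
            step_logits = network.temporal_logits(sub, s.times)
            steps.append(step_logits)
            logits.append(step_logits[-1])
        else:
            logits.append(network.temporal_logit(sub, s.times))
        offset += t
    out = stack(logits)
    return (out, steps) if per_step else out


def _augment_sample(s: SeriesSample, rng: np.random.Generator,
                    noise_sd: float) -> SeriesSample:
    """Random cube flips (one draw per series) + per-scan intensity noise."""
    patches = s.patches
    flips = [ax + 1 for ax in range(3) if rng.random() < 0.5]
    if flips:
        patches = np.flip(patches, axis=flips)
    if noise_sd > 0.0:
        patches = patches + rng.normal(0.0, noise_sd,
                                       patches.shape).astype(np.float32)
    return SeriesSample(np.ascontiguousarray(patches), s.times, s.y)


def _clip_gradients(params, max_norm: float):
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad.astype(np.float64) ** 2))
    total = np.sqrt(total)
    if total > max_norm > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def score_samples(network, samples: list[SeriesSample],
                  batch_size: int = 64) -> np.ndarray:
    """Inference-mode series logits."""
    network.eval()
    out = []
    with no_grad():
        for i in range(0, len(samples), batch_size):
            out.append(_batch_logits(network, samples[i:i + batch_size],
                                     network.dtype).data)
    return np.concatenate(out) if out else np.empty(0)


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    val_auc: float | None


def fit_network(network, train_samples: list[SeriesSample],
                val_samples: list[SeriesSample] | None,
                cfg: TrainConfig) -> list[EpochRecord]:
    """Train any encoder+temporal-head network under the shared protocol.

    Returns the per-epoch history; the network is left holding the selected
    checkpoint (best validation AUC, or the final epoch if no validation
    data or `model_selection="final"`).
    """
    if not train_samples:
        raise ValueError("empty training split")
    rng = np.random.default_rng(cfg.seed)
    nn.seed_dropout(network, rng)
    params = network.parameters()
    opt = nn.AdamW(params, lr=cfg.lr_max, betas=(0.9, cfg.beta2),
                   weight_decay=cfg.weight_decay)
    aux = cfg.aux_step_weight if hasattr(network, "temporal_logits") else 0.0
    history: list[EpochRecord] = []
    best_auc, best_state = -np.inf, None
    y_val = np.array([s.y for s in val_samples]) if val_samples else None
    n_batches = max(1, int(np.ceil(len(train_samples) / cfg.batch_size)))
    warmup_steps = max(1, int(round(cfg.warmup_epochs * n_batches)))
    step = 0
    for epoch in range(cfg.epochs):
        base_lr = cosine_lr(epoch, cfg)
        network.train()
        losses = []
        for idx in _iter_batches(len(train_samples), cfg.batch_size, rng):
            step += 1
            opt.lr = base_lr * min(1.0, step / warmup_steps) \
                if cfg.warmup_epochs > 0 else base_lr
            batch = [train_samples[i] for i in idx]
            if cfg.augment:
                batch = [_augment_sample(s, rng, cfg.aug_noise_sd)
                         for s in batch]
            y = np.array([s.y for s in batch])
            if aux > 0.0:
                logits, steps = _batch_logits(network, batch, network.dtype,
                                              per_step=True)
                loss = (1.0 - aux) * bce_with_logits(logits, y)
                step_losses = [bce_with_logits(sl, np.full(sl.shape, s.y))
                               for sl, s in zip(steps, batch)]
                loss = loss + aux * stack(step_losses).mean()
            else:
                logits = _batch_logits(network, batch, network.dtype)
                loss = bce_with_logits(logits, y)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            _clip_gradients(params, cfg.grad_clip)
            opt.step()
            losses.append(float(loss.data))
        val_auc = None
        if val_samples and len(np.unique(y_val)) == 2:
            val_auc = auc(score_samples(network, val_samples), y_val)
            if val_auc > best_auc:
                best_auc = val_auc
                best_state = network.state_dict()
        history.append(EpochRecord(epoch, opt.lr, float(np.mean(losses)), val_auc))
    if cfg.model_selection == "best_val_auc" and best_state is not None:
        network.load_state_dict(best_state)
    nn.seed_dropout(network, None)
    network.eval()
    return history


# -- metrics -----------------------------------------------------------------

@dataclass
class MetricsReport:
    """Threshold-free and thresholded evaluation of one scorer.

    Metrics with a zero denominator are reported as None, never coerced to 0.
    """

    auc: float | None = None
    accuracy: float | None = None
    precision: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    f1: float | None = None
    threshold: float | None = None
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    roc: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("roc")
        return d


def auc(scores, labels) -> float:
    """Area under the ROC curve (pairwise concordance; ties count 1/2)."""
    y = as_binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc_points(scores, labels) -> list[tuple[float, float]]:
    y = as_binary_labels(labels)
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    return list(zip(fpr.tolist(), tpr.tolist()))


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def thresholded_metrics(scores, labels, threshold: float) -> MetricsReport:
    """Confusion-matrix metrics at `threshold` (positive iff score >= it)."""
    scores = np.asarray(scores, dtype=float)
    y = as_binary_labels(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    f1 = None
    if precision is not None and sensitivity is not None \
            and precision + sensitivity > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
        precision=precision, sensitivity=sensitivity,
        specificity=_ratio(tn, tn + fp), f1=f1,
        threshold=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class CutoffRule:
    """A decision threshold on a score (positive iff score >= threshold)."""

    threshold: float
    origin: str = "best_youden"     # {"fixed_400_days", "best_youden"}
    youden: float | None = None


def best_youden_cutoff(scores, labels) -> CutoffRule:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints between adjacent distinct sorted scores plus
    +/- infinity; ties break toward the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = as_binary_labels(labels)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Youden cutoff undefined: only one class present")
    uniq = np.unique(scores)
    candidates = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0,
                                 [np.inf]])
    pred = scores[None, :] >= candidates[:, None]
    tp = (pred & (y == 1)).sum(axis=1)
    tn = (~pred & (y == 0)).sum(axis=1)
    j = tp / n_pos + tn / n_neg - 1.0
    best = int(np.argmax(j))          # argmax takes the first (= smallest)
    return CutoffRule(threshold=float(candidates[best]), origin="best_youden",
                      youden=float(j[best]))


def evaluate_scorer(scores, labels, threshold: float | None = None) -> MetricsReport:
    """Full report: AUC + ROC plus thresholded metrics if a cutoff is given."""
    report = (thresholded_metrics(scores, labels, threshold)
              if threshold is not None else MetricsReport())
    report.auc = auc(scores, labels)
    report.roc = roc_points(scores, labels)
    return report


def compare_report(method_reports: dict[str, MetricsReport],
                   radiologists: dict[str, dict] | None = None,
                   out_dir: str | Path | None = None) -> pd.DataFrame:
    """Comparison table (methods + radiologist reference rows) and ROC figure.

    Radiologist rows are fixed external reference constants and are marked
    as such; they carry no ROC curve, only an operating point.
    """
    rows = []
    for name, rep in method_reports.items():
        rows.append({"method": name, "reference": False, "auc": rep.auc,
                     "accuracy": rep.accuracy, "precision": rep.precision,
                     "sensitivity": rep.sensitivity, "f1": rep.f1})
    for name, vals in (radiologists or {}).items():
        rows.append({"method": name, "reference": True, "auc": None, **vals})
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "comparison.csv", index=False)
        _plot_roc(method_reports, radiologists or {}, out_dir / "roc.png")
    return table


def _plot_roc(method_reports, radiologists, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, rep in method_reports.items():
        if rep.roc:
            fpr, tpr = zip(*rep.roc)
            label = name if rep.auc is None else f"{name} (AUC {rep.auc:.3f})"
            ax.plot(fpr, tpr, label=label)
    for name, vals in radiologists.items():
        spec, sens = vals.get("specificity"), vals.get("sensitivity")
        if spec is not None and sens is not None:
            ax.plot(1 - spec, sens, "o", label=f"{name} (reference)")
    ax.plot([0, 1], [0, 1], ":", color="gray")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# -- sklearn estimator base --------------------------------------------------

class SeriesNetClassifier(BaseEstimator, ClassifierMixin):
    """Base for network classifiers over follow-up series.

    Subclasses build the network and define how series become training and
    evaluation samples.  X is a sequence of FollowUpSeries; y may be omitted
    when the series carry labels.  Validation data for checkpoint selection
    can be passed to `fit`, otherwise a stratified fraction of the training
    set is held out.
    """

    def __init__(self, epochs=20, batch_size=32, lr_max=1e-3, lr_min=1e-6,
                 weight_decay=0.01, dropout=0.2, validation_fraction=0.15,
                 model_selection="best_val_auc", aux_step_weight=0.0,
                 random_state=0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_max = lr_max
        self.lr_min = lr_min
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.validation_fraction = validation_fraction
        self.model_selection = model_selection
        self.aux_step_weight = aux_step_weight
        self.random_state = random_state

    # subclass hooks --------------------------------------------------------
    def _build_network(self, rng: np.random.Generator):
        raise NotImplementedError

    def _train_samples(self, X, y) -> list[SeriesSample]:
        return [SeriesSample(s.patches, s.times, yi) for s, yi in zip(X, y)]

    def _eval_sample(self, series: FollowUpSeries) -> SeriesSample:
        return SeriesSample(series.patches, series.times, 0)

    # sklearn API -----------------------------------------------------------
    def fit(self, X, y=None, validation_data=None):
        X = list(X)
        if y is None:
            y = [s.label for s in X]
        y = as_binary_labels(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        cfg = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                          lr_max=self.lr_max, lr_min=self.lr_min,
                          weight_decay=self.weight_decay, dropout=self.dropout,
                          seed=self.random_state,
                          model_selection=self.model_selection,
                          aux_step_weight=self.aux_step_weight)
        rng = np.random.default_rng(self.random_state)
        if validation_data is not None:
            Xv, yv = validation_data
            yv = as_binary_labels(yv)
            X_tr, y_tr = X, y
        elif self.validation_fraction and len(X) >= 10:
            idx = rng.permutation(len(X))
            n_val = max(2, int(round(self.validation_fraction * len(X))))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            Xv = [X[i] for i in val_idx]
            yv = y[val_idx]
            X_tr = [X[i] for i in tr_idx]
            y_tr = y[tr_idx]
        else:
            Xv, yv, X_tr, y_tr = None, None, X, y
        self.network_ = self._build_network(rng)
        train_samples = self._train_samples(X_tr, y_tr)
        val_samples = ([self._val_sample_of(s, yi) for s, yi in zip(Xv, yv)]
                       if Xv is not None else None)
        self.history_ = fit_network(self.network_, train_samples, val_samples, cfg)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X[0].patches.shape[-1] ** 3 if len(X) else 0
        return self

    def _val_sample_of(self, series, yi) -> SeriesSample:
        s = self._eval_sample(series)
        return SeriesSample(s.patches, s.times, int(yi))

    def decision_function(self, X) -> np.ndarray:
        samples = [self._eval_sample(s) for s in X]
        return score_samples(self.network_, samples)

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        threshold = getattr(self, "threshold_", 0.5)
        return (self.predict_proba(X)[:, 1] >= threshold).astype(int)

    def set_decision_threshold(self, threshold: float):
        """Fix the probability cutoff used by `predict` (e.g. best Youden)."""
        self.threshold_ = float(threshold)
        return self
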