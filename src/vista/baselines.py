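"""Counterpart methods: VDT scoring and cutoffs, static CNNs, CNN+LSTM.

VDT (volume doubling time) is the classical size-based growth indicator: the
Schwartz exponential form VDT = dt * ln 2 / ln(v2 / v1) between the first and
last scan of a series.  Ranking uses 1/VDT so that stable and shrinking
nodules order below every grower.  The deep baselines share ViSTA's CNN
backbone: static CNNs score one time point per nodule; CNN+LSTM feeds the
encodings to a recurrent unit in visit order and never consumes the time
stamps, making it blind to interval structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from ._autodiff import Tensor
from .model import BackboneConfig, CNNBackbone
from .preprocess import FollowUpSeries
from .traineval import (CutoffRule, SeriesNetClassifier, SeriesSample,
                        as_binary_labels, best_youden_cutoff)

LN2 = np.log(2.0)
FAST_VDT_DAYS = 400.0


@dataclass(frozen=True)
class VDTResult:
    """Volume doubling time (days) and its inverse, the ranking score."""

    vdt_days: float
    inv_vdt: float


def compute_vdt(v1: float, v2: float, dt: float) -> VDTResult:
    """Schwartz VDT between two volumes dt days apart.

    v2 == v1 maps to inv_vdt = 0 and VDT = +inf; shrinkage gives negative
    inv_vdt (and negative VDT) so every nodule remains rankable.
    """
    if v1 <= 0 or v2 <= 0:
        raise ValueError("volumes must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    growth = np.log(v2 / v1)
    if growth == 0.0:
        return VDTResult(vdt_days=np.inf, inv_vdt=0.0)
    inv = growth / (dt * LN2)
    return VDTResult(vdt_days=1.0 / inv, inv_vdt=inv)


def vdt_score_series(series: FollowUpSeries) -> VDTResult:
    """VDT between the first and last scan of a follow-up series."""
    if len(series) < 2:
        raise ValueError("VDT needs at least two time points")
    return compute_vdt(float(series.volumes[0]), float(series.volumes[-1]),
                       float(series.times[-1] - series.times[0]))


def vdt_classify(res: VDTResult, rule: CutoffRule) -> str:
    """Apply a cutoff policy to a VDT result."""
    if rule.origin == "fixed_400_days":
        positive = 0.0 < res.vdt_days < FAST_VDT_DAYS
    elif rule.origin == "best_youden":
        positive = res.inv_vdt >= rule.threshold
    else:
        raise ValueError(f"unknown cutoff origin {rule.origin!r}")
    return "positive" if positive else "negative"


class VDTClassifier:
    """Size-based baseline: rank by 1/VDT, threshold by policy.

    cutoff="fixed" uses the 400-day fast-growth convention; cutoff="youden"
    calibrates the threshold that maximizes the Youden index on the data
    passed to `fit` (use the validation split).
    """

    def __init__(self, cutoff: str = "youden", threshold_days: float = FAST_VDT_DAYS):
        self.cutoff = cutoff
        self.threshold_days = threshold_days

    def get_params(self, deep=True):
        return {"cutoff": self.cutoff, "threshold_days": self.threshold_days}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        if self.cutoff == "fixed":
            self.rule_ = CutoffRule(threshold=1.0 / self.threshold_days,
                                    origin="fixed_400_days")
        elif self.cutoff == "youden":
            if y is None:
                y = [s.label for s in X]
            self.rule_ = best_youden_cutoff(self.decision_function(X),
                                            as_binary_labels(y))
        else:
            raise ValueError(f"unknown cutoff policy {self.cutoff!r}")
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        return np.array([vdt_score_series(s).inv_vdt for s in X])

    def predict(self, X) -> np.ndarray:
        return np.array([1 if vdt_classify(vdt_score_series(s), self.rule_)
                         == "positive" else 0 for s in X])

    def results_table(self, X):
        import pandas as pd

        rows = []
        for s in X:
            res = vdt_score_series(s)
            rows.append({"series_id": s.series_id,
                         "v1": float(s.volumes[0]), "v2": float(s.volumes[-1]),
                         "dt_days": float(s.times[-1] - s.times[0]),
                         "vdt_days": res.vdt_days, "inv_vdt": res.inv_vdt,
                         "pred": vdt_classify(res, self.rule_)})
        return pd.DataFrame(rows)


class CNNStaticNetwork(nn.Module):
    """Shared backbone + dropout + linear-sigmoid head on a single patch."""

    def __init__(self, backbone_cfg: BackboneConfig, rng, dropout=0.2,
                 dtype=np.float32):
        self.backbone = CNNBackbone(backbone_cfg, rng, dtype)
        self.drop = nn.Dropout(dropout)
        self.head = nn.Linear(backbone_cfg.dim, 1, rng, dtype)
        self.dtype = dtype

    def encode(self, patches):
        if not isinstance(patches, Tensor):
            patches = Tensor(np.asarray(patches, dtype=self.dtype))
        x = patches if patches.ndim == 5 else patches.reshape(
            patches.shape[0], 1, *patches.shape[1:])
        return self.backbone(x)

    def temporal_logit(self, feats: Tensor, times) -> Tensor:
        return self.head(self.drop(feats[-1]))[0]


class CNNLSTMNetwork(nn.Module):
    """Shared backbone + LSTM over encodings in visit order; interval-blind."""

    def __init__(self, backbone_cfg: BackboneConfig, hidden_dim: int,
                 rng, dropout=0.2, dtype=np.float32):
        self.backbone = CNNBackbone(backbone_cfg, rng, dtype)
        self.cell = nn.LSTMCell(backbone_cfg.dim, hidden_dim, rng, dtype)
        self.drop = nn.Dropout(dropout)
        self.head = nn.Linear(hidden_dim, 1, rng, dtype)
        self.hidden_dim = hidden_dim
        self.dtype = dtype

    def encode(self, patches):
        if not isinstance(patches, Tensor):
            patches = Tensor(np.asarray(patches, dtype=self.dtype))
        x = patches if patches.ndim == 5 else patches.reshape(
            patches.shape[0], 1, *patches.shape[1:])
        return self.backbone(x)

    def temporal_logits(self, feats: Tensor, times) -> Tensor:
        """Per-prefix logits: head applied to the hidden state at every step."""
        # time stamps are deliberately never consumed
        h = Tensor(np.zeros(self.hidden_dim, dtype=self.dtype))
        c = Tensor(np.zeros(self.hidden_dim, dtype=self.dtype))
        logits = []
        for t in range(feats.shape[0]):
            h, c = self.cell(feats[t], h, c)
            logits.append(self.head(self.drop(h))[0])
        from ._autodiff import stack
        return stack(logits)

    def temporal_logit(self, feats: Tensor, times) -> Tensor:
        return self.temporal_logits(feats, times)[-1]


class CNNStaticClassifier(SeriesNetClassifier):
    """Static CNN baseline over single time points.

    train_policy selects the training scans (first_only / last_only /
    all_points, the latter treating every scan as an independent sample with
    the series label); eval_policy fixes the scan scored at prediction time
    (one nodule = one prediction).
    """

    def __init__(self, train_policy="last_only", eval_policy="last",
                 dim=64, channels=(8, 16, 32, 64),
                 epochs=20, batch_size=32, lr_max=1e-3, lr_min=1e-6,
                 weight_decay=0.01, dropout=0.2, validation_fraction=0.15,
                 model_selection="best_val_auc", random_state=0):
        super().__init__(epochs=epochs, batch_size=batch_size, lr_max=lr_max,
                         lr_min=lr_min, weight_decay=weight_decay,
                         dropout=dropout,
                         validation_fraction=validation_fraction,
                         model_selection=model_selection,
                         random_state=random_state)
        self.train_policy = train_policy
        self.eval_policy = eval_policy
        self.dim = dim
        self.channels = channels

    def _build_network(self, rng):
        return CNNStaticNetwork(BackboneConfig(tuple(self.channels), self.dim),
                                rng, dropout=self.dropout)

    def _train_samples(self, X, y):
        samples = []
        for series, yi in zip(X, y):
            if self.train_policy == "first_only":
                idx = [0]
            elif self.train_policy == "last_only":
                idx = [len(series) - 1]
            elif self.train_policy == "all_points":
                idx = list(range(len(series)))
            else:
                raise ValueError(f"unknown train policy {self.train_policy!r}")
            for k in idx:
                samples.append(SeriesSample(series.patches[k:k + 1],
                                            series.times[k:k + 1], int(yi)))
        return samples

    def _eval_sample(self, series):
        k = 0 if self.eval_policy == "first" else len(series) - 1
        return SeriesSample(series.patches[k:k + 1], series.times[k:k + 1], 0)


class CNNLSTMClassifier(SeriesNetClassifier):
    """CNN+LSTM baseline: sequential but blind to inter-scan intervals."""

    def __init__(self, hidden_dim=64, dim=64, channels=(8, 16, 32, 64),
                 epochs=20, batch_size=32, lr_max=1e-3, lr_min=1e-6,
                 weight_decay=0.01, dropout=0.2, validation_fraction=0.15,
                 model_selection="best_val_auc", aux_step_weight=0.5,
                 random_state=0):
        super().__init__(epochs=epochs, batch_size=batch_size, lr_max=lr_max,
                         lr_min=lr_min, weight_decay=weight_decay,
                         dropout=dropout,
                         validation_fraction=validation_fraction,
                         model_selection=model_selection,
                         aux_step_weight=aux_step_weight,
                         random_state=random_state)
        self.hidden_dim = hidden_dim
        self.dim = dim
        self.channels = channels

    def _build_network(self, rng):
        return CNNLSTMNetwork(BackboneConfig(tuple(self.channels), self.dim),
                              self.hidden_dim, rng, dropout=self.dropout)
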