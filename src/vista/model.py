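"""ViSTA: a 3D-CNN patch encoder with SimTA exponential-decay temporal attention.

SimTA (Simple Temporal Attention) addresses irregularly sampled follow-up
series.  At step j the attention weight on an earlier step i is a causal
softmax over scores

    s[j, i] = -softplus(lambda) * (t_j - t_i) / tau,   i <= j,

so weight decays exponentially with elapsed time, later steps never receive
less weight than earlier ones, and only pairwise time differences matter.
tau is a fixed time scale (days per attention unit); lambda is learnable —
by default one rate per feature channel, so a layer summarizes the history
at `dim` parallel time scales (a scalar shared rate is available).  A SimTA
layer applies the attention to a learned value projection with residual +
LayerNorm, followed by a position-wise feed-forward block; attention is
purely time-driven (no query/key content terms).  The prediction head maps
every step's representation to an IA probability; the series-level
prediction is the final step's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from ._autodiff import Tensor, no_grad, softmax
from .preprocess import FollowUpSeries
from .traineval import SeriesNetClassifier

DEFAULT_TIME_SCALE = 30.0    # days per attention unit
_MASK_NEG = 1e9


@dataclass
class SimTAConfig:
    """Hyperparameters of the SimTA stack.

    With `rate_per_channel` each feature channel carries its own learnable
    decay rate, so one layer summarizes the history at `dim` different time
    scales in parallel (initialized log-spaced over `init_rate_range`); with
    a scalar rate all channels share one decay (initial value `init_rate`).
    """

    n_layers: int = 2
    dim: int = 64
    time_scale: float = DEFAULT_TIME_SCALE
    dropout: float = 0.2
    ffn_expand: int = 1
    rate_per_channel: bool = True
    init_rate: float = 1.0      # scalar-rate mode, 1/attention-unit
    init_rate_range: tuple[float, float] = (0.02, 2.0)

    def __post_init__(self):
        if self.n_layers < 1 or self.dim < 1 or self.time_scale <= 0:
            raise ValueError("invalid SimTA configuration")


@dataclass
class BackboneConfig:
    """Hyperparameters of the 3D CNN patch encoder."""

    channels: tuple[int, ...] = (8, 16, 32, 64)
    dim: int = 64


@dataclass
class Prediction:
    """IA probability at the last step plus the probability at every prefix."""

    p_ia: float
    per_step_p: np.ndarray


def simta_attention(times: np.ndarray, rate: float,
                    time_scale: float = DEFAULT_TIME_SCALE) -> np.ndarray:
    """Causal exponential-decay attention weights for a visit schedule.

    Returns a (T, T) row-stochastic matrix with zeros above the diagonal:
    row j is the softmax over i <= j of -rate * (t_j - t_i) / time_scale.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    dt = (times[:, None] - times[None, :]) / time_scale    # dt[j, i] = t_j - t_i
    scores = -rate * dt
    scores[np.triu_indices(len(times), k=1)] = -np.inf     # mask i > j
    scores -= scores.max(axis=1, keepdims=True)
    w = np.exp(scores)
    return w / w.sum(axis=1, keepdims=True)


def _decay_inputs(times: np.ndarray, time_scale: float,
                  dtype) -> tuple[np.ndarray, np.ndarray]:
    """Constant (dt, causal-mask) matrices for the autodiff attention path."""
    t = np.asarray(times, dtype=float)
    dt = np.maximum(t[:, None] - t[None, :], 0.0) / time_scale
    mask = np.where(t[None, :] > t[:, None], -_MASK_NEG, 0.0)
    return dt.astype(dtype), mask.astype(dtype)


class SimTALayer(nn.Module):
    """One SimTA block: time-decay attention + value projection, then FFN."""

    def __init__(self, cfg: SimTAConfig, rng: np.random.Generator,
                 dtype=np.float32):
        self.cfg = cfg
        if cfg.rate_per_channel:
            lo, hi = cfg.init_rate_range
            rates0 = np.geomspace(lo, hi, cfg.dim)
            raw0 = np.log(np.expm1(rates0)).astype(dtype)
        else:
            raw0 = np.array(np.log(np.expm1(cfg.init_rate)), dtype=dtype)
        self.decay_raw = Tensor(raw0, requires_grad=True)
        self.value = nn.Linear(cfg.dim, cfg.dim, rng, dtype)
        self.ffn_in = nn.Linear(cfg.dim, cfg.ffn_expand * cfg.dim, rng, dtype)
        self.ffn_out = nn.Linear(cfg.ffn_expand * cfg.dim, cfg.dim, rng, dtype)
        self.norm1 = nn.LayerNorm(cfg.dim, dtype=dtype)
        self.norm2 = nn.LayerNorm(cfg.dim, dtype=dtype)
        self.drop1 = nn.Dropout(cfg.dropout)
        self.drop2 = nn.Dropout(cfg.dropout)

    @property
    def rates(self) -> np.ndarray:
        """Fitted decay rates softplus(lambda), per attention unit."""
        return np.atleast_1d(np.logaddexp(0.0, self.decay_raw.data))

    @property
    def rate(self) -> float:
        """Median fitted decay rate (scalar summary)."""
        return float(np.median(self.rates))

    def attention(self, times: np.ndarray) -> np.ndarray:
        """Per-channel attention weights (T, T, n_rates), inference mode."""
        rates = self.rates
        return np.stack([simta_attention(times, float(r), self.cfg.time_scale)
                         for r in rates], axis=-1)

    def forward(self, x: Tensor, times: np.ndarray) -> Tensor:
        dt, mask = _decay_inputs(times, self.cfg.time_scale, x.data.dtype)
        rate = self.decay_raw.softplus()
        if self.cfg.rate_per_channel:
            # scores (T, T, D); softmax over the attended index i (axis 1)
            scores = -(Tensor(dt[:, :, None]) * rate) + Tensor(mask[:, :, None])
            attn = softmax(scores, axis=1)
            ctx = (attn * self.value(x).reshape(1, len(times), -1)).sum(axis=1)
        else:
            scores = -(rate * Tensor(dt)) + Tensor(mask)
            ctx = softmax(scores, axis=-1) @ self.value(x)
        h = self.norm1(x + self.drop1(ctx))
        return self.norm2(h + self.drop2(self.ffn_out(self.ffn_in(h).relu())))


class CNNBackbone(nn.Module):
    """Four-stage 3D conv encoder with BN/ReLU, GAP and a linear projection.

    The stem is a non-overlapping 4x4x4 patchify convolution (cheap on CPU:
    its im2col is a plain reshape); the remaining stages are 3x3x3 stride-2
    convolutions.  A 32 mm patch is reduced 32 -> 8 -> 4 -> 2 -> 1.
    """

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator,
                 dtype=np.float32):
        self.cfg = cfg
        chans = (1,) + tuple(cfg.channels)
        self.convs = [nn.Conv3d(chans[0], chans[1], 4, stride=4, padding=0,
                                rng=rng, dtype=dtype)]
        self.convs += [nn.Conv3d(ci, co, 3, stride=2, padding=1, rng=rng, dtype=dtype)
                       for ci, co in zip(chans[1:-1], chans[2:])]
        self.norms = [nn.BatchNorm3d(c, dtype=dtype) for c in cfg.channels]
        self.proj = nn.Linear(cfg.channels[-1], cfg.dim, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        """(N, 1, S, S, S) patches -> (N, dim) features."""
        for conv, norm in zip(self.convs, self.norms):
            x = norm(conv(x)).relu()
        pooled = x.mean(axis=(2, 3, 4))
        return self.proj(pooled)


class ViSTANetwork(nn.Module):
    """CNN backbone -> stack of SimTA layers -> per-step sigmoid head."""

    def __init__(self, backbone_cfg: BackboneConfig | None = None,
                 simta_cfg: SimTAConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.backbone_cfg = backbone_cfg or BackboneConfig()
        self.simta_cfg = simta_cfg or SimTAConfig(dim=self.backbone_cfg.dim)
        if self.simta_cfg.dim != self.backbone_cfg.dim:
            raise ValueError("backbone and SimTA dims must agree")
        self.backbone = CNNBackbone(self.backbone_cfg, rng, dtype)
        self.layers = [SimTALayer(self.simta_cfg, rng, dtype)
                       for _ in range(self.simta_cfg.n_layers)]
        self.head = nn.Linear(self.simta_cfg.dim, 1, rng, dtype)
        self.dtype = dtype

    def encode(self, patches: np.ndarray | Tensor) -> Tensor:
        """Encode (N, S, S, S) or (N, 1, S, S, S) patches to (N, dim)."""
        if not isinstance(patches, Tensor):
            patches = Tensor(np.asarray(patches, dtype=self.dtype))
        x = patches if patches.ndim == 5 else patches.reshape(
            patches.shape[0], 1, *patches.shape[1:])
        return self.backbone(x)

    def temporal_logits(self, feats: Tensor, times: np.ndarray) -> Tensor:
        """Per-step logits (T,) from encoded features (T, dim)."""
        h = feats
        for layer in self.layers:
            h = layer(h, times)
        return self.head(h).reshape(-1)

    def temporal_logit(self, feats: Tensor, times: np.ndarray) -> Tensor:
        return self.temporal_logits(feats, times)[-1]

    def forward(self, patches, times) -> Tensor:
        return self.temporal_logits(self.encode(patches), times)

    def predict_series(self, series: FollowUpSeries) -> Prediction:
        """Inference-mode per-prefix IA probabilities for one series."""
        self.eval()
        with no_grad():
            logits = self.forward(series.patches, series.times)
        p = 1.0 / (1.0 + np.exp(-logits.data))
        return Prediction(p_ia=float(p[-1]), per_step_p=p)


def vista_forward(network: ViSTANetwork, series: FollowUpSeries) -> Prediction:
    """Run ViSTA on a preprocessed series; errors on an empty one."""
    if len(series) == 0:
        raise ValueError("empty series")
    return network.predict_series(series)


def count_params(model: nn.Module) -> int:
    """Total trainable scalar count (frozen tensors excluded)."""
    return model.n_parameters()


def freeze(module: nn.Module):
    """Mark every parameter of `module` as non-trainable."""
    for p in module.parameters():
        p.requires_grad = False
    return module


class ViSTAClassifier(SeriesNetClassifier):
    """sklearn-style estimator for the full ViSTA network.

    Fits the CNN backbone, SimTA stack and head end-to-end on labelled
    follow-up series; `decision_function` returns the final-step logit and
    `predict_proba` the IA probability.
    """

    def __init__(self, n_layers=2, dim=64, channels=(8, 16, 32, 64),
                 time_scale=DEFAULT_TIME_SCALE, rate_per_channel=True,
                 init_rate=1.0, epochs=20, batch_size=32, lr_max=1e-3,
                 lr_min=1e-6, weight_decay=0.01, dropout=0.2,
                 validation_fraction=0.15, model_selection="best_val_auc",
                 aux_step_weight=0.5, random_state=0):
        super().__init__(epochs=epochs, batch_size=batch_size, lr_max=lr_max,
                         lr_min=lr_min, weight_decay=weight_decay,
                         dropout=dropout,
                         validation_fraction=validation_fraction,
                         model_selection=model_selection,
                         aux_step_weight=aux_step_weight,
                         random_state=random_state)
        self.n_layers = n_layers
        self.dim = dim
        self.channels = channels
        self.time_scale = time_scale
        self.rate_per_channel = rate_per_channel
        self.init_rate = init_rate

    def _build_network(self, rng):
        return ViSTANetwork(
            BackboneConfig(tuple(self.channels), self.dim),
            SimTAConfig(n_layers=self.n_layers, dim=self.dim,
                        time_scale=self.time_scale, dropout=self.dropout,
                        rate_per_channel=self.rate_per_channel,
                        init_rate=self.init_rate),
            rng)

    def predict_series(self, series: FollowUpSeries) -> Prediction:
        return vista_forward(self.network_, series)

    @property
    def fitted_rates_(self) -> list[float]:
        """softplus(lambda) per SimTA layer, in 1/attention-unit."""
        return [layer.rate for layer in self.network_.layers]
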