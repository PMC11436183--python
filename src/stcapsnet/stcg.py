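"""Spatio-Temporal Capsule-Generation (STCG) block.

Maps one raw EEG epoch of shape (channels C, samples T) to ``n_caps``
primary capsules of dimension ``d_caps`` through five convolutional layers
and two pooling layers:

1. temporal convolution, kernel ``(1, TI)``, ``F1`` filters, same-padding;
2. spatial depthwise convolution, kernel ``(C, 1)``, depth multiplier ``D``
   — collapses the electrode axis into spatial filters;
3. average pooling of width ``pool1`` along time;
4. depthwise convolution, kernel ``(1, 16)``, same-padding, followed by
5. pointwise convolution with ``F2`` ``(1, 1)`` kernels (together a
   depthwise-separable convolution);
6. average pooling of width ``pool2``;
7. depthwise feature-fusion convolution spanning the whole residual
   temporal extent, leaving exactly ``F2`` values per epoch which are
   reshaped to ``(n_caps, d_caps)`` and squashed.

The squash nonlinearity rescales each capsule vector s to norm
``1 - exp(-||s||)`` while preserving its direction, so capsule length can
be read as a feature-presence probability in [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, astensor, avg_pool2d, conv2d, same_padding
from .errors import ConfigurationError, NumericError, ShapeError

SEP_KERNEL = 16  # depthwise kernel width of the separable layer


# ---------------------------------------------------------------------- squash
def squash(s, axis: int = -1, eps: float = 1e-12):
    """Capsule squash: ``(1 - exp(-||s||)) * s / ||s||`` along ``axis``.

    Accepts a plain array or a :class:`Tensor` and returns the same kind.
    The zero vector maps to itself (the continuous extension of the 0/0
    limit at the origin).
    """
    if isinstance(s, Tensor):
        n = ((s * s).sum(axis=axis, keepdims=True) + eps) ** 0.5
        return s * ((1.0 - (-n).exp()) / n)
    s = np.asarray(s, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise NumericError("squash requires finite input")
    n = np.sqrt(np.sum(s * s, axis=axis, keepdims=True) + eps)
    return s * (-np.expm1(-n)) / n


def capsule_norms(s, axis: int = -1, eps: float = 1e-12):
    """Euclidean norm per capsule (Tensor-aware)."""
    if isinstance(s, Tensor):
        return ((s * s).sum(axis=axis) + eps) ** 0.5
    s = np.asarray(s, dtype=np.float64)
    return np.sqrt(np.sum(s * s, axis=axis))


# ---------------------------------------------------------------- configuration
@dataclass
class ModelConfig:
    """Architecture hyperparameters for the STCG block and routing head.

    The temporal pipeline must close exactly: after both poolings the
    fusion layer consumes the full residual temporal extent, so the block
    emits ``F2`` values per epoch and ``F2`` must equal
    ``n_caps * d_caps``.
    """

    n_channels: int = 124
    n_samples: int = 3073
    F1: int = 16
    TI: int = 65
    D: int = 2
    F2: int = 64
    pool1: int = 4
    pool2: int = 8
    n_caps: int = 8
    d_caps: int = 8
    n_out: int = 2
    d_out: int = 16
    batch_norm: bool = True
    squash_output: bool = True
    corr_scale: str = "d"  # "d" or "sqrt_d" scaling of the self-correlation tensor
    seed: int = 0

    def __post_init__(self):
        for name in ("n_channels", "n_samples", "F1", "TI", "D", "F2",
                     "pool1", "pool2", "n_caps", "d_caps", "n_out", "d_out"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.F2 != self.n_caps * self.d_caps:
            raise ConfigurationError(
                f"capsule reshape is inexact: F2 ({self.F2}) != "
                f"n_caps * d_caps ({self.n_caps} * {self.d_caps} = {self.n_caps * self.d_caps})"
            )
        if self.corr_scale not in ("d", "sqrt_d"):
            raise ConfigurationError(f"corr_scale must be 'd' or 'sqrt_d', got {self.corr_scale!r}")
        t_after = (self.n_samples // self.pool1) // self.pool2
        if t_after < 1:
            raise ConfigurationError(
                f"temporal pipeline collapses: ({self.n_samples} // {self.pool1}) "
                f"// {self.pool2} = {t_after} < 1"
            )

    @property
    def t_pool1(self) -> int:
        return self.n_samples // self.pool1

    @property
    def t_pool2(self) -> int:
        return self.t_pool1 // self.pool2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class LayerSpec:
    """One entry of the symbolic shape plan."""

    name: str
    kind: str  # "conv" or "pool"
    kernel: tuple[int, int]
    out_shape: tuple[int, int, int]  # (feature maps, height, width)
    depthwise: bool = False
    params: int = 0


def layer_plan(cfg: ModelConfig) -> list[LayerSpec]:
    """Symbolic per-layer shapes of the STCG block for a single epoch."""
    C, T = cfg.n_channels, cfg.n_samples
    F1, D, F2 = cfg.F1, cfg.D, cfg.F2
    t1, t2 = cfg.t_pool1, cfg.t_pool2
    return [
        LayerSpec("temporal_conv", "conv", (1, cfg.TI), (F1, C, T),
                  params=F1 * cfg.TI + F1),
        LayerSpec("spatial_depthwise_conv", "conv", (C, 1), (F1 * D, 1, T),
                  depthwise=True, params=F1 * D * C + F1 * D),
        LayerSpec("avg_pool_1", "pool", (1, cfg.pool1), (F1 * D, 1, t1)),
        LayerSpec("separable_depthwise_conv", "conv", (1, SEP_KERNEL), (F1 * D, 1, t1),
                  depthwise=True, params=F1 * D * SEP_KERNEL),
        LayerSpec("separable_pointwise_conv", "conv", (1, 1), (F2, 1, t1),
                  params=F2 * F1 * D + F2),
        LayerSpec("avg_pool_2", "pool", (1, cfg.pool2), (F2, 1, t2)),
        LayerSpec("fusion_depthwise_conv", "conv", (1, t2), (F2, 1, 1),
                  depthwise=True, params=F2 * t2 + F2),
    ]


# ----------------------------------------------------------------------- layers
class _BatchNorm:
    """Per-feature-map batch normalization with running statistics."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        C = x.shape[1]
        if train:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(C))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(C))
        else:
            mu = Tensor(self.running_mean.reshape(1, C, 1, 1))
            var = Tensor(self.running_var.reshape(1, C, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape), requires_grad=True)


class STCG:
    """Parameter bundle + forward pass for the capsule-generation block."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.plan = layer_plan(cfg)
        C, F1, D, F2 = cfg.n_channels, cfg.F1, cfg.D, cfg.F2
        self.w_temporal = _he_normal(rng, (F1, 1, 1, cfg.TI), cfg.TI)
        self.b_temporal = Tensor(np.zeros(F1), requires_grad=True)
        self.w_spatial = _he_normal(rng, (F1 * D, 1, C, 1), C)
        self.b_spatial = Tensor(np.zeros(F1 * D), requires_grad=True)
        self.w_sep_dw = _he_normal(rng, (F1 * D, 1, 1, SEP_KERNEL), SEP_KERNEL)
        self.w_sep_pw = _he_normal(rng, (F2, F1 * D, 1, 1), F1 * D)
        self.b_sep_pw = Tensor(np.zeros(F2), requires_grad=True)
        self.w_fusion = _he_normal(rng, (F2, 1, 1, cfg.t_pool2), cfg.t_pool2)
        self.b_fusion = Tensor(np.zeros(F2), requires_grad=True)
        self.bn = [_BatchNorm(F1), _BatchNorm(F1 * D), _BatchNorm(F2)] if cfg.batch_norm else []

    def parameters(self) -> list[Tensor]:
        ps = [self.w_temporal, self.b_temporal, self.w_spatial, self.b_spatial,
              self.w_sep_dw, self.w_sep_pw, self.b_sep_pw, self.w_fusion, self.b_fusion]
        for bn in self.bn:
            ps.extend(bn.parameters())
        return ps

    def forward(self, batch, train: bool = False) -> Tensor:
        """(B, C, T) epochs -> squashed capsules (B, n_caps, d_caps)."""
        x = astensor(batch)
        cfg = self.cfg
        if x.ndim != 3 or x.shape[1] != cfg.n_channels or x.shape[2] != cfg.n_samples:
            raise ShapeError(
                f"expected batch of shape (B, {cfg.n_channels}, {cfg.n_samples}), "
                f"got {x.shape}"
            )
        B = x.shape[0]
        x = x.reshape(B, 1, cfg.n_channels, cfg.n_samples)

        x = conv2d(x, self.w_temporal, self.b_temporal,
                   padding=((0, 0), same_padding(cfg.TI)))
        if self.bn:
            x = self.bn[0](x, train)
        x = x.elu()

        x = conv2d(x, self.w_spatial, self.b_spatial, depthwise=True)
        if self.bn:
            x = self.bn[1](x, train)
        x = x.elu()

        x = avg_pool2d(x, (1, cfg.pool1))
        x = conv2d(x, self.w_sep_dw, padding=((0, 0), same_padding(SEP_KERNEL)),
                   depthwise=True)
        x = conv2d(x, self.w_sep_pw, self.b_sep_pw)
        if self.bn:
            x = self.bn[2](x, train)
        x = x.elu()

        x = avg_pool2d(x, (1, cfg.pool2))
        x = conv2d(x, self.w_fusion, self.b_fusion, depthwise=True)
        caps = x.reshape(B, cfg.n_caps, cfg.d_caps)
        return squash(caps)


def build_stcg(cfg: ModelConfig, seed: int | None = None) -> STCG:
    """Construct an STCG parameter bundle (its ``.plan`` is the shape plan)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    return STCG(cfg, rng)
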