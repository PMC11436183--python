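"""Full network: a capsule front-end plus one routed capsule layer.

Two front-ends are available — the spatio-temporal STCG block (the
default) and a deliberately plain "traditional" front-end (two standard
square-kernel convolutions, then a capsule reshape) used only as the
ablation baseline — crossed with two routing mechanisms (self-correlation
or iterative dynamic routing).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, astensor, avg_pool2d, conv2d, same_padding
from .errors import ConfigurationError, ShapeError
from .routing import (
    RoutingWeights,
    class_scores,
    dynamic_routing,
    init_routing_weights,
    predict_classes,
    self_correlation_routing,
)
from .stcg import STCG, ModelConfig, _BatchNorm, _he_normal, build_stcg, squash

ROUTINGS = ("selfcorr", "dynamic")
FRONTENDS = ("st", "traditional")


class TraditionalFrontend:
    """Plain-convolution primary-capsule generator for the ablation.

    Two square-kernel convolutions (5x5 then 3x3), a (2, 4) average
    pooling in between, and a global average over the remaining plane into
    exactly ``n_caps * d_caps`` values, reshaped to capsules and squashed.
    Capsule geometry matches the STCG block so routing sees identical
    shapes.
    """

    K1, K2 = 5, 3
    F_MID = 8
    POOL = (2, 4)

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        F2 = cfg.n_caps * cfg.d_caps
        self.w1 = _he_normal(rng, (self.F_MID, 1, self.K1, self.K1), self.K1 * self.K1)
        self.b1 = Tensor(np.zeros(self.F_MID), requires_grad=True)
        self.w2 = _he_normal(rng, (F2, self.F_MID, self.K2, self.K2),
                             self.F_MID * self.K2 * self.K2)
        self.b2 = Tensor(np.zeros(F2), requires_grad=True)
        self.bn = [_BatchNorm(self.F_MID), _BatchNorm(F2)] if cfg.batch_norm else []

    def parameters(self) -> list[Tensor]:
        ps = [self.w1, self.b1, self.w2, self.b2]
        for bn in self.bn:
            ps.extend(bn.parameters())
        return ps

    def forward(self, batch, train: bool = False) -> Tensor:
        x = astensor(batch)
        cfg = self.cfg
        if x.ndim != 3 or x.shape[1] != cfg.n_channels or x.shape[2] != cfg.n_samples:
            raise ShapeError(
                f"expected batch of shape (B, {cfg.n_channels}, {cfg.n_samples}), "
                f"got {x.shape}"
            )
        B = x.shape[0]
        x = x.reshape(B, 1, cfg.n_channels, cfg.n_samples)
        x = conv2d(x, self.w1, self.b1,
                   padding=(same_padding(self.K1), same_padding(self.K1)))
        if self.bn:
            x = self.bn[0](x, train)
        x = x.elu()
        x = avg_pool2d(x, self.POOL)
        x = conv2d(x, self.w2, self.b2,
                   padding=(same_padding(self.K2), same_padding(self.K2)))
        if self.bn:
            x = self.bn[1](x, train)
        x = x.elu()
        caps = x.mean(axis=(2, 3)).reshape(B, cfg.n_caps, cfg.d_caps)
        return squash(caps)


class STCapsNet:
    """Front-end + routed capsule layer; norms of the two output capsules
    are the class scores."""

    def __init__(
        self,
        cfg: ModelConfig,
        routing: str = "selfcorr",
        frontend: str = "st",
        iterations: int = 3,
        seed: int | None = None,
    ):
        if routing not in ROUTINGS:
            raise ConfigurationError(f"routing must be one of {ROUTINGS}, got {routing!r}")
        if frontend not in FRONTENDS:
            raise ConfigurationError(f"frontend must be one of {FRONTENDS}, got {frontend!r}")
        self.cfg = cfg
        self.routing = routing
        self.frontend_kind = frontend
        self.iterations = iterations
        seed = cfg.seed if seed is None else seed
        ss = np.random.SeedSequence(seed)
        rng_front, rng_route = [np.random.default_rng(s) for s in ss.spawn(2)]
        if frontend == "st":
            self.frontend = STCG(cfg, rng_front)
        else:
            self.frontend = TraditionalFrontend(cfg, rng_front)
        self.weights: RoutingWeights = init_routing_weights(
            cfg.n_caps, cfg.n_out, cfg.d_caps, cfg.d_out, rng_route
        )

    def parameters(self) -> list[Tensor]:
        return self.frontend.parameters() + self.weights.parameters()

    def forward(self, batch, train: bool = False) -> Tensor:
        """(B, C, T) epochs -> squashed output capsules (B, n_out, d_out)."""
        U = self.frontend.forward(batch, train=train)
        if self.routing == "selfcorr":
            out = self_correlation_routing(
                U, self.weights,
                squash_output=self.cfg.squash_output, scale=self.cfg.corr_scale,
            )
        else:
            out = dynamic_routing(U, self.weights, iterations=self.iterations)
        return out.values

    def scores(self, batch) -> np.ndarray:
        """Per-class capsule norms in eval mode."""
        return np.asarray(class_scores(self.forward(batch, train=False)))

    def predict(self, batch) -> np.ndarray:
        return predict_classes(self.scores(batch))

    # ------------------------------------------------------------- persistence
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(getattr(self.frontend, "bn", [])):
            state[f"bn_{i}_mean"] = bn.running_mean
            state[f"bn_{i}_var"] = bn.running_var
        return state

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for i, p in enumerate(params):
            src = np.asarray(arrays[f"param_{i}"])
            if src.shape != p.data.shape:
                raise ShapeError(f"param_{i}: saved {src.shape} vs model {p.data.shape}")
            p.data = src.astype(np.float64)
        for i, bn in enumerate(getattr(self.frontend, "bn", [])):
            if f"bn_{i}_mean" in arrays:
                bn.running_mean = np.asarray(arrays[f"bn_{i}_mean"], dtype=np.float64)
                bn.running_var = np.asarray(arrays[f"bn_{i}_var"], dtype=np.float64)
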