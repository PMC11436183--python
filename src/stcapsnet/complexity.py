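"""Analytic parameter and FLOP accounting.

Counts are closed-form, per layer, for a single epoch forward pass.
Convention: one multiply-accumulate (MAC) = 2 FLOPs; elementwise
exponentials, divisions and comparisons count 1 FLOP each. The routing
mechanisms share the prediction transform Û = U W, which is therefore
reported as its own line item; ``routing_flops`` covers only the routing
computation proper (coupling + aggregation + squash), which is what
differs between mechanisms.

For self-correlation routing the dominant routing-proper term is the Gram
tensor, ~n_l^2 * n_out * d_out MACs; for dynamic routing with r rounds it
is ~2 r * n_l * n_out * d_out MACs (aggregation + agreement per round).
Their ratio dynamic/selfcorr is therefore approximately ``2 r / (n_l + 1)``
— about 2 at r = 3 for a small primary-capsule count (n_l = 2) and
decreasing as n_l grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .stcg import SEP_KERNEL, ModelConfig, layer_plan

MAC_FLOPS = 2


@dataclass
class LayerCount:
    name: str
    params: int
    macs: int

    @property
    def flops(self) -> int:
        return MAC_FLOPS * self.macs


@dataclass
class ComplexityReport:
    layers: list[LayerCount]
    routing_mechanism: str

    @property
    def total_params(self) -> int:
        return sum(layer.params for layer in self.layers)

    @property
    def total_flops(self) -> int:
        return sum(layer.flops for layer in self.layers)

    @property
    def routing_flops(self) -> int:
        """FLOPs of the routing computation proper (excl. the shared Û transform)."""
        return sum(layer.flops for layer in self.layers if layer.name.startswith("routing"))

    def by_name(self, name: str) -> LayerCount:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(name)


def _stcg_counts(cfg: ModelConfig) -> list[LayerCount]:
    counts = []
    for spec in layer_plan(cfg):
        f, h, w = spec.out_shape
        n_out_elems = f * h * w
        if spec.kind == "pool":
            macs = n_out_elems * spec.kernel[0] * spec.kernel[1]
        elif spec.depthwise:
            macs = n_out_elems * spec.kernel[0] * spec.kernel[1]
        else:
            kh, kw = spec.kernel
            fan_in = {"temporal_conv": 1, "separable_pointwise_conv": cfg.F1 * cfg.D}[spec.name]
            macs = n_out_elems * kh * kw * fan_in
        counts.append(LayerCount(spec.name, spec.params, macs))
    if cfg.batch_norm:
        bn_params = 2 * (cfg.F1 + cfg.F1 * cfg.D + cfg.F2)
        bn_elems = (cfg.F1 * cfg.n_channels * cfg.n_samples
                    + cfg.F1 * cfg.D * cfg.n_samples + cfg.F2 * cfg.t_pool1)
        counts.append(LayerCount("batch_norm", bn_params, 2 * bn_elems))
    return counts


def _squash_flops(n_caps: int, d_caps: int) -> int:
    # norms (d MACs -> 2d FLOPs), exp, division, scale multiply per capsule
    return n_caps * (2 * d_caps + 2 + d_caps) // MAC_FLOPS  # expressed back in MACs


def _routing_counts(cfg: ModelConfig, mechanism: str, iterations: int) -> list[LayerCount]:
    n_l, n_out, d_l, d_out = cfg.n_caps, cfg.n_out, cfg.d_caps, cfg.d_out
    counts = [LayerCount(
        "prediction_transform",
        params=n_l * n_out * d_l * d_out,
        macs=n_l * n_out * d_l * d_out,
    )]
    softmax_macs = (4 * n_l * n_out) // MAC_FLOPS
    squash_macs = _squash_flops(n_out, d_out)
    if mechanism == "selfcorr":
        gram = n_l * n_l * n_out * d_out + (n_l * n_l * n_out) // MAC_FLOPS  # Gram + /d_l
        logit_sum = (n_l * n_l * n_out) // MAC_FLOPS  # additions
        aggregate = n_l * n_out * d_out + (n_l * n_out) // MAC_FLOPS  # + log priors
        counts.append(LayerCount(
            "routing_selfcorr", params=n_l * n_out,
            macs=gram + logit_sum + softmax_macs + aggregate + squash_macs,
        ))
    elif mechanism == "dynamic":
        per_iter = softmax_macs + n_l * n_out * d_out + squash_macs
        agreement = n_l * n_out * d_out + (n_l * n_out) // MAC_FLOPS
        macs = iterations * per_iter + (iterations - 1) * agreement
        counts.append(LayerCount("routing_dynamic", params=0, macs=macs))
    else:
        raise ConfigurationError(f"unknown routing mechanism {mechanism!r}")
    return counts


def count_complexity(
    cfg: ModelConfig, routing: str = "selfcorr", iterations: int = 3
) -> ComplexityReport:
    """Per-layer analytic parameter and MAC counts for one epoch."""
    layers = _stcg_counts(cfg) + _routing_counts(cfg, routing, iterations)
    return ComplexityReport(layers=layers, routing_mechanism=routing)


def sweep_param_counts(cfg: ModelConfig, n_caps_values=range(2, 13)) -> list[tuple[int, int]]:
    """(n_caps, total trainable parameters) with F2 kept reshape-exact."""
    rows = []
    for n in n_caps_values:
        swept = ModelConfig(**{**cfg.to_dict(), "n_caps": n, "F2": n * cfg.d_caps})
        rows.append((n, count_complexity(swept, routing="selfcorr").total_params))
    return rows
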