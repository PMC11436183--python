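"""Capsule routing: non-iterative self-correlation routing and the classic
iterative dynamic-routing baseline.

Self-correlation routing replaces routing-by-agreement's iterations with a
single similarity computation. Writing U for the (squashed) input capsules
(n_l capsules of dimension d_l) and W for the learnable transformation
tensor (n_l, n_out, d_l, d_out):

1. predictions      ``Û[i, j, :] = U[i, :] @ W[i, j, :, :]``
2. self-correlation ``A[i, k, j] = Û[i, j, :] · Û[k, j, :] / d_l``
   (a Gram matrix per output capsule; dividing by d_l tames its scale)
3. coupling         ``C[i, j] = softmax_j( Σ_k A[i, k, j] )``
4. aggregation      ``S[j, :] = Σ_i (C[i, j] + B[i, j]) · Û[i, j, :]``
   with B a trainable log-prior matrix, followed by a squash so output
   capsule norms stay in [0, 1).

Every step is a fixed computation graph — no iteration count — and is
differentiable end-to-end. All functions accept plain arrays or autodiff
Tensors and return Tensors (``np.asarray`` recovers the values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor, einsum
from .errors import ConfigurationError, ShapeError
from .stcg import capsule_norms, squash


@dataclass
class RoutingWeights:
    """Learnable state of one routing layer: transform W and log priors B."""

    W: Tensor  # (n_l, n_out, d_l, d_out)
    B: Tensor  # (n_l, n_out)

    def parameters(self) -> list[Tensor]:
        return [self.W, self.B]

    @property
    def shapes(self) -> tuple[int, int, int, int]:
        n_l, n_out, d_l, d_out = self.W.shape
        return n_l, n_out, d_l, d_out


@dataclass
class CapsuleTensor:
    """A batch of capsule sets: values (batch, n capsules, d dims)."""

    values: Tensor
    squashed: bool = False

    @property
    def shape(self):
        return self.values.shape


def init_routing_weights(
    n_l: int, n_out: int, d_l: int, d_out: int, seed: int | np.random.Generator = 0
) -> RoutingWeights:
    """Seeded init: fan-in-scaled normal W, zero log priors B."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d_l), size=(n_l, n_out, d_l, d_out)),
               requires_grad=True)
    B = Tensor(np.zeros((n_l, n_out)), requires_grad=True)
    return RoutingWeights(W=W, B=B)


def _values(U) -> Tensor:
    if isinstance(U, CapsuleTensor):
        return U.values
    return astensor(U)


def predict_capsules(U, W) -> Tensor:
    """Transform input capsules into per-output-capsule predictions Û."""
    U, W = _values(U), astensor(W)
    if U.ndim != 3:
        raise ShapeError(f"capsules must be (batch, n_l, d_l), got {U.shape}")
    if U.shape[1] != W.shape[0] or U.shape[2] != W.shape[2]:
        raise ShapeError(
            f"capsules {U.shape} incompatible with transform {W.shape} "
            f"(need n_l={W.shape[0]}, d_l={W.shape[2]})"
        )
    return einsum("bid,ijde->bije", U, W)


def self_correlation(U_hat, d_l: int, scale: str = "d") -> Tensor:
    """Per-output-capsule Gram matrix of predictions, scaled by d_l.

    ``scale='sqrt_d'`` divides by sqrt(d_l) instead (the attention-style
    convention); the default follows the routing definition exactly.
    """
    U_hat = astensor(U_hat)
    if d_l < 1:
        raise ShapeError(f"d_l must be positive, got {d_l}")
    denom = float(d_l) if scale == "d" else float(np.sqrt(d_l))
    return einsum("bije,bkje->bikj", U_hat, U_hat) * (1.0 / denom)


def coupling_coefficients(A) -> Tensor:
    """Softmax-normalized coupling from the self-correlation tensor.

    Logits are the sums of A over its second input-capsule axis; the
    softmax runs across output capsules, stabilized by subtracting the
    per-row maximum (value-preserving).
    """
    A = astensor(A)
    logits = A.sum(axis=2)  # (batch, n_l, n_out)
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))  # constant
    z = (logits - shift).exp()
    return z * (z.sum(axis=-1, keepdims=True) ** -1.0)


def route(U_hat, C, B, squash_output: bool = True) -> Tensor:
    """Aggregate predictions with coupling + log priors into output capsules."""
    U_hat, C, B = astensor(U_hat), astensor(C), astensor(B)
    if C.shape != U_hat.shape[:3]:
        raise ShapeError(f"coupling {C.shape} does not match predictions {U_hat.shape}")
    if B.shape != U_hat.shape[1:3]:
        raise ShapeError(f"log priors {B.shape} do not match predictions {U_hat.shape}")
    weights = C + B.reshape(1, *B.shape)
    S = einsum("bije,bij->bje", U_hat, weights)
    return squash(S) if squash_output else S


def self_correlation_routing(
    U, weights: RoutingWeights, squash_output: bool = True, scale: str = "d"
) -> CapsuleTensor:
    """Single-pass routing: predict -> self-correlation -> coupling -> route."""
    Uv = _values(U)
    d_l = Uv.shape[2]
    U_hat = predict_capsules(Uv, weights.W)
    A = self_correlation(U_hat, d_l, scale=scale)
    C = coupling_coefficients(A)
    S = route(U_hat, C, weights.B, squash_output=squash_output)
    return CapsuleTensor(values=S, squashed=squash_output)


def _softmax_last(x: Tensor) -> Tensor:
    shift = Tensor(x.data.max(axis=-1, keepdims=True))
    z = (x - shift).exp()
    return z * (z.sum(axis=-1, keepdims=True) ** -1.0)


def dynamic_routing(U, weights: RoutingWeights, iterations: int = 3) -> CapsuleTensor:
    """Iterative routing-by-agreement baseline.

    Logits start at zero; each round couples via a softmax over output
    capsules, aggregates, squashes, and reinforces logits by the
    prediction-output agreement. Cost grows linearly with ``iterations``.
    """
    if iterations < 1:
        raise ConfigurationError(f"iterations must be >= 1, got {iterations}")
    Uv = _values(U)
    U_hat = predict_capsules(Uv, weights.W)
    batch, n_l, n_out, _ = U_hat.shape
    b_logits = Tensor(np.zeros((batch, n_l, n_out)))
    v = None
    for it in range(iterations):
        c = _softmax_last(b_logits)
        s = einsum("bije,bij->bje", U_hat, c)
        v = squash(s)
        if it < iterations - 1:
            b_logits = b_logits + einsum("bije,bje->bij", U_hat, v)
    return CapsuleTensor(values=v, squashed=True)


def class_scores(S) -> Tensor:
    """Per-class scores = Euclidean norms of the output capsules."""
    return capsule_norms(_values(S))


def predict_classes(scores) -> np.ndarray:
    """Argmax class per trial; exact ties resolve to the lower class index."""
    return np.argmax(np.asarray(scores), axis=-1)
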