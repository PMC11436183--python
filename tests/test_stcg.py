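"""Squash law, configuration invariants, layer-plan conformance, and
shape-plan vs realized-forward agreement for the capsule front-end."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stcapsnet as sc
from stcapsnet.errors import ConfigurationError, NumericError, ShapeError


# ------------------------------------------------------------------- squash
def test_squash_closed_forms():
    np.testing.assert_array_equal(np.asarray(sc.squash(np.zeros(4))), np.zeros(4))
    unit = np.array([1.0, 0.0, 0.0])
    assert np.linalg.norm(sc.squash(unit)) == pytest.approx(1 - np.exp(-1), abs=1e-9)
    v = np.array([3.0, 4.0])
    out = np.asarray(sc.squash(v))
    np.testing.assert_allclose(out, (1 - np.exp(-5)) * np.array([0.6, 0.8]), atol=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(-50, 50), min_size=1, max_size=6),
       st.floats(min_value=-8, max_value=8))
def test_squash_norm_law_and_direction(vec, log_scale):
    s = np.array(vec) * 10.0**log_scale
    out = np.asarray(sc.squash(s))
    n = np.linalg.norm(s)
    assert np.linalg.norm(out) == pytest.approx(1 - np.exp(-n), abs=1e-6)
    assert np.linalg.norm(out) <= 1.0
    if n < 30:  # strictly below 1 wherever 1 - e^-n is resolvable in float64
        assert np.linalg.norm(out) < 1.0
    if n > 1e-6:
        cos = np.dot(out, s) / (np.linalg.norm(out) * n + 1e-300)
        assert cos == pytest.approx(1.0, abs=1e-9)


def test_squash_monotone_in_input_norm():
    norms = np.linspace(0.01, 30, 50)
    out = [np.linalg.norm(sc.squash(np.array([n, 0.0]))) for n in norms]
    assert np.all(np.diff(out) > 0)


def test_squash_rejects_non_finite():
    with pytest.raises(NumericError):
        sc.squash(np.array([np.nan, 1.0]))


# ------------------------------------------------------------- configuration
def test_reshape_inexact_config_rejected():
    with pytest.raises(ConfigurationError, match="F2"):
        sc.ModelConfig(F2=63)


def test_invalid_counts_rejected():
    with pytest.raises(ConfigurationError):
        sc.ModelConfig(n_channels=0)
    with pytest.raises(ConfigurationError, match="collapses"):
        sc.ModelConfig(n_samples=16, pool1=8, pool2=8)


@pytest.mark.parametrize("n_samples", [3073, 2049])
def test_layer_plan_conformance(n_samples):
    """5 conv + 2 pool layers; spatial kernel (C, 1); separable depthwise
    kernel (1, 16); both the visual and auditory geometries close."""
    cfg = sc.ModelConfig(n_samples=n_samples)
    plan = sc.layer_plan(cfg)
    kinds = [spec.kind for spec in plan]
    assert kinds.count("conv") == 5 and kinds.count("pool") == 2
    assert plan[1].kernel == (124, 1)
    assert plan[3].kernel == (1, 16)
    assert plan[-1].out_shape == (cfg.F2, 1, 1)


def _small_valid_configs():
    rng = np.random.default_rng(2024)
    configs = []
    while len(configs) < 5:
        n_caps = int(rng.integers(2, 6))
        d_caps = int(rng.integers(2, 6))
        cfg = dict(
            n_channels=int(rng.integers(2, 10)),
            n_samples=int(rng.integers(64, 200)),
            F1=int(rng.integers(2, 6)), TI=int(rng.integers(3, 17)),
            D=int(rng.integers(1, 3)), pool1=int(rng.integers(2, 5)),
            pool2=int(rng.integers(2, 5)),
            n_caps=n_caps, d_caps=d_caps, F2=n_caps * d_caps,
            d_out=int(rng.integers(2, 8)),
        )
        try:
            configs.append(sc.ModelConfig(**cfg))
        except ConfigurationError:
            continue
    return configs


@pytest.mark.parametrize("cfg", _small_valid_configs(),
                         ids=lambda c: f"C{c.n_channels}T{c.n_samples}")
def test_plan_shapes_match_forward(cfg):
    stcg = sc.build_stcg(cfg, seed=1)
    x = np.random.default_rng(0).normal(size=(3, cfg.n_channels, cfg.n_samples))
    caps = np.asarray(stcg.forward(x))
    assert caps.shape == (3, cfg.n_caps, cfg.d_caps)
    f, h, w = stcg.plan[-1].out_shape
    assert f * h * w == cfg.n_caps * cfg.d_caps


def test_forward_output_squashed_and_deterministic(tiny_model_config, tiny_eset):
    stcg = sc.build_stcg(tiny_model_config, seed=3)
    a = np.asarray(stcg.forward(tiny_eset.data))
    b = np.asarray(stcg.forward(tiny_eset.data))
    np.testing.assert_array_equal(a, b)
    norms = np.linalg.norm(a, axis=-1)
    assert np.all(norms >= 0) and np.all(norms < 1)


def test_forward_geometry_mismatch_named(tiny_model_config):
    stcg = sc.build_stcg(tiny_model_config)
    with pytest.raises(ShapeError, match="expected batch"):
        stcg.forward(np.zeros((2, 4, 128)))


def test_spatial_params_linear_in_channels():
    """Spatial depthwise parameters scale linearly with C; temporal
    parameters do not depend on C."""
    def plan_for(C):
        return {spec.name: spec.params for spec in sc.layer_plan(
            sc.ModelConfig(n_channels=C))}

    p64, p124, p248 = plan_for(64), plan_for(124), plan_for(248)
    assert p124["temporal_conv"] == p64["temporal_conv"] == p248["temporal_conv"]
    slope1 = (p124["spatial_depthwise_conv"] - p64["spatial_depthwise_conv"]) / (124 - 64)
    slope2 = (p248["spatial_depthwise_conv"] - p124["spatial_depthwise_conv"]) / (248 - 124)
    assert slope1 == slope2 > 0
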