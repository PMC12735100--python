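"""Architecture contracts: shape traces, parameter accounting, component
behavior on hand-analyzable inputs, and checkpoint round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from macnext import nn
from macnext.architecture import (
    MACNeXtBlock,
    PredictionBatch,
    ShapeTrace,
    build_model,
    count_parameters,
    downsample_forward,
    head_forward,
    load_checkpoint,
    macnext_block_forward,
    save_checkpoint,
    stem_forward,
    trace_shapes,
)
from macnext.config import ConfigError, MACNeXtConfig

from conftest import tiny_config


def make_bn_identity(bn: nn.BatchNorm2d) -> None:
    """Identity-affine inference BN: running_var chosen so var + eps == 1."""
    bn.gamma.data[...] = 1
    bn.beta.data[...] = 0
    bn.running_mean[...] = 0
    bn.running_var[...] = 1.0 - bn.eps


def zero_convs(module) -> None:
    for layer in module.layers():
        if isinstance(layer, nn.Conv2d):
            layer.weight.data[...] = 0
        elif isinstance(layer, nn.BatchNorm2d):
            make_bn_identity(layer)


# ---------------------------------------------------------------- stem ----

def test_stem_default_shape():
    cfg = MACNeXtConfig()
    out = stem_forward(np.zeros((1, 3, 224, 224), np.float32), cfg)
    assert out.shape == (1, 96, 56, 56)


def test_stem_half_size_input():
    cfg = MACNeXtConfig()
    out = stem_forward(np.zeros((2, 3, 112, 112), np.float32), cfg)
    assert out.shape == (2, 96, 28, 28)


def test_stem_zero_input_zero_output():
    # GELU(0) = 0 and BN with zero mean / unit variance keeps zeros at zero
    cfg = tiny_config()
    from macnext.architecture import Stem

    stem = Stem(cfg, np.random.default_rng(0))
    for layer in stem.layers():
        if isinstance(layer, nn.BatchNorm2d):
            make_bn_identity(layer)
    out = stem.forward(np.zeros((1, 3, 64, 64), np.float32))
    np.testing.assert_array_equal(out, 0)


def test_stem_rejects_bad_input():
    cfg = MACNeXtConfig()
    with pytest.raises(ValueError, match="channels"):
        stem_forward(np.zeros((1, 4, 64, 64), np.float32), cfg)
    bad = np.full((1, 3, 64, 64), np.nan, np.float32)
    with pytest.raises(ValueError, match="finite"):
        stem_forward(bad, cfg)


# --------------------------------------------------------------- block ----

def test_block_preserves_shape():
    cfg = MACNeXtConfig()
    x = np.random.default_rng(0).normal(size=(1, 96, 14, 14)).astype(np.float32)
    out = macnext_block_forward(x, 96, cfg)
    assert out.shape == x.shape


def test_block_identity_when_convs_zeroed():
    cfg = tiny_config()
    block = MACNeXtBlock(16, cfg, np.random.default_rng(0))
    zero_convs(block)
    x = np.random.default_rng(1).normal(size=(2, 16, 8, 8)).astype(np.float32)
    np.testing.assert_array_equal(block.forward(x), x)


def test_block_rejects_width_mismatch():
    cfg = tiny_config()
    with pytest.raises(ValueError, match="channels"):
        macnext_block_forward(np.zeros((1, 8, 8, 8), np.float32), 16, cfg)


def test_block_width_group_divisibility_enforced():
    with pytest.raises(ConfigError, match="divide"):
        tiny_config(channels_per_group=12)


# ---------------------------------------------------------- downsample ----

@pytest.mark.parametrize(
    "side_in,f,side_out",
    [(56, 96, 28), (14, 384, 7), (15, 32, 8)],
)
def test_downsample_halves_and_doubles(side_in, f, side_out):
    cfg = MACNeXtConfig()
    x = np.zeros((1, f, side_in, side_in), np.float32)
    out = downsample_forward(x, f, cfg)
    assert out.shape == (1, 2 * f, side_out, side_out)


# ---------------------------------------------------------------- head ----

def test_head_probabilities_normalized():
    cfg = MACNeXtConfig(num_classes=24)
    x = np.random.default_rng(0).normal(size=(3, 768, 7, 7)).astype(np.float32)
    pred = head_forward(x, cfg)
    assert pred.probabilities.shape == (3, 24)
    np.testing.assert_allclose(pred.probabilities.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(pred.probabilities >= 0)


def test_head_zero_fc_gives_uniform():
    cfg = tiny_config(num_classes=4)
    from macnext.architecture import Head

    head = Head(cfg, np.random.default_rng(0))
    head.fc.weight.data[...] = 0
    head.fc.bias.data[...] = 0
    x = np.random.default_rng(1).normal(size=(5, 32, 4, 4)).astype(np.float32)
    logits = head.forward(x)
    probs = nn.softmax(logits, axis=1)
    np.testing.assert_allclose(probs, 0.25, atol=1e-7)


def test_gap_of_constant_map_is_the_constant():
    pool = nn.GlobalAvgPool()
    c = np.arange(1.0, 6.0)
    x = np.broadcast_to(c[None, :, None, None], (2, 5, 7, 7)).copy()
    np.testing.assert_allclose(pool.forward(x), np.tile(c, (2, 1)))


# --------------------------------------------------------------- trace ----

def test_trace_doubles_with_input_size():
    base = trace_shapes(MACNeXtConfig())
    big = trace_shapes(MACNeXtConfig(input_height=448, input_width=448))
    for (s1, h1, w1, c1), (s2, h2, w2, c2) in zip(base, big):
        assert (s1, c1) == (s2, c2)
        assert (h2, w2) == (2 * h1, 2 * w1)


def test_trace_monotonicity():
    tr = trace_shapes(MACNeXtConfig())
    hs = [h for _, h, _, _ in tr]
    cs = [c for _, _, _, c in tr]
    assert hs == sorted(hs, reverse=True)
    assert cs == sorted(cs)


@pytest.mark.parametrize("seed", range(5))
def test_analytic_trace_matches_built_network(seed):
    rng = np.random.default_rng(seed)
    w0 = int(rng.choice([4, 8]))
    n_stages = int(rng.integers(2, 4))
    side = int(rng.choice([48, 64, 80]))
    cfg = MACNeXtConfig(
        input_height=side,
        input_width=side,
        stem_widths=(w0, 2 * w0),
        stage_widths=tuple(2 * w0 * 2**i for i in range(n_stages)),
        stage_repeats=tuple(int(rng.integers(1, 3)) for _ in range(n_stages)),
        channels_per_group=2,
        num_classes=int(rng.integers(2, 6)),
        init_seed=seed,
    )
    model = build_model(cfg)
    batch = rng.normal(size=(2, 3, side, side)).astype(np.float32)
    assert model.observed_trace(batch) == trace_shapes(cfg)


# ---------------------------------------------------------- parameters ----

def test_fc_parameter_count():
    cfg = MACNeXtConfig(num_classes=24)
    breakdown = count_parameters(cfg, "closed_form")
    fc = dict(breakdown.entries)["head.fc"]
    assert fc == 768 * 24 + 24 == 18456


def test_class_count_only_moves_fc():
    t24 = count_parameters(MACNeXtConfig(num_classes=24), "closed_form").total
    t25 = count_parameters(MACNeXtConfig(num_classes=25), "closed_form").total
    assert t25 - t24 == 768 + 1  # one extra FC row plus its bias


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    w0=st.sampled_from([4, 8, 12]),
    n_stages=st.integers(2, 3),
    repeats=st.integers(1, 3),
    cpg=st.sampled_from([1, 2, 4]),
    expansion_grouped=st.booleans(),
    squeeze_grouped=st.booleans(),
    n=st.integers(2, 10),
)
def test_closed_form_equals_enumeration(w0, n_stages, repeats, cpg, expansion_grouped, squeeze_grouped, n):
    if cpg % 2 and squeeze_grouped:
        squeeze_grouped = False  # 2F -> F grouped squeeze needs an even group width
    if w0 % cpg:
        w0 = cpg * max(1, w0 // cpg)
    cfg = MACNeXtConfig(
        input_height=64,
        input_width=64,
        stem_widths=(w0, 2 * w0),
        stage_widths=tuple(2 * w0 * 2**i for i in range(n_stages)),
        stage_repeats=(repeats,) * n_stages,
        channels_per_group=cpg,
        expansion_grouped=expansion_grouped,
        squeeze_grouped=squeeze_grouped,
        num_classes=n,
    )
    closed = count_parameters(cfg, "closed_form")
    built = count_parameters(cfg, "built")
    assert closed.total == built.total


def test_breakdown_total_is_sum_of_entries():
    b = count_parameters(MACNeXtConfig(), "closed_form")
    assert b.total == sum(c for _, c in b.entries)


# ------------------------------------------------------- build & model ----

def test_build_rejects_invalid_config_with_named_invariant():
    with pytest.raises(ConfigError, match="double"):
        MACNeXtConfig(stage_widths=(96, 180, 384, 768))
    with pytest.raises(ConfigError, match="stem width"):
        MACNeXtConfig(stem_widths=(48, 64))
    with pytest.raises(ConfigError, match="collapses"):
        MACNeXtConfig(input_height=16, input_width=16, **{
            k: v for k, v in dict(
                stem_widths=(8, 16), stage_widths=(16, 32, 64, 128),
                stage_repeats=(1, 1, 1, 1), num_classes=4).items()
        })


def test_same_seed_same_initial_weights():
    cfg = tiny_config(init_seed=9)
    a, b = build_model(cfg), build_model(cfg)
    for pa, pb in zip(a.parameters(), b.parameters()):
        np.testing.assert_array_equal(pa.data, pb.data)
    c = build_model(tiny_config(init_seed=10))
    assert any(
        not np.array_equal(pa.data, pc.data)
        for pa, pc in zip(a.parameters(), c.parameters())
    )


def test_no_cross_sample_leakage_in_inference():
    cfg = tiny_config(input_height=32, input_width=32)
    model = build_model(cfg)
    rng = np.random.default_rng(5)
    x = rng.normal(size=(6, 3, 32, 32)).astype(np.float32)
    batched = model.predict(x).probabilities
    singly = np.concatenate([model.predict(x[i : i + 1]).probabilities for i in range(6)])
    np.testing.assert_allclose(batched, singly, atol=1e-6)


def test_checkpoint_round_trip_bit_exact(tmp_path):
    cfg = tiny_config(init_seed=2)
    model = build_model(cfg)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, 3, 64, 64)).astype(np.float32)
    model.forward_logits(x, training=True)  # move the BN running statistics
    before = model.predict(x).probabilities
    path = tmp_path / "model.ckpt"
    save_checkpoint(model, path)
    clone = load_checkpoint(path)
    np.testing.assert_array_equal(before, clone.predict(x).probabilities)


def test_prediction_batch_validates_rows():
    with pytest.raises(ValueError, match="sum to 1"):
        PredictionBatch(np.array([[0.5, 0.2]]))
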