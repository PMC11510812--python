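"""Leave-one-out pairing, block machinery and training contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectral_n2i.n2i import (
    BlockSpec,
    ModelConfig,
    N2IError,
    TrainingPair,
    assemble_blocks,
    denoise,
    extract_blocks,
    load_model,
    make_loo_pairs,
    save_model,
    train,
)
from spectral_n2i.recon import SpectralImageStack


def stack_of(value_or_array, channels=4, size=16):
    if np.isscalar(value_or_array):
        px = np.full((channels, size, size), float(value_or_array))
    else:
        px = np.asarray(value_or_array)
    return SpectralImageStack(px, 20.0 + np.arange(px.shape[0]) * 1.0)


# ---------------------------------------------------------------- LOO pairs
def test_k2_pairs_swap_roles():
    a, b = stack_of(1.0), stack_of(2.0)
    pairs = make_loo_pairs([a, b])
    np.testing.assert_array_equal(pairs[0].input.pixels, b.pixels)
    np.testing.assert_array_equal(pairs[0].target.pixels, a.pixels)
    np.testing.assert_array_equal(pairs[1].input.pixels, a.pixels)
    np.testing.assert_array_equal(pairs[1].target.pixels, b.pixels)


def test_identical_stacks_give_identical_pairs():
    stacks = [stack_of(3.3) for _ in range(4)]
    for pair in make_loo_pairs(stacks):
        np.testing.assert_allclose(pair.input.pixels, pair.target.pixels, rtol=1e-15)


def test_k4_constant_fixture_inputs():
    stacks = [stack_of(v) for v in (1.0, 2.0, 3.0, 4.0)]
    pairs = make_loo_pairs(stacks)
    inputs = [p.input.pixels.flat[0] for p in pairs]
    np.testing.assert_allclose(inputs, [3.0, 8.0 / 3.0, 7.0 / 3.0, 2.0])


def test_leave_one_out_mean_identity(rng):
    stacks = [stack_of(rng.standard_normal((4, 16, 16))) for _ in range(4)]
    pairs = make_loo_pairs(stacks)
    mean_inputs = np.mean([p.input.pixels for p in pairs], axis=0)
    mean_stacks = np.mean([s.pixels for s in stacks], axis=0)
    np.testing.assert_allclose(mean_inputs, mean_stacks, atol=1e-14)


def test_loo_pairs_validation():
    with pytest.raises(N2IError):
        make_loo_pairs([stack_of(1.0)])
    with pytest.raises(N2IError):
        make_loo_pairs([stack_of(1.0), stack_of(1.0, size=8)])


# -------------------------------------------------------------------- blocks
def test_block_grid_matches_study_configuration():
    spec = BlockSpec((4, 16, 16), (0.75, 0.75, 0.75))
    assert spec.strides == (1, 4, 4)
    origins = spec.origins((128, 96, 96))
    assert len(origins) == 125 * 21 * 21  # 55,125 blocks


def test_block_grid_volumetric_stride_rule():
    spec = BlockSpec((4, 16, 16, 16), (0.75, 0.5, 0.5, 0.5))
    assert spec.strides == (1, 8, 8, 8)


def test_single_block_when_block_equals_stack(rng):
    data = rng.standard_normal((4, 16, 16))
    blocks, origins = extract_blocks(data, BlockSpec((4, 16, 16), (0.5, 0.5, 0.5)))
    assert len(blocks) == 1 and origins == [(0, 0, 0)]
    np.testing.assert_array_equal(blocks[0], data)


@given(
    e=st.integers(5, 12), h=st.integers(17, 40),
    oe=st.sampled_from([0.0, 0.5, 0.75]), oh=st.sampled_from([0.0, 0.5, 0.75]),
)
@settings(max_examples=20, deadline=None, derandomize=True)
def test_block_round_trip_identity(e, h, oe, oh):
    rng = np.random.default_rng(e * 100 + h)
    data = rng.standard_normal((e, h, h))
    spec = BlockSpec((4, 16, 16), (oe, oh, oh))
    blocks, origins = extract_blocks(data, spec)
    back = assemble_blocks(blocks, origins, data.shape)
    np.testing.assert_array_equal(back, data)


def test_overlap_averaging_of_two_blocks():
    shape = (1, 4, 6)
    blocks = np.array([np.full((1, 4, 4), 1.0), np.full((1, 4, 4), 3.0)])
    back = assemble_blocks(blocks, [(0, 0, 0), (0, 0, 2)], shape)
    np.testing.assert_array_equal(back[0, :, 2:4], 2.0)  # (1+3)/2 in overlap
    np.testing.assert_array_equal(back[0, :, :2], 1.0)
    np.testing.assert_array_equal(back[0, :, 4:], 3.0)


def test_block_larger_than_stack_raises():
    with pytest.raises(N2IError):
        extract_blocks(np.zeros((2, 8, 8)), BlockSpec((4, 16, 16), (0, 0, 0)))


def test_uncovered_voxel_raises():
    blocks = np.zeros((1, 1, 4, 4))
    with pytest.raises(N2IError):
        assemble_blocks(blocks, [(0, 0, 0)], (1, 4, 8))


# ------------------------------------------------------------------ training
def small_config(**kw):
    defaults = dict(base_channels=4, epochs=5, seed=0, lr=1e-3)
    defaults.update(kw)
    return ModelConfig(**defaults)


def test_published_configuration_accepted_verbatim():
    cfg = ModelConfig(depth=3, base_channels=32, lr=1e-4, epochs=100, batch_size=32)
    assert cfg.depth == 3 and cfg.lr == 1e-4 and cfg.epochs == 100


def test_identity_task_overfits(rng):
    base = rng.standard_normal((4, 64, 64))
    stack = stack_of(base)
    pair = TrainingPair(stack, stack_of(base.copy()), 0)
    spec = BlockSpec((4, 16, 16), (0.5, 0.5, 0.5))
    model = train([pair], spec, small_config(epochs=20, lr=3e-3))
    assert model.training_log[-1] < 0.1 * model.training_log[0]


def test_training_is_seed_deterministic(rng):
    base = rng.standard_normal((4, 32, 32))
    noisy = base + 0.3 * rng.standard_normal((4, 32, 32))
    pair = TrainingPair(stack_of(base), stack_of(noisy), 0)
    spec = BlockSpec((4, 16, 16), (0.5, 0.5, 0.5))
    log1 = train([pair], spec, small_config()).training_log
    log2 = train([pair], spec, small_config()).training_log
    assert log1 == log2


def test_block_channel_mismatch_raises():
    pair = TrainingPair(stack_of(1.0), stack_of(2.0), 0)
    with pytest.raises(N2IError):
        train([pair], BlockSpec((2, 16, 16), (0, 0, 0)), small_config())


def test_identity_network_denoise_returns_mean(rng):
    stacks = [stack_of(rng.standard_normal((4, 32, 32))) for _ in range(4)]
    pairs = make_loo_pairs(stacks)
    spec = BlockSpec((4, 16, 16), (0.5, 0.5, 0.5))
    model = train(pairs, spec, small_config(epochs=1))
    # force the residual network to the identity map by zeroing every weight
    for p, _ in model.network.params():
        p[...] = 0.0
    out = denoise(model, stacks)
    expected = np.mean([s.pixels for s in stacks], axis=0)
    np.testing.assert_allclose(out.pixels, expected, atol=1e-5)


def test_model_save_load_round_trip(tmp_path, rng):
    base = rng.standard_normal((4, 32, 32))
    pair = TrainingPair(stack_of(base), stack_of(base.copy()), 0)
    spec = BlockSpec((4, 16, 16), (0.5, 0.5, 0.5))
    model = train([pair], spec, small_config(epochs=2))
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    assert back.training_log == model.training_log
    stacks = [stack_of(base) for _ in range(2)]
    np.testing.assert_allclose(
        denoise(back, stacks).pixels, denoise(model, stacks).pixels, atol=1e-6
    )
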