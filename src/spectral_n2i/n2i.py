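"""Self-supervised spectral-CT denoising by leave-one-out projection splits.

The measurement noise in CT is independent from projection to projection,
so reconstructions from K mutually exclusive angular subsets carry
independent noise realisations of the same underlying image.  A network is
trained to predict the reconstruction of each held-out subset (target) from
the mean of the other K-1 reconstructions (input); because the noise is
unpredictable, the minimum-MSE predictor converges towards the clean image.
Training operates on small overlapping energy-spatial blocks whose energy
depth (default 4 channels) maps onto the network's convolution channels,
which regularises along the energy axis.  At inference the network is
applied to the average of all K reconstructions and overlapping block
predictions are averaged back into a full stack.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np

from .nn import Adam, UNet2d, mse_loss
from .recon import SpectralImageStack

__all__ = [
    "N2IError",
    "TrainingPair",
    "BlockSpec",
    "ModelConfig",
    "DenoisingModel",
    "make_loo_pairs",
    "extract_blocks",
    "assemble_blocks",
    "train",
    "denoise",
    "save_model",
    "load_model",
]


class N2IError(ValueError):
    pass


@dataclass
class TrainingPair:
    """input = mean of K-1 subset reconstructions; target = the held-out one."""

    input: SpectralImageStack
    target: SpectralImageStack
    heldout_index: int

    def __post_init__(self):
        if self.input.pixels.shape != self.target.pixels.shape:
            raise N2IError("input and target must share shape")
        if not np.array_equal(self.input.energies, self.target.energies):
            raise N2IError("input and target must share the energy grid")


@dataclass(frozen=True)
class BlockSpec:
    """Overlapping (energy, height, width) block grid.

    stride per axis = max(1, round(size * (1 - overlap))); a final flush
    block is added on each axis when the stride grid does not reach the
    border, so every voxel is covered.
    """

    block_shape: tuple[int, ...] = (4, 16, 16)
    overlap: tuple[float, ...] = (0.75, 0.75, 0.75)

    def __post_init__(self):
        if len(self.block_shape) != len(self.overlap):
            raise N2IError("block_shape and overlap must have equal length")
        if any(s < 1 for s in self.block_shape):
            raise N2IError("block sides must be >= 1")
        if any(not (0.0 <= o < 1.0) for o in self.overlap):
            raise N2IError("overlap fractions must be in [0, 1)")

    @property
    def strides(self) -> tuple[int, ...]:
        return tuple(
            max(1, int(round(s * (1.0 - o))))
            for s, o in zip(self.block_shape, self.overlap)
        )

    def origins(self, shape: tuple[int, ...]) -> list[tuple[int, ...]]:
        if len(shape) != len(self.block_shape):
            raise N2IError("stack rank does not match block spec")
        axes = []
        for size, block, stride in zip(shape, self.block_shape, self.strides):
            if block > size:
                raise N2IError(f"block {block} larger than axis size {size}")
            starts = list(range(0, size - block + 1, stride))
            if starts[-1] != size - block:  # flush block at the border
                starts.append(size - block)
            axes.append(starts)
        return list(itertools.product(*axes))


@dataclass
class ModelConfig:
    """U-Net and optimisation settings (defaults follow the study setup)."""

    depth: int = 3
    base_channels: int = 32
    in_out_channels: int = 4  # == energy depth of the blocks
    activation: str = "relu"
    norm: str = "batch"
    pooling: str = "max"
    lr: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    normalize: bool = True  # standardise blocks by training-input mean/SD
    residual: bool = True  # network predicts the correction to its input

    def __post_init__(self):
        if min(self.depth, self.base_channels, self.in_out_channels,
               self.epochs, self.batch_size) < 1:
            raise N2IError("all counts must be positive")
        if (self.activation, self.norm, self.pooling) != ("relu", "batch", "max"):
            raise N2IError("only relu/batch/max variants are implemented")


@dataclass
class DenoisingModel:
    network: UNet2d
    config: ModelConfig
    block_spec: BlockSpec
    training_log: list[float] = field(default_factory=list)
    input_mean: float = 0.0
    input_sd: float = 1.0


def make_loo_pairs(recons: list[SpectralImageStack]) -> list[TrainingPair]:
    """K leave-one-out pairs from K subset reconstructions."""
    k = len(recons)
    if k < 2:
        raise N2IError("need K >= 2 subset reconstructions")
    shape = recons[0].pixels.shape
    if any(r.pixels.shape != shape for r in recons):
        raise N2IError("all reconstructions must share shape")
    pairs = []
    for j in range(k):
        others = [recons[i].pixels for i in range(k) if i != j]
        mean = np.mean(others, axis=0)
        pairs.append(
            TrainingPair(
                SpectralImageStack(
                    mean, recons[j].energies, {"role": f"loo_input_{j}"}
                ),
                recons[j],
                heldout_index=j,
            )
        )
    return pairs


def extract_blocks(stack, spec: BlockSpec):
    """All overlapping blocks plus their origin coordinates.

    Returns (blocks (N, e, h, w), origins list of (e0, y0, x0)).
    """
    data = stack.pixels if hasattr(stack, "pixels") else np.asarray(stack)
    origins = spec.origins(data.shape)
    blocks = np.empty((len(origins),) + tuple(spec.block_shape), dtype=data.dtype)
    for i, origin in enumerate(origins):
        sl = tuple(slice(o, o + b) for o, b in zip(origin, spec.block_shape))
        blocks[i] = data[sl]
    return blocks, origins


def assemble_blocks(blocks, origins, shape: tuple[int, ...]) -> np.ndarray:
    """Average overlapping block predictions back into a full stack."""
    blocks = np.asarray(blocks)
    if len(blocks) != len(origins):
        raise N2IError("blocks and origins must have equal length")
    bshape = blocks.shape[1:]
    # extended-precision accumulator: the mean of up to ~2000 identical
    # copies of a float64 value is then bit-exact (round-trip identity)
    acc = np.zeros(shape, dtype=np.longdouble)
    count = np.zeros(shape, dtype=np.int64)
    for block, origin in zip(blocks, origins):
        sl = tuple(slice(o, o + b) for o, b in zip(origin, bshape))
        acc[sl] += block
        count[sl] += 1
    if np.any(count == 0):
        raise N2IError("blocks do not cover every voxel")
    return np.asarray(acc / count, dtype=np.float64)


def train(
    pairs: list[TrainingPair],
    spec: BlockSpec,
    config: ModelConfig,
    verbose: bool = False,
) -> DenoisingModel:
    """Minimise MSE between network(input blocks) and target blocks."""
    if not pairs:
        raise N2IError("no training pairs")
    if spec.block_shape[0] != config.in_out_channels:
        raise N2IError(
            f"block energy depth {spec.block_shape[0]} != network channels "
            f"{config.in_out_channels}"
        )
    xs, ys = [], []
    for pair in pairs:
        bx, _ = extract_blocks(pair.input, spec)
        by, _ = extract_blocks(pair.target, spec)
        xs.append(bx)
        ys.append(by)
    x = np.concatenate(xs).astype(np.float32)
    y = np.concatenate(ys).astype(np.float32)

    if config.normalize:
        mean = float(x.mean())
        sd = float(x.std()) or 1.0
    else:
        mean, sd = 0.0, 1.0
    x = (x - mean) / sd
    y = (y - mean) / sd
    if config.residual:
        y = y - x  # learn the correction; prediction adds the input back

    net = UNet2d(
        config.in_out_channels,
        config.in_out_channels,
        base_channels=config.base_channels,
        depth=config.depth,
        seed=config.seed,
    )
    opt = Adam(net.params(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    log = []
    n = len(x)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            out = net.forward(x[idx], training=True)
            loss, grad = mse_loss(out, y[idx])
            net.backward(grad)
            opt.step()
            losses.append(loss)
        log.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}  loss {log[-1]:.6f}")
    return DenoisingModel(net, config, spec, log, mean, sd)


def _predict_blocks(model: DenoisingModel, blocks: np.ndarray) -> np.ndarray:
    x = (blocks.astype(np.float32) - model.input_mean) / model.input_sd
    out = np.empty_like(x)
    bs = model.config.batch_size
    for start in range(0, len(x), bs):
        out[start : start + bs] = model.network.forward(
            x[start : start + bs], training=False
        )
    if model.config.residual:
        out += x
    return out * model.input_sd + model.input_mean


def denoise(
    model: DenoisingModel,
    recons: list[SpectralImageStack],
    spec: BlockSpec | None = None,
) -> SpectralImageStack:
    """Apply the trained network to the mean of the K reconstructions.

    The inference input equals the mean of the K leave-one-out training
    inputs, which is algebraically the mean of the K reconstructions.
    """
    spec = spec or model.block_spec
    if spec.block_shape[0] != model.config.in_out_channels:
        raise N2IError("block energy depth does not match the trained model")
    mean_stack = np.mean([r.pixels for r in recons], axis=0)
    blocks, origins = extract_blocks(mean_stack, spec)
    pred = _predict_blocks(model, blocks)
    out = assemble_blocks(pred, origins, mean_stack.shape)
    return SpectralImageStack(
        out,
        recons[0].energies,
        {"method": "noise2inverse", "K": len(recons), "epochs": model.config.epochs},
    )


def save_model(model: DenoisingModel, path) -> None:
    """Single-file .npz archive: config, block spec, weights, training log."""
    meta = {
        "config": model.config.__dict__,
        "block_spec": {
            "block_shape": list(model.block_spec.block_shape),
            "overlap": list(model.block_spec.overlap),
        },
        "training_log": model.training_log,
        "input_mean": model.input_mean,
        "input_sd": model.input_sd,
    }
    state = model.network.state_dict()
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_model(path) -> DenoisingModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    config = ModelConfig(**meta["config"])
    spec = BlockSpec(
        tuple(meta["block_spec"]["block_shape"]),
        tuple(meta["block_spec"]["overlap"]),
    )
    net = UNet2d(
        config.in_out_channels,
        config.in_out_channels,
        base_channels=config.base_channels,
        depth=config.depth,
        seed=config.seed,
    )
    net.load_state_dict(state)
    return DenoisingModel(
        net, config, spec, list(meta["training_log"]),
        float(meta["input_mean"]), float(meta["input_sd"]),
    )
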