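"""Comparison methods: Low2High filter-pair training and TV-regularised
iterative reconstruction (IR-TV).

Low2High forms a self-supervision pair from a *single* full-angle sinogram
by reconstructing twice with different ramp apodisations: a Hann low-pass
reconstruction (cutoff 0.2 of Nyquist, nearly noise-free input) and the
standard Ram-Lak reconstruction (noisy, full-band target).  The network
learns to restore the coherent high frequencies; at inference it is applied
to the low-pass reconstruction.

IR-TV minimises 0.5 ||A x - y||^2 + alpha TV(x) channel-by-channel with
FISTA; the proximal TV step uses the Chambolle projection algorithm
(scikit-image) and the gradient step size comes from a power-iteration
estimate of ||A||^2.  TV is isotropic and strictly 2-D: no coupling along
the energy axis, which is precisely the baseline's known weakness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.restoration import denoise_tv_chambolle

from .forward import SpectralSinogram
from .n2i import BlockSpec, DenoisingModel, ModelConfig, TrainingPair, _predict_blocks
from .n2i import assemble_blocks, extract_blocks, train
from .recon import SpectralImageStack, fbp_channelwise

__all__ = [
    "TvConfig",
    "TvDivergenceError",
    "low2high_pairs",
    "low2high_denoise",
    "tv_reconstruct",
    "isotropic_tv",
]


class TvDivergenceError(FloatingPointError):
    pass


@dataclass(frozen=True)
class TvConfig:
    """IR-TV settings. Study presets: alpha=1 (phantom 1), 0.5 (phantom 2),
    0.035 (real data); 100 FISTA iterations."""

    alpha: float = 1.0
    iterations: int = 100
    seed: int = 0
    power_iterations: int = 50

    def __post_init__(self):
        if self.alpha < 0 or self.iterations < 1:
            raise ValueError("alpha must be >= 0 and iterations >= 1")


def isotropic_tv(img: np.ndarray) -> float:
    """Isotropic total variation with forward differences (edge-replicated)."""
    gx = np.diff(img, axis=1, append=img[:, -1:])
    gy = np.diff(img, axis=0, append=img[-1:, :])
    return float(np.sqrt(gx**2 + gy**2).sum())


def low2high_pairs(sino: SpectralSinogram) -> TrainingPair:
    """(Hann s=0.2 reconstruction, Ram-Lak s=1 reconstruction) from all
    projections of one sinogram — the Low2High training pair."""
    low = fbp_channelwise(sino, filter_name="hann", cutoff=0.2)
    high = fbp_channelwise(sino, filter_name="ram-lak", cutoff=1.0)
    return TrainingPair(low, high, heldout_index=-1)


def low2high_denoise(
    sino: SpectralSinogram,
    spec: BlockSpec,
    config: ModelConfig,
    verbose: bool = False,
) -> SpectralImageStack:
    """Train on (low -> high) blocks, then denoise the low reconstruction.

    The published Low2High scheme trains a plain U-Net, so the residual
    shortcut used by the Noise2Inverse denoiser is disabled here; it is
    this plain network that inherits the low-pass filter's amplitude
    shrinkage, the baseline's documented bias.
    """
    from dataclasses import replace as _replace

    config = _replace(config, residual=False)
    pair = low2high_pairs(sino)
    model: DenoisingModel = train([pair], spec, config, verbose=verbose)
    blocks, origins = extract_blocks(pair.input, spec)
    pred = _predict_blocks(model, blocks)
    out = assemble_blocks(pred, origins, pair.input.pixels.shape)
    return SpectralImageStack(
        out, sino.energies, {"method": "low2high", "epochs": config.epochs}
    )


def tv_reconstruct(
    sino: SpectralSinogram,
    config: TvConfig,
    channels=None,
) -> SpectralImageStack:
    """Channel-wise FISTA minimisation of 0.5||Ax - y||^2 + alpha TV(x).

    ``channels``: optional list of channel indices to reconstruct (default
    all).  Raises TvDivergenceError if the objective turns non-finite.
    """
    proj = sino.projector()
    a_mat = proj.system_matrix()
    at_mat = a_mat.T.tocsr()
    n = proj.grid_n

    # power iteration for the Lipschitz constant L = ||A||_2^2
    rng = np.random.default_rng(config.seed)
    v = rng.standard_normal(n * n)
    v /= np.linalg.norm(v)
    for _ in range(config.power_iterations):
        v = at_mat @ (a_mat @ v)
        v /= np.linalg.norm(v)
    lip = float(v @ (at_mat @ (a_mat @ v)))

    chan_idx = list(range(sino.n_channels)) if channels is None else list(channels)
    out = np.zeros((len(chan_idx), n, n))
    objectives = []
    for row, c in enumerate(chan_idx):
        y = sino.attenuation[c].ravel()
        x = np.zeros(n * n)
        z = x.copy()
        t = 1.0
        obj_first = None
        for _ in range(config.iterations):
            resid = a_mat @ z - y
            grad = at_mat @ resid
            x_new = z - grad / lip
            if config.alpha > 0:
                x_new = denoise_tv_chambolle(
                    x_new.reshape(n, n), weight=config.alpha / lip
                ).ravel()
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            z = x_new + ((t - 1.0) / t_new) * (x_new - x)
            x, t = x_new, t_new
            obj = 0.5 * float(((a_mat @ x - y) ** 2).sum()) + config.alpha * isotropic_tv(
                x.reshape(n, n)
            )
            if not np.isfinite(obj):
                raise TvDivergenceError(f"IR-TV objective diverged (channel {c})")
            if obj_first is None:
                obj_first = obj
        objectives.append((obj_first, obj))
        out[row] = x.reshape(n, n)
    energies = sino.energies[list(chan_idx)]
    return SpectralImageStack(
        out,
        energies,
        {
            "method": "ir-tv",
            "alpha": config.alpha,
            "iterations": config.iterations,
            "objective_first_last": [list(map(float, o)) for o in objectives],
        },
    )
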