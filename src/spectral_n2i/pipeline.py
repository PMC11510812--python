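"""End-to-end orchestration: simulate -> split/reconstruct -> train ->
denoise -> baselines -> evaluate, with reproducible on-disk artifacts.

Every stage writes its outputs plus a manifest (inputs, seeds, a hash of
the configuration) so a run can be regenerated exactly.  ``make_fixture``
produces the scaled-down study bundle used throughout the test-suite: a
two-material phantom on a small grid, a matching rebinned source spectrum
normalised to the standard 60,000 photons per detector pixel, and the
Poisson-noisy fan-beam sinogram.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import binary_erosion

from . import baselines, metrics, n2i, recon
from .forward import add_poisson_noise, project, save_sinogram_h5, load_sinogram_h5
from .geometry import default_geometry
from .phantom import center_crop, load_phantom_h5, preset_phantom, save_phantom_h5
from .spectrum import (
    EnergySpectrum,
    load_spectrum_csv,
    normalize_total_counts,
    study_channel_spectrum,
    rebin_average,
    save_spectrum_csv,
)

__all__ = ["RunConfig", "DependencyError", "FixtureError", "run_pipeline",
           "make_fixture", "fixture_spectrum"]

STAGES = ("simulate", "reconstruct", "train", "denoise", "baseline", "evaluate")


class DependencyError(RuntimeError):
    pass


class FixtureError(ValueError):
    pass


@dataclass
class RunConfig:
    """Flat configuration for the full pipeline.

    Defaults describe the scaled-down synthetic study (32 channels,
    64 x 64 phantom); the full-size study uses channels=131, grid=100,
    n_materials=4, epochs=100, base_channels=32, crop to 128 x 96 x 96.
    """

    out_dir: str = "run"
    seed: int = 0
    # simulation
    channels: int = 32
    grid: int = 64
    preset: int = 1
    n_materials: int = 2
    total_counts: float = 60000.0
    detector_pixels: int | None = None  # default 2 * grid
    n_angles: int = 360
    beam: str = "fan"
    # reconstruction
    K: int = 4
    filter: str = "ram-lak"
    cutoff: float = 1.0
    crop_channels: int | None = None
    crop_spatial: int | None = None
    # training
    block_shape: tuple = (4, 16, 16)
    overlap: tuple = (0.5, 0.5, 0.5)
    depth: int = 3
    base_channels: int = 8
    lr: float = 1e-4  # the study's published optimiser setting
    epochs: int = 20  # scaled down from 100 for single-CPU runs
    batch_size: int = 32
    # baselines
    tv_alpha: float = 1.0
    tv_iterations: int = 100
    tv_channels: tuple | None = (0,)  # None = all channels (slow)
    verbose: bool = False

    def model_config(self) -> n2i.ModelConfig:
        return n2i.ModelConfig(
            depth=self.depth,
            base_channels=self.base_channels,
            in_out_channels=self.block_shape[0],
            lr=self.lr,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.seed + 10,
        )

    def block_spec(self) -> n2i.BlockSpec:
        return n2i.BlockSpec(tuple(self.block_shape), tuple(self.overlap))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("block_shape", "overlap", "tv_channels"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, default_flow_style=None)


def fixture_spectrum(channels: int, total_counts: float = 60000.0) -> EnergySpectrum:
    """Rebin the 131-channel study spectrum down to ``channels`` coarse
    channels (dropping the highest-energy channels so 128 divides evenly)."""
    full = study_channel_spectrum(total_counts=total_counts)
    usable = 128  # 131 channels minus the 3 highest-energy ones
    if usable % channels != 0:
        raise FixtureError(f"channels must divide {usable}")
    trimmed = EnergySpectrum(
        full.bin_centers[:usable], full.fluence[:usable], full.bin_width
    )
    coarse = rebin_average(trimmed, usable // channels)
    return normalize_total_counts(coarse, total_counts)


def make_fixture(
    size: tuple[int, int, int] = (32, 64, 64),
    seed: int = 0,
    out_dir=None,
    preset: int = 1,
    n_materials: int = 2,
    n_angles: int = 360,
    beam: str = "fan",
    total_counts: float = 60000.0,
):
    """Scaled-down study bundle: phantom, spectrum and noisy sinogram.

    ``size`` is (channels, height, width) with channels >= 8 and height ==
    width >= 32.  The ground truth depends only on the size arguments; the
    seed scopes the Poisson noise.
    """
    channels, h, w = size
    if channels < 8 or h != w or h < 32:
        raise FixtureError("minimum fixture size is 8 channels and 32 x 32 pixels")
    spec = fixture_spectrum(channels, total_counts)
    ph = preset_phantom(
        preset, grid=(h, w), energies=spec.bin_centers, n_materials=n_materials
    )
    geom = default_geometry(n_angles=n_angles, detector_pixels=2 * h, beam=beam)
    clean = project(ph, geom)
    noisy = add_poisson_noise(clean, spec, seed=seed)
    bundle = {
        "phantom": ph,
        "spectrum": spec,
        "geometry": geom,
        "clean_sinogram": clean,
        "noisy_sinogram": noisy,
        "seed": seed,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_phantom_h5(ph, out / "phantom.h5")
        save_spectrum_csv(spec, out / "spectrum.csv")
        save_sinogram_h5(noisy, out / "sinogram.h5")
        manifest = {
            "size": list(size),
            "seed": seed,
            "preset": preset,
            "n_materials": n_materials,
            "n_angles": n_angles,
            "beam": beam,
            "total_counts": total_counts,
            "outputs": ["phantom.h5", "spectrum.csv", "sinogram.h5"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True))
    return bundle


def _write_manifest(out: Path, stage: str, cfg: RunConfig, inputs, outputs):
    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "inputs": sorted(inputs),
        "outputs": sorted(outputs),
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, sort_keys=True))


def _require(out: Path, stage: str, *names: str):
    for name in names:
        if not (out / name).exists():
            raise DependencyError(
                f"stage {stage!r} needs {name!r}; run the earlier stage that "
                f"produces it first (see pipeline order {STAGES})"
            )


def _phantom_rois(ph, eroded: int = 2):
    rois = []
    for mat_id, mat in enumerate(ph.metadata.get("materials", []), start=1):
        mask = ph.labels == mat_id
        if eroded:
            mask = binary_erosion(mask, iterations=eroded)
        if mask.sum() >= 4:
            rois.append(metrics.RoiMask(mask, mat["name"]))
    return rois


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Run the requested stages; returns {stage: outputs} summary."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    if "simulate" in stages:
        make_fixture(
            (config.channels, config.grid, config.grid),
            seed=config.seed,
            out_dir=out,
            preset=config.preset,
            n_materials=config.n_materials,
            n_angles=config.n_angles,
            beam=config.beam,
            total_counts=config.total_counts,
        )
        _write_manifest(out, "simulate", config, [],
                        ["phantom.h5", "spectrum.csv", "sinogram.h5"])
        summary["simulate"] = ["phantom.h5", "spectrum.csv", "sinogram.h5"]

    if "reconstruct" in stages:
        _require(out, "reconstruct", "sinogram.h5")
        sino = load_sinogram_h5(out / "sinogram.h5")
        full = recon.fbp_channelwise(sino, config.filter, config.cutoff)
        recon.save_stack_h5(full, out / "recon_full.h5")
        _, subs = recon.split_angles(sino, config.K)
        names = ["recon_full.h5"]
        for j, sub in enumerate(subs):
            stack = recon.fbp_channelwise(sub, config.filter, config.cutoff)
            recon.save_stack_h5(stack, out / f"recon_sub{j}.h5")
            names.append(f"recon_sub{j}.h5")
        _write_manifest(out, "reconstruct", config, ["sinogram.h5"], names)
        summary["reconstruct"] = names

    if "train" in stages:
        _require(out, "train", *[f"recon_sub{j}.h5" for j in range(config.K)])
        recons = [
            recon.load_stack_h5(out / f"recon_sub{j}.h5") for j in range(config.K)
        ]
        if config.crop_channels or config.crop_spatial:
            recons = [
                center_crop(
                    r,
                    config.crop_spatial or r.pixels.shape[1],
                    config.crop_channels or r.n_channels,
                )
                for r in recons
            ]
        pairs = n2i.make_loo_pairs(recons)
        model = n2i.train(pairs, config.block_spec(), config.model_config(),
                          verbose=config.verbose)
        n2i.save_model(model, out / "model.npz")
        _write_manifest(out, "train", config,
                        [f"recon_sub{j}.h5" for j in range(config.K)], ["model.npz"])
        summary["train"] = ["model.npz"]

    if "denoise" in stages:
        _require(out, "denoise", "model.npz",
                 *[f"recon_sub{j}.h5" for j in range(config.K)])
        model = n2i.load_model(out / "model.npz")
        recons = [
            recon.load_stack_h5(out / f"recon_sub{j}.h5") for j in range(config.K)
        ]
        if config.crop_channels or config.crop_spatial:
            recons = [
                center_crop(
                    r,
                    config.crop_spatial or r.pixels.shape[1],
                    config.crop_channels or r.n_channels,
                )
                for r in recons
            ]
        denoised = n2i.denoise(model, recons)
        recon.save_stack_h5(denoised, out / "denoised.h5")
        _write_manifest(out, "denoise", config, ["model.npz"], ["denoised.h5"])
        summary["denoise"] = ["denoised.h5"]

    if "baseline" in stages:
        _require(out, "baseline", "sinogram.h5")
        sino = load_sinogram_h5(out / "sinogram.h5")
        tv_cfg = baselines.TvConfig(
            alpha=config.tv_alpha, iterations=config.tv_iterations,
            seed=config.seed + 20,
        )
        tv_stack = baselines.tv_reconstruct(
            sino, tv_cfg,
            channels=None if config.tv_channels is None else list(config.tv_channels),
        )
        recon.save_stack_h5(tv_stack, out / "tv.h5")
        l2h = baselines.low2high_denoise(
            sino, config.block_spec(), config.model_config(),
            verbose=config.verbose,
        )
        recon.save_stack_h5(l2h, out / "low2high.h5")
        _write_manifest(out, "baseline", config, ["sinogram.h5"],
                        ["tv.h5", "low2high.h5"])
        summary["baseline"] = ["tv.h5", "low2high.h5"]

    if "evaluate" in stages:
        _require(out, "evaluate", "phantom.h5", "recon_full.h5")
        ph = load_phantom_h5(out / "phantom.h5")
        reports = {}
        for name in ("recon_full", "denoised", "low2high"):
            path = out / f"{name}.h5"
            if not path.exists():
                continue
            stack = recon.load_stack_h5(path)
            truth = ph
            if stack.pixels.shape != ph.lac.shape:
                truth = center_crop(
                    ph, stack.pixels.shape[1], stack.pixels.shape[0]
                )
            report = metrics.evaluate_stack(stack, truth, rois=_phantom_rois(truth))
            (out / f"report_{name}.json").write_text(report.to_json())
            report.save_csv(out / f"report_{name}.csv")
            reports[name] = report.summary
        _write_manifest(out, "evaluate", config, ["phantom.h5"],
                        [f"report_{k}.json" for k in reports])
        summary["evaluate"] = reports

    return summary
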