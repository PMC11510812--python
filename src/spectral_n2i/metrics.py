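"""Channel-wise image-quality metrics: MSE, PSNR, SSIM, CNR, ROI profiles.

Conventions follow the evaluation protocol of the denoising study exactly:

* PSNR uses the *joint* maximum of both images as the peak signal,
  PSNR = 20 log10(max(f, g)) - 10 log10(MSE(f, g)); a ``peak="reference"``
  switch gives the more common reference-max convention.
* SSIM is the local-window form with a 7x7 uniform window and constants
  c1 = (0.01 L)^2, c2 = (0.03 L)^2, L = data range of the reference.
* CNR = |mean(target) - mean(background)| / (SD(target) + SD(background)).
* Exact agreement (MSE = 0, or constant ROIs in CNR) is reported as an
  infinity sentinel, never silently capped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

__all__ = [
    "MetricError",
    "RoiMask",
    "MetricReport",
    "mse",
    "psnr",
    "ssim",
    "cnr",
    "roi_profile",
    "profile_mse",
    "evaluate_stack",
    "circular_roi",
]


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class RoiMask:
    pixels: np.ndarray  # 2-D boolean
    label: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2 or px.sum() < 1:
            raise MetricError("ROI must be a 2-D mask with >= 1 pixel")
        object.__setattr__(self, "pixels", px)


def circular_roi(shape: tuple[int, int], cx: float, cy: float, radius: float,
                 label: str = "") -> RoiMask:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return RoiMask((xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2, label)


def _check_pair(f, g):
    f = np.asarray(f, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if f.shape != g.shape:
        raise MetricError(f"shape mismatch: {f.shape} vs {g.shape}")
    return f, g


def mse(f, g) -> float:
    f, g = _check_pair(f, g)
    return float(np.mean((f - g) ** 2))


def psnr(f, g, peak: str = "joint") -> float:
    """Peak signal-to-noise ratio in dB; f is the reference image.

    ``peak="joint"`` uses max over both images (the study's printed form);
    ``peak="reference"`` uses max(f).  Returns +inf when MSE == 0.
    """
    f, g = _check_pair(f, g)
    err = mse(f, g)
    if err == 0.0:
        return float("inf")
    if peak == "joint":
        m = max(f.max(), g.max())
    elif peak == "reference":
        m = f.max()
    else:
        raise MetricError(f"unknown peak convention {peak!r}")
    if m <= 0:
        raise MetricError("peak signal must be positive")
    return float(20.0 * np.log10(m) - 10.0 * np.log10(err))


def ssim(f, g, window: int = 7, constants: tuple[float, float] | None = None) -> float:
    """Mean local structural similarity between f (reference) and g.

    Uniform ``window`` x ``window`` local statistics; constants default to
    (0.01 L)^2 and (0.03 L)^2 with L the data range of the reference.
    """
    f, g = _check_pair(f, g)
    if window > min(f.shape) or window < 2:
        raise MetricError("window must be >= 2 and fit inside the image")
    if constants is None:
        data_range = float(f.max() - f.min())
        if data_range == 0:
            data_range = max(abs(float(f.max())), 1e-12)
        c1 = (0.01 * data_range) ** 2
        c2 = (0.03 * data_range) ** 2
    else:
        c1, c2 = constants

    def filt(x):
        return uniform_filter(x, size=window, mode="reflect")

    mu_f, mu_g = filt(f), filt(g)
    var_f = filt(f * f) - mu_f**2
    var_g = filt(g * g) - mu_g**2
    cov = filt(f * g) - mu_f * mu_g
    num = (2 * mu_f * mu_g + c1) * (2 * cov + c2)
    den = (mu_f**2 + mu_g**2 + c1) * (var_f + var_g + c2)
    # crop the border where reflect-padding biases the local statistics,
    # but never crop the map away entirely (large windows on small images)
    pad = min(window // 2, (min(f.shape) - 1) // 2)
    ssim_map = (num / den)[pad:-pad, pad:-pad] if pad else num / den
    return float(ssim_map.mean())


def cnr(img, target: RoiMask, background: RoiMask) -> float:
    img = np.asarray(img, dtype=np.float64)
    for roi in (target, background):
        if roi.pixels.shape != img.shape:
            raise MetricError("ROI shape must match the image")
        if roi.pixels.sum() < 2:
            raise MetricError("each ROI needs >= 2 pixels")
    if np.any(target.pixels & background.pixels):
        raise MetricError("target and background ROIs must be disjoint")
    st, sb = img[target.pixels].mean(), img[background.pixels].mean()
    sig = img[target.pixels].std() + img[background.pixels].std()
    if sig == 0.0:
        return float("inf") if st != sb else 0.0
    return float(abs(st - sb) / sig)


def roi_profile(stack, roi: RoiMask):
    """(mean per channel, SD per channel, channel-averaged SD) over a ROI."""
    data = stack.pixels if hasattr(stack, "pixels") else stack.lac
    if roi.pixels.shape != data.shape[1:]:
        raise MetricError("ROI shape must match the stack's spatial dims")
    vals = data[:, roi.pixels]  # (E, n_roi)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1)
    return mean, sd, float(sd.mean())


def profile_mse(profile, reference) -> tuple[float, float]:
    """Mean and SD over channels of the per-channel squared error."""
    p = np.asarray(profile, dtype=np.float64)
    r = np.asarray(reference, dtype=np.float64)
    if p.shape != r.shape:
        raise MetricError("profile length mismatch")
    sq = (p - r) ** 2
    return float(sq.mean()), float(sq.std())


@dataclass
class MetricReport:
    per_channel: pd.DataFrame  # columns: energy, psnr, ssim
    summary: dict  # mean/sd over channels per metric
    roi_stats: dict = field(default_factory=dict)
    cnr_per_channel: np.ndarray | None = None

    def to_json(self) -> str:
        payload = {
            "per_channel": self.per_channel.to_dict(orient="list"),
            "summary": self.summary,
            "roi_stats": self.roi_stats,
        }
        if self.cnr_per_channel is not None:
            payload["cnr_per_channel"] = list(map(float, self.cnr_per_channel))
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "MetricReport":
        payload = json.loads(text)
        cnr_pc = payload.get("cnr_per_channel")
        return cls(
            pd.DataFrame(payload["per_channel"]),
            payload["summary"],
            payload.get("roi_stats", {}),
            np.asarray(cnr_pc) if cnr_pc is not None else None,
        )

    def save_csv(self, path) -> None:
        self.per_channel.to_csv(path, index=False)


def evaluate_stack(
    stack,
    truth,
    rois: list[RoiMask] | None = None,
    cnr_rois: tuple[RoiMask, RoiMask] | None = None,
) -> MetricReport:
    """Channel-wise PSNR/SSIM against the ground truth + ROI statistics.

    ``truth`` may be a SpectralPhantom (lac) or another image stack.
    """
    data = stack.pixels
    ref = truth.lac if hasattr(truth, "lac") else truth.pixels
    if data.shape != ref.shape:
        raise MetricError("stack and truth shapes must match")
    rows = []
    for e in range(data.shape[0]):
        rows.append(
            {
                "energy": float(stack.energies[e]),
                "psnr": psnr(ref[e], data[e]),
                "ssim": ssim(ref[e], data[e]),
            }
        )
    per_channel = pd.DataFrame(rows)
    finite = per_channel.replace(np.inf, np.nan)
    summary = {
        "psnr_mean": float(finite["psnr"].mean()),
        "psnr_sd": float(finite["psnr"].std(ddof=0)),
        "ssim_mean": float(finite["ssim"].mean()),
        "ssim_sd": float(finite["ssim"].std(ddof=0)),
    }
    roi_stats = {}
    for roi in rois or []:
        mean, sd, avg_sd = roi_profile(stack, roi)
        ref_mean = ref[:, roi.pixels].mean(axis=1)
        pm, psd = profile_mse(mean, ref_mean)
        roi_stats[roi.label or f"roi{len(roi_stats)}"] = {
            "mean_profile": list(map(float, mean)),
            "sd_profile": list(map(float, sd)),
            "channel_averaged_sd": avg_sd,
            "profile_mse_mean": pm,
            "profile_mse_sd": psd,
        }
    cnr_pc = None
    if cnr_rois is not None:
        tgt, bg = cnr_rois
        cnr_pc = np.array([cnr(data[e], tgt, bg) for e in range(data.shape[0])])
    return MetricReport(per_channel, summary, roi_stats, cnr_pc)
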