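"""Image-quality metrics for reconstruction evaluation.

Four criteria are implemented, all comparing a reconstruction R with the
reference T:

* **SSIM** — windowed luminance/contrast/structure similarity with the
  standard stabilisers c1 = (0.01 P)^2 and c2 = (0.03 P)^2, where
  P = max(T) - min(T) is the dynamic range of the reference. Computed
  with a uniform 7x7 window and unbiased local covariances, matching the
  conventional reference implementation.
* **PSNR** — 10 log10(255^2 / MSE) on the 8-bit scale. Images on the
  nominal [0, 1] scale are mapped to [0, 255] first; inputs whose values
  already exceed 1 are taken to be 8-bit.
* **NRMSE** — root-mean-square error divided by the dynamic range of
  the reference.
* **VIFP** — pixel-domain visual information fidelity: a four-scale
  Gaussian-window local-statistics model in which the distortion is
  fit as a scalar gain plus additive noise per window, and the score is
  the ratio of the information the distorted image retains about the
  source to the information in the reference (1 for identical images).

Higher SSIM/PSNR/VIFP and lower NRMSE indicate better reconstructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .errors import ValidationError

__all__ = [
    "SSIMParams",
    "VIFPParams",
    "MetricReport",
    "psnr",
    "ssim",
    "nrmse",
    "vifp",
    "evaluate_batch",
    "PSNR_CAP_DB",
]

PSNR_CAP_DB = 100.0  # sentinel for identical images in aggregate reports


@dataclass(frozen=True)
class SSIMParams:
    """Stabilisation constants and window of the SSIM computation."""

    win_size: int = 7
    k1_const: float = 0.01
    k2_const: float = 0.03

    def constants(self, data_range: float) -> tuple[float, float]:
        if data_range <= 0:
            raise ValidationError("SSIM requires a positive dynamic range")
        return (self.k1_const * data_range) ** 2, (self.k2_const * data_range) ** 2


@dataclass(frozen=True)
class VIFPParams:
    """Scale count and visual-noise variance of the VIFP model."""

    n_scales: int = 4
    noise_variance: float = 2.0

    def __post_init__(self) -> None:
        if self.n_scales < 1:
            raise ValidationError("n_scales must be at least 1")
        if self.noise_variance <= 0:
            raise ValidationError("noise_variance must be positive")


def _pair(t, r) -> tuple[np.ndarray, np.ndarray]:
    from .kspace import ImageGrid

    ta = t.values if isinstance(t, ImageGrid) else np.asarray(t, dtype=np.float64)
    ra = r.values if isinstance(r, ImageGrid) else np.asarray(r, dtype=np.float64)
    if ta.shape != ra.shape:
        raise ValidationError(f"shape mismatch: {ta.shape} vs {ra.shape}")
    return ta.astype(np.float64), ra.astype(np.float64)


def _to_8bit(t: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map nominal [0, 1] images to the 8-bit scale; pass 8-bit through.

    The decision is based on the reference image only, so reconstruction
    overshoot slightly above 1.0 cannot flip the scale of a pair.
    """
    if t.max(initial=0.0) <= 1.0:
        return t * 255.0, r * 255.0
    return t, r


def psnr(t, r) -> float:
    """Peak signal-to-noise ratio in dB on the 8-bit scale.

    Identical images return ``inf``; batch reports cap the value at
    ``PSNR_CAP_DB`` so averages stay finite.
    """
    ta, ra = _to_8bit(*_pair(t, r))
    mse = float(np.mean((ta - ra) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(255.0**2 / mse)


def ssim(t, r, data_range: float | None = None, params: SSIMParams = SSIMParams()) -> float:
    """Mean structural similarity over uniform local windows."""
    ta, ra = _pair(t, r)
    if data_range is None:
        data_range = float(ta.max() - ta.min())
    if data_range == 0.0:
        if np.array_equal(ta, ra):
            return 1.0
        raise ValidationError("constant reference with non-identical input: SSIM undefined")
    c1, c2 = params.constants(data_range)
    win = params.win_size
    if min(ta.shape) < win:
        raise ValidationError(f"images must be at least {win} pixels per side")

    kernel = np.ones((win, win)) / win**2
    conv = lambda a: fftconvolve(a, kernel, mode="valid")
    mu_t = conv(ta)
    mu_r = conv(ra)
    np_win = win**2
    cov_norm = np_win / (np_win - 1)  # unbiased local (co)variance
    var_t = cov_norm * (conv(ta * ta) - mu_t**2)
    var_r = cov_norm * (conv(ra * ra) - mu_r**2)
    cov = cov_norm * (conv(ta * ra) - mu_t * mu_r)

    s = ((2 * mu_t * mu_r + c1) * (2 * cov + c2)) / ((mu_t**2 + mu_r**2 + c1) * (var_t + var_r + c2))
    return float(s.mean())


def nrmse(t, r) -> float:
    """RMSE normalised by the dynamic range of the reference."""
    ta, ra = _pair(t, r)
    rng = float(ta.max() - ta.min())
    if rng == 0.0:
        raise ValidationError("NRMSE undefined for a constant reference")
    return float(np.sqrt(np.mean((ta - ra) ** 2)) / rng)


def _gaussian_kernel(n: int, sd: float) -> np.ndarray:
    ax = np.arange(n) - (n - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sd**2))
    k = np.outer(g, g)
    return k / k.sum()


def vifp(t, r, params: VIFPParams = VIFPParams()) -> float:
    """Pixel-domain visual information fidelity (0 to ~1)."""
    ta, ra = _pair(t, r)
    if min(ta.shape) < 32:
        raise ValidationError("VIFP requires images at least 32x32")
    if ta.max() == ta.min():
        raise ValidationError("VIFP undefined for a constant reference")
    ta, ra = _to_8bit(ta, ra)
    sigma_nsq = params.noise_variance
    eps = 1e-10

    num = 0.0
    den = 0.0
    ref, dist = ta, ra
    for scale in range(1, params.n_scales + 1):
        n = 2 ** (params.n_scales - scale + 1) + 1
        win = _gaussian_kernel(n, n / 5.0)
        if scale > 1:
            ref = fftconvolve(ref, win, mode="valid")[::2, ::2]
            dist = fftconvolve(dist, win, mode="valid")[::2, ::2]

        mu1 = fftconvolve(ref, win, mode="valid")
        mu2 = fftconvolve(dist, win, mode="valid")
        sigma1_sq = fftconvolve(ref * ref, win, mode="valid") - mu1**2
        sigma2_sq = fftconvolve(dist * dist, win, mode="valid") - mu2**2
        sigma12 = fftconvolve(ref * dist, win, mode="valid") - mu1 * mu2
        sigma1_sq = np.maximum(sigma1_sq, 0.0)
        sigma2_sq = np.maximum(sigma2_sq, 0.0)

        g = sigma12 / (sigma1_sq + eps)
        sv_sq = sigma2_sq - g * sigma12

        g = np.where(sigma1_sq < eps, 0.0, g)
        sv_sq = np.where(sigma1_sq < eps, sigma2_sq, sv_sq)
        sigma1_sq = np.where(sigma1_sq < eps, 0.0, sigma1_sq)
        sv_sq = np.where(sigma2_sq < eps, 0.0, sv_sq)
        g = np.where(sigma2_sq < eps, 0.0, g)
        sv_sq = np.where(g < 0.0, sigma2_sq, sv_sq)
        g = np.maximum(g, 0.0)
        sv_sq = np.maximum(sv_sq, eps)

        num += float(np.sum(np.log10(1.0 + g**2 * sigma1_sq / (sv_sq + sigma_nsq))))
        den += float(np.sum(np.log10(1.0 + sigma1_sq / sigma_nsq)))

    return num / den


@dataclass
class MetricReport:
    """Per-image metrics and their means over a batch."""

    ssim: list[float]
    psnr: list[float]
    nrmse: list[float]
    vifp: list[float]
    labels: list = field(default_factory=list)
    mask_kind: str | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "slice": range(len(self.ssim)),
                "label": self.labels if self.labels else range(len(self.ssim)),
                "ssim": self.ssim,
                "psnr": self.psnr,
                "nrmse": self.nrmse,
                "vifp": self.vifp,
            }
        )

    @property
    def means(self) -> dict[str, float]:
        capped = [min(v, PSNR_CAP_DB) for v in self.psnr]
        return {
            "ssim": float(np.mean(self.ssim)),
            "psnr": float(np.mean(capped)),
            "nrmse": float(np.mean(self.nrmse)),
            "vifp": float(np.mean(self.vifp)),
        }

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> dict:
        return {"means": self.means, "n": len(self.ssim), "mask_kind": self.mask_kind}


def evaluate_batch(targets, reconstructions, labels=None, mask_kind: str | None = None) -> MetricReport:
    """All four metrics per image pair plus batch means."""
    ts = list(targets)
    rs = list(reconstructions)
    if len(ts) != len(rs):
        raise ValidationError("targets and reconstructions must have equal length")
    if labels is not None and len(labels) != len(ts):
        raise ValidationError("labels length must match the batch")
    report = MetricReport(ssim=[], psnr=[], nrmse=[], vifp=[], labels=list(labels or []), mask_kind=mask_kind)
    for t, r in zip(ts, rs):
        report.ssim.append(ssim(t, r))
        report.psnr.append(psnr(t, r))
        report.nrmse.append(nrmse(t, r))
        report.vifp.append(vifp(t, r))
    return report
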