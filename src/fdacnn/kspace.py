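"""Centered Fourier model of MRI acquisition and Cartesian under-sampling.

The scanner acquires the 2-D spatial-frequency content of the object
(k-space); accelerating the scan means skipping phase-encode lines, and
reconstructing by simply zero-filling the missing lines produces the
aliased images the de-aliasing network is trained to clean up.

Three retrospective under-sampling patterns are provided:

``2DG-US``
    individual k-space points drawn with an isotropic Gaussian density
    centred on DC (variable-density random sampling);
``1DG-US``
    whole phase-encode lines drawn with a 1-D Gaussian density;
``MCP-US``
    mixed center-periphery sampling: a deterministic contiguous block of
    the lowest frequencies (50% of the budget), the outermost
    highest-frequency lines (25%), and the remaining 25% drawn uniformly
    at random from the band in between, so both image contrast (center)
    and edges (periphery) are always represented.

All transforms use the orthonormal (unitary) FFT with the DC component
shifted to the array center, so Parseval's identity holds exactly and
image/k-space energies are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "KSpaceGrid",
    "ImageGrid",
    "SamplingMask",
    "MaskSpec",
    "forward_fft",
    "inverse_fft",
    "make_mask",
    "apply_mask",
    "zero_filled_recon",
]

MaskKind = Literal["2dg", "1dg", "mcp"]
MIN_SIZE = 32


@dataclass
class ImageGrid:
    """Real magnitude image; ``role`` tags its place in the pipeline."""

    values: np.ndarray
    role: str = "target"  # target | aliased | reconstruction

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("ImageGrid requires a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("ImageGrid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class KSpaceGrid:
    """Complex 2-D frequency grid with DC at the array center."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValidationError("KSpaceGrid requires a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("KSpaceGrid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class MaskSpec:
    """Parameters of an under-sampling mask.

    ``sampling_rate`` is the fraction of k-space kept (0.20 keeps one
    line in five, i.e. acceleration factor 5). ``axis=1`` samples
    columns of the stored matrix (vertical lines); ``axis=0`` rows.
    ``gaussian_sd`` is the Gaussian spread as a fraction of the grid
    side for the two Gaussian patterns.
    """

    kind: MaskKind
    sampling_rate: float = 0.20
    image_size: int = 256
    axis: int = 1
    gaussian_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("2dg", "1dg", "mcp"):
            raise ConfigurationError(f"unknown mask kind {self.kind!r}")
        if not 0.0 < self.sampling_rate <= 1.0:
            raise ConfigurationError("sampling_rate must be in (0, 1]")
        if self.image_size < MIN_SIZE:
            raise ConfigurationError(f"image_size must be at least {MIN_SIZE}")
        if self.axis not in (0, 1):
            raise ConfigurationError("axis must be 0 or 1")
        if self.gaussian_sd <= 0:
            raise ConfigurationError("gaussian_sd must be positive")


@dataclass
class SamplingMask:
    """Binary sampling matrix plus composition bookkeeping.

    For MCP-US the invariant ``S = s_c + s_p + s_r`` holds exactly; the
    Gaussian patterns report only the total ``S`` (lines for 1DG-US,
    points for 2DG-US).
    """

    matrix: np.ndarray
    kind: MaskKind
    axis: int
    S: int
    s_c: int = 0
    s_p: int = 0
    s_r: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValidationError("mask entries must be 0 or 1")

    @property
    def fraction(self) -> float:
        return float(self.matrix.mean())

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def _as_image(x) -> np.ndarray:
    arr = x.values if isinstance(x, ImageGrid) else np.asarray(x, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D image")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("image contains non-finite values")
    return arr


def _as_kspace(x) -> np.ndarray:
    arr = x.values if isinstance(x, KSpaceGrid) else np.asarray(x, dtype=np.complex128)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D k-space array")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("k-space contains non-finite values")
    return arr


def forward_fft(image) -> KSpaceGrid:
    """Orthonormal centered 2-D DFT of a magnitude image."""
    arr = _as_image(image)
    k = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(arr), norm="ortho"))
    return KSpaceGrid(k)


def inverse_fft(kspace) -> ImageGrid:
    """Magnitude of the orthonormal centered inverse 2-D DFT."""
    arr = _as_kspace(kspace)
    img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(arr), norm="ortho"))
    return ImageGrid(np.abs(img), role="reconstruction")


def _round_half_up(x: float) -> int:
    """Round half away from zero (numpy's round() rounds half to even)."""
    return int(np.floor(x + 0.5))


def _gumbel_topk(rng: np.random.Generator, weights: np.ndarray, k: int) -> np.ndarray:
    """k indices sampled without replacement with probability ∝ weights."""
    if k == 0:
        return np.empty(0, dtype=np.intp)
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=weights.shape)
    return np.argpartition(-keys, k - 1)[:k]


def mcp_line_counts(n_lines: int, rate: float) -> tuple[int, int, int, int]:
    """Line budget of the mixed center-periphery pattern.

    Returns ``(S, s_c, s_p, s_r)``: the total ``S = round(rate * N)``
    splits into 50% deterministic center lines, 25% deterministic
    periphery lines (rounded half away from zero) and a random remainder
    that absorbs the rounding slack so the total is exact.
    """
    total = _round_half_up(rate * n_lines)
    n_c = _round_half_up(rate / 2.0 * n_lines)
    n_p = _round_half_up(rate / 4.0 * n_lines)
    n_r = total - n_c - n_p
    if n_c == 0:
        raise ConfigurationError("sampling_rate too small: no center lines would be sampled")
    if n_r < 0:
        raise ConfigurationError("rounding produced a negative random component; adjust rate")
    return total, n_c, n_p, n_r


def _mcp_line_indices(n_lines: int, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    total, n_c, n_p, n_r = mcp_line_counts(n_lines, rate)
    dc = n_lines // 2
    # contiguous center block; even lengths put the extra line on the low side
    c_start = dc - n_c // 2
    center = np.arange(c_start, c_start + n_c)
    # periphery: outermost lines on both edges; odd counts favour the low edge
    n_low = (n_p + 1) // 2
    n_high = n_p // 2
    periphery = np.concatenate([np.arange(n_low), np.arange(n_lines - n_high, n_lines)])
    pool = np.concatenate([np.arange(n_low, c_start), np.arange(c_start + n_c, n_lines - n_high)])
    if len(pool) < n_r:
        raise ConfigurationError("random pool between center and periphery is smaller than s_r")
    random_lines = pool[_gumbel_topk(rng, np.ones(len(pool)), n_r)] if n_r else np.empty(0, dtype=np.intp)
    lines = np.concatenate([center, periphery, random_lines])
    return np.unique(lines), (total, n_c, n_p, n_r)


def make_mask(spec: MaskSpec) -> SamplingMask:
    """Generate a binary under-sampling mask from its spec (seeded)."""
    n = spec.image_size
    rate = spec.sampling_rate
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, n, spec.axis)))
    matrix = np.zeros((n, n), dtype=np.uint8)
    dc = n // 2
    counts = dict(S=0, s_c=0, s_p=0, s_r=0)

    if spec.kind == "mcp":
        lines, (total, n_c, n_p, n_r) = _mcp_line_indices(n, rate, rng)
        counts.update(S=total, s_c=n_c, s_p=n_p, s_r=n_r)
        if spec.axis == 1:
            matrix[:, lines] = 1
        else:
            matrix[lines, :] = 1
    elif spec.kind == "1dg":
        total = _round_half_up(rate * n)
        sd = spec.gaussian_sd * n
        weights = np.exp(-((np.arange(n) - dc) ** 2) / (2.0 * sd**2))
        weights[dc] = 0.0  # DC is always included
        rest = _gumbel_topk(rng, weights, total - 1)
        lines = np.unique(np.concatenate([[dc], rest]))
        counts.update(S=total)
        if spec.axis == 1:
            matrix[:, lines] = 1
        else:
            matrix[lines, :] = 1
    else:  # 2dg: individual points
        total_lines = _round_half_up(rate * n)
        n_points = total_lines * n
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        r2 = (ii - dc) ** 2.0 + (jj - dc) ** 2.0
        sd = spec.gaussian_sd * n
        weights = np.exp(-r2.ravel() / (2.0 * sd**2))
        dc_flat = dc * n + dc
        weights[dc_flat] = 0.0
        rest = _gumbel_topk(rng, weights, n_points - 1)
        flat = np.concatenate([[dc_flat], rest])
        matrix.ravel()[flat] = 1
        counts.update(S=n_points)

    return SamplingMask(matrix=matrix, kind=spec.kind, axis=spec.axis, seed=spec.seed, **counts)


def apply_mask(kspace, mask: SamplingMask) -> KSpaceGrid:
    """Retrospective under-sampling: element-wise product with the mask."""
    k = _as_kspace(kspace)
    if k.shape != mask.shape:
        raise ValidationError(f"k-space shape {k.shape} does not match mask shape {mask.shape}")
    return KSpaceGrid(k * mask.matrix)


def zero_filled_recon(kspace, mask: SamplingMask) -> ImageGrid:
    """Inverse FFT of the masked k-space: the aliased network input."""
    img = inverse_fft(apply_mask(kspace, mask))
    img.role = "aliased"
    return img
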