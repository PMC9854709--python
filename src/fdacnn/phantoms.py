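"""Seeded brain-like phantom generator with paired fully sampled k-space.

Real brain archives are large and licensed, so the package ships a
generator of ellipse-composite phantoms (in the Shepp-Logan tradition):
a skull-like outer ellipse containing randomly placed, rotated,
piecewise-constant elliptical structures, lightly smoothed and
optionally corrupted with additive Gaussian noise. Piecewise-smooth
images with sharp edges are exactly the structure that aliasing
artifacts corrupt and that a de-aliasing network must restore, which is
all the downstream modules need for testing.

Every phantom is a pure function of ``(spec.seed, index)``, so datasets
are bit-reproducible. The paired k-space is synthesised from the final
(noisy) image with the orthonormal centered FFT, making the image the
single source of truth: ``|IFFT(kspaces[i])| == images[i]`` to numerical
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .kspace import ImageGrid, KSpaceGrid, forward_fft

__all__ = [
    "PhantomSpec",
    "PhantomDataset",
    "generate_phantom",
    "generate_dataset",
    "generate_volume",
    "split_counts",
    "save_dataset",
    "load_dataset",
]

# The reference study splits its 150 volumes 100/30/20; datasets of any
# size follow the same proportions.
SPLIT_PROPORTIONS = {"train": 100, "val": 30, "test": 20}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom generator.

    ``image_size`` must be a power of two (>= 32) so that five levels of
    2x pooling divide it exactly. ``intensity_range`` bounds the tissue
    intensities on the normalised [0, 1] scale; ``noise_sd`` is the
    standard deviation of additive Gaussian noise in image units;
    ``smooth_sigma`` is the Gaussian blur (pixels) applied to soften
    edges, 0 for none.
    """

    image_size: int = 256
    n_ellipses: int = 6
    intensity_range: tuple[float, float] = (0.25, 1.0)
    noise_sd: float = 0.01
    smooth_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.image_size
        if n < 32 or (n & (n - 1)) != 0:
            raise ConfigurationError("image_size must be a power of two and at least 32")
        lo, hi = self.intensity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("intensity_range must satisfy 0 <= lo <= hi <= 1")
        if self.n_ellipses < 0:
            raise ConfigurationError("n_ellipses must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.smooth_sigma < 0:
            raise ConfigurationError("smooth_sigma must be non-negative")


@dataclass
class PhantomDataset:
    """Paired (ground-truth image, fully sampled k-space) samples."""

    images: list[ImageGrid]
    kspaces: list[KSpaceGrid]
    spec: PhantomSpec
    split_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.kspaces):
            raise ConfigurationError("images and kspaces must have equal length")
        for img, k in zip(self.images, self.kspaces):
            if img.shape != k.shape:
                raise ConfigurationError("image/k-space shape mismatch")

    def __len__(self) -> int:
        return len(self.images)

    def indices(self, split: str) -> list[int]:
        return [i for i, lab in enumerate(self.split_labels) if lab == split]


def _ellipse_mask(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float, a: float, b: float, theta: float) -> np.ndarray:
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _render(
    spec: PhantomSpec,
    index: int,
    size_scale: float = 1.0,
    intensity_scale: float = 1.0,
) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(index,)))
    n = spec.image_size
    coords = np.linspace(-1.0, 1.0, n)
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    lo, hi = spec.intensity_range

    img = np.zeros((n, n), dtype=np.float64)
    # skull-like outer ellipse with mild randomised geometry
    a = (0.72 + 0.08 * rng.random()) * size_scale
    b = (0.82 + 0.08 * rng.random()) * size_scale
    cx, cy = 0.04 * (rng.random(2) - 0.5)
    theta = 0.1 * (rng.random() - 0.5)
    outer = _ellipse_mask(xx, yy, cx, cy, a, b, theta)
    outer_level = (lo + 0.65 * (hi - lo)) * intensity_scale
    img[outer] = outer_level

    for _ in range(spec.n_ellipses):
        ea = (0.05 + 0.30 * rng.random()) * size_scale
        eb = (0.05 + 0.30 * rng.random()) * size_scale
        ecx = cx + 0.55 * a * (2 * rng.random() - 1)
        ecy = cy + 0.55 * b * (2 * rng.random() - 1)
        etheta = np.pi * rng.random()
        level = (lo + (hi - lo) * rng.random()) * intensity_scale
        sub = _ellipse_mask(xx, yy, ecx, ecy, ea, eb, etheta) & outer
        img[sub] = level

    if spec.smooth_sigma > 0:
        img = gaussian_filter(img, sigma=spec.smooth_sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_phantom(spec: PhantomSpec, index: int = 0) -> ImageGrid:
    """Deterministic phantom image for ``(spec.seed, index)``."""
    if index < 0:
        raise ConfigurationError("index must be non-negative")
    return ImageGrid(_render(spec, index), role="target")


def split_counts(n: int) -> dict[str, int]:
    """Split ``n`` samples into train/val/test following 100:30:20.

    Floors with the remainder assigned to train, but never leaves a
    split empty (hence ``n >= 3``).
    """
    if n < 3:
        raise ConfigurationError("need at least 3 samples so all splits are non-empty")
    total = sum(SPLIT_PROPORTIONS.values())
    counts = {k: max(1, (n * v) // total) for k, v in SPLIT_PROPORTIONS.items()}
    counts["train"] += n - sum(counts.values())
    if counts["train"] < 1:
        # tiny n: rebalance so train keeps at least one sample
        counts = {"train": n - 2, "val": 1, "test": 1}
    return counts


def generate_dataset(n: int, spec: PhantomSpec) -> PhantomDataset:
    """n paired (image, k-space) phantoms with train/val/test labels."""
    counts = split_counts(n)
    images = [generate_phantom(spec, i) for i in range(n)]
    kspaces = [forward_fft(img) for img in images]
    labels = ["train"] * counts["train"] + ["val"] * counts["val"] + ["test"] * counts["test"]
    return PhantomDataset(images=images, kspaces=kspaces, spec=spec, split_labels=labels)


def generate_volume(spec: PhantomSpec, n_slices: int) -> list[ImageGrid]:
    """A stack of slices emulating a pass through a head.

    Structure size and intensity follow an elliptical profile along the
    slice axis, so edge slices contain small, dim anatomy the way the
    first and last slices of a real volume do.
    """
    if n_slices < 3:
        raise ConfigurationError("a volume needs at least 3 slices")
    zs = np.linspace(-1.0, 1.0, n_slices)
    profile = np.sqrt(np.clip(1.0 - zs**2, 0.0, None))
    slices = []
    for i, p in enumerate(profile):
        # outermost slices hold small, very dim anatomy while the
        # acquisition noise floor stays constant, as in real volumes
        size_scale = 0.20 + 0.80 * p
        intensity_scale = 0.05 + 0.95 * p
        slices.append(ImageGrid(_render(spec, i, size_scale, intensity_scale), role="target"))
    return slices


def save_dataset(dataset: PhantomDataset, path: str | Path) -> None:
    """Write a dataset to one HDF5 container (images, k-space, spec)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=np.stack([g.values for g in dataset.images]))
        kvals = np.stack([g.values for g in dataset.kspaces])
        f.create_dataset("kspace_real", data=kvals.real)
        f.create_dataset("kspace_imag", data=kvals.imag)
        f.create_dataset("split_labels", data=np.array(dataset.split_labels, dtype="S8"))
        spec = dataset.spec
        f.attrs.update(
            image_size=spec.image_size,
            n_ellipses=spec.n_ellipses,
            intensity_lo=spec.intensity_range[0],
            intensity_hi=spec.intensity_range[1],
            noise_sd=spec.noise_sd,
            smooth_sigma=spec.smooth_sigma,
            seed=spec.seed,
        )


def load_dataset(path: str | Path) -> PhantomDataset:
    import h5py

    with h5py.File(path, "r") as f:
        images = [ImageGrid(v, role="target") for v in f["images"][...]]
        kvals = f["kspace_real"][...] + 1j * f["kspace_imag"][...]
        kspaces = [KSpaceGrid(v) for v in kvals]
        labels = [s.decode() for s in f["split_labels"][...]]
        spec = PhantomSpec(
            image_size=int(f.attrs["image_size"]),
            n_ellipses=int(f.attrs["n_ellipses"]),
            intensity_range=(float(f.attrs["intensity_lo"]), float(f.attrs["intensity_hi"])),
            noise_sd=float(f.attrs["noise_sd"]),
            smooth_sigma=float(f.attrs["smooth_sigma"]),
            seed=int(f.attrs["seed"]),
        )
    return PhantomDataset(images=images, kspaces=kspaces, spec=spec, split_labels=labels)
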