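"""Scikit-learn style front end for the de-aliasing pipeline.

:class:`CNNReconstructor` bundles mask generation, retrospective
under-sampling, network construction and MSE training behind the
familiar ``fit`` / ``predict`` interface, so the reconstructor composes
with scikit-learn model selection (``clone``, ``get_params`` /
``set_params``) even though the heavy lifting lives in the functional
modules.

``fit`` takes a stack of fully sampled ground-truth images: training
data acquisition is simulated internally (forward FFT, masking,
zero-filled reconstruction). ``predict`` accepts either complex k-space
arrays (reconstructed directly) or real images (under-sampled with the
fitted mask first, emulating an accelerated acquisition).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, ValidationError
from .kspace import MaskSpec, forward_fft
from .metrics import psnr
from .network import ModelConfig, build_model, build_unet_baseline
from .phantoms import PhantomDataset, PhantomSpec
from .training import TrainConfig, reconstruct, train

__all__ = ["CNNReconstructor"]


class CNNReconstructor(BaseEstimator):
    """De-aliasing reconstructor with a scikit-learn estimator surface.

    Parameters mirror the mask, architecture and optimiser configs; see
    :class:`~fdacnn.kspace.MaskSpec`, :class:`~fdacnn.network.ModelConfig`
    and :class:`~fdacnn.training.TrainConfig` for semantics. ``arch``
    selects the fully dense attention network (``"fdacnn"``) or the
    plain Unet baseline (``"unet"``).

    Attributes set by :meth:`fit` (trailing underscore): ``model_``,
    ``mask_``, ``history_``, ``image_size_``.
    """

    def __init__(
        self,
        arch: str = "fdacnn",
        mask_kind: str = "mcp",
        sampling_rate: float = 0.20,
        gaussian_sd: float = 0.15,
        k1: int = 8,
        f1: int = 64,
        stem_channels: int = 32,
        batch_norm: bool = True,
        lr0: float = 1e-4,
        decay: float = 0.95,
        decay_every: int = 20,
        batch_size: int = 8,
        epochs: int = 30,
        val_fraction: float = 0.25,
        seed: int = 0,
    ):
        self.arch = arch
        self.mask_kind = mask_kind
        self.sampling_rate = sampling_rate
        self.gaussian_sd = gaussian_sd
        self.k1 = k1
        self.f1 = f1
        self.stem_channels = stem_channels
        self.batch_norm = batch_norm
        self.lr0 = lr0
        self.decay = decay
        self.decay_every = decay_every
        self.batch_size = batch_size
        self.epochs = epochs
        self.val_fraction = val_fraction
        self.seed = seed

    # ------------------------------------------------------------------
    def _validate_images(self, X) -> np.ndarray:
        arr = np.asarray(X, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
            raise ValidationError("expected a (n_samples, size, size) image stack")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("images contain non-finite values")
        return arr

    def fit(self, X, y=None) -> "CNNReconstructor":
        """Train on fully sampled ground-truth images (n, size, size)."""
        arr = self._validate_images(X)
        n, size, _ = arr.shape
        if n < 2:
            raise ConfigurationError("need at least 2 images (train + val)")
        n_val = max(1, int(round(self.val_fraction * n)))
        if n_val >= n:
            raise ConfigurationError("val_fraction leaves no training images")

        from .kspace import ImageGrid

        images = [ImageGrid(a, role="target") for a in arr]
        kspaces = [forward_fft(a) for a in arr]
        labels = ["train"] * (n - n_val) + ["val"] * n_val
        data = PhantomDataset(
            images=images,
            kspaces=kspaces,
            spec=PhantomSpec(image_size=size, seed=self.seed),
            split_labels=labels,
        )

        config = ModelConfig(
            k1=self.k1,
            f1=self.f1,
            stem_channels=self.stem_channels,
            input_size=size,
            batch_norm=self.batch_norm,
            init_seed=self.seed,
        )
        builder = {"fdacnn": build_model, "unet": build_unet_baseline}.get(self.arch)
        if builder is None:
            raise ConfigurationError(f"unknown arch {self.arch!r}")
        model = builder(config)

        mask_spec = MaskSpec(
            kind=self.mask_kind,
            sampling_rate=self.sampling_rate,
            image_size=size,
            gaussian_sd=self.gaussian_sd,
            seed=self.seed,
        )
        train_config = TrainConfig(
            lr0=self.lr0,
            decay=self.decay,
            decay_every=self.decay_every,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.seed,
        )
        self.model_, self.history_ = train(model, data, mask_spec, train_config)
        self.mask_spec_ = mask_spec
        from .kspace import make_mask

        self.mask_ = make_mask(mask_spec)
        self.image_size_ = size
        self.n_features_in_ = size * size
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise ValidationError("this CNNReconstructor instance is not fitted yet")

    def predict(self, X) -> np.ndarray:
        """Reconstruct de-aliased images.

        Complex input is treated as fully sampled k-space; real input as
        ground-truth images whose accelerated acquisition is simulated
        with the fitted mask.
        """
        self._check_fitted()
        arr = np.asarray(X)
        if arr.ndim == 2:
            arr = arr[None]
        if not np.iscomplexobj(arr):
            arr = np.stack([forward_fft(a).values for a in arr.astype(np.float64)])
        out = [reconstruct(self.model_, k, self.mask_).values for k in arr]
        return np.stack(out)

    def score(self, X, y) -> float:
        """Mean PSNR (dB) of reconstructions against ground truth."""
        self._check_fitted()
        preds = self.predict(X)
        truths = self._validate_images(y)
        return float(np.mean([psnr(t, p) for t, p in zip(truths, preds)]))
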