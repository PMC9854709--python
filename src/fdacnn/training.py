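"""Supervised training of the de-aliasing networks.

The network learns the mapping from a zero-filled (aliased) magnitude
image to the fully sampled ground truth by minimising the pixel-wise
mean squared error with Adam (beta1 = 0.9, beta2 = 0.999). The learning
rate starts at ``lr0`` and is multiplied by ``decay`` every
``decay_every`` epochs. One under-sampling mask, generated once from
``mask_spec``, is shared by every sample and epoch (per-sample random
masks are available behind a flag as an extension).

Each zero-filled input is normalised to [0, 1] by its own maximum and
the paired target shares that constant, so the network always sees
inputs on a common scale while reconstruction can undo the scaling
exactly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .kspace import ImageGrid, MaskSpec, SamplingMask, make_mask, zero_filled_recon
from .network import ReconModel
from .nn import Adam
from .nn import autograd as ag
from .nn.autograd import Tensor
from .phantoms import PhantomDataset

__all__ = ["TrainConfig", "TrainHistory", "mse_loss", "lr_at", "train", "reconstruct"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser and schedule hyperparameters (defaults follow the
    full-scale study; tests use far fewer epochs)."""

    lr0: float = 1e-4
    decay: float = 0.95
    decay_every: int = 20
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 8
    epochs: int = 2000
    seed: int = 0
    per_sample_masks: bool = False

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ConfigurationError("lr0 must be positive")
        if not 0.0 < self.decay <= 1.0:
            raise ConfigurationError("decay must be in (0, 1]")
        if self.decay_every < 1:
            raise ConfigurationError("decay_every must be at least 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be at least 1")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be at least 1")


@dataclass
class TrainHistory:
    """Per-epoch losses, learning rates and wall time of one run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    best_state: list | None = None


def mse_loss(t, r) -> float:
    """Mean squared error (1/N) sum (T_i - R_i)^2."""
    ta = t.values if isinstance(t, ImageGrid) else np.asarray(t, dtype=np.float64)
    ra = r.values if isinstance(r, ImageGrid) else np.asarray(r, dtype=np.float64)
    if ta.shape != ra.shape:
        raise ValidationError(f"shape mismatch: {ta.shape} vs {ra.shape}")
    return float(np.mean((ta - ra) ** 2))


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Stepped learning rate: lr0 * decay**floor(epoch / decay_every)."""
    if epoch < 0:
        raise ValidationError("epoch must be non-negative")
    return config.lr0 * config.decay ** (epoch // config.decay_every)


def _normalised_pair(image: np.ndarray, kspace: np.ndarray, mask: SamplingMask) -> tuple[np.ndarray, np.ndarray]:
    zf = zero_filled_recon(kspace, mask).values
    scale = zf.max()
    if scale <= 0:
        scale = 1.0
    return (zf / scale).astype(np.float32), (image / scale).astype(np.float32)


def train(
    model: ReconModel,
    data: PhantomDataset,
    mask_spec: MaskSpec,
    config: TrainConfig,
) -> tuple[ReconModel, TrainHistory]:
    """Train ``model`` on the dataset's train split; validate per epoch.

    Returns the model with its final weights; the best-validation
    weights are kept in ``history.best_state`` and can be restored with
    ``model.set_state``.
    """
    train_idx = data.indices("train")
    val_idx = data.indices("val")
    if not train_idx or not val_idx:
        raise ConfigurationError("train and val splits must both be non-empty")

    mask = make_mask(mask_spec)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(3,)))

    def prepare(indices: list[int], sample_rng: np.random.Generator | None) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        for i in indices:
            m = mask
            if config.per_sample_masks and sample_rng is not None:
                m = make_mask(
                    MaskSpec(
                        kind=mask_spec.kind,
                        sampling_rate=mask_spec.sampling_rate,
                        image_size=mask_spec.image_size,
                        axis=mask_spec.axis,
                        gaussian_sd=mask_spec.gaussian_sd,
                        seed=int(sample_rng.integers(2**31)),
                    )
                )
            x, y = _normalised_pair(data.images[i].values, data.kspaces[i].values, m)
            xs.append(x)
            ys.append(y)
        return np.stack(xs), np.stack(ys)

    x_train, y_train = prepare(train_idx, rng if config.per_sample_masks else None)
    x_val, y_val = prepare(val_idx, None)

    optimiser = Adam(model.net.parameters(), lr=config.lr0, beta1=config.beta1, beta2=config.beta2)
    history = TrainHistory()
    n_train = len(train_idx)

    for epoch in range(config.epochs):
        t0 = time.perf_counter()
        lr = lr_at(epoch, config)
        optimiser.lr = lr
        model.net.train()
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, config.batch_size):
            batch = order[start : start + config.batch_size]
            xb = Tensor(x_train[batch][:, None])
            yb = y_train[batch][:, None]
            pred = model.net(xb)
            loss = ag.mse(pred, yb)
            model.net.zero_grad()
            loss.backward()
            optimiser.step()
            epoch_loss += float(loss.data) * len(batch)
        epoch_loss /= n_train
        if not np.isfinite(epoch_loss):
            raise RuntimeError(f"training diverged at epoch {epoch}: loss={epoch_loss}")

        model.net.eval()
        sq_err = 0.0
        with ag.no_grad():
            for start in range(0, len(val_idx), config.batch_size):
                xb = x_val[start : start + config.batch_size]
                yb = y_val[start : start + config.batch_size]
                pred = model.net(Tensor(xb[:, None]))
                sq_err += float(np.sum((pred.data - yb[:, None]) ** 2))
        val_loss = sq_err / x_val.size

        history.train_loss.append(epoch_loss)
        history.val_loss.append(val_loss)
        history.lr.append(lr)
        history.epoch_seconds.append(time.perf_counter() - t0)
        if val_loss < history.best_val_loss:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            history.best_state = model.get_state()

    return model, history


def reconstruct(model: ReconModel, kspace_under, mask: SamplingMask) -> ImageGrid:
    """De-aliased reconstruction of one under-sampled k-space."""
    zf = zero_filled_recon(kspace_under, mask).values
    scale = zf.max()
    if scale <= 0:
        scale = 1.0
    model.net.eval()
    with ag.no_grad():
        out = model.forward(zf / scale)
    return ImageGrid(np.clip(out * scale, 0.0, 1.0), role="reconstruction")
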