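"""Fully dense attention CNN (FDA-CNN) and the plain Unet baseline.

The de-aliasing network is a five-level encoder/decoder. Each level is a
*dense block*: four layers in which layer L receives the concatenation
of the block input and all previous layers' outputs (``F_in + (L-1)*k``
channels), compresses it with a 1x1 convolution back to ``F_in``
channels, and produces ``k`` new feature maps with a 3x3 convolution;
every convolution is followed by batch normalisation and ReLU. The block
output concatenates its input with the four k-channel outputs, so

    f_m = F_in + 4 * k_m,   k_m = 2**(m-1) * k_1,   f_m = 2**(m-1) * f_1.

With the defaults k_1 = 8, f_1 = 64 and a 32-channel stem, the deepest
block has k_5 = 128 and f_5 = 512.

Skip connections pass through *attention gates*: the encoder features x
(high resolution) and the deeper decoder gating signal g (half
resolution) are mapped by 1x1 convolutions into a joint intermediate
space (x with stride 2 so the geometries match), summed, passed through
ReLU, reduced to a single channel, and squashed by a sigmoid into
coefficients in (0, 1) which — after bilinear upsampling back to the
resolution of x — multiplicatively reweight the skip features.

Counting every convolution and transposed convolution (including the
three 1x1 convolutions inside each attention gate and a channel-
preserving 1x1 transition convolution after each of the three deepest
encoder poolings), the default FDA-CNN contains 97 such layers across 9
dense blocks; the classical Unet baseline contains 23.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ValidationError
from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = [
    "DenseBlockSpec",
    "AttentionGateSpec",
    "ModelConfig",
    "LayerRecord",
    "ReconModel",
    "dense_block_plan",
    "build_dense_block",
    "attention_gate_forward",
    "build_model",
    "build_unet_baseline",
    "count_layers",
    "DenseBlock",
    "AttentionGate",
]

DENSE_LAYERS = 4  # layers per dense block, fixed by the architecture


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``f1`` must equal ``stem_channels + 4 * k1`` so the first dense
    block's concatenated output hits the nominal level-1 width.
    """

    depth: int = 5
    k1: int = 8
    f1: int = 64
    stem_channels: int = 32
    input_size: int = 256
    batch_norm: bool = True
    init_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k1, self.f1, self.stem_channels) < 1:
            raise ConfigurationError("k1, f1 and stem_channels must be positive")
        if self.f1 != self.stem_channels + DENSE_LAYERS * self.k1:
            raise ConfigurationError(
                f"f1 must equal stem_channels + 4*k1 ({self.stem_channels} + {4 * self.k1})"
            )
        if self.input_size % 2 ** (self.depth - 1) != 0:
            raise ConfigurationError(
                f"input_size must be divisible by {2 ** (self.depth - 1)} for {self.depth} levels"
            )


@dataclass(frozen=True)
class DenseBlockSpec:
    """Channel plan of one dense block at spatial level ``m``."""

    m: int
    k: int
    f: int
    f_in: int
    layers: int = DENSE_LAYERS

    def __post_init__(self) -> None:
        if self.f != self.f_in + self.layers * self.k:
            raise ConfigurationError("dense block invariant f = F_in + L*k violated")


@dataclass(frozen=True)
class AttentionGateSpec:
    """Channel plan of one attention gate."""

    f_x: int
    f_g: int
    f_int: int

    def __post_init__(self) -> None:
        if self.f_int < 1:
            raise ConfigurationError("F_int must be at least 1")


@dataclass(frozen=True)
class LayerRecord:
    """One entry in the auditable layer inventory."""

    name: str
    kind: str  # conv | conv_transpose
    kernel: int
    stride: int
    in_channels: int
    out_channels: int


def dense_block_plan(m: int, config: ModelConfig) -> DenseBlockSpec:
    """Growth rate, output width and input width of the level-m block.

    Both the growth rate and the block width double per level:
    ``k_m = 2**(m-1) * k1`` and ``f_m = 2**(m-1) * f1``, which forces
    ``F_in = f_m - 4 * k_m``.
    """
    if not 1 <= m <= config.depth:
        raise ValidationError(f"level m={m} outside 1..{config.depth}")
    k = 2 ** (m - 1) * config.k1
    f = 2 ** (m - 1) * config.f1
    f_in = f - DENSE_LAYERS * k
    if f_in < 1:
        raise ConfigurationError("dense block input width would be non-positive")
    return DenseBlockSpec(m=m, k=k, f=f, f_in=f_in)


class DenseBlock(nn.Module):
    """Four densely connected 1x1->3x3 convolution pairs with BN+ReLU."""

    def __init__(self, spec: DenseBlockSpec, batch_norm: bool, rng: np.random.Generator) -> None:
        super().__init__()
        self.spec = spec
        self.compress = []
        self.grow = []
        self.bn_c = []
        self.bn_g = []
        for layer in range(spec.layers):
            cin = spec.f_in + layer * spec.k
            self.compress.append(nn.Conv2d(cin, spec.f_in, 1, rng=rng))
            self.bn_c.append(nn.BatchNorm2d(spec.f_in) if batch_norm else None)
            self.grow.append(nn.Conv2d(spec.f_in, spec.k, 3, padding=1, rng=rng))
            self.bn_g.append(nn.BatchNorm2d(spec.k) if batch_norm else None)

    def children(self):
        for pair in zip(self.compress, self.bn_c, self.grow, self.bn_g):
            for mod in pair:
                if mod is not None:
                    yield mod

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        for conv1, bn1, conv3, bn3 in zip(self.compress, self.bn_c, self.grow, self.bn_g):
            h = ag.concat(feats, axis=1) if len(feats) > 1 else feats[0]
            h = conv1(h)
            if bn1 is not None:
                h = bn1(h)
            h = ag.relu(h)
            h = conv3(h)
            if bn3 is not None:
                h = bn3(h)
            feats.append(ag.relu(h))
        return ag.concat(feats, axis=1)


class AttentionGate(nn.Module):
    """Additive attention gate over a skip connection.

    ``x`` enters at full resolution, the gating signal ``g`` at half
    resolution; the attention map is computed at the coarse grid and
    bilinearly upsampled before reweighting ``x``.
    """

    def __init__(self, spec: AttentionGateSpec, rng: np.random.Generator) -> None:
        super().__init__()
        self.spec = spec
        self.theta_x = nn.Conv2d(spec.f_x, spec.f_int, 1, stride=2, rng=rng)
        self.phi_g = nn.Conv2d(spec.f_g, spec.f_int, 1, rng=rng)
        self.psi = nn.Conv2d(spec.f_int, 1, 1, rng=rng)

    def attention(self, x: Tensor, g: Tensor) -> Tensor:
        xs = self.theta_x(x)
        gs = self.phi_g(g)
        if xs.shape[2:] != gs.shape[2:]:
            raise ValidationError(
                f"gating signal spatial size {g.shape[2:]} must be half of skip input {x.shape[2:]}"
            )
        alpha = ag.sigmoid(self.psi(ag.relu(ag.add(xs, gs))))
        return ag.upsample2x_bilinear(alpha)

    def forward(self, x: Tensor, g: Tensor) -> Tensor:
        return ag.mul(x, self.attention(x, g))


def build_dense_block(
    spec: DenseBlockSpec,
    batch_norm: bool = True,
    rng: np.random.Generator | None = None,
) -> DenseBlock:
    """Construct one dense block module from its channel plan."""
    return DenseBlock(spec, batch_norm, rng or np.random.default_rng(0))


def attention_gate_forward(
    x: np.ndarray,
    g: np.ndarray,
    spec: AttentionGateSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply a freshly initialised attention gate to numpy feature maps.

    ``x`` is (N, F_x, H, W) and ``g`` is (N, F_g, H/2, W/2); the result
    has the shape of ``x``.
    """
    gate = AttentionGate(spec, rng or np.random.default_rng(0))
    gate.eval()
    out = gate(Tensor(np.asarray(x, dtype=np.float32)), Tensor(np.asarray(g, dtype=np.float32)))
    return out.data


class _FDACNN(nn.Module):
    def __init__(self, config: ModelConfig) -> None:
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.init_seed, spawn_key=(1,)))
        self.config = config
        bn = config.batch_norm
        d = config.depth

        self.stem = nn.Conv2d(1, config.stem_channels, 3, padding=1, rng=rng)
        self.stem_bn = nn.BatchNorm2d(config.stem_channels) if bn else None

        self.enc_specs = [dense_block_plan(m, config) for m in range(1, d + 1)]
        self.enc_blocks = [DenseBlock(s, bn, rng) for s in self.enc_specs]
        # channel-preserving transitions after the deepest d-2 poolings
        self.transitions = []
        self.transition_bns = []
        for m in range(2, d):
            f = self.enc_specs[m - 1].f
            self.transitions.append(nn.Conv2d(f, f, 1, rng=rng))
            self.transition_bns.append(nn.BatchNorm2d(f) if bn else None)

        self.up_convs = []
        self.gates = []
        self.dec_reduce = []
        self.dec_reduce_bns = []
        self.dec_blocks = []
        for m in range(d - 1, 0, -1):
            spec_m = self.enc_specs[m - 1]
            f_deep = self.enc_specs[m].f
            self.up_convs.append(nn.ConvTranspose2d(f_deep, spec_m.f, 2, stride=2, rng=rng))
            self.gates.append(
                AttentionGate(AttentionGateSpec(f_x=spec_m.f, f_g=f_deep, f_int=max(1, spec_m.f // 2)), rng)
            )
            self.dec_reduce.append(nn.Conv2d(2 * spec_m.f, spec_m.f_in, 1, rng=rng))
            self.dec_reduce_bns.append(nn.BatchNorm2d(spec_m.f_in) if bn else None)
            self.dec_blocks.append(DenseBlock(spec_m, bn, rng))

        self.head = nn.Conv2d(config.f1, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        d = self.config.depth
        h = self.stem(x)
        if self.stem_bn is not None:
            h = self.stem_bn(h)
        h = ag.relu(h)

        skips: list[Tensor] = []
        for m in range(1, d + 1):
            h = self.enc_blocks[m - 1](h)
            skips.append(h)
            if m < d:
                h = ag.maxpool2x2(h)
                if m >= 2:
                    h = self.transitions[m - 2](h)
                    bn = self.transition_bns[m - 2]
                    if bn is not None:
                        h = bn(h)
                    h = ag.relu(h)

        for i, m in enumerate(range(d - 1, 0, -1)):
            gated = self.gates[i](skips[m - 1], h)
            up = self.up_convs[i](h)
            h = ag.concat([gated, up], axis=1)
            h = self.dec_reduce[i](h)
            bn = self.dec_reduce_bns[i]
            if bn is not None:
                h = bn(h)
            h = ag.relu(h)
            h = self.dec_blocks[i](h)

        return self.head(h)


class _Unet(nn.Module):
    """Classical five-level Unet: two 3x3 convolutions per level."""

    def __init__(self, config: ModelConfig) -> None:
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.init_seed, spawn_key=(2,)))
        self.config = config
        bn = config.batch_norm
        d = config.depth
        widths = [config.f1 * 2 ** (m - 1) for m in range(1, d + 1)]

        def conv_pair(cin: int, cout: int):
            return (
                nn.Conv2d(cin, cout, 3, padding=1, rng=rng),
                nn.BatchNorm2d(cout) if bn else None,
                nn.Conv2d(cout, cout, 3, padding=1, rng=rng),
                nn.BatchNorm2d(cout) if bn else None,
            )

        self.enc = []
        cin = 1
        for w in widths:
            self.enc.append(conv_pair(cin, w))
            cin = w
        self.up_convs = []
        self.dec = []
        for m in range(d - 1, 0, -1):
            self.up_convs.append(nn.ConvTranspose2d(widths[m], widths[m - 1], 2, stride=2, rng=rng))
            self.dec.append(conv_pair(2 * widths[m - 1], widths[m - 1]))
        self.head = nn.Conv2d(widths[0], 1, 1, rng=rng)

    def children(self):
        for group in self.enc:
            yield from (mod for mod in group if mod is not None)
        for up, group in zip(self.up_convs, self.dec):
            yield up
            yield from (mod for mod in group if mod is not None)
        yield self.head

    @staticmethod
    def _apply_pair(group, h: Tensor) -> Tensor:
        c1, b1, c2, b2 = group
        h = c1(h)
        if b1 is not None:
            h = b1(h)
        h = ag.relu(h)
        h = c2(h)
        if b2 is not None:
            h = b2(h)
        return ag.relu(h)

    def forward(self, x: Tensor) -> Tensor:
        d = self.config.depth
        skips = []
        h = x
        for m, group in enumerate(self.enc, start=1):
            h = self._apply_pair(group, h)
            skips.append(h)
            if m < d:
                h = ag.maxpool2x2(h)
        for i, m in enumerate(range(d - 1, 0, -1)):
            h = self.up_convs[i](h)
            h = ag.concat([skips[m - 1], h], axis=1)
            h = self._apply_pair(self.dec[i], h)
        return self.head(h)


class ReconModel:
    """A built network plus its auditable layer inventory.

    ``forward`` accepts (H, W) or (N, H, W) float arrays and returns the
    same shape; internally images travel as (N, 1, H, W) tensors.
    """

    def __init__(self, net: nn.Module, config: ModelConfig, tag: str) -> None:
        self.net = net
        self.config = config
        self.tag = tag
        self.inventory: list[LayerRecord] = _build_inventory(net)

    # -- audit ---------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.net.parameters()))

    def count_layers(self) -> int:
        return len(self.inventory)

    def n_dense_blocks(self) -> int:
        return sum(1 for mod in self.net.modules() if isinstance(mod, DenseBlock))

    def summary(self) -> dict:
        return {
            "tag": self.tag,
            "config": asdict(self.config),
            "counted_layers": self.count_layers(),
            "dense_blocks": self.n_dense_blocks(),
            "parameters": self.n_parameters,
            "inventory": [asdict(r) for r in self.inventory],
        }

    def summary_json(self, indent: int = 2) -> str:
        return json.dumps(self.summary(), indent=indent)

    # -- inference -----------------------------------------------------
    def forward(self, images: np.ndarray) -> np.ndarray:
        arr = np.asarray(images, dtype=np.float32)
        squeeze = arr.ndim == 2
        if squeeze:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValidationError("expected (H, W) or (N, H, W) input")
        out = self.net(Tensor(arr[:, None]))
        result = out.data[:, 0].astype(np.float64)
        return result[0] if squeeze else result

    __call__ = forward

    # -- persistence ---------------------------------------------------
    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.net.state_arrays()]

    def set_state(self, arrays: list[np.ndarray]) -> None:
        self.net.load_state_arrays(arrays)

    def save(self, path) -> None:
        np.savez_compressed(path, tag=self.tag, config=json.dumps(asdict(self.config)),
                            **{f"arr_{i}": a for i, a in enumerate(self.net.state_arrays())})

    @classmethod
    def load(cls, path) -> "ReconModel":
        with np.load(path, allow_pickle=False) as f:
            tag = str(f["tag"])
            config = ModelConfig(**json.loads(str(f["config"])))
            arrays = [f[f"arr_{i}"] for i in range(sum(1 for k in f.files if k.startswith("arr_")))]
        model = build_model(config) if tag == "FDA-CNN" else build_unet_baseline(config)
        model.set_state(arrays)
        return model


def _build_inventory(net: nn.Module) -> list[LayerRecord]:
    records = []
    for idx, mod in enumerate(net.modules()):
        if isinstance(mod, nn.Conv2d):
            records.append(
                LayerRecord(f"conv_{idx}", "conv", mod.kernel_size, mod.stride, mod.in_channels, mod.out_channels)
            )
        elif isinstance(mod, nn.ConvTranspose2d):
            records.append(
                LayerRecord(
                    f"convT_{idx}", "conv_transpose", mod.kernel_size, mod.stride, mod.in_channels, mod.out_channels
                )
            )
    return records


def build_model(config: ModelConfig | None = None) -> ReconModel:
    """Assemble the fully dense attention CNN."""
    config = config or ModelConfig()
    return ReconModel(_FDACNN(config), config, tag="FDA-CNN")


def build_unet_baseline(config: ModelConfig | None = None) -> ReconModel:
    """Assemble the classical Unet comparison network."""
    config = config or ModelConfig()
    return ReconModel(_Unet(config), config, tag="Unet")


def count_layers(model: ReconModel) -> int:
    """Number of convolutional plus transposed-convolutional layers.

    Counts every learned convolution in the inventory, including the
    three 1x1 convolutions inside each attention gate; the fixed-weight
    bilinear resampler is not a learned layer and is not counted.
    """
    return model.count_layers()
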