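"""Architecture audits: channel plans, layer counts, gates, assembly."""

import numpy as np
import pytest

from fdacnn import (
    AttentionGateSpec,
    ConfigurationError,
    ModelConfig,
    ValidationError,
    build_dense_block,
    build_model,
    build_unet_baseline,
    count_layers,
    dense_block_plan,
)
from fdacnn.network import DENSE_LAYERS, AttentionGate, attention_gate_forward
from fdacnn.nn.autograd import Tensor

CFG = ModelConfig(input_size=64)
NARROW = ModelConfig(k1=2, f1=16, stem_channels=8, input_size=32)


class TestDenseBlockPlan:
    @pytest.mark.parametrize(
        "m, k, f, f_in",
        [(1, 8, 64, 32), (2, 16, 128, 64), (5, 128, 1024, 512)],
    )
    def test_doubling_rule(self, m, k, f, f_in):
        spec = dense_block_plan(m, CFG)
        assert (spec.k, spec.f, spec.f_in) == (k, f, f_in)
        assert spec.f == spec.f_in + DENSE_LAYERS * spec.k

    def test_out_of_range_level_rejected(self):
        with pytest.raises(ValidationError):
            dense_block_plan(6, CFG)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(k1=8, f1=60, stem_channels=32)


class TestDenseBlock:
    def test_eight_convolutions_four_of_each_kernel(self):
        block = build_dense_block(dense_block_plan(5, CFG))
        kernels = [c.kernel_size for c in block.compress] + [c.kernel_size for c in block.grow]
        assert sorted(kernels) == [1, 1, 1, 1, 3, 3, 3, 3]

    def test_first_block_output_channels(self):
        spec = dense_block_plan(1, CFG)
        block = build_dense_block(spec)
        x = Tensor(np.zeros((1, spec.f_in, 8, 8), dtype=np.float32))
        block.eval()
        assert block(x).shape == (1, 32 + 4 * 8, 8, 8)

    def test_dense_concatenation_recurrence(self):
        # layer L consumes F_in + k*(L-1) channels
        block = build_dense_block(dense_block_plan(1, CFG))
        assert [c.in_channels for c in block.compress] == [32, 40, 48, 56]
        assert all(c.out_channels == 32 for c in block.compress)
        assert all(c.out_channels == 8 for c in block.grow)


class TestAttentionGate:
    def test_shape_contract(self, rng):
        x = rng.normal(size=(1, 32, 64, 64))
        g = rng.normal(size=(1, 64, 32, 32))
        out = attention_gate_forward(x, g, AttentionGateSpec(f_x=32, f_g=64, f_int=16), rng=rng)
        assert out.shape == (1, 32, 64, 64)

    def test_attention_coefficients_strictly_in_unit_interval(self, rng):
        gate = AttentionGate(AttentionGateSpec(f_x=8, f_g=16, f_int=4), rng)
        gate.eval()
        x = Tensor(rng.normal(size=(2, 8, 16, 16)).astype(np.float32))
        g = Tensor(rng.normal(size=(2, 16, 8, 8)).astype(np.float32))
        alpha = gate.attention(x, g).data
        assert (alpha > 0).all() and (alpha < 1).all()

    def test_saturated_gate_passes_input_through(self, rng):
        gate = AttentionGate(AttentionGateSpec(f_x=4, f_g=8, f_int=2), rng)
        gate.psi.weight.data[:] = 0.0
        gate.psi.bias.data[:] = 50.0  # sigmoid saturates to 1
        gate.eval()
        x = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        g = Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
        np.testing.assert_allclose(gate(x, g).data, x.data, rtol=1e-5, atol=1e-6)

    def test_mismatched_gating_resolution_rejected(self, rng):
        gate = AttentionGate(AttentionGateSpec(f_x=4, f_g=8, f_int=2), rng)
        x = Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32))
        g = Tensor(np.zeros((1, 8, 8, 8), dtype=np.float32))
        with pytest.raises(ValidationError):
            gate(x, g)


class TestAssembly:
    def test_fdacnn_counted_layers_and_blocks(self):
        model = build_model(CFG)
        assert count_layers(model) == 97
        assert model.n_dense_blocks() == 9

    def test_unet_counted_layers(self):
        assert count_layers(build_unet_baseline(CFG)) == 23

    def test_layer_count_independent_of_width(self):
        assert count_layers(build_model(NARROW)) == 97

    def test_single_conv_inventory_counts_one(self):
        block = build_dense_block(dense_block_plan(1, CFG))
        records = [c for c in block.compress] + [c for c in block.grow]
        assert len(records) == 8  # the counting unit is one convolution

    @pytest.mark.parametrize("builder", [build_model, build_unet_baseline])
    def test_forward_shape_contract(self, builder, rng):
        model = builder(NARROW)
        model.net.eval()
        x = rng.random((32, 32))
        assert model.forward(x).shape == (32, 32)
        batch = rng.random((3, 32, 32))
        assert model.forward(batch).shape == (3, 32, 32)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(input_size=40)

    def test_initialization_determinism(self, rng):
        a = build_model(NARROW)
        b = build_model(NARROW)
        for pa, pb in zip(a.net.parameters(), b.net.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
        x = rng.random((32, 32))
        a.net.eval()
        b.net.eval()
        np.testing.assert_array_equal(a.forward(x), b.forward(x))

    def test_gate_neutrality_under_saturation(self, rng):
        """Saturating every gate (alpha = 1) reduces FDA-CNN to the
        ungated network: the gated forward equals multiplying skips by 1."""
        model = build_model(NARROW)
        for gate in model.net.gates:
            gate.psi.weight.data[:] = 0.0
            gate.psi.bias.data[:] = 60.0
        model.net.eval()
        x = rng.random((32, 32)).astype(np.float32)
        gated = model.forward(x)

        # bypass the gates entirely
        originals = [g.forward for g in model.net.gates]
        for g in model.net.gates:
            g.forward = lambda x_, g_: x_
        try:
            ungated = model.forward(x)
        finally:
            for g, f in zip(model.net.gates, originals):
                g.forward = f
        np.testing.assert_allclose(gated, ungated, rtol=1e-4, atol=1e-5)

    def test_channel_bookkeeping_in_inventory(self):
        model = build_model(CFG)
        # encoder dense blocks start from F_in = 2^(m-1) * 32
        for m in range(1, 6):
            spec = dense_block_plan(m, CFG)
            assert spec.f_in == 2 ** (m - 1) * 32

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = build_model(NARROW)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = type(model).load(path)
        model.net.eval()
        loaded.net.eval()
        x = rng.random((32, 32))
        np.testing.assert_allclose(loaded.forward(x), model.forward(x), atol=1e-7)
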