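"""Block semantics, parameter-count invariants and network shape contracts."""

import numpy as np
import pytest

from hsiseg.network import (
    DualBranchUNet,
    FeatureExtractionModule,
    ModuleSpec,
    NetConfig,
    build_dual_branch,
    build_plain_unet,
    build_single_branch,
    count_parameters,
    h_swish,
)
from hsiseg.nn import Tensor

SMALL = dict(channels=(8, 16, 32, 64, 128), n_classes=3)


class TestHSwish:
    @pytest.mark.parametrize("x,expected", [
        (3.0, 3.0), (-3.0, 0.0), (1.0, 2.0 / 3.0), (0.0, 0.0),
    ])
    def test_closed_form_points(self, x, expected):
        assert h_swish(x) == pytest.approx(expected, abs=1e-12)

    def test_saturates_to_identity_and_zero(self):
        grid = np.linspace(-10, 10, 201)
        out = h_swish(grid)
        np.testing.assert_allclose(out[grid >= 3], grid[grid >= 3])
        np.testing.assert_allclose(out[grid <= -3], 0.0)

    def test_smooth_nonmonotonic_dip(self):
        # the characteristic negative dip between -3 and 0
        assert h_swish(-1.5) < 0


class TestFeatureExtractionModule:
    def test_spatial_shape_preserved_channels_changed(self):
        rng = np.random.default_rng(0)
        mod = FeatureExtractionModule(ModuleSpec(6, 32), rng)
        out = mod(Tensor(rng.normal(size=(2, 6, 16, 16))))
        assert out.shape == (2, 32, 16, 16)

    def test_zeroed_branch_passes_input_through_shortcut(self):
        rng = np.random.default_rng(1)
        mod = FeatureExtractionModule(ModuleSpec(8, 8, residual=True), rng)
        mod.depthwise.weight.data[:] = 0.0
        mod.pointwise.weight.data[:] = 0.0
        mod.eval()  # running stats are identity (mean 0, var 1)
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        out = mod(Tensor(x))
        np.testing.assert_allclose(out.data, h_swish(x), atol=1e-5)

    def test_parameter_count_closed_form(self):
        rng = np.random.default_rng(2)
        mod = FeatureExtractionModule(ModuleSpec(32, 32), rng)
        # depthwise 32*9 + pointwise 32*32 + BN 2*32
        assert count_parameters(mod) == 1376
        assert ModuleSpec(32, 32).parameter_count == 1376
        # a plain 3x3 convolution with the same widths is much larger
        assert 32 * 32 * 9 == 9216 > 1376

    def test_residual_toggle_does_not_change_parameters(self):
        rng = np.random.default_rng(3)
        on = FeatureExtractionModule(ModuleSpec(16, 16, residual=True), rng)
        off = FeatureExtractionModule(ModuleSpec(16, 16, residual=False), rng)
        assert count_parameters(on) == count_parameters(off)

    def test_width_change_disables_shortcut(self):
        assert not ModuleSpec(16, 32, residual=True).uses_residual
        assert ModuleSpec(16, 16, residual=True).uses_residual

    def test_doubling_widths_quadruples_pointwise_dominated_count(self):
        small = ModuleSpec(64, 64).parameter_count
        big = ModuleSpec(128, 128).parameter_count
        assert big / small == pytest.approx(4.0, rel=0.1)


class TestSingleBranch:
    def test_forward_shape_contract(self):
        model = build_single_branch(NetConfig(**SMALL))
        rng = np.random.default_rng(0)
        out = model(rng.normal(size=(1, 6, 64, 64)).astype(np.float32))
        assert out.shape == (1, 3, 64, 64)

    def test_indivisible_input_raises(self):
        model = build_single_branch(NetConfig(**SMALL))
        with pytest.raises(ValueError, match="divisible"):
            model(np.zeros((1, 6, 60, 60), dtype=np.float32))

    def test_residual_toggle_parameter_invariance(self):
        on = build_single_branch(NetConfig(residual=True, **SMALL))
        off = build_single_branch(NetConfig(residual=False, **SMALL))
        assert count_parameters(on) == count_parameters(off)

    def test_fewer_parameters_than_plain_unet(self):
        ours = build_single_branch(NetConfig(**SMALL))
        plain = build_plain_unet(NetConfig(**SMALL))
        assert count_parameters(ours) < count_parameters(plain)

    def test_output_finite_for_finite_input(self):
        model = build_single_branch(NetConfig(**SMALL))
        rng = np.random.default_rng(1)
        out = model(rng.normal(size=(2, 6, 32, 32)).astype(np.float32))
        assert np.isfinite(out.data).all()

    def test_horizontal_flip_equivariance(self):
        # all padding and resampling is left/right symmetric, so flipping
        # the input and mirroring every spatial kernel flips the output
        # exactly (an asymmetric border would break this)
        model = build_single_branch(NetConfig(**SMALL, seed=4))
        model.eval()
        rng = np.random.default_rng(5)
        x = rng.normal(size=(1, 6, 32, 32)).astype(np.float32)
        out = model(x).data
        for _, p in model.named_parameters():
            if p.data.ndim >= 3:  # 3x3 kernels: mirror the column axis
                p.data = p.data[..., ::-1].copy()
        out_flipped = model(x[:, :, :, ::-1].copy()).data
        np.testing.assert_allclose(out[:, :, :, ::-1], out_flipped,
                                   rtol=2e-4, atol=1e-5)


class TestDualBranch:
    def make(self, **kw):
        cfg = NetConfig(branch_mode="dual", **SMALL, **kw)
        return build_dual_branch(cfg)

    def test_forward_shape_contract(self):
        model = self.make()
        rng = np.random.default_rng(0)
        a = rng.normal(size=(1, 6, 64, 64)).astype(np.float32)
        b = rng.normal(size=(1, 6, 64, 64)).astype(np.float32)
        assert model(a, b).shape == (1, 3, 64, 64)

    def test_more_parameters_than_single_branch(self):
        dual = self.make()
        single = build_single_branch(NetConfig(**SMALL))
        assert count_parameters(dual) > count_parameters(single)

    def test_residual_toggle_parameter_invariance(self):
        on = self.make(residual=True)
        off = self.make(residual=False)
        assert count_parameters(on) == count_parameters(off)

    def test_artificial_branch_is_live(self):
        model = self.make()
        model.eval()
        rng = np.random.default_rng(2)
        a = rng.normal(size=(1, 6, 32, 32)).astype(np.float32)
        b = rng.normal(size=(1, 6, 32, 32)).astype(np.float32)
        out_b = model(a, b).data
        out_zero = model(a, np.zeros_like(b)).data
        assert np.abs(out_b - out_zero).max() > 1e-3

    def test_spatial_mismatch_between_branches_raises(self):
        model = self.make()
        a = np.zeros((1, 6, 32, 32), dtype=np.float32)
        b = np.zeros((1, 6, 64, 64), dtype=np.float32)
        with pytest.raises(ValueError, match="disagree"):
            model(a, b)

    def test_branch_widths_can_differ(self):
        model = self.make(in_channels_art=1)
        a = np.zeros((1, 6, 32, 32), dtype=np.float32)
        b = np.zeros((1, 1, 32, 32), dtype=np.float32)
        assert model(a, b).shape == (1, 3, 32, 32)


class TestDeterminism:
    def test_same_seed_same_weights_same_output(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 6, 32, 32)).astype(np.float32)
        outs = []
        for _ in range(2):
            model = build_single_branch(NetConfig(**SMALL, seed=9))
            model.eval()
            outs.append(model(x).data)
        np.testing.assert_array_equal(outs[0], outs[1])


def test_config_validation():
    with pytest.raises(ValueError, match="per level"):
        NetConfig(n_classes=2, channels=(8, 16))
    with pytest.raises(ValueError, match="branch_mode"):
        NetConfig(n_classes=2, branch_mode="triple")
    with pytest.raises(ValueError, match="single"):
        build_single_branch(NetConfig(n_classes=2, branch_mode="dual"))


def test_checkpoint_round_trip(tmp_path):
    from hsiseg.training import load_checkpoint, save_checkpoint

    model = build_dual_branch(NetConfig(branch_mode="dual", **SMALL, seed=3))
    model.eval()
    rng = np.random.default_rng(0)
    a = rng.normal(size=(1, 6, 32, 32)).astype(np.float32)
    b = rng.normal(size=(1, 6, 32, 32)).astype(np.float32)
    before = model(a, b).data
    path = tmp_path / "model.ckpt.npz"
    save_checkpoint(model, path)
    restored = load_checkpoint(path)
    restored.eval()
    np.testing.assert_array_equal(before, restored(a, b).data)
    assert isinstance(restored, DualBranchUNet)
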