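import numpy as np
import pytest

import eegdenoiser as ed
from eegdenoiser import _autodiff as ad
from eegdenoiser.network import (ArchitectureSpec, MultiResBlock,
                                 MultiResUNet3Plus, ResConvBlock, ResPath,
                                 filter_budget, multires_widths,
                                 respath_blocks)


class TestArchitectureArithmetic:
    def test_reference_filter_budget(self):
        assert filter_budget(64, 5) == 320

    @pytest.mark.parametrize("W,expected", [
        (320, (53, 107, 160)),
        (6, (1, 2, 3)),
        (24, (4, 8, 12)),
        (40, (7, 13, 20)),
    ])
    def test_branch_widths(self, W, expected):
        widths = multires_widths(W)
        assert widths == expected
        assert sum(widths) == W

    def test_widths_always_sum_to_budget(self):
        for W in range(6, 400):
            assert sum(multires_widths(W)) == W

    def test_tiny_budget_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            multires_widths(5)

    @pytest.mark.parametrize("side,origin,d,expected", [
        ("inter", 1, 5, 4), ("inter", 2, 5, 3), ("inter", 3, 5, 2),
        ("inter", 4, 5, 1),
        ("intra", 5, 5, 1), ("intra", 4, 5, 2), ("intra", 3, 5, 3),
        ("intra", 2, 5, 4),
        ("inter", 1, 3, 2), ("intra", 3, 3, 1),
    ])
    def test_respath_block_counts(self, side, origin, d, expected):
        assert respath_blocks(side, origin, d) == expected

    @pytest.mark.parametrize("side,origin", [("inter", 0), ("inter", 5),
                                             ("intra", 1), ("intra", 6)])
    def test_out_of_range_origins_rejected(self, side, origin):
        with pytest.raises(ValueError):
            respath_blocks(side, origin, 5)

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="depth"):
            ArchitectureSpec(d=1)
        with pytest.raises(ValueError, match="odd"):
            ArchitectureSpec(kernel=4)
        with pytest.raises(ValueError, match="divisible"):
            ArchitectureSpec(d=5, input_length=500)
        assert ArchitectureSpec(d=5, n_base=64).W == 320


@pytest.fixture(scope="module")
def tiny_net():
    spec = ArchitectureSpec(d=3, n_base=8, input_length=64)
    return MultiResUNet3Plus(spec, seed=4)


@pytest.fixture(scope="module")
def net_rng():
    return np.random.default_rng(31)


class TestBuildingBlocks:
    def test_resconv_block_shape(self, net_rng):
        block = ResConvBlock(4, 9, 3, net_rng)
        out = block(ad.Tensor(net_rng.normal(size=(2, 4, 32))))
        assert out.shape == (2, 9, 32)

    def test_respath_pooling_halves_length(self, net_rng):
        path = ResPath(4, 8, n_blocks=2, scale=2, kernel=3, rng=net_rng)
        out = path(ad.Tensor(net_rng.normal(size=(2, 4, 32))))
        assert out.shape == (2, 8, 16)

    def test_respath_upsampling_doubles_length(self, net_rng):
        path = ResPath(4, 8, n_blocks=1, scale=-2, kernel=3, rng=net_rng)
        out = path(ad.Tensor(net_rng.normal(size=(2, 4, 32))))
        assert out.shape == (2, 8, 64)

    def test_multires_block_channel_budget(self, net_rng):
        block = MultiResBlock(1, 24, 3, net_rng)
        assert block.widths == (4, 8, 12)
        out = block(ad.Tensor(net_rng.normal(size=(2, 1, 32))))
        assert out.shape == (2, 24, 32)

    def test_relu_output_nonnegative(self, net_rng):
        block = MultiResBlock(1, 24, 3, net_rng)
        out = block(ad.Tensor(net_rng.normal(size=(2, 1, 32))))
        assert np.all(out.data >= 0)


class TestNetworkStructure:
    def test_decoder_receives_d_incoming_paths(self, tiny_net):
        d = tiny_net.spec.d
        for M, inter in tiny_net.inter_paths.items():
            intra = tiny_net.intra_paths[M]
            assert len(inter) + len(intra) == d
            assert set(inter) == set(range(1, M + 1))
            assert set(intra) == set(range(M + 1, d + 1))

    def test_respath_block_census(self, tiny_net):
        d = tiny_net.spec.d
        for M, inter in tiny_net.inter_paths.items():
            for i, path in inter.items():
                assert len(path.blocks) == d - i
            for j, path in tiny_net.intra_paths[M].items():
                assert len(path.blocks) == d - j + 1

    def test_number_of_decoders(self, tiny_net):
        assert len(tiny_net.fusions) == tiny_net.spec.d - 1

    def test_reference_depth_five_census(self):
        net = MultiResUNet3Plus(ArchitectureSpec(d=5, n_base=2,
                                                 input_length=64), seed=0)
        inter_counts = {i: len(p.blocks)
                        for i, p in net.inter_paths[4].items()}
        assert inter_counts == {1: 4, 2: 3, 3: 2, 4: 1}
        intra_counts = {j: len(net.intra_paths[1][j].blocks)
                        for j in (2, 3, 4, 5)}
        assert intra_counts == {2: 4, 3: 3, 4: 2, 5: 1}

    def test_describe_mentions_reference_widths(self):
        net = MultiResUNet3Plus(ArchitectureSpec(d=5, n_base=64), seed=0)
        text = net.describe()
        assert "W=320" in text
        assert "(53, 107, 160)" in text


class TestForwardPass:
    @pytest.mark.parametrize("length", [512, 1024])
    def test_output_matches_input_length(self, length):
        net = MultiResUNet3Plus(ArchitectureSpec(d=3, n_base=8,
                                                 input_length=length), seed=0)
        y = np.random.default_rng(0).normal(size=(2, length))
        out = net(y)
        assert out.shape == (2, 1, length)
        assert np.all(np.isfinite(out.data))

    def test_predict_returns_2d_float64(self, tiny_net):
        y = np.random.default_rng(1).normal(size=(3, 64))
        z = tiny_net.predict(y)
        assert z.shape == (3, 64) and z.dtype == np.float64

    def test_deterministic_given_seed(self):
        spec = ArchitectureSpec(d=3, n_base=8, input_length=64)
        y = np.random.default_rng(2).normal(size=(2, 64))
        a = MultiResUNet3Plus(spec, seed=7).predict(y)
        b = MultiResUNet3Plus(spec, seed=7).predict(y)
        assert np.array_equal(a, b)

    def test_wrong_length_rejected(self, tiny_net):
        with pytest.raises(ValueError, match="expected input"):
            tiny_net(np.zeros((2, 65)))

    def test_deep_supervision_head_count(self):
        spec = ArchitectureSpec(d=5, n_base=2, input_length=64,
                                deep_supervision=True)
        net = MultiResUNet3Plus(spec, seed=0)
        y = np.random.default_rng(3).normal(size=(2, 64))
        out, sides = net(y, return_side_outputs=True)
        assert len(sides) == 4  # decoders 2..4 plus the bottleneck
        assert set(sides) == {2, 3, 4, 5}
        for s in sides.values():
            assert s.shape == (2, 1, 64)

    def test_eval_mode_is_batch_independent(self, tiny_net):
        y = np.random.default_rng(4).normal(size=(4, 64))
        full = tiny_net.predict(y)
        split = np.concatenate([tiny_net.predict(y[:1]),
                                tiny_net.predict(y[1:])])
        assert np.allclose(full, split, atol=1e-5)


class TestGradients:
    def test_every_parameter_moves_after_one_step(self):
        spec = ArchitectureSpec(d=3, n_base=8, input_length=64,
                                deep_supervision=True)
        net = MultiResUNet3Plus(spec, seed=0)
        params = list(net.parameters())
        before = [p.data.copy() for p in params]
        opt = ad.Adam(params, lr=1e-2)
        rng = np.random.default_rng(0)
        y = rng.normal(size=(4, 64)).astype(np.float32)
        x = rng.normal(size=(4, 1, 64)).astype(np.float32)
        net.train()
        out, sides = net(y, return_side_outputs=True)
        loss = ad.mean_scalars([ad.mse(out, x)]
                               + [ad.mse(s, x) for s in sides.values()])
        loss.backward()
        opt.step()
        moved = [not np.array_equal(b, p.data)
                 for b, p in zip(before, params)]
        assert all(moved), f"{moved.count(False)} parameters received no update"

    def test_loss_gradient_matches_finite_differences(self):
        # end-to-end gradcheck on a micro-network in float64
        spec = ArchitectureSpec(d=2, n_base=6, input_length=8, kernel=3)
        net = MultiResUNet3Plus(spec, seed=1)
        for p in net.parameters():
            p.data = p.data.astype(np.float64)
        for m in net.modules():
            if hasattr(m, "running_mean"):
                m.training = False  # freeze BN stats for a clean comparison
        rng = np.random.default_rng(2)
        y = rng.normal(size=(2, 8))
        x = rng.normal(size=(2, 1, 8))

        def loss_value():
            return float(ad.mse(net(y), x).data)

        loss = ad.mse(net(y), x)
        loss.backward()
        eps = 1e-6
        checked = 0
        for p in list(net.parameters())[:6]:
            flat = p.data.reshape(-1)
            g = p.grad.reshape(-1)
            for idx in (0, flat.size // 2):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_value()
                flat[idx] = orig - eps
                dn = loss_value()
                flat[idx] = orig
                numeric = (up - dn) / (2 * eps)
                assert g[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)
                checked += 1
        assert checked >= 12


class TestPersistence:
    def test_save_load_round_trip(self, tiny_net, tmp_path):
        path = tmp_path / "weights.npz"
        tiny_net.save(path)
        clone = MultiResUNet3Plus.load(path, tiny_net.spec)
        y = np.random.default_rng(8).normal(size=(2, 64))
        assert np.allclose(tiny_net.predict(y), clone.predict(y), atol=1e-7)

    def test_missing_tensor_rejected(self, tiny_net):
        state = tiny_net.state_dict()
        key = next(iter(state))
        del state[key]
        fresh = MultiResUNet3Plus(tiny_net.spec, seed=9)
        with pytest.raises(KeyError, match="missing"):
            fresh.load_state_dict(state)
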