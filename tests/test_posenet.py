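"""Pose transformer: encoder/decoder/head contracts with loop oracles,
training basics and checkpoint stability."""

import numpy as np
import pytest

import tacpose as tp
from tacpose._seeding import rng as _rng
from tacpose.nn import Tensor
from tacpose.posenet import PoseNet, PoseNetConfig, Stage2TrainConfig


@pytest.fixture(scope="module")
def cfg():
    return PoseNetConfig(patch_size=4, d_model=16, n_layers=1, n_heads=2,
                         decoder_blocks=1, frame_h=32, frame_w=20)


@pytest.fixture(scope="module")
def net(cfg):
    return PoseNet(cfg, _rng(0, "pose"))


class TestEncode:
    def test_zero_layers_is_patch_embedding_plus_positions(self):
        cfg = PoseNetConfig(patch_size=4, d_model=16, n_layers=0, n_heads=2,
                            decoder_blocks=1, frame_h=16, frame_w=8)
        net = PoseNet(cfg, _rng(1, "pose"))
        frames = np.random.default_rng(0).uniform(0, 15, size=(2, 16, 8))
        tokens = net.encode(frames)
        expected = (net.patch_embed(Tensor(net.patchify(frames) / 15.0))
                    + net.pos_emb)
        np.testing.assert_allclose(tokens.data, expected.data, atol=1e-12)

    def test_attention_rows_sum_to_one(self, net):
        frames = np.random.default_rng(1).uniform(0, 15, size=(1, 32, 20))
        tok = net.patch_embed(Tensor(net.patchify(frames) / 15.0)) + net.pos_emb
        blk = net.blocks[0]
        _, w = blk.attn(blk.ln1(tok), return_weights=True)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_token_permutation_equivariance(self, net):
        frames = np.random.default_rng(2).uniform(0, 15, size=(1, 32, 20))
        tokens = net.patchify(frames)
        perm = np.random.default_rng(3).permutation(tokens.shape[1])

        def run(tok_arr, pos):
            x = net.patch_embed(Tensor(tok_arr / 15.0)) + Tensor(pos)
            for blk in net.blocks:
                x = blk(x)
            return x.data

        base = run(tokens, net.pos_emb.data)
        permuted = run(tokens[:, perm], net.pos_emb.data[perm])
        np.testing.assert_allclose(permuted, base[:, perm], atol=1e-10)

    def test_wrong_frame_shape_rejected(self, net):
        with pytest.raises(ValueError, match="expected frames"):
            net.encode(np.zeros((1, 30, 20)))


class TestDecode:
    def test_output_nonnegative_after_relu(self, net):
        frames = np.random.default_rng(4).uniform(0, 15, size=(2, 32, 20))
        k = net.decode(net.encode(frames))
        assert np.all(k.data >= 0.0)

    def test_spatial_size_doubles_per_block(self, cfg, net):
        frames = np.random.default_rng(5).uniform(0, 15, size=(1, 32, 20))
        k = net.decode(net.encode(frames))
        gh, gw = cfg.grid
        assert k.shape[-2:] == (gh * 2, gw * 2)

    def test_single_block_matches_loop_transposed_convolution(self):
        rng = np.random.default_rng(6)
        from tacpose import nn as tnn

        deconv = tnn.ConvTranspose2x2(1, 1, rng)
        x = rng.normal(size=(1, 1, 2, 2))
        out = deconv(Tensor(x)).data[0, 0]
        w = deconv.weight.data[0, 0]
        b = deconv.bias.data[0]
        expected = np.zeros((4, 4))
        for i in range(2):
            for j in range(2):
                for a in range(2):
                    for c in range(2):
                        expected[2 * i + a, 2 * j + c] += x[0, 0, i, j] * w[a, c]
        np.testing.assert_allclose(out, expected + b, atol=1e-12)


class TestKeypointHead:
    def test_zero_weight_returns_bias(self, cfg, net):
        saved = net.head.weight.data.copy()
        net.head.weight.data[...] = 0.0
        k = net.decode(net.encode(np.random.default_rng(7).uniform(0, 15, size=(1, 32, 20))))
        out = net.predict_keypoints(k).data
        np.testing.assert_allclose(out[0].ravel(), net.head.bias.data)
        net.head.weight.data[...] = saved

    def test_head_is_affine(self, net):
        k = net.decode(net.encode(np.random.default_rng(8).uniform(0, 15, size=(1, 32, 20))))
        out1 = net.predict_keypoints(k).data
        net.head.weight.data[...] *= 2.0
        out2 = net.predict_keypoints(k).data
        b = net.head.bias.data.reshape(1, -1, 3)
        np.testing.assert_allclose(out2 - b, 2.0 * (out1 - b), atol=1e-9)
        net.head.weight.data[...] /= 2.0

    def test_matches_hand_computed_affine(self):
        from tacpose import nn as tnn

        rng = np.random.default_rng(9)
        lin = tnn.Linear(4, 6, rng)
        x = rng.normal(size=(1, 4))
        expected = x @ lin.weight.data + lin.bias.data
        np.testing.assert_allclose(lin(Tensor(x)).data, expected, atol=1e-12)


class TestTrainStage2:
    def test_lr_zero_constant_loss(self, cfg, desk_body):
        scene_cfg = tp.desk_config(frame_h=32, frame_w=20, seed=6)
        scenes, _ = tp.make_dataset(24, scene_cfg, desk_body)
        X = np.stack([s.clean for s in scenes])
        Y = np.stack([s.pose for s in scenes])
        _, hist = tp.train_stage2(X, Y, cfg, Stage2TrainConfig(epochs=3, lr=0.0, seed=0))
        assert np.allclose(hist, hist[0])

    def test_loss_decreases(self, cfg, desk_body):
        scene_cfg = tp.desk_config(frame_h=32, frame_w=20, seed=6)
        scenes, _ = tp.make_dataset(40, scene_cfg, desk_body)
        X = np.stack([s.clean for s in scenes])
        Y = np.stack([s.pose for s in scenes])
        _, hist = tp.train_stage2(X, Y, cfg, Stage2TrainConfig(epochs=4, seed=0))
        assert hist[-1] < hist[0]

    def test_checkpoint_roundtrip_bitwise(self, cfg, desk_body, tmp_path):
        scene_cfg = tp.desk_config(frame_h=32, frame_w=20, seed=6)
        scenes, _ = tp.make_dataset(16, scene_cfg, desk_body)
        X = np.stack([s.clean for s in scenes])
        Y = np.stack([s.pose for s in scenes])
        model, _ = tp.train_stage2(X, Y, cfg, Stage2TrainConfig(epochs=1, seed=0))
        before = model.predict_mm(X[:4])
        path = tmp_path / "pose.npz"
        model.save(path)
        after = PoseNet.load(path).predict_mm(X[:4])
        np.testing.assert_array_equal(before, after)

    def test_predictions_have_joint_shape_and_are_finite(self, cfg, desk_body):
        scene_cfg = tp.desk_config(frame_h=32, frame_w=20, seed=6)
        scenes, _ = tp.make_dataset(16, scene_cfg, desk_body)
        X = np.stack([s.clean for s in scenes])
        Y = np.stack([s.pose for s in scenes])
        model, _ = tp.train_stage2(X, Y, cfg, Stage2TrainConfig(epochs=1, seed=0))
        pred = model.predict_mm(X)
        assert pred.shape == (16, 12, 3)
        assert np.all(np.isfinite(pred))
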