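"""Scene generator: pose geometry, renderer physics, corruption statistics,
dataset splitting."""

import numpy as np
import pytest

import tacpose as tp
from tacpose._seeding import spawn_seed
from tacpose.synthetic import JOINT_NAMES, contact_joints

_J = {n: i for i, n in enumerate(JOINT_NAMES)}


def brute_force_label(mask: np.ndarray) -> int:
    """4-connected component count via BFS (independent of scipy)."""
    seen = np.zeros_like(mask, dtype=bool)
    H, W = mask.shape
    n = 0
    for r in range(H):
        for c in range(W):
            if mask[r, c] and not seen[r, c]:
                n += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    i, j = stack.pop()
                    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        a, b = i + di, j + dj
                        if 0 <= a < H and 0 <= b < W and mask[a, b] and not seen[a, b]:
                            seen[a, b] = True
                            stack.append((a, b))
    return n


class TestSamplePose:
    def test_standing_geometry(self):
        pose = tp.sample_pose(tp.BodyModel(), "standing", rng_seed=0)
        assert pose[_J["l_foot"], 2] == 0.0
        assert pose[_J["r_foot"], 2] == 0.0
        assert pose[_J["head"], 2] > 1000.0

    def test_plank_has_at_least_four_contacts(self):
        pose = tp.sample_pose(tp.BodyModel(), "plank", rng_seed=0)
        assert contact_joints(pose).size >= 4

    def test_deterministic_given_seed(self):
        a = tp.sample_pose(tp.BodyModel(), "squat", rng_seed=7)
        b = tp.sample_pose(tp.BodyModel(), "squat", rng_seed=7)
        np.testing.assert_array_equal(a, b)

    def test_unknown_activity_lists_supported(self):
        with pytest.raises(ValueError, match="standing"):
            tp.sample_pose(tp.BodyModel(), "cartwheel", rng_seed=0)


class TestRenderPressure:
    def test_standing_gives_two_components_above_half_max(self, desk_cfg, desk_body):
        pose = tp.sample_pose(desk_body, "standing", 5, center_mm=(320, 160))
        frame = tp.render_pressure(pose, desk_cfg)
        assert brute_force_label(frame > frame.max() / 2) == 2

    def test_no_contacts_renders_zero_frame(self, desk_cfg):
        pose = np.full((12, 3), 500.0)  # everything airborne
        assert tp.render_pressure(pose, desk_cfg).sum() == 0.0

    def test_linearity_in_body_weight(self, desk_cfg, desk_body):
        pose = tp.sample_pose(desk_body, "standing", 5, center_mm=(320, 160))
        f1 = tp.render_pressure(pose, desk_cfg, weight_kg=30.0)
        f2 = tp.render_pressure(pose, desk_cfg, weight_kg=60.0)
        np.testing.assert_allclose(f2, 2.0 * f1, atol=1e-12)

    def test_translation_equivariance_on_pixel_shifts(self, desk_body):
        # mat 640 x 320 mm at 64 x 40 px -> 10 x 8 mm per pixel
        cfg = tp.desk_config(seed=0)
        pose = tp.sample_pose(desk_body, "standing", 3, center_mm=(280, 140))
        shift = np.array([30.0, 16.0, 0.0])  # 3 rows, 2 cols
        f0 = tp.render_pressure(pose, cfg)
        f1 = tp.render_pressure(pose + shift, cfg)
        np.testing.assert_allclose(f1[3:, 2:], f0[:-3, :-2], atol=1e-9)

    def test_nonfinite_pose_rejected(self, desk_cfg):
        pose = np.zeros((12, 3))
        pose[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            tp.render_pressure(pose, desk_cfg)


class TestCorrupt:
    def test_identity_when_all_noise_off(self, desk_body):
        cfg = tp.desk_config(noise_sigma=0.0, spurious_blob_rate=0.0)
        pose = tp.sample_pose(desk_body, "standing", 1, center_mm=(320, 160))
        clean = tp.render_pressure(pose, cfg)
        np.testing.assert_array_equal(tp.corrupt(clean, cfg), clean)

    def test_additive_noise_is_zero_mean(self):
        cfg = tp.desk_config(frame_h=100, frame_w=100, noise_sigma=0.5,
                             spurious_blob_rate=0.0)
        clean = np.full((100, 100), 7.0)  # far from both clip bounds
        out = tp.corrupt(clean, cfg, rng_seed=4)
        resid = out - clean
        assert abs(resid.mean()) < 3 * 0.5 / 100  # 3 standard errors
        assert abs(resid.std() - 0.5) < 0.02

    def test_spurious_blob_count_matches_poisson_rate(self):
        cfg = tp.desk_config(noise_sigma=0.0, spurious_blob_rate=3.0)
        clean = np.zeros((64, 40))
        counts = []
        for i in range(100):
            out = tp.corrupt(clean, cfg, rng_seed=i)
            counts.append(brute_force_label(out > 0))
        # mean component count tracks the Poisson mean (blobs may merge)
        assert 2.0 <= np.mean(counts) <= 4.0

    def test_output_bounded_and_deterministic(self, desk_cfg, desk_body):
        pose = tp.sample_pose(desk_body, "plank", 2, center_mm=(320, 160))
        clean = tp.render_pressure(pose, desk_cfg)
        a = tp.corrupt(clean, desk_cfg, rng_seed=9)
        b = tp.corrupt(clean, desk_cfg, rng_seed=9)
        np.testing.assert_array_equal(a, b)
        assert a.min() >= 0.0 and a.max() <= desk_cfg.max_pressure


class TestMakeDataset:
    def test_validation_activities_disjoint_from_train(self, desk_cfg, desk_body):
        scenes, split = tp.make_dataset(80, desk_cfg, desk_body)
        val_acts = {scenes[i].activity for i in split["val"]}
        train_acts = {scenes[i].activity for i in split["train"]}
        assert val_acts == {"sit", "squat"}
        assert val_acts & train_acts == set()

    def test_split_counts_follow_fractions(self, desk_cfg, desk_body):
        scenes, split = tp.make_dataset(80, desk_cfg, desk_body)
        k = len(split["val"])
        rest = 80 - k
        assert abs(len(split["train"]) - 0.8 * rest) <= 1
        assert abs(len(split["test"]) - 0.2 * rest) <= 1

    def test_same_seed_reproduces_split_and_frames(self, desk_cfg, desk_body):
        s1, i1 = tp.make_dataset(40, desk_cfg, desk_body)
        s2, i2 = tp.make_dataset(40, desk_cfg, desk_body)
        assert i1 == i2
        np.testing.assert_array_equal(s1[0].noisy, s2[0].noisy)
        np.testing.assert_array_equal(s1[-1].pose, s2[-1].pose)

    def test_too_few_frames_rejected(self, desk_cfg, desk_body):
        with pytest.raises(ValueError, match=">= 10"):
            tp.make_dataset(5, desk_cfg, desk_body)

    def test_frames_pair_poses_by_exact_timestamp(self, desk_cfg, desk_body):
        scenes, _ = tp.make_dataset(20, desk_cfg, desk_body)
        ts = [s.t for s in scenes]
        assert ts == [i / 60.0 for i in range(20)]
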