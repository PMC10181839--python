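"""Targets, augmentation, batching, losses and the optimization loop."""

import numpy as np
import pytest

from peakcloud import trainer
from peakcloud.autodiff import Tensor
from peakcloud.network import MSPointNet, NetworkConfig
from peakcloud.preprocess import PointCloud
from peakcloud.trainer import (TrainConfig, augment, focal_loss, make_targets,
                               pad_batch, polar_iou_loss, quality_focal_loss,
                               split_dataset)

SMALL = NetworkConfig(widths=(8, 16, 32, 64), k_neighbors=4, head_widths=(16, 8))


def labeled_cloud(n_noise=20, seed=0):
    """Two clean features plus scattered noise, in normalized coordinates."""
    rng = np.random.default_rng(seed)
    out_rt, out_mz, out_i, out_l = [], [], [], []
    for inst, (cx, cy, amp) in enumerate([(-2.0, -1.0, 10.0), (2.5, 1.5, 12.0)]):
        g = np.mgrid[-1.2:1.2:9j, -1.2:1.2:9j].reshape(2, -1).T
        inten = amp * np.exp(-(g ** 2).sum(axis=1))
        keep = inten > amp * 0.05
        out_rt.append(cx + g[keep, 0])
        out_mz.append(cy + g[keep, 1])
        out_i.append(np.log2(1 + inten[keep] * 100))
        out_l.append(np.full(keep.sum(), inst))
    out_rt.append(rng.uniform(-5, 5, n_noise))
    out_mz.append(rng.uniform(-4, 4, n_noise))
    out_i.append(rng.uniform(1, 3, n_noise))
    out_l.append(np.full(n_noise, -1))
    return PointCloud(rt=np.concatenate(out_rt), mz=np.concatenate(out_mz),
                      intensity=np.concatenate(out_i), normalized=True,
                      labels=np.concatenate(out_l))


class TestSplitDataset:
    def test_annotated_corpus_ratio(self):
        # 306 clouds at 7:3 -> 214 train / 92 validation
        tr, va = split_dataset(list(range(306)), 0.7, seed=0)
        assert (len(tr), len(va)) == (214, 92)

    def test_small_case(self):
        tr, va = split_dataset(list(range(10)), 0.7, seed=1)
        assert (len(tr), len(va)) == (7, 3)
        assert sorted(tr + va) == list(range(10))

    def test_seed_determinism(self):
        a1, _ = split_dataset(list(range(50)), 0.5, seed=3)
        a2, _ = split_dataset(list(range(50)), 0.5, seed=3)
        b1, _ = split_dataset(list(range(50)), 0.5, seed=4)
        assert a1 == a2
        assert a1 != b1

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            split_dataset([1], 0.5, 0)


class TestMakeTargets:
    def test_noise_only_cloud_all_zero(self):
        cloud = labeled_cloud(n_noise=30)
        cloud.labels[:] = -1
        t = make_targets(cloud, 0.5)
        assert not t.semantic.any()
        assert not t.centerness.any()
        assert not t.valid_mask.any()

    def test_apex_centerness_is_one(self):
        cloud = labeled_cloud()
        t = make_targets(cloud, 0.5)
        for inst in (0, 1):
            members = cloud.labels == inst
            apex = np.flatnonzero(members)[cloud.intensity[members].argmax()]
            assert t.centerness[apex] == pytest.approx(1.0)

    def test_centerness_at_one_sigma(self):
        # a member exactly center_sigma from the apex gets exp(-1/2)
        cloud = PointCloud(rt=np.array([0.0, 0.5]), mz=np.array([0.0, 0.0]),
                           intensity=np.array([10.0, 5.0]), normalized=True,
                           labels=np.array([0, 0]))
        t = make_targets(cloud, center_sigma=0.5)
        assert t.centerness[1] == pytest.approx(np.exp(-0.5), rel=1e-9)

    def test_members_inside_own_gt_mask(self):
        from peakcloud.polarmask import PolarMask, point_in_mask

        cloud = labeled_cloud()
        t = make_targets(cloud, 0.5)
        members = np.flatnonzero(cloud.labels == 0)
        xy = np.column_stack([cloud.rt, cloud.mz])
        for i in members[:5]:
            mask = PolarMask(tuple(xy[i]), t.gt_rays[i])
            assert point_in_mask(xy[members], mask).all()

    def test_semantic_zero_implies_centerness_zero(self):
        t = make_targets(labeled_cloud(), 0.5)
        assert not t.centerness[t.semantic == 0].any()


class TestAugment:
    def test_forced_identity(self):
        cloud = labeled_cloud()
        out = augment(cloud, seed=0, scale_range=(1.0, 1.0),
                      offset_rt=0.0, offset_mz=0.0)
        np.testing.assert_allclose(out.rt, cloud.rt)
        np.testing.assert_allclose(out.intensity, cloud.intensity)

    def test_scale_factors_within_half_to_two(self):
        cloud = labeled_cloud()
        for seed in range(30):
            out = augment(cloud, seed=seed, offset_rt=0.0, offset_mz=0.0)
            s_rt = np.ptp(out.rt) / np.ptp(cloud.rt)
            s_i = np.ptp(out.intensity) / np.ptp(cloud.intensity)
            assert 0.5 - 1e-6 <= s_rt <= 2.0 + 1e-6
            assert 0.5 - 1e-6 <= s_i <= 2.0 + 1e-6

    def test_footprint_area_scales_as_srt_times_smz(self):
        cloud = labeled_cloud(n_noise=0)
        out = augment(cloud, seed=5)
        s_rt = np.ptp(out.rt) / np.ptp(cloud.rt)
        s_mz = np.ptp(out.mz) / np.ptp(cloud.mz)
        members = cloud.labels == 0
        hull0 = (np.ptp(cloud.rt[members]) * np.ptp(cloud.mz[members]))
        hull1 = (np.ptp(out.rt[members]) * np.ptp(out.mz[members]))
        assert hull1 / hull0 == pytest.approx(s_rt * s_mz, rel=1e-6)

    def test_labels_unchanged(self):
        cloud = labeled_cloud()
        out = augment(cloud, seed=9)
        np.testing.assert_array_equal(out.labels, cloud.labels)


class TestPadBatch:
    def test_equal_sizes_unpadded(self):
        batch = pad_batch([labeled_cloud(seed=1), labeled_cloud(seed=2)], 0)
        assert all(not c.pad_mask.any() for c in batch)

    def test_padding_count_and_labels(self):
        a = labeled_cloud(n_noise=40, seed=1)
        b = labeled_cloud(n_noise=20, seed=2)
        batch = pad_batch([a, b], 0)
        assert len(batch[0]) == len(batch[1])
        added = batch[1].pad_mask.sum()
        assert added == len(a) - len(b)
        assert np.all(batch[1].labels[batch[1].pad_mask] == -1)

    def test_padding_excluded_from_ray_targets(self):
        a = labeled_cloud(n_noise=40, seed=1)
        b = labeled_cloud(n_noise=20, seed=2)
        batch = pad_batch([a, b], 0)
        t = make_targets(batch[1], 0.5)
        assert not t.valid_mask[batch[1].pad_mask].any()


class TestFocalLoss:
    def test_confident_correct_prediction_is_zero(self):
        assert float(focal_loss(np.array([1.0 - 1e-7]), np.array([1.0])).data) \
            == pytest.approx(0.0, abs=1e-10)

    def test_hand_value_at_half(self):
        # p=0.5, y=1, α=0.25, γ=2 -> 0.25 · 0.25 · ln 2
        val = float(focal_loss(np.array([0.5]), np.array([1.0]), 0.25, 2.0).data)
        assert val == pytest.approx(0.25 * 0.25 * np.log(2.0), rel=1e-6)

    def test_gamma_zero_alpha_half_is_half_bce(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 20)
        y = (rng.random(20) > 0.5).astype(float)
        fl = float(focal_loss(p, y, alpha=0.5, gamma=0.0).data)
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert fl == pytest.approx(0.5 * bce, rel=1e-5)

    def test_extreme_probabilities_clamped_finite(self):
        val = float(focal_loss(np.array([0.0, 1.0]), np.array([1.0, 0.0])).data)
        assert np.isfinite(val)


class TestQualityFocalLoss:
    def test_zero_at_exact_soft_prediction(self):
        y = np.array([0.0, 0.3, 0.8, 1.0])
        val = float(quality_focal_loss(y.copy(), y).data)
        # |y-p|^γ modulation kills the loss when p == y
        assert val == pytest.approx(0.0, abs=1e-8)

    def test_reduces_to_symmetric_focal_on_hard_labels(self):
        p = np.array([0.3, 0.7])
        y = np.array([1.0, 0.0])
        qfl = float(quality_focal_loss(p, y, gamma=2.0).data)
        fl = float(focal_loss(p, y, alpha=0.5, gamma=2.0).data)
        assert qfl == pytest.approx(2.0 * fl, rel=1e-6)

    def test_gradient_larger_for_worse_predictions(self):
        for p0, p1 in [(0.2, 0.4), (0.5, 0.9)]:
            t0 = Tensor(np.array([p0]), requires_grad=True)
            quality_focal_loss(t0, np.array([1.0])).backward()
            t1 = Tensor(np.array([p1]), requires_grad=True)
            quality_focal_loss(t1, np.array([1.0])).backward()
            assert abs(t0.grad[0]) > abs(t1.grad[0])


class TestPolarIoULoss:
    def test_perfect_prediction_zero_loss(self):
        r = np.random.default_rng(0).uniform(0.5, 2, (4, 36))
        loss = polar_iou_loss(Tensor(r), r)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-6)

    def test_half_iou_gives_ln2(self):
        pred = Tensor(np.ones((3, 36)))
        loss = polar_iou_loss(pred, np.full((3, 36), 2.0))
        assert float(loss.data) == pytest.approx(np.log(2.0), rel=1e-6)

    def test_monotone_toward_target(self):
        gt = np.full((1, 36), 2.0)
        losses = [float(polar_iou_loss(Tensor(np.full((1, 36), s)), gt).data)
                  for s in (0.5, 1.0, 1.5, 2.0)]
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestTrainLoop:
    def test_one_epoch_bookkeeping(self):
        clouds = [labeled_cloud(seed=s) for s in range(4)]
        model = MSPointNet(SMALL, seed=0)
        cfg = TrainConfig(epochs=1, batch_size=2, seed=0)
        _, hist = trainer.train(model, clouds[:3], clouds[3:], cfg)
        assert set(hist.split) == {"train", "val"}
        assert {"sem_loss", "cen_loss", "mask_loss",
                "semantic_acc", "center_acc", "mask_iou"} <= set(hist.columns)
        assert hist[["sem_loss", "cen_loss", "mask_loss"]].notna().all().all()
        assert np.isfinite(hist[["sem_loss", "cen_loss", "mask_loss"]]).all().all()

    def test_loss_decreases_on_small_run(self):
        clouds = [labeled_cloud(seed=s) for s in range(6)]
        model = MSPointNet(SMALL, seed=1)
        cfg = TrainConfig(epochs=8, batch_size=3, lr=2e-3, seed=0)
        _, hist = trainer.train(model, clouds, [], cfg)
        tr = hist[hist.split == "train"]
        first = tr.iloc[0][["sem_loss", "cen_loss", "mask_loss"]].sum()
        last = tr.iloc[-1][["sem_loss", "cen_loss", "mask_loss"]].sum()
        assert last < first

    def test_total_loss_is_weighted_sum(self):
        cloud = labeled_cloud(seed=0)
        model = MSPointNet(SMALL, seed=0)
        cfg = TrainConfig(loss_weights=(2.0, 0.5, 1.5))
        t = make_targets(cloud, cfg.center_sigma, SMALL.n_rays)
        pred = model.forward(cloud, seed=0)
        l_sem, l_cen, l_mask = trainer.cloud_losses(pred, t, cfg)
        total = (2.0 * float(l_sem.data) + 0.5 * float(l_cen.data)
                 + 1.5 * float(l_mask.data))
        assert total >= 0
        assert all(float(x.data) >= 0 for x in (l_sem, l_cen, l_mask))
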