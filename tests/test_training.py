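"""Balanced batch sampling, augmentation, LR schedule, optimiser contract."""

import numpy as np
import pytest

import sononet as sn
from sononet.taxonomy import LabelTaxonomy
from sononet.training import (AugmentationSpec, BatchComposition,
                              LabelledDataset, LRSchedule, augment,
                              default_schedule, draw_augmentation, lr_at,
                              sample_balanced_batch, train)

rng = np.random.default_rng(0)


def toy_taxonomy(K):
    return LabelTaxonomy(names=[f"c{i}" for i in range(K - 1)] + ["bg"],
                         background_index=K - 1)


def toy_dataset(K, n_per_class, n_background):
    items = []
    for k in range(K - 1):
        items += [(np.full((4, 4), float(k)), k)] * n_per_class
    items += [(np.zeros((4, 4)), K - 1)] * n_background
    return LabelledDataset(items, toy_taxonomy(K))


class TestBalancedBatches:
    def test_default_composition_gives_52_frame_batch(self):
        data = toy_dataset(14, 5, 40)
        batch = sample_balanced_batch(data, BatchComposition(),
                                      np.random.default_rng(1))
        assert len(batch) == 52
        labels = np.array([lab for _, lab in batch])
        counts = np.bincount(labels, minlength=14)
        assert (counts[:13] == 2).all() and counts[13] == 26

    def test_small_composition_arithmetic(self):
        data = toy_dataset(3, 2, 4)
        batch = sample_balanced_batch(data, BatchComposition(1, 2),
                                      np.random.default_rng(1))
        assert len(batch) == 4

    def test_empty_foreground_pool_names_class(self):
        data = toy_dataset(3, 1, 3)
        data.items = [it for it in data.items if it[1] != 1]
        with pytest.raises(ValueError, match="class 1"):
            sample_balanced_batch(data, BatchComposition(1, 2),
                                  np.random.default_rng(0))

    def test_singleton_pools_sampled_with_replacement(self):
        data = toy_dataset(4, 1, 1)
        batch = sample_balanced_batch(data, BatchComposition(3, 5),
                                      np.random.default_rng(2))
        labels = np.array([lab for _, lab in batch])
        counts = np.bincount(labels, minlength=4)
        assert (counts == [3, 3, 3, 5]).all()

    def test_composition_exact_over_many_draws(self):
        data = toy_dataset(5, 3, 10)
        comp = BatchComposition(2, 6)
        r = np.random.default_rng(3)
        for _ in range(200):
            labels = np.array([lab for _, lab in
                               sample_balanced_batch(data, comp, r)])
            counts = np.bincount(labels, minlength=5)
            assert (counts == [2, 2, 2, 2, 6]).all()


class TestAugmentation:
    def test_degenerate_spec_is_identity_on_square_input(self):
        spec = AugmentationSpec(min_crop=16, max_crop=16, out_size=16,
                                flip_lr=False, rotation_range_deg=(0, 0))
        x = rng.uniform(size=(16, 16))
        out = augment(x, spec, np.random.default_rng(0))
        np.testing.assert_allclose(out.pixels, x, atol=1e-12)

    def test_seeded_determinism(self):
        spec = AugmentationSpec(min_crop=20, max_crop=28, out_size=28)
        x = rng.uniform(size=(32, 32))
        a = augment(x, spec, np.random.default_rng(5)).pixels
        b = augment(x, spec, np.random.default_rng(5)).pixels
        np.testing.assert_array_equal(a, b)

    def test_source_too_small(self):
        spec = AugmentationSpec(min_crop=20, max_crop=64, out_size=64)
        with pytest.raises(ValueError, match="smaller"):
            augment(np.zeros((32, 32)), spec, np.random.default_rng(0))

    def test_rotation_angles_uniform_in_range(self):
        # Monte-Carlo check of the stated +-25 degree uniform draw
        spec = AugmentationSpec(min_crop=174, max_crop=224, out_size=224)
        r = np.random.default_rng(7)
        angles = np.array([draw_augmentation(spec, 224, 288, r)[4]
                           for _ in range(10_000)])
        assert angles.min() >= -25.0 and angles.max() <= 25.0
        se = 50 / np.sqrt(12) / np.sqrt(len(angles))
        assert abs(angles.mean()) < 3 * se

    def test_crop_sides_span_range(self):
        spec = AugmentationSpec(min_crop=174, max_crop=224, out_size=224)
        r = np.random.default_rng(8)
        sides = {draw_augmentation(spec, 224, 288, r)[0]
                 for _ in range(2000)}
        assert min(sides) == 174 and max(sides) == 224

    def test_canonical_spec_scales_to_other_sizes(self):
        spec = AugmentationSpec.for_size(64)
        assert spec.out_size == spec.max_crop == 64
        assert spec.min_crop == round(64 * 174 / 224)


class TestSchedule:
    def test_warmup_then_initial_then_decay(self):
        s = LRSchedule()
        assert lr_at(s, 499, 0) == 0.01
        assert lr_at(s, 500, 0) == 0.1
        assert lr_at(s, 10_000, 2) == pytest.approx(0.001)

    def test_rate_non_increasing_in_plateau_events(self):
        s = LRSchedule()
        rates = [lr_at(s, 1000, e) for e in range(5)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_smallnet_default_initial_rate(self):
        assert default_schedule("smallnet").initial_lr == 0.001
        assert default_schedule("sononet").initial_lr == 0.1

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            LRSchedule(warmup_lr=0.5, initial_lr=0.1)
        with pytest.raises(ValueError):
            LRSchedule(decay_factor=1.0)

    def test_negative_iteration_rejected(self):
        with pytest.raises(ValueError):
            lr_at(LRSchedule(), -1, 0)


def shapes_dataset(K=3, n=12, size=32, seed=0):
    """Tiny separable task: bright square vs bright disc vs speckle."""
    r = np.random.default_rng(seed)
    items = []
    yy, xx = np.mgrid[:size, :size]
    for k in range(K - 1):
        for _ in range(n):
            img = r.uniform(0.1, 0.3, size=(size, size))
            cr, cc = r.integers(10, size - 10, 2)
            if k == 0:
                img[cr - 6:cr + 6, cc - 6:cc + 6] += 0.7
            else:
                img += 0.7 * ((yy - cr) ** 2 + (xx - cc) ** 2 < 36)
            items.append((img, k))
    for _ in range(2 * n):
        items.append((r.uniform(0.1, 0.3, size=(size, size)), K - 1))
    return LabelledDataset(items, toy_taxonomy(K))


class TestTrain:
    def test_loss_decreases_on_separable_task(self):
        data = shapes_dataset()
        net = sn.build_network(sn.NetworkConfig("sononet", 4, 3),
                               np.random.default_rng(0))
        schedule = LRSchedule(warmup_lr=0.01, warmup_iters=5, initial_lr=0.05)
        net, hist = train(net, data, schedule=schedule,
                          comp=BatchComposition(2, 4),
                          rng=np.random.default_rng(1), n_iterations=40,
                          val_every=20, do_augment=False)
        losses = [r["loss"] for r in hist.records]
        assert np.mean(losses[-5:]) < losses[0]

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        data = shapes_dataset()
        net = sn.build_network(sn.NetworkConfig("sononet", 2, 3),
                               np.random.default_rng(0))
        before = [p.copy() for _, _, p in net.parameters()]
        schedule = LRSchedule(warmup_lr=0.0, warmup_iters=10**6,
                              initial_lr=0.1)
        train(net, data, schedule=schedule, comp=BatchComposition(1, 2),
              rng=np.random.default_rng(1), n_iterations=3,
              val_every=100, do_augment=False)
        for old, (_, _, new) in zip(before, net.parameters()):
            np.testing.assert_array_equal(old, new)

    def test_same_seed_reproduces_loss_curve(self):
        curves = []
        for _ in range(2):
            data = shapes_dataset()
            net = sn.build_network(sn.NetworkConfig("sononet", 2, 3),
                                   np.random.default_rng(0))
            _, hist = train(net, data, comp=BatchComposition(1, 2),
                            rng=np.random.default_rng(9), n_iterations=5,
                            val_every=100, do_augment=False)
            curves.append([r["loss"] for r in hist.records])
        assert curves[0] == curves[1]

    def test_divergence_aborts_with_diagnostic(self):
        data = shapes_dataset()
        net = sn.build_network(sn.NetworkConfig("sononet", 2, 3),
                               np.random.default_rng(0))
        # poison the adaptation output (no rectifier after it, so the
        # non-finite value reaches the loss)
        from sononet.nn import Conv2d
        last_conv = [l for l in net.layers if isinstance(l, Conv2d)][-1]
        last_conv.params["b"][0] = np.nan
        with pytest.raises(RuntimeError, match="diverged"):
            train(net, data, comp=BatchComposition(1, 2),
                  rng=np.random.default_rng(1), n_iterations=2,
                  val_every=100, do_augment=False)
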