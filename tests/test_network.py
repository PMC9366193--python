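"""Network architecture, losses, gradients and training mechanics.

Heavy end-to-end training lives in the acceptance suite; here the model
is exercised at tiny scale (depth 2, 8x8 inputs) so every contract is
checked in seconds.
"""

import numpy as np
import pytest

from boundaryseg.errors import ConfigError, DataError, ShapeMismatchError, TrainingError
from boundaryseg.nn import (
    CLIP_EPS,
    NetworkConfig,
    TrainingConfig,
    build_model,
    kfold_split,
    map_loss,
    predict,
    seg_loss,
    total_loss,
    train,
)
from boundaryseg.nn.layers import sigmoid
from boundaryseg.nn.training import evaluate_loss


def tiny_cfg(placement="both"):
    return NetworkConfig(depth=2, base_channels=4, head_placement=placement,
                        input_size=(8, 8))


def tiny_batch(rng, n=4, size=8):
    return {
        "images": rng.random((n, size, size)),
        "masks": (rng.random((n, size, size)) > 0.5).astype(float),
        "maps": (rng.random((n, size, size)) > 0.8).astype(float),
    }


# ---------------------------------------------------------------- architecture


class TestArchitecture:
    @pytest.mark.parametrize(
        "placement,expected_heads",
        [("encoder", 4), ("decoder", 4), ("both", 8)],
    )
    def test_head_count_per_placement(self, placement, expected_heads):
        cfg = NetworkConfig(depth=4, base_channels=4, head_placement=placement,
                           input_size=(32, 32))
        model = build_model(cfg)
        assert model.n_stages == expected_heads
        _, head_logits = model.forward(np.zeros((1, 1, 32, 32), dtype=np.float32))
        assert len(head_logits) == expected_heads

    def test_all_outputs_at_input_resolution(self, rng):
        model = build_model(tiny_cfg())
        seg, heads = model.forward(rng.random((2, 1, 8, 8)))
        assert seg.shape == (2, 1, 8, 8)
        for h in heads:
            assert h.shape == (2, 1, 8, 8)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ConfigError):
            NetworkConfig(depth=4, input_size=(60, 60))

    def test_wrong_runtime_shape_rejected(self, rng):
        model = build_model(tiny_cfg())
        with pytest.raises(ShapeMismatchError):
            model.forward(rng.random((1, 1, 16, 16)))

    def test_zero_init_heads_start_at_half(self, rng):
        model = build_model(tiny_cfg())
        seg, heads = model.forward(rng.random((1, 1, 8, 8)))
        assert np.all(seg == 0.0)
        assert all(np.all(h == 0.0) for h in heads)


# ---------------------------------------------------------------- losses


class TestLosses:
    def test_uniform_half_prediction_gives_ln2(self):
        gt = (np.arange(64).reshape(8, 8) % 2).astype(float)
        pred = np.full((8, 8), 0.5)
        assert seg_loss(pred, gt) == pytest.approx(np.log(2))
        assert map_loss([pred], gt) == pytest.approx(np.log(2))

    def test_perfect_prediction_near_zero(self):
        gt = np.zeros((8, 8))
        gt[2:6, 2:6] = 1.0
        pred = np.clip(gt, CLIP_EPS, 1 - CLIP_EPS)
        assert seg_loss(pred, gt) <= 1e-6
        assert map_loss([pred, pred], gt) <= 2e-6

    def test_all_ones_gt_closed_form(self):
        p = 0.3
        gt = np.ones((4, 4))
        assert seg_loss(np.full((4, 4), p), gt) == pytest.approx(-np.log(p))

    def test_stage_additivity(self, rng):
        gt = (rng.random((8, 8)) > 0.7).astype(float)
        preds = [rng.random((8, 8)) for _ in range(4)]
        total = map_loss(preds, gt)
        assert total == pytest.approx(sum(map_loss([p], gt) for p in preds), abs=1e-12)

    def test_bundle_additivity_on_random_inputs(self, rng):
        for _ in range(20):
            gt_map = (rng.random((6, 6)) > 0.8).astype(float)
            gt_mask = (rng.random((6, 6)) > 0.5).astype(float)
            preds = [rng.random((6, 6)) for _ in range(3)]
            seg = rng.random((6, 6))
            bundle = total_loss(preds, gt_map, seg, gt_mask)
            assert bundle.total_loss == pytest.approx(
                bundle.map_loss + bundle.seg_loss, abs=1e-9
            )
            assert bundle.map_loss == pytest.approx(sum(bundle.per_stage), abs=1e-9)
            assert bundle.map_loss >= 0 and bundle.seg_loss >= 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            seg_loss(np.full((4, 4), 0.5), np.ones((5, 5)))


# ---------------------------------------------------------------- gradients


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        model = build_model(tiny_cfg(), seed=3)
        x = rng.random((2, 1, 8, 8)).astype(np.float32)
        g = (rng.random((2, 1, 8, 8)) > 0.5).astype(np.float32)
        m = (rng.random((2, 1, 8, 8)) > 0.8).astype(np.float32)

        def loss_value():
            sl, hl = model.forward(x)
            return total_loss([sigmoid(h) for h in hl], m, sigmoid(sl), g).total_loss

        sl, hl = model.forward(x)
        sp, hp = sigmoid(sl), [sigmoid(h) for h in hl]
        model.zero_grad()
        model.backward((sp - g) / sp.size, [(p - m) / p.size for p in hp])
        pairs = model.params()
        for pi in range(0, len(pairs), 5):
            param, grad = pairs[pi]
            flat, gflat = param.reshape(-1), grad.reshape(-1)
            for j in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                eps = 1e-3
                old = flat[j]
                flat[j] = old + eps
                lp = loss_value()
                flat[j] = old - eps
                lm = loss_value()
                flat[j] = old
                numeric = (lp - lm) / (2 * eps)
                analytic = gflat[j]
                assert abs(numeric - analytic) <= 1e-3 * max(1.0, abs(numeric))

    def test_single_adam_step_decreases_loss(self, rng):
        from boundaryseg.nn.layers import Adam

        model = build_model(tiny_cfg(), seed=1)
        x = rng.random((1, 1, 8, 8)).astype(np.float32)
        g = (rng.random((1, 1, 8, 8)) > 0.5).astype(np.float32)
        m = (rng.random((1, 1, 8, 8)) > 0.8).astype(np.float32)
        opt = Adam(model.params(), lr=1e-3)

        def loss_value():
            sl, hl = model.forward(x)
            return total_loss([sigmoid(h) for h in hl], m, sigmoid(sl), g).total_loss

        before = loss_value()
        sl, hl = model.forward(x)
        sp, hp = sigmoid(sl), [sigmoid(h) for h in hl]
        model.zero_grad()
        model.backward((sp - g) / sp.size, [(p - m) / p.size for p in hp])
        opt.step()
        assert loss_value() < before


# ---------------------------------------------------------------- training loop


class TestTraining:
    def test_single_epoch_history(self, rng):
        data = tiny_batch(rng, n=4)
        model = build_model(tiny_cfg())
        result = train(model, data, TrainingConfig(max_epochs=1, batch_size=2))
        assert len(result.history) == 1

    def test_empty_dataset_rejected(self):
        model = build_model(tiny_cfg())
        with pytest.raises(DataError):
            train(model, {"images": np.empty((0, 8, 8)), "masks": np.empty((0, 8, 8)),
                          "maps": np.empty((0, 8, 8))}, TrainingConfig(max_epochs=1))

    def test_best_checkpoint_restored(self, rng):
        data = tiny_batch(rng, n=6)
        val = tiny_batch(rng, n=2)
        model = build_model(tiny_cfg())
        result = train(model, data, TrainingConfig(max_epochs=5, batch_size=2), val_data=val)
        best = min(r.val_total_loss for r in result.history)
        assert result.best_val_loss == pytest.approx(best)
        assert evaluate_loss(model, val).total_loss == pytest.approx(best, rel=1e-6)

    def test_training_is_seed_deterministic(self, rng):
        data = tiny_batch(rng, n=4)
        h1 = train(build_model(tiny_cfg(), seed=2), data,
                   TrainingConfig(max_epochs=3, batch_size=2, seed=5)).history
        h2 = train(build_model(tiny_cfg(), seed=2), data,
                   TrainingConfig(max_epochs=3, batch_size=2, seed=5)).history
        assert [r.total_loss for r in h1] == [r.total_loss for r in h2]

    def test_supervision_variants_share_seg_loss(self, rng):
        """Swapping the gt map on a fixed batch leaves the segmentation term unchanged."""
        model = build_model(tiny_cfg())
        x = rng.random((2, 1, 8, 8))
        g = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)
        map_a = (rng.random((2, 1, 8, 8)) > 0.8).astype(float)
        map_b = (rng.random((2, 1, 8, 8)) > 0.6).astype(float)
        sl, hl = model.forward(x)
        hp = [sigmoid(h) for h in hl]
        ba = total_loss(hp, map_a, sigmoid(sl), g)
        bb = total_loss(hp, map_b, sigmoid(sl), g)
        assert ba.seg_loss == bb.seg_loss

    def test_divergence_reports_epoch(self, rng):
        data = tiny_batch(rng, n=2)
        model = build_model(tiny_cfg())
        model.final.b[...] = np.nan  # poisons the segmentation logits
        with pytest.raises(TrainingError) as exc:
            train(model, data, TrainingConfig(max_epochs=2, batch_size=2))
        assert exc.value.epoch == 1


class TestPredictAndFolds:
    def test_threshold_semantics(self, rng):
        model = build_model(tiny_cfg())
        img = rng.random((8, 8))
        # zero-init final conv -> probability exactly 0.5 everywhere
        assert predict(model, img, threshold=0.5).sum() == 0
        assert predict(model, img, threshold=0.4).sum() == 64

    def test_kfold_partition(self):
        folds = kfold_split(100, 10, seed=1)
        assert len(folds) == 10
        all_test = np.concatenate([t for _, t in folds])
        assert len(all_test) == 100
        assert len(np.unique(all_test)) == 100
        for train_idx, test_idx in folds:
            assert len(test_idx) == 10
            assert np.intersect1d(train_idx, test_idx).size == 0

    def test_kfold_needs_at_least_two_folds(self):
        with pytest.raises(DataError):
            kfold_split(10, 1, seed=0)
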