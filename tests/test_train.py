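"""Dataset splitting, weighted cross-entropy, and the optimization loop."""

import numpy as np
import pytest

from octseg.nn import Tensor, build_model, ModelConfig, AttentionConfig
from octseg.nn.optim import clip_grad_norm
from octseg.train import (TrainConfig, UNetSegmenter, split_dataset, train,
                          evaluate, weighted_ce_loss, save_checkpoint,
                          load_checkpoint)


class TestSplit:
    def test_exact_ratios_n10(self):
        tr, va, te = split_dataset(list(range(10)), (8, 1, 1), seed=0)
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_floor_remainder_rule_n2176(self):
        tr, va, te = split_dataset(list(range(2176)), (8, 1, 1), seed=0)
        assert (len(tr), len(va), len(te)) == (1742, 217, 217)

    def test_deterministic_and_exhaustive(self):
        a = split_dataset(list(range(37)), seed=5)
        b = split_dataset(list(range(37)), seed=5)
        assert a == b
        merged = sorted(a[0] + a[1] + a[2])
        assert merged == list(range(37))

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2])


class TestWeightedCE:
    def test_saturated_logits_near_zero_loss(self):
        y = np.array([[0, 1], [1, 0]])
        logits = np.zeros((2, 2, 2), np.float32)
        logits[0] = np.where(y == 0, 50.0, -50.0)
        logits[1] = np.where(y == 1, 50.0, -50.0)
        assert float(weighted_ce_loss(logits, y).data) < 1e-3

    def test_uniform_logits_closed_form(self):
        # half the pixels per class, weights (1.0, 1.5) -> 1.25 * log 2
        y = np.array([[0, 1], [0, 1]])
        logits = np.zeros((2, 2, 2), np.float32)
        loss = float(weighted_ce_loss(logits, y, (1.0, 1.5)).data)
        assert loss == pytest.approx(1.25 * np.log(2), rel=1e-6)

    def test_linear_in_weights(self, rng):
        y = (rng.random((4, 4)) < 0.5).astype(int)
        logits = rng.standard_normal((2, 4, 4)).astype(np.float32)
        l1 = float(weighted_ce_loss(logits, y, (1.0, 1.5)).data)
        l2 = float(weighted_ce_loss(logits, y, (2.0, 3.0)).data)
        assert l2 == pytest.approx(2 * l1, rel=1e-5)

    def test_pixel_permutation_invariance(self, rng):
        y = (rng.random((4, 4)) < 0.5).astype(int)
        logits = rng.standard_normal((2, 4, 4)).astype(np.float32)
        perm = rng.permutation(16)
        y_p = y.ravel()[perm].reshape(4, 4)
        logits_p = logits.reshape(2, -1)[:, perm].reshape(2, 4, 4)
        a = float(weighted_ce_loss(logits, y).data)
        b = float(weighted_ce_loss(logits_p, y_p).data)
        assert a == pytest.approx(b, rel=1e-6)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            weighted_ce_loss(np.zeros((2, 2, 2), np.float32),
                             np.full((2, 2), 3))


def _phantom_items(n, seed):
    from octseg.phantom import benchmark_set, PhantomSpec
    pairs = benchmark_set(n, PhantomSpec(height=32, width=32,
                                         lesion_center=(0, 18, 16),
                                         lesion_radii=(0, 5, 6)), seed=seed)
    return [(p.images.slices[0].pixels, p.truth.slices[0].labels)
            for p in pairs]


def _tiny_model(seed=0):
    return build_model(ModelConfig(base_width=8, depth=2,
                                   attention=AttentionConfig(mode="none")),
                       seed=seed)


class TestTrainLoop:
    def test_history_bookkeeping_one_epoch(self):
        items = _phantom_items(6, 0)
        cfg = TrainConfig(epochs=1, batch_size=2, seed=0)
        _, hist = train(_tiny_model(), (items[:4], items[4:], []), cfg)
        assert len(hist) == 1
        assert len(hist.val_dice) == 1

    def test_two_runs_identical(self):
        items = _phantom_items(6, 1)
        cfg = TrainConfig(epochs=2, batch_size=2, seed=3)
        m1, h1 = train(_tiny_model(7), (items[:4], items[4:], []), cfg)
        m2, h2 = train(_tiny_model(7), (items[:4], items[4:], []), cfg)
        assert h1.train_loss == h2.train_loss
        for (k1, v1), (k2, v2) in zip(sorted(m1.state_dict().items()),
                                      sorted(m2.state_dict().items())):
            assert k1 == k2 and np.array_equal(v1, v2)

    def test_loss_decreases_on_small_set(self):
        items = _phantom_items(8, 2)
        cfg = TrainConfig(epochs=8, batch_size=4, lr=1e-3, seed=0)
        _, hist = train(_tiny_model(), (items[:6], items[6:], []), cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(_tiny_model(), ([], [], []), TrainConfig(epochs=1))

    def test_gradient_clipping_bounds_norm(self, rng):
        model = _tiny_model()
        x = Tensor(rng.standard_normal((2, 1, 16, 16)).astype(np.float32))
        y = (rng.random((2, 16, 16)) < 0.5).astype(int)
        loss = weighted_ce_loss(model(x), y) * 1e4  # inflate gradients
        loss.backward()
        params = model.parameters()
        pre = clip_grad_norm(params, max_norm=1.0)
        assert pre > 1.0
        post = float(np.sqrt(sum(float((p.grad ** 2).sum())
                                 for p in params if p.grad is not None)))
        assert post <= 1.0 + 1e-6


class TestEvaluate:
    def test_perfect_and_complement_predictions(self):
        from octseg.metrics import pooled_confusion, report_from_confusion
        masks = [np.array([[1, 0], [0, 1]]), np.array([[0, 1], [1, 0]])]
        rep = report_from_confusion(pooled_confusion(masks, masks))
        assert (rep.dice, rep.miou, rep.mpa, rep.accuracy) == (1.0, 100.0,
                                                               100.0, 100.0)
        comp = [1 - m for m in masks]
        rep2 = report_from_confusion(pooled_confusion(comp, masks))
        assert rep2.dice == 0.0

    def test_evaluate_matches_per_image_oracle(self):
        items = _phantom_items(4, 3)
        model = _tiny_model()
        res = evaluate(model, items)
        from octseg.metrics import confusion, dice, pooled_confusion
        preds = [np.argmax(model(Tensor(i[None, None])).data[0], axis=0)
                 for i, _ in items]
        cm = pooled_confusion(preds, [m for _, m in items])
        assert res["pooled"].dice == pytest.approx(dice(cm))


class TestSegmenterEstimator:
    def test_sklearn_param_round_trip(self):
        est = UNetSegmenter(variant="tandem", base_width=8, depth=2)
        params = est.get_params()
        est2 = UNetSegmenter(**params)
        assert est2.get_params() == params

    def test_fit_predict_shapes_and_checkpoint(self, tmp_path):
        items = _phantom_items(8, 4)
        X = np.stack([i for i, _ in items])
        y = np.stack([m for _, m in items])
        est = UNetSegmenter(variant="unet", base_width=8, depth=2, epochs=2,
                            lr=1e-3, seed=0)
        est.fit(X[:6], y[:6], validation_data=(X[6:], y[6:]))
        pred = est.predict(X[:2])
        assert pred.shape == (2, 32, 32)
        assert set(np.unique(pred)) <= {0, 1}
        ckpt = tmp_path / "model.npz"
        save_checkpoint(ckpt, est.model_, est.model_config_)
        model2, cfg2 = load_checkpoint(ckpt)
        model2.eval()
        est.model_.eval()
        xb = Tensor(X[:2][:, None])
        assert np.array_equal(model2(xb).data, est.model_(xb).data)

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            UNetSegmenter().predict(np.zeros((1, 16, 16)))

    def test_predict_stack_empty_and_identical(self):
        from octseg.io import ImageStack, BScanImage
        items = _phantom_items(6, 5)
        X = np.stack([i for i, _ in items])
        y = np.stack([m for _, m in items])
        est = UNetSegmenter(variant="unet", base_width=8, depth=2, epochs=1,
                            seed=0)
        est.fit(X[:4], y[:4])
        assert len(est.predict_stack(ImageStack([]))) == 0
        stack = ImageStack([BScanImage(X[0])] * 3)
        masks = est.predict_stack(stack)
        arrs = masks.as_array()
        assert len(masks) == 3
        assert np.array_equal(arrs[0], arrs[1]) and np.array_equal(arrs[1],
                                                                   arrs[2])
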