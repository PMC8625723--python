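"""Semi-supervised EM trainer: E-step, objective reductions, fit loop."""

import numpy as np
import pytest

from sonarseg.model import CrfSegmenter
from sonarseg.training import (
    AnnotationImage,
    Responsibilities,
    TrainingConfig,
    e_step,
    em_objective,
    fit,
)
from sonarseg.unary import FrameStack

from conftest import small_unary_config


def make_stack(rng, shape=(6, 6)):
    return FrameStack(rng.random(shape + (3,)))


def full_annotation(rng, shape=(6, 6), num_labels=2):
    return AnnotationImage(rng.integers(1, num_labels + 1, shape))


class TestAnnotationImage:
    def test_labeled_mask_and_onehot(self):
        ann = AnnotationImage(np.array([[0, 1], [2, 0]]))
        assert ann.labeled_mask.tolist() == [[False, True], [True, False]]
        h = ann.onehot(2)
        assert h[0, 1].tolist() == [1.0, 0.0]
        assert h[1, 0].tolist() == [0.0, 1.0]
        assert np.all(h[0, 0] == 0.0)

    def test_code_range_checked(self):
        with pytest.raises(ValueError):
            AnnotationImage(np.array([[3]])).onehot(2)
        with pytest.raises(ValueError):
            AnnotationImage(np.array([[-1]]))


class TestEStep:
    def test_fully_labeled_ignores_model(self, tiny_model, rng):
        x = make_stack(rng)
        ann = full_annotation(rng)
        resp = e_step(tiny_model, x, ann)
        assert np.array_equal(resp.h, ann.onehot(2))

    def test_fully_unlabeled_returns_model_posterior(self, tiny_model, rng):
        x = make_stack(rng)
        ann = AnnotationImage(np.zeros((6, 6), dtype=int))
        resp = e_step(tiny_model, x, ann)
        assert np.allclose(resp.h, tiny_model.predict(x).q)

    def test_mixed_rows_partition_by_labeled_set(self, tiny_model, rng):
        x = make_stack(rng)
        labels = rng.integers(0, 3, (6, 6))
        ann = AnnotationImage(labels)
        resp = e_step(tiny_model, x, ann)
        q = tiny_model.predict(x).q
        onehot = ann.onehot(2)
        mask = ann.labeled_mask
        assert np.array_equal(resp.h[mask], onehot[mask])
        assert np.allclose(resp.h[~mask], q[~mask])

    def test_shape_mismatch_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError):
            e_step(tiny_model, make_stack(rng, (6, 6)),
                   AnnotationImage(np.ones((4, 4), dtype=int)))

    def test_responsibility_rows_normalized(self, tiny_model, rng):
        for _ in range(10):
            x = make_stack(rng)
            ann = AnnotationImage(rng.integers(0, 3, (6, 6)))
            resp = e_step(tiny_model, x, ann)
            assert np.allclose(resp.h.sum(axis=-1), 1.0, atol=1e-6)

    def test_unnormalized_responsibilities_rejected(self):
        with pytest.raises(ValueError):
            Responsibilities(h=np.full((2, 2, 2), 0.7))


class TestEmObjective:
    def test_fully_labeled_equals_negative_cross_entropy(self, tiny_model, rng):
        x = make_stack(rng)
        ann = full_annotation(rng)
        resp = e_step(tiny_model, x, ann)
        pi = em_objective(tiny_model, x, resp, ann, C=1.0)
        q = tiny_model.predict(x).q
        idx = ann.class_indices()
        iy, ix = np.meshgrid(range(6), range(6), indexing="ij")
        ce = -np.log(q[iy, ix, idx]).sum()
        assert pi == pytest.approx(-ce, abs=1e-9)

    def test_labeled_weight_scales_labeled_term(self, tiny_model, rng):
        x = make_stack(rng)
        ann = full_annotation(rng)
        resp = e_step(tiny_model, x, ann)
        pi1 = em_objective(tiny_model, x, resp, ann, C=1.0)
        pi3 = em_objective(tiny_model, x, resp, ann, C=3.0)
        assert pi3 == pytest.approx(3.0 * pi1, rel=1e-12)

    def test_never_positive(self, tiny_model, rng):
        for _ in range(5):
            x = make_stack(rng)
            ann = AnnotationImage(rng.integers(0, 3, (6, 6)))
            resp = e_step(tiny_model, x, ann)
            assert em_objective(tiny_model, x, resp, ann) <= 0.0

    def test_tiny_fixture_against_double_sum_oracle(self, tiny_model, rng):
        x = make_stack(rng, (2, 2))
        ann = AnnotationImage(np.array([[1, 0], [2, 0]]))
        resp = e_step(tiny_model, x, ann)
        pi = em_objective(tiny_model, x, resp, ann, C=1.0)
        q = tiny_model.predict(x).q
        ref = 0.0
        for i in range(2):
            for j in range(2):
                for u in range(2):
                    ref += resp.h[i, j, u] * np.log(max(q[i, j, u], 1e-8))
        assert pi == pytest.approx(ref, abs=1e-9)


class TestFit:
    def tiny_dataset(self, rng, n=2, shape=(8, 8)):
        out = []
        for _ in range(n):
            frames = np.clip(
                0.2 + 0.05 * rng.standard_normal(shape + (3,)), 0, 1
            )
            labels = np.zeros(shape, dtype=int)
            labels[2:4, 2:4] = 2
            labels[5:7, 5:7] = 1
            frames[2:4, 2:4, :] = np.clip(
                0.7 + 0.05 * rng.standard_normal((2, 2, 3)), 0, 1
            )
            out.append((FrameStack(frames), AnnotationImage(labels)))
        return out

    def test_same_seed_same_final_loss(self, rng):
        dataset = self.tiny_dataset(rng)
        losses = []
        for _ in range(2):
            model = CrfSegmenter(small_unary_config(), mf_iterations=2,
                                 sim_hidden=4, seed=3)
            cfg = TrainingConfig(epochs=3, seed=11)
            _, hist = fit(model, dataset, cfg)
            losses.append(hist[-1]["loss"])
        assert losses[0] == losses[1]

    def test_full_batch_descent_loss_non_increasing(self, rng):
        dataset = self.tiny_dataset(rng)
        model = CrfSegmenter(small_unary_config(dropout=0.0), mf_iterations=2,
                             sim_hidden=4, seed=5)
        cfg = TrainingConfig(learning_rate=1e-2, momentum=0.0,
                             batch_size=len(dataset), epochs=20, seed=1)
        _, hist = fit(model, dataset, cfg)
        losses = [h["loss"] for h in hist]
        assert all(b <= a + 1e-10 for a, b in zip(losses, losses[1:]))

    def test_compatibility_nonnegative_after_training(self, rng):
        dataset = self.tiny_dataset(rng)
        model = CrfSegmenter(small_unary_config(), mf_iterations=2,
                             sim_hidden=4, seed=2)
        _, _ = fit(model, dataset, TrainingConfig(epochs=3, learning_rate=0.5,
                                                  seed=0))
        assert np.all(model.compat.c.data >= 0.0)

    def test_empty_dataset_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            fit(tiny_model, [], TrainingConfig())

    def test_recovers_bright_fish_on_heldout_pixels(self):
        """Fish ~N(0.7, s) on background ~N(0.2, s): after training, held-out
        labeled pixels are classified with > 0.9 accuracy."""
        rng = np.random.default_rng(42)
        dataset, heldout = [], []
        for _ in range(3):
            shape = (24, 24)
            frames = np.clip(0.2 + 0.05 * rng.standard_normal(shape + (3,)), 0, 1)
            truth = np.zeros(shape, dtype=int)
            for _ in range(3):
                cy, cx = rng.integers(4, 20, 2)
                yy, xx = np.ogrid[:24, :24]
                m = ((yy - cy) ** 2 / 9 + (xx - cx) ** 2 / 4) <= 1
                truth[m] = 1
                for f in range(3):
                    frames[:, :, f][m] = np.clip(
                        0.7 + 0.05 * rng.standard_normal(int(m.sum())), 0, 1
                    )
            labels = truth + 1  # fully known
            visible = rng.random(shape) < 0.5  # half annotated, half held out
            ann = AnnotationImage(np.where(visible, labels, 0))
            dataset.append((FrameStack(frames), ann))
            heldout.append((frames, truth, ~visible))
        model = CrfSegmenter(small_unary_config(), mf_iterations=3,
                             sim_hidden=4, seed=9)
        cfg = TrainingConfig(learning_rate=0.2, epochs=25, seed=4)
        model, _ = fit(model, dataset, cfg)
        correct = total = 0
        for frames, truth, held in heldout:
            pred = model.predict(FrameStack(frames)).label_map()
            correct += (pred[held] == truth[held]).sum()
            total += held.sum()
        assert correct / total > 0.9

    def test_trained_accuracy_reported_in_history(self, trained_binary):
        _, history, _ = trained_binary
        assert history[-1]["labeled_accuracy"] > 0.9
        assert all(np.isfinite(h["loss"]) for h in history)
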