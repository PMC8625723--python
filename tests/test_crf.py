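"""CRF layer: similarity, messages, mean-field updates, exact oracles."""

import numpy as np
import pytest

from sonarseg import autodiff as ad
from sonarseg.crf import (
    CompatibilityParams,
    MeanFieldState,
    NeighborhoodSpec,
    SimilarityMap,
    SimilarityNet,
    gibbs_energy,
    kl_divergence,
    meanfield_infer,
    meanfield_init,
    meanfield_step,
    meanfield_sweep_sequential,
    oracle_exact_posterior,
    pairwise_message,
    pairwise_similarity,
)
from sonarseg.unary import unary_potential

from oracles import (
    loop_gibbs_energy,
    loop_meanfield_step,
    loop_pairwise_message,
    random_instance,
)


@pytest.fixture
def spec():
    return NeighborhoodSpec()


def two_pixel_instance():
    """1 x 2 image, similarity 1 between the two pixels, c = identity."""
    spec = NeighborhoodSpec()
    q = np.array([[[0.8, 0.2], [0.3, 0.7]]])
    sim = np.zeros((1, 2, 8))
    sim[0, 0, spec.index_of((0, 1))] = 1.0
    sim[0, 1, spec.index_of((0, -1))] = 1.0
    return q, SimilarityMap(values=sim, spec=spec), np.eye(2)


class TestNeighborhood:
    def test_default_offsets(self, spec):
        assert len(spec.offsets) == 8
        assert (0, 0) not in spec.offsets
        assert sorted(spec.distances) == sorted([1.0] * 4 + [np.sqrt(2)] * 4)

    def test_rejects_bad_offsets(self):
        with pytest.raises(ValueError):
            NeighborhoodSpec(offsets=((0, 0),))
        with pytest.raises(ValueError):
            NeighborhoodSpec(offsets=((2, 0),))

    def test_unknown_offset_lookup(self, spec):
        with pytest.raises(ValueError):
            spec.index_of((2, 2))

    def test_valid_mask_boundary(self, spec):
        mask = spec.valid_mask((3, 3))
        # center pixel has all 8 neighbors, corner only 3
        assert mask[1, 1].sum() == 8
        assert mask[0, 0].sum() == 3


class TestSimilarity:
    def test_values_in_unit_interval_interior(self, spec, rng):
        net = SimilarityNet(4, hidden=4, spec=spec, seed=0)
        sim = pairwise_similarity(rng.random((6, 6, 4)), spec, net)
        interior = sim.values[1:-1, 1:-1]
        assert np.all(interior > 0) and np.all(interior < 1)

    def test_boundary_neighbors_zero(self, spec, rng):
        net = SimilarityNet(4, hidden=4, spec=spec, seed=0)
        sim = pairwise_similarity(rng.random((5, 5, 4)), spec, net)
        k = spec.index_of((-1, 0))  # northern neighbor: invalid on row 0
        assert np.all(sim.values[0, :, k] == 0.0)

    def test_zero_weights_give_quarter(self, spec, rng):
        net = SimilarityNet(4, hidden=4, spec=spec, seed=0)
        for p in net.parameters():
            p.data[...] = 0.0
        sim = pairwise_similarity(rng.random((6, 6, 4)), spec, net)
        assert np.allclose(sim.values[1:-1, 1:-1], 0.25)  # sigma(0)^2

    def test_trained_similarity_orders_feature_pairs(self, trained_binary):
        """After training on scenes with contrasting regions, neighbors with
        near-identical features look more similar than cross-edge pairs."""
        model, _, dataset = trained_binary
        x, _ = dataset[0]
        _, feats = model.unary.forward_t(x.frames)
        sim = model.similarity.compute_t(feats).data
        f = feats.data
        k_e = model.spec.index_of((0, 1))
        diff = np.linalg.norm(f - np.roll(f, -1, axis=1), axis=-1)[:, :-1]
        s = sim[:, :-1, k_e]
        lo, hi = np.quantile(diff, [0.1, 0.9])
        assert s[diff <= lo].mean() > s[diff >= hi].mean()


class TestPairwiseMessage:
    def test_zero_compatibility_zero_message(self, rng):
        psi, sim, _ = random_instance(rng)
        q = meanfield_init(psi).q
        msg = pairwise_message(q, sim, np.zeros((2, 2)))
        assert np.all(msg == 0.0)

    def test_two_pixel_hand_example(self):
        q, sim, c = two_pixel_instance()
        msg = pairwise_message(q, sim, c)
        assert np.allclose(msg[0, 0], [0.3, 0.7])
        assert np.allclose(msg[0, 1], [0.8, 0.2])

    @pytest.mark.parametrize("num_labels", [2, 5])
    def test_matches_loop_oracle(self, rng, num_labels):
        for trial in range(50):
            psi, sim, c = random_instance(rng, num_labels=num_labels)
            q = meanfield_init(psi).q
            vec = pairwise_message(q, sim, c)
            ref = loop_pairwise_message(q, sim.values, c, sim.spec.offsets)
            assert np.abs(vec - ref).max() < 1e-5


class TestMeanFieldUpdates:
    def test_init_uniform_potential(self):
        st = meanfield_init(np.full((3, 3, 2), 1.7))
        assert np.allclose(st.q, 0.5)
        assert st.t == 0

    def test_init_inverts_unary_potential(self, rng):
        p = rng.dirichlet(np.ones(2), size=(4, 4))
        st = meanfield_init(unary_potential(p, eps=1e-300))
        assert np.allclose(st.q, p, atol=1e-12)

    def test_init_normalized_many_draws(self, rng):
        for _ in range(100):
            st = meanfield_init(rng.uniform(-5, 5, (5, 5, 3)))
            assert np.allclose(st.q.sum(axis=-1), 1.0, atol=1e-6)

    def test_zero_compatibility_is_stationary(self, rng):
        psi, sim, _ = random_instance(rng)
        c0 = np.zeros((2, 2))
        st = meanfield_init(psi)
        for _ in range(3):
            st = meanfield_step(st, psi, sim, c0)
        assert np.allclose(st.q, meanfield_init(psi).q, atol=1e-12)

    def test_two_pixel_hand_update(self):
        q, sim, c = two_pixel_instance()
        psi = np.full((1, 2, 2), 0.5)
        st = meanfield_step(MeanFieldState(q=q), psi, sim, c)
        e0 = np.exp(-(psi[0, 0] + np.array([0.3, 0.7])))
        e1 = np.exp(-(psi[0, 1] + np.array([0.8, 0.2])))
        assert np.allclose(st.q[0, 0], e0 / e0.sum())
        assert np.allclose(st.q[0, 1], e1 / e1.sum())
        assert st.t == 1

    @pytest.mark.parametrize("num_labels", [2, 5])
    def test_step_matches_loop_oracle(self, rng, num_labels):
        for trial in range(50):
            psi, sim, c = random_instance(rng, (8, 8), num_labels)
            st = meanfield_init(psi)
            vec = meanfield_step(st, psi, sim, c)
            ref = loop_meanfield_step(st.q, psi, sim.values, c, sim.spec.offsets)
            assert np.abs(vec.q - ref).max() < 1e-5

    def test_converged_state_is_fixed_point(self, rng):
        psi, sim, c = random_instance(rng, (4, 4), coupling=0.3)
        st = meanfield_init(psi)
        for _ in range(300):
            st = meanfield_step(st, psi, sim, c)
        nxt = meanfield_step(st, psi, sim, c)
        assert np.abs(nxt.q - st.q).max() < 1e-6

    def test_infer_zero_iterations_equals_init(self, rng):
        psi, sim, c = random_instance(rng)
        assert np.array_equal(meanfield_infer(psi, sim, c, 0).q, meanfield_init(psi).q)

    def test_infer_composes_steps(self, rng):
        psi, sim, c = random_instance(rng)
        st = meanfield_init(psi)
        for _ in range(5):
            st = meanfield_step(st, psi, sim, c)
        assert np.allclose(meanfield_infer(psi, sim, c, 5).q, st.q, atol=1e-12)

    def test_infer_normalized(self, rng):
        for _ in range(20):
            psi, sim, c = random_instance(rng, (6, 6), num_labels=5)
            st = meanfield_infer(psi, sim, c, 5)
            assert np.allclose(st.q.sum(axis=-1), 1.0, atol=1e-6)

    def test_gradient_wrt_compatibility_matches_finite_differences(self, rng):
        from sonarseg.crf import _infer_t

        psi, sim, c = random_instance(rng, (4, 4), coupling=0.5)
        target = rng.dirichlet(np.ones(2), size=(4, 4))

        def loss_for(cval):
            ct = ad.parameter(cval)
            q = _infer_t(ad.Tensor(psi), ad.Tensor(sim.values), ct, sim.spec, 3)
            d = ad.sub(q, ad.Tensor(target))
            return ad.tsum(ad.mul(d, d)), ct

        loss, ct = loss_for(c)
        loss.backward()
        assert np.all(np.isfinite(ct.grad))
        eps = 1e-5
        for idx in np.ndindex(2, 2):
            cp, cm = c.copy(), c.copy()
            cp[idx] += eps
            cm[idx] -= eps
            num = (float(loss_for(cp)[0].data) - float(loss_for(cm)[0].data)) / (2 * eps)
            assert abs(ct.grad[idx] - num) <= 1e-3 * max(1.0, abs(num))


class TestGibbsEnergy:
    def test_single_pixel_energy_is_unary(self, spec):
        psi = np.array([[[0.4, 1.2]]])
        sim = SimilarityMap(values=np.ones((1, 1, 8)), spec=spec)
        assert gibbs_energy(np.array([[1]]), psi, sim, np.eye(2)) == pytest.approx(1.2)

    def test_zero_compatibility_energy_is_unary_sum(self, rng):
        psi, sim, _ = random_instance(rng, (4, 4))
        y = rng.integers(0, 2, (4, 4))
        iy, ix = np.meshgrid(range(4), range(4), indexing="ij")
        assert gibbs_energy(y, psi, sim, np.zeros((2, 2))) == pytest.approx(
            psi[iy, ix, y].sum()
        )

    def test_matches_summation_oracle(self, rng):
        for _ in range(10):
            psi, sim, c = random_instance(rng, (2, 2))
            y = rng.integers(0, 2, (2, 2))
            assert gibbs_energy(y, psi, sim, c) == pytest.approx(
                loop_gibbs_energy(y, psi, sim.values, c, sim.spec.offsets)
            )


class TestExactPosterior:
    def test_probabilities_sum_to_one(self, rng):
        psi, sim, c = random_instance(rng, (2, 3))
        ex = oracle_exact_posterior(psi, sim, c)
        assert ex.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert ex.configs.shape == (64, 6)

    def test_zero_coupling_marginals_are_unary(self, rng):
        psi, sim, _ = random_instance(rng, (2, 3))
        ex = oracle_exact_posterior(psi, sim, np.zeros((2, 2)))
        expected = meanfield_init(psi).q
        assert np.abs(ex.marginals - expected).max() < 1e-9

    def test_instance_size_guard(self, spec):
        psi = np.zeros((8, 8, 5))
        sim = SimilarityMap(values=np.zeros((8, 8, 8)), spec=spec)
        with pytest.raises(ValueError):
            oracle_exact_posterior(psi, sim, np.zeros((5, 5)))

    def test_meanfield_kl_finite(self, rng):
        psi, sim, c = random_instance(rng, (2, 3), coupling=0.3)
        ex = oracle_exact_posterior(psi, sim, c)
        kl = kl_divergence(meanfield_infer(psi, sim, c, 5), ex)
        assert np.isfinite(kl)


class TestKLDivergence:
    def test_zero_for_factorized_target(self, rng):
        psi, sim, _ = random_instance(rng, (2, 2))
        c0 = np.zeros((2, 2))
        ex = oracle_exact_posterior(psi, sim, c0)
        st = MeanFieldState(q=ex.marginals)
        assert kl_divergence(st, ex) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(10):
            psi, sim, c = random_instance(rng, (2, 2), coupling=0.5)
            ex = oracle_exact_posterior(psi, sim, c)
            q = rng.dirichlet(np.ones(2), size=(2, 2))
            assert kl_divergence(MeanFieldState(q=q), ex) >= -1e-12

    def test_sequential_sweeps_decrease_kl(self, rng):
        """Coordinate-ascent mean-field monotonically lowers KL(Q||P)."""
        for trial in range(3):
            psi, sim, c = random_instance(rng, (2, 3), coupling=0.3)
            ex = oracle_exact_posterior(psi, sim, c)
            st = meanfield_init(psi)
            kls = [kl_divergence(st, ex)]
            for _ in range(10):
                st = meanfield_sweep_sequential(st, psi, sim, c)
                kls.append(kl_divergence(st, ex))
            assert all(b <= a + 1e-10 for a, b in zip(kls, kls[1:]))


class TestCompatibilityParams:
    def test_rejects_negative_init(self):
        with pytest.raises(ValueError):
            CompatibilityParams(2, init=np.array([[0.0, -0.1], [0.1, 0.0]]))

    def test_projection_restores_nonnegativity(self):
        cp = CompatibilityParams(2)
        cp.c.data[0, 1] = -0.3
        cp.project()
        assert np.all(cp.c.data >= 0.0)
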