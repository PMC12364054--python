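"""Degree-family centrality measures and their equivalence partners."""

import numpy as np
import pytest

from uninet.core import Network, Partition, UninetError, validate_network
from uninet.centrality import (
    average_controllability,
    coefficient_of_variation_sq,
    communicability_centrality,
    degree,
    diffusion_efficiency,
    eigenvector_centrality,
    mean_first_passage_time,
    modal_controllability,
    participation,
    rescale_spectral,
    second_degree,
)
from uninet.synth import synth_structural


@pytest.fixture(scope="module")
def rescaled(structural_network):
    return rescale_spectral(structural_network)


class TestDegrees:
    def test_binary_network_second_degree_equals_degree(self, two_cliques):
        np.testing.assert_array_equal(
            second_degree(two_cliques), degree(two_cliques)
        )

    def test_constant_weight_scaling(self):
        W = validate_network(0.5 * (np.ones((4, 4)) - np.eye(4)), "structural")
        np.testing.assert_allclose(second_degree(W), 0.5 * degree(W))

    def test_elementwise_oracle(self, structural_network):
        W = structural_network.weights
        np.testing.assert_allclose(degree(structural_network), W.sum(1))
        np.testing.assert_allclose(second_degree(structural_network), (W**2).sum(1))


class TestEigenvectorCentrality:
    def test_regular_graph_constant(self):
        n = 6
        ring = np.roll(np.eye(n), 1, axis=1) + np.roll(np.eye(n), -1, axis=1)
        v = eigenvector_centrality(validate_network(ring, "structural"))
        np.testing.assert_allclose(v, v[0], atol=1e-10)

    def test_star_graph_hub_maximal(self):
        W = np.zeros((6, 6))
        W[0, 1:] = W[1:, 0] = 1.0
        v = eigenvector_centrality(validate_network(W, "structural"))
        assert v[0] > v[1:].max()

    def test_power_iteration_agrees(self, structural_network):
        v = eigenvector_centrality(structural_network)
        x = np.ones(structural_network.n)
        for _ in range(500):
            x = structural_network.weights @ x
            x /= np.linalg.norm(x)
        np.testing.assert_allclose(v, x, atol=1e-8)

    def test_tracks_degree_on_dense_networks(self, structural_network):
        r = np.corrcoef(
            eigenvector_centrality(structural_network), degree(structural_network)
        )[0, 1]
        assert r > 0.85

    def test_disconnected_rejected(self, two_cliques):
        with pytest.raises(UninetError):
            eigenvector_centrality(two_cliques)


class TestMeanFirstPassageTime:
    def test_two_node_single_step(self):
        W = validate_network(np.array([[0.0, 1.0], [1.0, 0.0]]), "structural")
        np.testing.assert_allclose(
            mean_first_passage_time(W), [[0.0, 1.0], [1.0, 0.0]]
        )

    def test_monte_carlo_oracle_small_graphs(self):
        rng = np.random.default_rng(1)
        for n in (3, 5, 6):
            W = rng.uniform(0.2, 1.0, size=(n, n))
            W = 0.5 * (W + W.T)
            np.fill_diagonal(W, 0.0)
            net = validate_network(W, "structural")
            mfpt = mean_first_passage_time(net)
            cum = (W / W.sum(axis=1, keepdims=True)).cumsum(axis=1)
            walks = 60_000
            sim = np.zeros((n, n))
            for src in range(n):
                pos = np.full(walks, src)
                reached = np.zeros((walks, n), bool)
                reached[:, src] = True
                times = np.zeros((walks, n))
                for step in range(1, 600):
                    pos = (rng.random(walks)[:, None] > cum[pos]).sum(axis=1)
                    newly = ~reached[np.arange(walks), pos]
                    times[newly, pos[newly]] = step
                    reached[np.arange(walks), pos] = True
                    if reached.all():
                        break
                sim[src] = times.mean(axis=0)
            off = ~np.eye(n, dtype=bool)
            rel = np.abs(sim - mfpt)[off] / mfpt[off]
            assert rel.max() < 0.02

    def test_degree_inverse_approximation(self, structural_network):
        mfpt = mean_first_passage_time(structural_network)
        off = ~np.eye(structural_network.n, dtype=bool)
        inv = np.zeros_like(mfpt)
        inv[off] = 1.0 / mfpt[off]
        col_means = inv.sum(axis=0) / (structural_network.n - 1)
        assert np.corrcoef(col_means, degree(structural_network))[0, 1] > 0.9


class TestDiffusionEfficiency:
    def test_symmetric_two_node(self):
        W = validate_network(np.array([[0.0, 0.7], [0.7, 0.0]]), "structural")
        de = diffusion_efficiency(W)
        assert de[0] == pytest.approx(de[1])

    def test_tracks_degree(self, structural_network):
        r = np.corrcoef(
            diffusion_efficiency(structural_network), degree(structural_network)
        )[0, 1]
        assert r > 0.9

    def test_invariant_to_uniform_rescaling(self, structural_network):
        a = diffusion_efficiency(structural_network)
        b = diffusion_efficiency(Network(structural_network.weights * 3.7))
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestCommunicability:
    def test_empty_network_ones(self):
        W = Network(np.zeros((4, 4)))
        np.testing.assert_allclose(communicability_centrality(W), 1.0)

    def test_tracks_second_degree(self, rescaled):
        r = np.corrcoef(
            communicability_centrality(rescaled), second_degree(rescaled)
        )[0, 1]
        assert r > 0.99

    def test_truncation_error_third_order(self, rescaled):
        full = communicability_centrality(rescaled)
        trunc = communicability_centrality(rescaled, truncated=True)
        W3 = np.linalg.matrix_power(rescaled.weights, 3)
        bound = np.abs(np.diagonal(W3)) / 6.0 * 2.0  # remainder ~ W^3/6
        assert np.abs(full - trunc).max() < max(bound.max(), 1e-3) * 5


class TestControllability:
    def test_gramian_closed_form_matches_series(self, rescaled):
        g = average_controllability(rescaled)  # default gamma = 2
        A = rescaled.weights / 2.0
        acc = np.eye(rescaled.n)
        P = np.eye(rescaled.n)
        for _ in range(50):
            P = P @ A @ A
            acc += P
        np.testing.assert_allclose(g, np.diagonal(acc), atol=1e-10)

    def test_empty_network_identity_gramian(self):
        W = Network(np.zeros((4, 4)))
        np.testing.assert_allclose(average_controllability(W), 1.0)

    def test_gamma_not_above_spectral_radius_rejected(self, rescaled):
        with pytest.raises(UninetError):
            average_controllability(rescaled, gamma=0.9)

    def test_modal_two_node_unit_network(self):
        W = rescale_spectral(
            validate_network(np.array([[0.0, 1.0], [1.0, 0.0]]), "structural")
        )
        np.testing.assert_allclose(modal_controllability(W), 0.0, atol=1e-12)

    def test_modal_empty_network_ones(self):
        np.testing.assert_allclose(
            modal_controllability(Network(np.zeros((5, 5)))), 1.0
        )

    def test_modal_exactly_complements_second_degree(self, rescaled):
        np.testing.assert_allclose(
            modal_controllability(rescaled) + second_degree(rescaled),
            1.0,
            atol=1e-10,
        )


class TestParticipationAndCV:
    def test_all_links_one_module(self, two_cliques):
        P = Partition(np.array([0, 0, 1, 1]), 2)
        np.testing.assert_allclose(participation(two_cliques, P), 0.0, atol=1e-12)

    def test_equal_split_closed_form(self):
        n, k = 12, 3
        W = validate_network(np.ones((n, n)) - np.eye(n), "structural")
        P = Partition(np.arange(n) % k, k)
        # near-equal split: s_ih/s_i ~ 1/k, participation ~ 1 - 1/k
        np.testing.assert_allclose(
            participation(W, P), 1.0 - 1.0 / k, atol=0.02
        )

    def test_constant_weights_zero_cv(self):
        W = Network(np.full((5, 5), 0.3))
        np.testing.assert_allclose(coefficient_of_variation_sq(W), 0.0, atol=1e-12)

    def test_cv_tracks_k_participation_with_resolution(self):
        from uninet.core import correlation_network
        from uninet.loyvain import LoyvainConfig, loyvain
        from uninet.neighbor_gradients import co_neighbor
        from uninet.synth import SynthSpec, synth_timeseries

        X, _ = synth_timeseries(SynthSpec(n=64, p=800, k=8, seed=11))
        S = co_neighbor(correlation_network(X), 10)
        cv2 = coefficient_of_variation_sq(S)
        corrs = []
        for k in (2, 4, 8):
            part = loyvain(S, LoyvainConfig(k=k, replicates=10, seed=1)).partition
            kp = participation(S, part, normalized=True)
            corrs.append(np.corrcoef(-cv2, kp)[0, 1])
        assert corrs[0] < corrs[1] < corrs[2]
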