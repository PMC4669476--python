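"""Spectra stacking, ALS-NMF and component-network reshaping."""

import numpy as np
import pytest

import musclenet as mn
from musclenet.errors import (DegenerateInputError, InvalidInputError,
                              InvalidParameterError)


def _spectra(n_channels, subjects, conditions, freqs, directed=False, seed=0):
    rng = np.random.default_rng(seed)
    pairs = (mn.directed_pairs(n_channels) if directed
             else mn.undirected_pairs(n_channels))
    out = []
    for s in subjects:
        for c in conditions:
            vals = rng.uniform(0, 0.9, (len(pairs), len(freqs)))
            out.append(mn.ConnectivitySpectra(
                values=vals, freqs=freqs, pairs=pairs, directed=directed,
                channel_labels=tuple(f"m{i}" for i in range(n_channels)),
                subject=s, condition=c))
    return out


class TestStackSpectra:
    def test_paper_scale_design_gives_3240_columns(self):
        freqs = np.arange(0.0, 61.0, 1.0)
        spectra = _spectra(10, range(18), ["a", "b", "c", "d"], freqs)
        stack = mn.stack_spectra(spectra)
        assert stack.V.shape == (61, 45 * 4 * 18)

    def test_directed_ten_channels_give_90_rows_per_cell(self):
        freqs = np.arange(0.0, 61.0, 1.0)
        stack = mn.stack_spectra(_spectra(10, [0], ["a"], freqs, directed=True))
        assert stack.V.shape[1] == 90

    def test_unstack_round_trip(self):
        freqs = np.arange(0.0, 31.0, 1.0)
        spectra = _spectra(4, [0, 1], ["a", "b"], freqs, seed=3)
        stack = mn.stack_spectra(spectra, band=(0, 30))
        back = mn.unstack_spectra(stack)
        assert len(back) == len(spectra)
        for orig, rec in zip(spectra, back):
            np.testing.assert_array_equal(orig.values, rec.values)
            assert (orig.subject, orig.condition) == (rec.subject, rec.condition)

    def test_band_restriction(self):
        freqs = np.arange(0.0, 101.0, 1.0)
        stack = mn.stack_spectra(_spectra(3, [0], ["a"], freqs), band=(0, 60))
        assert stack.freqs.max() == 60.0

    def test_missing_cell_rejected(self):
        freqs = np.arange(0.0, 11.0, 1.0)
        spectra = _spectra(3, [0, 1], ["a", "b"], freqs)
        with pytest.raises(InvalidInputError):
            mn.stack_spectra(spectra[:-1])


class TestNmfAls:
    def test_exact_low_rank_matrix_recovered(self):
        rng = np.random.default_rng(0)
        W0 = rng.uniform(0, 1, (30, 3))
        H0 = rng.uniform(0, 1, (3, 40))
        V = W0 @ H0
        fact = mn.nmf_als(V, K=3, tol=1e-14, max_iter=2000, n_restarts=30,
                          seed=1)
        assert fact.reconstruction_error < 1e-6 * np.linalg.norm(V)

    def test_rank_one_identical_columns(self):
        col = np.random.default_rng(1).uniform(0.1, 1, 20)
        V = np.tile(col[:, None], (1, 15))
        fact = mn.nmf_als(V, K=1, tol=1e-12, seed=2)
        assert fact.reconstruction_error < 1e-8 * np.linalg.norm(V)
        basis = fact.W[:, 0] / np.linalg.norm(fact.W[:, 0])
        np.testing.assert_allclose(basis, col / np.linalg.norm(col), atol=1e-6)

    def test_error_history_non_increasing(self):
        rng = np.random.default_rng(2)
        V = rng.uniform(0, 1, (25, 30))
        fact = mn.nmf_als(V, K=4, seed=3)
        assert np.all(np.diff(fact.error_history) <= 1e-12)

    def test_deterministic_given_seed(self):
        V = np.random.default_rng(3).uniform(0, 1, (20, 20))
        f1 = mn.nmf_als(V, K=2, seed=7)
        f2 = mn.nmf_als(V, K=2, seed=7)
        np.testing.assert_array_equal(f1.W, f2.W)
        np.testing.assert_array_equal(f1.H, f2.H)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        V = rng.uniform(0, 1, (15, 12))
        perm = rng.permutation(12)
        f1 = mn.nmf_als(V, K=2, seed=5)
        f2 = mn.nmf_als(V[:, perm], K=2, seed=5)
        np.testing.assert_allclose(f1.H[:, perm], f2.H, atol=1e-10)
        np.testing.assert_allclose(f1.W, f2.W, atol=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            mn.nmf_als(np.ones((4, 4)), K=5)
        with pytest.raises(DegenerateInputError):
            mn.nmf_als(np.zeros((4, 4)), K=2)
        with pytest.raises(InvalidInputError):
            mn.nmf_als(-np.ones((4, 4)), K=2)


class TestOrderAndNormalize:
    def test_product_unchanged_and_columns_unit_norm(self):
        V = np.random.default_rng(5).uniform(0, 1, (20, 18))
        fact = mn.nmf_als(V, K=3, seed=1)
        fact.freqs = np.arange(20.0)
        out = mn.order_and_normalize(fact)
        np.testing.assert_allclose(out.W @ out.H, fact.W @ fact.H, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(out.W, axis=0), 1.0,
                                   atol=1e-12)

    def test_components_sorted_by_peak_frequency(self):
        freqs = np.arange(0.0, 50.0, 1.0)
        W = np.zeros((50, 4))
        for k, peak in enumerate([40, 3, 16, 9]):
            W[peak, k] = 1.0
        fact = mn.NmfFactorization(W=W, H=np.ones((4, 6)),
                                   error_history=np.array([1.0]), n_iter=1,
                                   restart_index=0, converged=True, freqs=freqs)
        out = mn.order_and_normalize(fact)
        np.testing.assert_array_equal(mn.basis_peak_freqs(out), [3, 9, 16, 40])

    def test_zero_component_dropped_with_warning(self):
        W = np.zeros((10, 2))
        W[3, 0] = 1.0
        fact = mn.NmfFactorization(W=W, H=np.ones((2, 5)),
                                   error_history=np.array([1.0]), n_iter=1,
                                   restart_index=0, converged=True,
                                   freqs=np.arange(10.0))
        with pytest.warns(UserWarning):
            out = mn.order_and_normalize(fact)
        assert out.K == 1


class TestComponentNetworks:
    def _stack_and_fact(self, directed, n_channels=4):
        freqs = np.arange(0.0, 21.0, 1.0)
        spectra = _spectra(n_channels, [0, 1], ["a", "b"], freqs,
                           directed=directed, seed=6)
        stack = mn.stack_spectra(spectra, band=(0, 20))
        fact = mn.nmf_als(stack.V, K=2, seed=8)
        fact.freqs = stack.freqs
        return stack, mn.order_and_normalize(fact)

    def test_undirected_networks_symmetric_and_counted(self):
        stack, fact = self._stack_and_fact(directed=False)
        nets = mn.component_networks(fact, stack)
        assert len(nets) == fact.K * 2 * 2
        for net in nets:
            np.testing.assert_array_equal(net.adjacency, net.adjacency.T)
            assert np.all(np.diag(net.adjacency) == 0)

    def test_directed_networks_place_source_target_weights(self):
        stack, fact = self._stack_and_fact(directed=True)
        nets = mn.component_networks(fact, stack)
        net = nets[0]
        block = stack.index.iloc[:len(stack.pairs)]
        row = block.index[(block["source"] == 0) & (block["target"] == 2)][0]
        assert net.adjacency[0, 2] == fact.H[0, row]

    def test_index_mismatch_rejected(self):
        stack, fact = self._stack_and_fact(directed=False)
        bad = mn.NmfFactorization(W=fact.W, H=fact.H[:, :-1],
                                  error_history=fact.error_history, n_iter=1,
                                  restart_index=0, converged=True)
        with pytest.raises(InvalidInputError):
            mn.component_networks(bad, stack)

    def test_restart_stability_of_peak_locations(self):
        """Distinct seeds find the same two spectral peaks on an easy matrix."""
        rng = np.random.default_rng(9)
        freqs = np.arange(0.0, 40.0, 1.0)
        w1 = np.exp(-0.5 * ((freqs - 5) / 1.5) ** 2)
        w2 = np.exp(-0.5 * ((freqs - 25) / 2.0) ** 2)
        H = rng.uniform(0, 1, (2, 50))
        V = np.outer(w1, H[0]) + np.outer(w2, H[1]) + 0.01 * rng.uniform(0, 1, (40, 50))
        peaks = []
        for seed in (1, 2, 3):
            fact = mn.nmf_als(V, K=2, seed=seed)
            fact.freqs = freqs
            peaks.append(sorted(mn.basis_peak_freqs(mn.order_and_normalize(fact))))
        for p in peaks[1:]:
            assert np.abs(np.asarray(p) - np.asarray(peaks[0])).max() <= 1.0
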