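"""MVAR fitting, order selection, instantaneous effects, coherence and PDC."""

import numpy as np
import pytest

import musclenet as mn
from musclenet.errors import DegenerateInputError, SingularFitError
from musclenet.mvar import _abar


class TestFitMvar:
    def test_recovers_known_var2_coefficients(self, var2_spec):
        devs = []
        for seed in range(3):
            x = mn.simulate_var(var2_spec, 12000, np.random.default_rng(seed))
            model = mn.fit_mvar(x, 2, fs=200.0)
            devs.append(np.abs(model.A - var2_spec.coefficients).max())
        assert np.median(devs) < 0.05

    def test_white_noise_gives_near_zero_coefficients(self):
        x = np.random.default_rng(0).standard_normal((3, 12000))
        model = mn.fit_mvar(x, 2, fs=200.0)
        # 3 standard errors of an OLS coefficient on unit-variance regressors
        assert np.abs(model.A).max() < 3.0 / np.sqrt(12000 / 1.2)

    def test_duplicated_channel_raises_singular_fit(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 5000))
        x3 = np.vstack([x, x[0]])
        with pytest.raises(SingularFitError, match="ch"):
            mn.fit_mvar(x3, 2, fs=200.0)

    def test_residual_covariance_symmetric(self, var2_spec):
        x = mn.simulate_var(var2_spec, 4000, np.random.default_rng(2))
        model = mn.fit_mvar(x, 2, fs=200.0)
        np.testing.assert_allclose(model.resid_cov, model.resid_cov.T,
                                   atol=1e-12)

    def test_stability_flag(self, var2_spec):
        x = mn.simulate_var(var2_spec, 8000, np.random.default_rng(3))
        assert mn.fit_mvar(x, 2, fs=200.0).is_stable()


class TestSelectOrderAic:
    def test_curve_has_requested_length_and_is_finite(self):
        x = np.random.default_rng(4).standard_normal((2, 4000))
        p, curve = mn.select_order_aic(x, p_max=10, fs=200.0)
        assert curve.shape == (10,)
        assert np.all(np.isfinite(curve))
        assert 1 <= p <= 10

    def test_var5_order_selected_in_plausible_range(self, var5_spec):
        hits = 0
        for seed in range(5):
            x = mn.simulate_var(var5_spec, 12000, np.random.default_rng(100 + seed))
            p, _ = mn.select_order_aic(x, p_max=12, fs=200.0)
            hits += 4 <= p <= 7
        assert hits >= 4

    def test_white_noise_selects_small_order(self):
        for seed in range(5):
            x = np.random.default_rng(200 + seed).standard_normal((3, 12000))
            p, _ = mn.select_order_aic(x, p_max=12, fs=200.0)
            assert p <= 3


class TestIdentifyInstantaneous:
    def test_diagonal_covariance_gives_zero_b0(self, var2_spec):
        x = mn.simulate_var(var2_spec, 6000, np.random.default_rng(5))
        model = mn.fit_mvar(x, 2, fs=200.0)
        model.resid_cov = np.diag(np.diag(model.resid_cov))
        ext = mn.identify_instantaneous(model)
        np.testing.assert_allclose(ext.B0, 0.0, atol=1e-12)
        np.testing.assert_allclose(ext.A_ext, model.A, atol=1e-12)

    def test_two_channel_closed_form(self):
        """Sigma = [[1, .5], [.5, 1]] gives B0[1,0] = 0.5 under order (0, 1)."""
        model = mn.MvarModel(A=np.zeros((1, 2, 2)),
                             resid_cov=np.array([[1.0, 0.5], [0.5, 1.0]]),
                             fs=200.0)
        ext = mn.identify_instantaneous(model, ordering=(0, 1))
        assert ext.B0[1, 0] == pytest.approx(0.5, abs=1e-12)
        assert ext.B0[0, 1] == 0.0
        np.testing.assert_allclose(np.diag(np.diag(ext.resid_cov_ext)),
                                   ext.resid_cov_ext, atol=1e-10)

    def test_ordering_does_not_change_model_spectrum(self, var2_spec):
        x = mn.simulate_var(var2_spec, 8000, np.random.default_rng(6))
        model = mn.fit_mvar(x, 2, fs=200.0)
        freqs = np.arange(0.0, 100.0, 2.0)
        e1 = mn.identify_instantaneous(model, ordering=(0, 1, 2))
        e2 = mn.identify_instantaneous(model, ordering=(2, 1, 0))
        assert not np.allclose(e1.B0, e2.B0)
        s1 = mn.model_spectrum(e1, freqs)
        s2 = mn.model_spectrum(e2, freqs)
        np.testing.assert_allclose(s1, s2, atol=1e-8)

    def test_extended_innovation_covariance_is_diagonal(self, var2_spec):
        x = mn.simulate_var(var2_spec, 8000, np.random.default_rng(7))
        ext = mn.identify_instantaneous(mn.fit_mvar(x, 2, fs=200.0))
        off = ext.resid_cov_ext - np.diag(np.diag(ext.resid_cov_ext))
        assert np.abs(off).max() < 1e-8

    def test_non_positive_definite_sigma_rejected(self):
        model = mn.MvarModel(A=np.zeros((1, 2, 2)),
                             resid_cov=np.array([[1.0, 1.0], [1.0, 1.0]]),
                             fs=200.0)
        with pytest.raises(DegenerateInputError):
            mn.identify_instantaneous(model)


class TestModelCoherency:
    def test_decoupled_blocks_have_zero_cross_coherence(self):
        A = np.zeros((1, 4, 4))
        A[0] = np.diag([0.5, 0.4, 0.3, 0.2])
        A[0][1, 0] = 0.3
        A[0][3, 2] = 0.3
        model = mn.MvarModel(A=A, resid_cov=np.eye(4), fs=200.0)
        coh = mn.model_coherency(model, np.arange(0.0, 100.0, 1.0))
        for row, (i, j) in enumerate(coh.pairs):
            if {i, j} in ({0, 1}, {2, 3}):
                continue
            np.testing.assert_allclose(np.abs(coh.values[row]), 0.0, atol=1e-10)

    def test_model_spectrum_consistency(self, var2_spec):
        """Abar * H = I; S Hermitian; integrated S_ii ~ process variance."""
        model = var2_spec.true_model()
        freqs = np.linspace(0.0, 100.0, 2001)
        Ab = _abar(model, freqs)
        H = np.linalg.inv(Ab)
        eye = np.broadcast_to(np.eye(3), Ab.shape)
        np.testing.assert_allclose(Ab @ H, eye, atol=1e-8)
        S = mn.model_spectrum(model, freqs)
        np.testing.assert_allclose(S, np.conj(np.swapaxes(S, 1, 2)), atol=1e-8)
        df = freqs[1] - freqs[0]
        var_spec = 2.0 * np.real(np.einsum("fii->fi", S)).sum(axis=0) * df / 200.0
        var_true = np.diag(var2_spec.stationary_cov())
        np.testing.assert_allclose(var_spec, var_true, rtol=0.05)

    def test_unstable_model_rejected(self):
        A = np.zeros((1, 2, 2))
        A[0] = [[1.05, 0.0], [0.0, 0.2]]
        model = mn.MvarModel(A=A, resid_cov=np.eye(2), fs=200.0)
        with pytest.raises(Exception):
            mn.model_coherency(model, np.arange(0.0, 10.0, 1.0))


class TestModelPdc:
    def test_column_normalization_including_diagonal(self, var2_spec):
        pdc = mn.model_pdc(var2_spec.true_model(), np.arange(0.0, 60.5, 0.5))
        colsums = np.sum(np.abs(pdc.full) ** 2, axis=0)
        np.testing.assert_allclose(colsums, 1.0, atol=1e-10)

    def test_one_way_coupling_has_zero_reverse_pdc(self):
        A = np.zeros((1, 2, 2))
        A[0][1, 0] = 0.5
        model = mn.MvarModel(A=A, resid_cov=np.eye(2), fs=200.0)
        pdc = mn.model_pdc(model, np.arange(0.0, 100.0, 1.0))
        sq = np.abs(pdc.full) ** 2
        assert np.all(sq[0, 1] == 0)
        assert np.all(sq[1, 0] > 0)

    def test_two_channel_closed_form_values(self):
        """A = [[d,0],[a,d]]: |pdc_21|^2 = a^2 / (|1 - d e^{-iw}|^2 + a^2)."""
        d, a, fs = 0.4, 0.5, 200.0
        A = np.zeros((1, 2, 2))
        A[0] = [[d, 0.0], [a, d]]
        model = mn.MvarModel(A=A, resid_cov=np.eye(2), fs=fs)
        pdc = mn.model_pdc(model, np.array([0.0, fs / 4.0]))
        sq = np.abs(pdc.full[1, 0]) ** 2
        assert sq[0] == pytest.approx(a ** 2 / ((1 - d) ** 2 + a ** 2), abs=1e-12)
        assert sq[1] == pytest.approx(a ** 2 / (1 + d ** 2 + a ** 2), abs=1e-12)

    def test_ninety_ordered_pairs_for_ten_channels(self):
        A = np.zeros((1, 10, 10))
        np.fill_diagonal(A[0], 0.3)
        model = mn.MvarModel(A=A, resid_cov=np.eye(10), fs=200.0)
        pdc = mn.model_pdc(model, np.arange(0.0, 60.5, 0.5))
        assert pdc.values.shape[0] == 90


class TestPoolPdc:
    def _pdc(self, full):
        return mn.PdcMatrix(full=np.asarray(full, dtype=complex),
                            freqs=np.arange(full.shape[-1], dtype=float),
                            channel_labels=("a", "b"))

    def test_single_trial_pooled_is_squared_magnitude(self, var2_spec):
        pdc = mn.model_pdc(var2_spec.true_model(), np.arange(0.0, 30.0, 1.0))
        pooled = mn.pool_pdc([pdc])
        np.testing.assert_allclose(pooled.values, np.abs(pdc.values) ** 2,
                                   atol=1e-14)
        assert pooled.directed

    def test_pooled_column_sums_bounded_by_one(self):
        rng = np.random.default_rng(11)
        trials = []
        for _ in range(4):
            raw = rng.standard_normal((2, 2, 8)) + 1j * rng.standard_normal((2, 2, 8))
            norm = np.sqrt(np.sum(np.abs(raw) ** 2, axis=0, keepdims=True))
            trials.append(self._pdc(raw / norm))
        pooled = mn.pool_pdc(trials)
        full = np.zeros((2, 2, 8))
        src, tgt = [1, 0], [0, 1]
        for row, (s, t) in enumerate([(1, 0), (0, 1)]):
            full[t, s] = pooled.values[row]
        colsums = full.sum(axis=0)
        assert np.all(colsums <= 1 + 1e-9)

    def test_mismatched_grids_rejected(self):
        a = self._pdc(np.zeros((2, 2, 4)))
        b = self._pdc(np.zeros((2, 2, 5)))
        with pytest.raises(Exception):
            mn.pool_pdc([a, b])


class TestModelVsWelchCoherence:
    def test_model_and_welch_coherence_agree_on_var_fixture(
            self, var1_chain_spec):
        """The model check: MVAR coherence tracks Welch coherence (0-60 Hz)."""
        design = mn.StudyDesign(n_subjects=1, conditions=("c",),
                                trials_per_condition=1, trial_duration=60.0,
                                fs=2000.0, channel_labels=("a", "b", "c"))
        mads = []
        for seed in range(3):
            study, _ = mn.generate_var_envelope_study(design, var1_chain_spec,
                                                      seed=seed)
            env = mn.highpass_rectify(study.trials[0])
            cond = mn.condition_for_mvar(env)
            _, model = mn.fit_trial_pdc(cond, order="auto", p_max=20)
            wf = np.arange(0.0, 61.0, 1.0)
            mc = mn.model_coherency(model, wf)
            wc = mn.welch_coherency(env, fmax=60.0)
            mads.append(np.abs(np.abs(mc.values) ** 2
                               - np.abs(wc.values) ** 2).mean())
        assert np.median(mads) < 0.1
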