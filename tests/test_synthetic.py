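"""Generator contracts: determinism, band limits, planted ground truth."""

import numpy as np
import pytest
from scipy import signal

import musclenet as mn
from musclenet.errors import InvalidParameterError


class TestCarrier:
    def test_deterministic_given_seed(self, small_design):
        a = mn.generate_carrier(2, small_design, seed=1)
        b = mn.generate_carrier(2, small_design, seed=1)
        np.testing.assert_array_equal(a, b)
        c = mn.generate_carrier(2, small_design, seed=2)
        assert not np.array_equal(a, c)

    def test_power_confined_to_acquisition_band(self, small_design):
        x = mn.generate_carrier(2, small_design, band=(5, 400), seed=1)
        f, p = signal.welch(x, fs=small_design.fs, nperseg=4096)
        inband = p[:, (f >= 5) & (f <= 400)].sum(axis=1) / p.sum(axis=1)
        assert np.all(inband >= 0.99)

    def test_zero_mean(self, small_design):
        x = mn.generate_carrier(3, small_design, seed=0)
        assert np.abs(x.mean(axis=1)).max() < 1e-12

    def test_band_outside_nyquist_rejected(self, small_design):
        with pytest.raises(InvalidParameterError):
            mn.generate_carrier(2, small_design, band=(5, 1500), seed=0)
        with pytest.raises(InvalidParameterError):
            mn.generate_carrier(2, small_design, band=(0, 400), seed=0)

    def test_independent_channels_below_surrogate_limit(self, small_design):
        """Without common drive, coherence stays at the chance level."""
        study = mn.generate_common_drive_study(small_design, [], seed=5)
        envs = [mn.highpass_rectify(t) for t in study.trials]
        pooled = mn.pool_coherence([mn.welch_coherency(e, fmax=60) for e in envs])
        thr = mn.surrogate_threshold(envs, n_surrogates=60, alpha=0.05,
                                     seed=9, fmax=60)
        frac_below = np.mean(pooled.values <= thr.values)
        assert frac_below >= 0.90


class TestDriveSpec:
    @pytest.mark.parametrize("kwargs", [
        dict(center_freq=2.0, bandwidth=6.0, targets=frozenset({0}), gain=0.1),
        dict(center_freq=10.0, bandwidth=0.0, targets=frozenset({0}), gain=0.1),
        dict(center_freq=10.0, bandwidth=4.0, targets=frozenset(), gain=0.1),
        dict(center_freq=10.0, bandwidth=4.0, targets=frozenset({0}), gain=-0.2),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            mn.DriveSpec(**kwargs)

    def test_targets_beyond_channel_count_rejected(self, small_design):
        d = mn.DriveSpec(center_freq=10.0, bandwidth=4.0,
                         targets=frozenset({99}), gain=0.2)
        with pytest.raises(InvalidParameterError):
            mn.generate_common_drive_study(small_design, [d], seed=0)

    def test_excessive_modulation_depth_rejected(self, small_design):
        """Summed gain >= 1 would drive the envelope scale negative."""
        d = [mn.DriveSpec(center_freq=10.0, bandwidth=4.0,
                          targets=frozenset({0}), gain=0.6),
             mn.DriveSpec(center_freq=20.0, bandwidth=4.0,
                          targets=frozenset({0}), gain=0.5)]
        with pytest.raises(InvalidParameterError):
            mn.generate_common_drive_study(small_design, d, seed=0)


class TestCommonDriveStudy:
    def test_deterministic_study(self, small_design):
        drives = [mn.DriveSpec(center_freq=10.0, bandwidth=4.0,
                               targets=frozenset({0, 1}), gain=0.5)]
        s1 = mn.generate_common_drive_study(small_design, drives, seed=3)
        s2 = mn.generate_common_drive_study(small_design, drives, seed=3)
        for a, b in zip(s1.trials, s2.trials):
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_planted_drive_produces_coherence_peak(self, ten_s_drive_study,
                                                   drive_envelopes):
        pooled = mn.pool_coherence(
            [mn.welch_coherency(e, fmax=60) for e in drive_envelopes])
        row = pooled.pairs.index((0, 1))
        v = pooled.values[row]
        peak = pooled.freqs[np.argmax(v)]
        assert abs(peak - 10.0) <= 2.0
        thr = mn.surrogate_threshold(drive_envelopes, n_surrogates=60,
                                     alpha=0.05, seed=2, fmax=60)
        band = (pooled.freqs >= 8) & (pooled.freqs <= 12)
        assert np.any(v[band] > thr.values[row, band])

    def test_study_shape_follows_design(self, ten_s_drive_study):
        st = ten_s_drive_study
        assert st.n_trials == 2
        assert st.trials[0].samples.shape == (10, 20000)


class TestVarEnvelopeStudy:
    def test_unstable_coupling_rejected(self):
        A = np.zeros((1, 2, 2))
        A[0] = [[1.1, 0], [0, 0.5]]
        with pytest.raises(InvalidParameterError):
            mn.VarCouplingSpec(coefficients=A, noise_cov=np.eye(2))

    def test_noise_cov_must_be_positive_definite(self):
        A = np.zeros((1, 2, 2))
        with pytest.raises(InvalidParameterError):
            mn.VarCouplingSpec(coefficients=A,
                               noise_cov=np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_true_pdc_respects_zero_pattern(self, var1_chain_spec):
        """Absent couplings give exactly zero PDC at every frequency."""
        _, truth = mn.generate_var_envelope_study(
            mn.StudyDesign(n_subjects=1, conditions=("c",),
                           trials_per_condition=1, trial_duration=1.0,
                           fs=2000.0, channel_labels=("a", "b", "c")),
            var1_chain_spec, seed=0)
        pdc = mn.model_pdc(truth, np.arange(0, 60.5, 0.5))
        sq = np.abs(pdc.full) ** 2
        assert np.all(sq[0, 1] == 0)   # no 1 -> 0 coupling
        assert np.all(sq[0, 2] == 0)
        assert np.all(sq[1, 2] == 0)
        assert np.all(sq[1, 0] > 0)    # planted 0 -> 1

    def test_diagonal_coupling_has_no_cross_pdc(self):
        A = np.zeros((1, 3, 3))
        A[0] = np.diag([0.5, 0.4, 0.3])
        spec = mn.VarCouplingSpec(coefficients=A, noise_cov=np.eye(3))
        pdc = mn.model_pdc(spec.standardized_model(), np.arange(0, 61.0, 1.0))
        sq = np.abs(pdc.full) ** 2
        off = sq[~np.eye(3, dtype=bool)]
        assert np.all(off == 0)

    def test_deterministic_study(self, var1_chain_spec):
        design = mn.StudyDesign(n_subjects=1, conditions=("c",),
                                trials_per_condition=1, trial_duration=5.0,
                                fs=2000.0, channel_labels=("a", "b", "c"))
        s1, _ = mn.generate_var_envelope_study(design, var1_chain_spec, seed=4)
        s2, _ = mn.generate_var_envelope_study(design, var1_chain_spec, seed=4)
        np.testing.assert_array_equal(s1.trials[0].samples, s2.trials[0].samples)

    def test_flat_carrier_envelope_is_nearly_constant(self):
        design = mn.StudyDesign(n_subjects=1, conditions=("c",),
                                trials_per_condition=1, trial_duration=5.0,
                                fs=2000.0, channel_labels=("a",))
        c = mn.generate_flat_carrier(1, design, seed=3)
        env = np.abs(signal.hilbert(c, axis=-1))[0, 500:-500]
        assert np.abs(env - 1.0).max() < 0.05

    def test_fitted_pdc_recovers_planted_truth(self, var1_chain_spec):
        """60-s trial: fitted squared PDC tracks the planted model."""
        design = mn.StudyDesign(n_subjects=1, conditions=("c",),
                                trials_per_condition=1, trial_duration=60.0,
                                fs=2000.0, channel_labels=("a", "b", "c"))
        freqs = np.arange(0, 60.5, 0.5)
        devs = []
        for seed in range(5):
            study, truth = mn.generate_var_envelope_study(
                design, var1_chain_spec, seed=seed)
            tp = np.abs(mn.model_pdc(truth, freqs).full) ** 2
            cond = mn.condition_for_mvar(mn.highpass_rectify(study.trials[0]))
            pdc, _ = mn.fit_trial_pdc(cond, order="auto", p_max=30)
            devs.append(np.abs(np.abs(pdc.full) ** 2 - tp).max())
        assert np.median(devs) < 0.1
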