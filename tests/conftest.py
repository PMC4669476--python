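"""Shared fixtures: small synthetic studies and reference VAR specs."""

import numpy as np
import pytest

import musclenet as mn


@pytest.fixture(scope="session")
def small_design():
    return mn.StudyDesign(n_subjects=1, conditions=("control",),
                          trials_per_condition=2, trial_duration=10.0,
                          fs=2000.0)


@pytest.fixture(scope="session")
def ten_s_drive_study(small_design):
    """One subject, two 10-s trials, a 10-Hz drive shared by channels 0 and 1."""
    drives = [mn.DriveSpec(center_freq=10.0, bandwidth=4.0,
                           targets=frozenset({0, 1}), gain=0.5)]
    return mn.generate_common_drive_study(small_design, drives, seed=1)


@pytest.fixture(scope="session")
def drive_envelopes(ten_s_drive_study):
    return [mn.highpass_rectify(t) for t in ten_s_drive_study.trials]


@pytest.fixture(scope="session")
def var1_chain_spec():
    """Stable VAR(1) chain 0 -> 1 -> 2 with low-frequency poles."""
    A = np.zeros((1, 3, 3))
    A[0] = [[0.5, 0, 0], [0.3, 0.45, 0], [0, 0.3, 0.45]]
    return mn.VarCouplingSpec(coefficients=A, noise_cov=0.3 * np.eye(3))


@pytest.fixture(scope="session")
def var2_spec():
    """Stable VAR(2) with mixed-sign couplings, used for recovery tests."""
    A = np.zeros((2, 3, 3))
    A[0] = [[0.4, 0.15, 0], [0, 0.35, 0.2], [0.1, 0, 0.4]]
    A[1] = [[-0.3, 0, 0.1], [0.1, -0.25, 0], [0, 0.15, -0.3]]
    return mn.VarCouplingSpec(coefficients=A, noise_cov=np.eye(3))


@pytest.fixture(scope="session")
def var5_spec():
    """Stable VAR(5) with substantial lag-5 structure, for order selection."""
    A = np.zeros((5, 3, 3))
    A[0] = 0.3 * np.eye(3) + np.array([[0, 0.2, 0], [0, 0, 0.2], [0.2, 0, 0]])
    A[4] = -np.array([[0.25, 0, 0.1], [0.1, 0.25, 0], [0, 0.1, 0.25]])
    return mn.VarCouplingSpec(coefficients=A, noise_cov=np.eye(3))


def make_envelope(samples, fs=2000.0, branch="coherence", labels=None):
    samples = np.asarray(samples, dtype=float)
    labels = labels or tuple(f"ch{i}" for i in range(samples.shape[0]))
    return mn.EnvelopeTrial(samples=samples, fs=fs, branch=branch,
                            channel_labels=tuple(labels))
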