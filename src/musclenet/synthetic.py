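"""Seedable surrogate-EMG generator with planted connectivity ground truth.

Two generative fixtures mirror the two halves of the analysis:

* **Common-drive studies** plant undirected networks: each channel is an
  independent band-limited Gaussian carrier (the interference EMG) whose
  amplitude is multiplicatively modulated by shared band-limited drive
  signals.  Channels sharing a drive acquire envelope coherence inside the
  drive band — the amplitude-modulation model under which intermuscular
  coherence reflects common synaptic input.
* **VAR-envelope studies** plant directed networks: a stable vector
  autoregressive process simulated at 200 Hz (the rate of the MVAR analysis
  branch) drives multiplicative log-envelope modulators ``exp(g * x)`` on
  independent constant-envelope swept-frequency carriers.  Because the
  carrier's Hilbert envelope is flat, the preprocessing chain hands back the
  planted modulator with minimal multiplicative noise, keeping the VAR
  ground truth meaningful after envelope extraction.  The ground-truth
  model is returned in standardized (unit stationary variance) units, the
  units in which the analysis branch — which z-scores every channel —
  estimates it; partial directed coherence is not invariant to per-channel
  rescaling, so this is the PDC the pipeline can recover.

One master seed yields per-(subject, condition, trial) substreams via
``numpy.random.SeedSequence(master, spawn_key=(subject, condition_index,
trial_index, salt))``, so any trial can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import InvalidParameterError
from .mvar import MvarModel
from .study import EmgStudy, EmgTrial, StudyDesign

#: Acquisition band of the emulated amplifier (Hz).
CARRIER_BAND = (5.0, 400.0)

#: Floor for the multiplicative envelope scale (see DriveSpec validation).
MODULATION_FLOOR = 0.05


@dataclass(frozen=True)
class DriveSpec:
    """One band-limited common drive: center/bandwidth, targets and depth."""

    center_freq: float
    bandwidth: float
    targets: frozenset[int]
    gain: float

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise InvalidParameterError("drive bandwidth must be positive")
        if self.center_freq - self.bandwidth / 2.0 <= 0:
            raise InvalidParameterError(
                f"drive band ({self.center_freq} +- {self.bandwidth / 2}) "
                "extends to or below 0 Hz"
            )
        if self.gain < 0:
            raise InvalidParameterError("drive gain must be >= 0")
        if not self.targets:
            raise InvalidParameterError("drive must target at least one channel")
        object.__setattr__(self, "targets", frozenset(int(i) for i in self.targets))

    @property
    def band(self) -> tuple[float, float]:
        return (self.center_freq - self.bandwidth / 2.0,
                self.center_freq + self.bandwidth / 2.0)

    def to_dict(self) -> dict:
        return {"center_freq": self.center_freq, "bandwidth": self.bandwidth,
                "targets": sorted(self.targets), "gain": self.gain}

    @classmethod
    def from_dict(cls, d: dict) -> "DriveSpec":
        return cls(center_freq=float(d["center_freq"]),
                   bandwidth=float(d["bandwidth"]),
                   targets=frozenset(d["targets"]), gain=float(d["gain"]))


@dataclass(frozen=True)
class VarCouplingSpec:
    """Generative VAR for directed envelope coupling (stable, SPD noise)."""

    coefficients: np.ndarray           # (order, n_channels, n_channels)
    noise_cov: np.ndarray              # (n_channels, n_channels)
    mod_depth: float = 0.6             # g in exp(g * x) log-envelope modulation
    fs_mod: float = 200.0              # modulator rate (matches the MVAR branch)

    def __post_init__(self) -> None:
        A = np.asarray(self.coefficients, dtype=float)
        if A.ndim != 3 or A.shape[1] != A.shape[2]:
            raise InvalidParameterError("coefficients must have shape (order, M, M)")
        object.__setattr__(self, "coefficients", A)
        S = np.asarray(self.noise_cov, dtype=float)
        if S.shape != (A.shape[1], A.shape[1]) or not np.allclose(S, S.T, atol=1e-10):
            raise InvalidParameterError("noise_cov must be symmetric (M, M)")
        if np.min(np.linalg.eigvalsh(0.5 * (S + S.T))) <= 0:
            raise InvalidParameterError("noise_cov must be positive definite")
        object.__setattr__(self, "noise_cov", S)
        if not self.true_model().is_stable():
            raise InvalidParameterError(
                "unstable VAR (companion spectral radius >= 1)"
            )
        if self.mod_depth < 0:
            raise InvalidParameterError("mod_depth must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[1]

    @property
    def order(self) -> int:
        return self.coefficients.shape[0]

    def true_model(self) -> MvarModel:
        """The planted process as an MvarModel (raw units)."""
        return MvarModel(A=self.coefficients, resid_cov=self.noise_cov,
                         fs=self.fs_mod)

    def stationary_cov(self) -> np.ndarray:
        """Stationary covariance of the VAR via the companion-form Lyapunov
        equation."""
        from scipy.linalg import solve_discrete_lyapunov
        p, M = self.order, self.n_channels
        C = self.true_model().companion()
        Q = np.zeros((p * M, p * M))
        Q[:M, :M] = self.noise_cov
        return solve_discrete_lyapunov(C, Q)[:M, :M]

    def standardized_model(self) -> MvarModel:
        """Ground truth in unit-stationary-variance units.

        The analysis branch z-scores each channel before fitting, and PDC is
        not invariant to per-channel rescaling, so the recoverable truth is
        the planted model re-expressed for standardized variables:
        ``A_k -> D^-1 A_k D``, ``Sigma -> D^-1 Sigma D^-1`` with
        ``D = diag(stationary sd)``.  Zero coefficients stay zero.
        """
        sd = np.sqrt(np.diag(self.stationary_cov()))
        D, Di = np.diag(sd), np.diag(1.0 / sd)
        A_std = np.einsum("ij,pjk,kl->pil", Di, self.coefficients, D)
        return MvarModel(A=A_std, resid_cov=Di @ self.noise_cov @ Di,
                         fs=self.fs_mod)


def _trial_rng(seed: int, subject: int, cond_index: int, trial_index: int,
               salt: int = 0) -> np.random.Generator:
    """Documented substream scheme: SeedSequence(master, spawn_key=(s, c, t, salt))."""
    ss = np.random.SeedSequence(seed, spawn_key=(subject, cond_index, trial_index, salt))
    return np.random.default_rng(ss)


def _bandlimited_noise(rng: np.random.Generator, shape: tuple[int, ...],
                       fs: float, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase band-pass filtered Gaussian noise (4th-order Butterworth)."""
    lo, hi = band
    if not (0 < lo < hi < fs / 2.0):
        raise InvalidParameterError(
            f"band {band} outside (0, Nyquist={fs / 2}) at fs={fs}"
        )
    sos = signal.butter(4, [lo / (fs / 2.0), hi / (fs / 2.0)],
                        btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)


def generate_carrier(n_channels: int, design: StudyDesign,
                     band: tuple[float, float] = CARRIER_BAND,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Mutually independent zero-mean band-limited Gaussian carrier channels.

    Band limitation is exact (Fourier masking of white Gaussian noise), so
    the carrier emulates the amplifier's acquisition band with no
    out-of-band leakage.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = band
    n = design.n_samples
    if not (0 < lo < hi < design.fs / 2.0):
        raise InvalidParameterError(
            f"band {band} outside (0, Nyquist={design.fs / 2}) at fs={design.fs}"
        )
    X = np.fft.rfft(rng.standard_normal((n_channels, n)), axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / design.fs)
    X[:, (freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(X, n=n, axis=-1)
    return x - x.mean(axis=-1, keepdims=True)


#: Instantaneous-frequency sweep range of the constant-envelope carrier (Hz).
FLAT_CARRIER_SWEEP = (30.0, 390.0)


def generate_flat_carrier(n_channels: int, design: StudyDesign,
                          sweep: tuple[float, float] = FLAT_CARRIER_SWEEP,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Broadband carriers with a constant (unit) Hilbert envelope.

    Each channel is a unit-amplitude cosine whose instantaneous frequency
    sweeps triangularly over ``sweep`` with a random period (0.8-1.4 s) and
    random phase per channel.  Unlike a Gaussian carrier, whose envelope
    fluctuates by ~52% (Rayleigh), this carrier's envelope is flat, so any
    planted amplitude modulation passes through envelope extraction almost
    untouched.  Used by the directed (VAR-envelope) generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = sweep
    if not (0 < lo < hi < design.fs / 2.0):
        raise InvalidParameterError(
            f"sweep {sweep} outside (0, Nyquist={design.fs / 2})"
        )
    t = np.arange(design.n_samples) / design.fs
    out = np.empty((n_channels, design.n_samples))
    for i in range(n_channels):
        period = rng.uniform(0.8, 1.4)
        tri = 2.0 * np.abs((t / period + rng.uniform(0.0, 1.0)) % 1.0 - 0.5)
        f_inst = lo + (hi - lo) * tri
        out[i] = np.cos(rng.uniform(0.0, 2.0 * np.pi)
                        + 2.0 * np.pi * np.cumsum(f_inst) / design.fs)
    return out


def _validate_drives(design: StudyDesign, drives: list[DriveSpec]) -> None:
    total_gain = np.zeros(design.n_channels)
    for d in drives:
        if max(d.targets) >= design.n_channels:
            raise InvalidParameterError(
                f"drive targets {sorted(d.targets)} exceed channel count "
                f"{design.n_channels}"
            )
        if d.band[1] >= design.fs / 2.0:
            raise InvalidParameterError("drive band exceeds Nyquist")
        for i in d.targets:
            total_gain[i] += d.gain
    if np.any(total_gain >= 1.0):
        bad = np.flatnonzero(total_gain >= 1.0).tolist()
        raise InvalidParameterError(
            f"summed drive gain >= 1 on channels {bad}: modulation depth "
            "would routinely produce a negative envelope scale"
        )


def generate_common_drive_study(design: StudyDesign, drives: list[DriveSpec],
                                seed: int = 0,
                                carrier_band: tuple[float, float] = CARRIER_BAND
                                ) -> EmgStudy:
    """Study with planted undirected (common-drive) envelope networks.

    Channel i of each trial is ``carrier_i(t) * max(1 + sum_d gain_d s_d(t),
    0.05)`` where each drive signal ``s_d`` is unit-variance Gaussian noise
    band-passed to the drive band and shared by the drive's target channels.
    """
    _validate_drives(design, drives)
    study = EmgStudy(design=design, provenance={
        "generator": "common_drive",
        "seed": int(seed),
        "drives": [d.to_dict() for d in drives],
        "carrier_band": list(carrier_band),
    })
    for s in range(design.n_subjects):
        for ci, cond in enumerate(design.conditions):
            for t in range(design.trials_per_condition):
                rng = _trial_rng(seed, s, ci, t)
                carrier = generate_carrier(design.n_channels, design,
                                           band=carrier_band, seed=rng)
                mod = np.ones((design.n_channels, design.n_samples))
                for d in drives:
                    sdrive = _bandlimited_noise(rng, (design.n_samples,),
                                                design.fs, d.band)
                    sdrive /= sdrive.std()
                    for i in d.targets:
                        mod[i] += d.gain * sdrive
                np.maximum(mod, MODULATION_FLOOR, out=mod)
                study.add(EmgTrial(samples=carrier * mod, fs=design.fs,
                                   channel_labels=design.channel_labels,
                                   subject=s, condition=cond, trial=t))
    return study


def simulate_var(coupling: VarCouplingSpec, n_samples: int,
                 rng: np.random.Generator, burn_in: int = 500) -> np.ndarray:
    """Simulate the VAR process, returning (n_channels, n_samples)."""
    A, S = coupling.coefficients, coupling.noise_cov
    p, M = coupling.order, coupling.n_channels
    L = np.linalg.cholesky(S)
    total = n_samples + burn_in + p
    e = rng.standard_normal((total, M)) @ L.T
    x = np.zeros((total, M))
    for t in range(p, total):
        acc = e[t]
        for k in range(p):
            acc = acc + A[k] @ x[t - 1 - k]
        x[t] = acc
    return x[-n_samples:].T


def generate_var_envelope_study(design: StudyDesign, coupling: VarCouplingSpec,
                                seed: int = 0,
                                sweep: tuple[float, float] = FLAT_CARRIER_SWEEP
                                ) -> tuple[EmgStudy, MvarModel]:
    """Study with planted directed envelope coupling, plus its true model.

    The VAR modulator runs at ``coupling.fs_mod`` (default 200 Hz, the
    analysis-branch rate); its upsampled trace multiplies constant-envelope
    swept carriers through ``exp(mod_depth * x)``, so the analysis-branch
    envelope approximately follows the planted VAR.  Returns
    ``(study, true_model)`` with the true model in standardized units (see
    :meth:`VarCouplingSpec.standardized_model`); the true squared PDC is
    ``|model_pdc(true_model, freqs).full|**2``.
    """
    if coupling.n_channels != design.n_channels:
        raise InvalidParameterError(
            f"coupling has {coupling.n_channels} channels, design "
            f"{design.n_channels}"
        )
    ratio = design.fs / coupling.fs_mod
    if abs(ratio - round(ratio)) > 1e-9:
        raise InvalidParameterError("fs must be an integer multiple of fs_mod")
    up = int(round(ratio))
    n_mod = int(round(design.trial_duration * coupling.fs_mod))
    study = EmgStudy(design=design, provenance={
        "generator": "var_envelope",
        "seed": int(seed),
        "order": coupling.order,
        "mod_depth": coupling.mod_depth,
        "fs_mod": coupling.fs_mod,
        "carrier_sweep": list(sweep),
    })
    for s in range(design.n_subjects):
        for ci, cond in enumerate(design.conditions):
            for t in range(design.trials_per_condition):
                rng = _trial_rng(seed, s, ci, t)
                x = simulate_var(coupling, n_mod, rng)
                x_up = signal.resample_poly(x, up, 1, axis=-1)[:, :design.n_samples]
                carrier = generate_flat_carrier(design.n_channels, design,
                                                sweep=sweep, seed=rng)
                mod = np.exp(coupling.mod_depth * x_up)
                study.add(EmgTrial(samples=carrier * mod, fs=design.fs,
                                   channel_labels=design.channel_labels,
                                   subject=s, condition=cond, trial=t))
    return study, coupling.standardized_model()
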