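"""Undirected connectivity spectra from Welch cross-spectral estimates.

For each trial, complex coherency between all unordered channel pairs is
computed from Hamming-tapered overlapping segments (default 1-s windows,
0.75-s overlap).  Complex coherency is then averaged across the trials of a
condition and squared, yielding pooled magnitude-squared coherence — a
stricter estimate than averaging magnitudes, because inconsistent phases
cancel.  Significance is assessed against phase-randomization surrogates
that preserve every channel's amplitude spectrum but destroy cross-channel
phase relations.

Each trial is demeaned by its whole-trial channel mean before segmentation,
which removes the trivial shared-DC coherence of nonnegative envelopes while
keeping the coherency of identical channels exactly 1 at every bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .errors import InvalidInputError, InvalidParameterError
from .pairs import pair_index_arrays, undirected_pairs
from .preprocess import EnvelopeTrial


@dataclass
class CoherencyMatrix:
    """Complex coherency, one row per unordered pair (i < j, row-major)."""

    values: np.ndarray  # complex, (n_pairs, n_freqs)
    freqs: np.ndarray
    n_windows: int
    pairs: list[tuple[int, int]]
    channel_labels: tuple[str, ...]
    subject: int = 0
    condition: str = ""
    trial: int = 0


@dataclass
class ConnectivitySpectra:
    """Nonnegative pair x frequency connectivity values for one design cell."""

    values: np.ndarray  # (n_pairs, n_freqs), >= 0
    freqs: np.ndarray
    pairs: list[tuple[int, int]]
    directed: bool
    channel_labels: tuple[str, ...]
    subject: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise InvalidInputError("connectivity values must be nonnegative")
        if not self.directed and np.any(self.values > 1 + 1e-9):
            raise InvalidInputError("undirected coherence must lie in [0, 1]")


@dataclass
class SurrogateThreshold:
    """Per-pair, per-frequency (1 - alpha) quantile of surrogate coherence."""

    values: np.ndarray  # (n_pairs, n_freqs)
    freqs: np.ndarray
    pairs: list[tuple[int, int]]
    n_surrogates: int
    alpha: float


def _segment_params(fs: float, n_samples: int, window_s: float, overlap_s: float
                    ) -> tuple[int, int, int]:
    nper = int(round(window_s * fs))
    step = nper - int(round(overlap_s * fs))
    if step <= 0:
        raise InvalidParameterError("overlap must be shorter than the window")
    if nper > n_samples:
        raise InvalidParameterError("window longer than the trial")
    n_win = 1 + (n_samples - nper) // step
    if n_win < 2:
        raise InvalidParameterError(
            f"only {n_win} Welch window fits the trial; coherency needs >= 2"
        )
    return nper, step, n_win


def _windowed_fft(x: np.ndarray, fs: float, window_s: float, overlap_s: float,
                  fmax: float | None) -> tuple[np.ndarray, np.ndarray, int]:
    """Hamming-tapered segment FFTs: (n_channels, n_windows, n_freqs)."""
    nper, step, n_win = _segment_params(fs, x.shape[-1], window_s, overlap_s)
    x = x - x.mean(axis=-1, keepdims=True)  # whole-trial demean per channel
    idx = np.arange(nper)[None, :] + step * np.arange(n_win)[:, None]
    segs = x[:, idx]  # (n_ch, n_win, nper)
    taper = _signal.get_window("hamming", nper)
    X = np.fft.rfft(segs * taper, axis=-1)
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    if fmax is not None:
        keep = freqs <= fmax + 1e-12
        X, freqs = X[..., keep], freqs[keep]
    return X, freqs, n_win


def welch_coherency(trial: EnvelopeTrial, window_s: float = 1.0,
                    overlap_s: float = 0.75,
                    fmax: float | None = None) -> CoherencyMatrix:
    """Complex coherency between all unordered channel pairs of one trial.

    ``coherency_ij(f) = <X_i X_j*> / sqrt(<|X_i|^2><|X_j|^2>)`` with ``<.>``
    averaging over tapered windows.  ``fmax`` optionally truncates the
    one-sided frequency grid (the cross-spectra are then only formed below
    it, which is much cheaper for surrogate loops).
    """
    X, freqs, n_win = _windowed_fft(np.asarray(trial.samples, float), trial.fs,
                                    window_s, overlap_s, fmax)
    auto = np.mean(np.abs(X) ** 2, axis=1)  # (n_ch, n_freq)
    prs = undirected_pairs(trial.n_channels)
    ia, ib = pair_index_arrays(prs)
    cross = np.mean(X[ia] * np.conj(X[ib]), axis=1)
    denom = np.sqrt(auto[ia] * auto[ib])
    coh = np.zeros_like(cross)
    ok = denom > 0
    coh[ok] = cross[ok] / denom[ok]
    return CoherencyMatrix(
        values=coh, freqs=freqs, n_windows=n_win, pairs=prs,
        channel_labels=tuple(trial.channel_labels),
        subject=trial.subject, condition=trial.condition, trial=trial.trial,
    )


def pool_coherence(trials: list[CoherencyMatrix]) -> ConnectivitySpectra:
    """Average complex coherency across trials, then square the magnitude."""
    if not trials:
        raise InvalidInputError("no trials to pool")
    first = trials[0]
    for t in trials[1:]:
        if t.values.shape != first.values.shape or not np.allclose(t.freqs, first.freqs):
            raise InvalidInputError("trials have mismatched frequency grids")
        if t.pairs != first.pairs:
            raise InvalidInputError("trials have mismatched pair maps")
    mean_coh = np.mean([t.values for t in trials], axis=0)
    values = np.abs(mean_coh) ** 2
    return ConnectivitySpectra(
        values=np.minimum(values, 1.0), freqs=first.freqs.copy(),
        pairs=list(first.pairs), directed=False,
        channel_labels=first.channel_labels,
        subject=first.subject, condition=first.condition,
    )


def phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fourier phase randomization preserving each channel's amplitude spectrum.

    Phases of the positive-frequency bins are drawn independently per channel;
    DC and Nyquist stay real, so the surrogate is real-valued.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    X = np.fft.rfft(x, axis=-1)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=X.shape)
    phases[..., 0] = 0.0
    if n % 2 == 0:
        phases[..., -1] = 0.0
    return np.fft.irfft(np.abs(X) * np.exp(1j * phases), n=n, axis=-1)


def surrogate_threshold(trials: list[EnvelopeTrial], n_surrogates: int = 200,
                        alpha: float = 0.05, seed: int | None = None,
                        window_s: float = 1.0, overlap_s: float = 0.75,
                        fmax: float | None = None, mode: str = "envelope",
                        preprocess=None) -> SurrogateThreshold:
    """95% confidence limit for pooled coherence from phase-randomized surrogates.

    For every surrogate, each channel of each trial is independently phase
    randomized and the full pooling pipeline re-run; the per-pair,
    per-frequency (1 - alpha) quantile over surrogates is returned.

    ``mode="envelope"`` (default) randomizes the envelopes themselves.  With
    ``mode="raw"``, pass raw-signal trials and a ``preprocess`` callable
    mapping a phase-randomized raw array to the envelope array whose
    coherence is pooled (envelope extraction is then re-run per surrogate).
    """
    if n_surrogates < 2:
        raise InvalidParameterError("need at least 2 surrogates")
    if not trials:
        raise InvalidInputError("no trials given")
    if mode not in ("envelope", "raw"):
        raise InvalidParameterError(f"unknown surrogate mode {mode!r}")
    if mode == "raw" and preprocess is None:
        raise InvalidParameterError("mode='raw' requires a preprocess callable")
    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(n_surrogates):
        surro_trials = []
        for t in trials:
            xs = phase_randomize(t.samples, rng)
            if mode == "raw":
                xs = preprocess(xs)
            st = EnvelopeTrial(samples=xs, fs=t.fs, branch="coherence",
                               channel_labels=t.channel_labels,
                               subject=t.subject, condition=t.condition,
                               trial=t.trial)
            surro_trials.append(
                welch_coherency(st, window_s=window_s, overlap_s=overlap_s, fmax=fmax)
            )
        pooled.append(pool_coherence(surro_trials).values)
    stack = np.asarray(pooled)
    thresh = np.quantile(stack, 1.0 - alpha, axis=0)
    ref = welch_coherency(
        EnvelopeTrial(samples=trials[0].samples, fs=trials[0].fs,
                      branch="coherence", channel_labels=trials[0].channel_labels),
        window_s=window_s, overlap_s=overlap_s, fmax=fmax)
    return SurrogateThreshold(values=thresh, freqs=ref.freqs,
                              pairs=ref.pairs, n_surrogates=n_surrogates,
                              alpha=alpha)
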