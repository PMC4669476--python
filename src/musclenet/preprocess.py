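"""Raw EMG -> amplitude envelopes, in the two flavors downstream stages need.

The coherence branch high-pass filters the raw EMG at 20 Hz and takes the
magnitude of the analytic (Hilbert) signal: a nonnegative envelope at the
native sampling rate.  The MVAR branch additionally band-pass filters that
envelope to 0.5-70 Hz, downsamples it to 200 Hz and z-scores each channel,
so that autoregressive fits are not dominated by amplitude differences
between muscles.

All filters are zero-phase (forward-backward) 4th-order Butterworth;
downsampling is polyphase with built-in anti-aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import DegenerateInputError, InvalidParameterError
from .study import EmgTrial


@dataclass
class EnvelopeTrial:
    """Conditioned version of one trial.

    ``branch`` is ``"coherence"`` (nonnegative Hilbert envelope at native fs)
    or ``"mvar"`` (band-limited, downsampled, z-scored envelope).
    """

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    branch: str
    channel_labels: tuple[str, ...]
    subject: int = 0
    condition: str = ""
    trial: int = 0

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def _butter_sos(kind: str, cutoff, fs: float, order: int = 4):
    nyq = fs / 2.0
    crit = np.atleast_1d(np.asarray(cutoff, dtype=float))
    if np.any(crit <= 0) or np.any(crit >= nyq):
        raise InvalidParameterError(
            f"filter cutoff {cutoff} Hz outside (0, {nyq}) Hz at fs={fs}"
        )
    wn = crit / nyq
    return signal.butter(order, wn if wn.size > 1 else float(wn[0]),
                         btype=kind, output="sos")


def highpass_rectify(trial: EmgTrial, cutoff_hz: float = 20.0) -> EnvelopeTrial:
    """High-pass filter raw EMG and rectify it via the Hilbert transform.

    Returns the magnitude of the analytic signal of the 20-Hz high-passed
    EMG, per channel — the amplitude envelope of the interference EMG, which
    carries the slow common-drive modulation analyzed for coherence.
    """
    sos = _butter_sos("highpass", cutoff_hz, trial.fs)
    x = np.asarray(trial.samples, dtype=float)
    if x.shape[1] < 10 * int(trial.fs / cutoff_hz):
        raise InvalidParameterError(
            "trial too short for a stable 20-Hz high-pass (need >= 10 time constants)"
        )
    filtered = signal.sosfiltfilt(sos, x, axis=-1)
    env = np.abs(signal.hilbert(filtered, axis=-1))
    return EnvelopeTrial(
        samples=env, fs=trial.fs, branch="coherence",
        channel_labels=tuple(trial.channel_labels),
        subject=trial.subject, condition=trial.condition, trial=trial.trial,
    )


def condition_for_mvar(envelope: EnvelopeTrial,
                       band: tuple[float, float] = (0.5, 70.0),
                       fs_out: float = 200.0) -> EnvelopeTrial:
    """Band-pass (0.5-70 Hz), downsample to 200 Hz and z-score an envelope.

    The output has per-channel mean 0 and unit variance, which equalizes the
    contribution of each muscle to the multivariate autoregressive fit.
    """
    if envelope.branch != "coherence":
        raise InvalidParameterError("condition_for_mvar expects a coherence-branch envelope")
    lo, hi = band
    if hi >= fs_out / 2.0:
        raise InvalidParameterError(
            f"band upper edge {hi} Hz >= Nyquist of fs_out {fs_out} Hz"
        )
    in_sd = envelope.samples.std(axis=-1, ddof=0)
    if np.any(in_sd == 0):
        bad = [envelope.channel_labels[i] for i in np.flatnonzero(in_sd == 0)]
        raise DegenerateInputError(f"zero-variance envelope channel(s): {bad}")
    sos = _butter_sos("bandpass", (lo, hi), envelope.fs)
    x = signal.sosfiltfilt(sos, envelope.samples, axis=-1)

    frac = Fraction(fs_out / envelope.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    # Anti-alias FIR cut at the band edge (not the output Nyquist), so the
    # Butterworth transition band does not leak past `hi` after decimation.
    fs_up = envelope.fs * up
    cutoff = min(1.03 * hi, 0.49 * fs_out)
    numtaps = max(101, int(801 * fs_up / 2000.0)) | 1
    fir = signal.firwin(numtaps, cutoff, fs=fs_up) * up
    y = signal.resample_poly(x, up, down, axis=-1, window=fir)
    n_expected = int(round(envelope.n_samples * fs_out / envelope.fs))
    y = y[:, :n_expected]

    sd = y.std(axis=-1, ddof=0)
    if np.any(sd == 0):
        bad = [envelope.channel_labels[i] for i in np.flatnonzero(sd == 0)]
        raise DegenerateInputError(f"zero-variance channel(s) after conditioning: {bad}")
    y = (y - y.mean(axis=-1, keepdims=True)) / sd[:, None]
    return EnvelopeTrial(
        samples=y, fs=fs_out, branch="mvar",
        channel_labels=envelope.channel_labels,
        subject=envelope.subject, condition=envelope.condition, trial=envelope.trial,
    )


def normalized_psd(envelope: EnvelopeTrial,
                   window_s: float = 1.0, overlap_s: float = 0.75,
                   band: tuple[float, float] | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD per channel, normalized to unit total power over ``band``.

    Returns ``(freqs, psd)`` with ``psd[c]`` summing to 1 over the analysis
    band (default: the full one-sided grid).  Raises for zero-power channels.
    """
    nper = int(round(window_s * envelope.fs))
    nover = int(round(overlap_s * envelope.fs))
    if nper > envelope.n_samples:
        raise InvalidParameterError("Welch window longer than the trial")
    freqs, psd = signal.welch(
        envelope.samples, fs=envelope.fs, window="hamming",
        nperseg=nper, noverlap=nover, axis=-1,
    )
    if band is not None:
        keep = (freqs >= band[0]) & (freqs <= band[1])
        freqs, psd = freqs[keep], psd[:, keep]
    totals = psd.sum(axis=-1)
    if np.any(totals <= 0):
        bad = [envelope.channel_labels[i] for i in np.flatnonzero(totals <= 0)]
        raise DegenerateInputError(f"zero spectral power in channel(s): {bad}")
    return freqs, psd / totals[:, None]
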