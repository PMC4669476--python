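"""Time-domain muscle synergies from EMG envelopes (comparison method).

Synergies are nonnegative muscle-weight basis vectors whose time-varying
activations reconstruct the envelope matrix.  The synergy count is the
number of principal components explaining 90% of the envelope variance;
extraction uses the same alternating-least-squares NMF engine as the
spectral unmixing, per participant and condition.  Basis vectors are
aligned across participants/conditions by the correlation-maximizing
permutation (a Procrustes-style reordering: nonnegativity forbids general
rotations), and per-synergy consistency is the mean inter-set correlation
of the aligned bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.optimize import linear_sum_assignment

from .errors import DegenerateInputError, InvalidInputError, InvalidParameterError
from .preprocess import EnvelopeTrial
from .unmixing import nmf_als


@dataclass
class SynergySet:
    """Synergies of one participant/condition: weights, activations, PCA curve."""

    basis: np.ndarray         # (n_synergies, n_muscles), unit-norm rows, >= 0
    activations: np.ndarray   # (n_synergies, n_samples), >= 0
    ve_curve: np.ndarray      # cumulative PCA variance explained, ends at 1
    subject: int = 0
    condition: str = ""

    @property
    def n_synergies(self) -> int:
        return self.basis.shape[0]


def condition_envelopes_for_synergy(envelope: EnvelopeTrial,
                                    lowpass_hz: float = 10.0,
                                    fs_out: float = 100.0) -> np.ndarray:
    """Smooth (10-Hz low-pass) and downsample (100 Hz) envelopes for synergy NMF.

    Zero-phase filtering can produce tiny negative excursions; these are
    clipped at 0 to keep the matrix factorizable.
    """
    nyq = envelope.fs / 2.0
    if not (0 < lowpass_hz < nyq):
        raise InvalidParameterError(f"lowpass {lowpass_hz} Hz outside (0, {nyq})")
    sos = signal.butter(4, lowpass_hz / nyq, btype="lowpass", output="sos")
    x = signal.sosfiltfilt(sos, envelope.samples, axis=-1)
    frac = Fraction(fs_out / envelope.fs).limit_denominator(10000)
    y = signal.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    return np.clip(y, 0.0, None)


def pca_variance_curve(env_matrix: np.ndarray) -> np.ndarray:
    """Cumulative fraction of variance explained by 1..n_muscles PCs."""
    X = np.asarray(env_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise InvalidInputError("need a muscles x time matrix with >= 2 of each")
    Xc = X - X.mean(axis=1, keepdims=True)
    total = np.sum(Xc ** 2)
    if total <= 0:
        raise DegenerateInputError("zero-variance envelope matrix")
    sv = np.linalg.svd(Xc, compute_uv=False)
    var = np.zeros(X.shape[0])
    var[:len(sv)] = sv ** 2
    return np.cumsum(var) / total


def estimate_n_synergies(env_matrix: np.ndarray,
                         variance_target: float = 0.90
                         ) -> tuple[int, np.ndarray]:
    """Smallest PC count whose cumulative variance reaches the target."""
    if not (0 < variance_target <= 1):
        raise InvalidParameterError("variance_target must be in (0, 1]")
    curve = pca_variance_curve(env_matrix)
    n = int(np.argmax(curve >= variance_target - 1e-12)) + 1
    return n, curve


def extract_synergies(env_matrix: np.ndarray, n_synergies: int,
                      seed: int | None = None, subject: int = 0,
                      condition: str = "", tol: float = 1e-8,
                      max_iter: int = 500, n_restarts: int = 10) -> SynergySet:
    """NMF of the muscle x time envelope matrix into synergies + activations."""
    V = np.asarray(env_matrix, dtype=float)
    if np.any(V < 0):
        raise InvalidInputError("envelopes must be nonnegative")
    fact = nmf_als(V, K=n_synergies, tol=tol, max_iter=max_iter,
                   n_restarts=n_restarts, seed=seed)
    W, H = fact.W, fact.H   # V (muscles x time) ~ W (muscles x K) @ H (K x time)
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    basis = (W / norms[None, :]).T            # rows: unit-norm muscle weights
    activations = H * norms[:, None]
    curve = pca_variance_curve(V)
    return SynergySet(basis=basis, activations=activations, ve_curve=curve,
                      subject=subject, condition=condition)


def _corr_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of A and every row of B."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(Ac, axis=1)
    nb = np.linalg.norm(Bc, axis=1)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (Ac @ Bc.T) / np.outer(na, nb)


def align_synergies(sets: list[SynergySet], reference: SynergySet
                    ) -> tuple[list[SynergySet], np.ndarray]:
    """Reorder each set's synergies to best match the reference.

    The permutation maximizing the summed basis-vector correlation with the
    reference is found by optimal assignment.  Returns the reordered sets
    and, per synergy, the mean correlation over all pairs of aligned sets
    (consistency r).
    """
    k = reference.n_synergies
    for s in sets:
        if s.n_synergies != k:
            raise InvalidInputError(
                f"synergy count mismatch: {s.n_synergies} != {k}"
            )
    aligned = []
    for s in sets:
        corr = _corr_rows(reference.basis, s.basis)
        ref_idx, set_idx = linear_sum_assignment(-corr)
        perm = np.empty(k, dtype=int)
        perm[ref_idx] = set_idx
        aligned.append(SynergySet(basis=s.basis[perm],
                                  activations=s.activations[perm],
                                  ve_curve=s.ve_curve, subject=s.subject,
                                  condition=s.condition))
    r = np.zeros(k)
    if len(aligned) > 1:
        for j in range(k):
            vecs = np.stack([s.basis[j] for s in aligned])
            C = _corr_rows(vecs, vecs)
            iu = np.triu_indices(len(aligned), k=1)
            r[j] = C[iu].mean()
    return aligned, r


def total_alignment_correlation(sets: list[SynergySet],
                                reference: SynergySet) -> float:
    """Summed per-synergy correlation with the reference (diagnostic)."""
    return float(sum(
        np.trace(_corr_rows(reference.basis, s.basis)) for s in sets
    ))
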