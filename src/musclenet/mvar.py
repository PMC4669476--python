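"""Multivariate autoregressive (MVAR) modeling of EMG envelopes.

Each conditioned trial (channels z-scored, 200 Hz) is modeled as

    y(t) = sum_{k=1..p} A_k y(t-k) + e(t),      cov(e) = Sigma,

fitted by ordinary least squares with the order p chosen per trial by
Akaike's information criterion.  From the frequency response
``Abar(f) = I - sum_k A_k exp(-i 2 pi f k / fs)`` follow the transfer
function ``H = Abar^-1``, the model spectrum ``S = H Sigma H^H``, the
model-based coherency, and partial directed coherence

    pdc_ij(f) = Abar_ij(f) / sqrt(sum_k |Abar_kj(f)|^2),

the column-normalized, frequency-resolved Granger-causal outflow from
source channel j to target channel i.  An extended variant absorbs
instantaneous (lag-zero) correlations via a Cholesky factorization of
Sigma under a declared causal channel ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (DegenerateInputError, InvalidInputError,
                     InvalidParameterError, SingularFitError)
from .pairs import directed_pairs, pair_index_arrays, undirected_pairs
from .coherence import CoherencyMatrix, ConnectivitySpectra
from .preprocess import EnvelopeTrial


@dataclass
class MvarModel:
    """Fitted (or specified) MVAR model.

    ``A`` stacks the lagged coefficient matrices, shape (p, M, M) with
    ``A[k-1][i, j]`` the influence of channel j at lag k on channel i.
    ``B0``/``A_ext``/``resid_cov_ext`` are populated by
    :func:`identify_instantaneous` for the extended (instantaneous-effects)
    variant.
    """

    A: np.ndarray                      # (p, M, M)
    resid_cov: np.ndarray              # (M, M)
    fs: float
    n_samples: int = 0
    channel_labels: tuple[str, ...] = ()
    B0: np.ndarray | None = None       # (M, M), zero diagonal
    A_ext: np.ndarray | None = None    # (p, M, M) re-expressed lagged coefficients
    resid_cov_ext: np.ndarray | None = None
    ordering: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 3 or self.A.shape[1] != self.A.shape[2]:
            raise InvalidInputError("A must have shape (p, M, M)")
        self.resid_cov = np.asarray(self.resid_cov, dtype=float)
        if not np.allclose(self.resid_cov, self.resid_cov.T, atol=1e-10):
            raise InvalidInputError("residual covariance must be symmetric")
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{i}" for i in range(self.n_channels))

    @property
    def order(self) -> int:
        return self.A.shape[0]

    @property
    def n_channels(self) -> int:
        return self.A.shape[1]

    def companion(self) -> np.ndarray:
        p, M = self.order, self.n_channels
        C = np.zeros((p * M, p * M))
        C[:M, :] = np.concatenate(list(self.A), axis=1)
        if p > 1:
            C[M:, :-M] = np.eye((p - 1) * M)
        return C

    def is_stable(self) -> bool:
        return bool(np.max(np.abs(np.linalg.eigvals(self.companion()))) < 1.0)


def _as_array(data, fs: float | None) -> tuple[np.ndarray, float, tuple[str, ...]]:
    if isinstance(data, EnvelopeTrial):
        return np.asarray(data.samples, float), data.fs, tuple(data.channel_labels)
    x = np.asarray(data, dtype=float)
    if fs is None:
        raise InvalidParameterError("fs is required when passing a bare array")
    return x, fs, tuple(f"ch{i}" for i in range(x.shape[0]))


def _collinear_channels(x: np.ndarray, labels) -> list[str]:
    """Name zero-variance or exactly collinear channels for error messages."""
    bad: list[str] = []
    sd = x.std(axis=1)
    for i in np.flatnonzero(sd == 0):
        bad.append(labels[i])
    if np.all(sd > 0):
        c = np.corrcoef(x)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if abs(c[i, j]) > 1 - 1e-12:
                    bad.extend([labels[i], labels[j]])
    return sorted(set(bad))


def fit_mvar(data, p: int, fs: float | None = None) -> MvarModel:
    """Least-squares fit of a strictly causal VAR(p) to a conditioned trial."""
    x, fs, labels = _as_array(data, fs)
    M, N = x.shape
    if p < 1:
        raise InvalidParameterError("order p must be >= 1")
    if N <= p * M + p:
        raise InvalidParameterError(f"trial too short ({N} samples) for order {p}")
    # Stacked regression: rows t = p..N-1, regressors [y(t-1); ...; y(t-p)].
    Y = x[:, p:].T                                   # (N-p, M)
    Z = np.concatenate([x[:, p - k:N - k].T for k in range(1, p + 1)], axis=1)
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        bad = _collinear_channels(x, labels)
        raise SingularFitError(
            f"rank-deficient MVAR regression (rank {rank} < {Z.shape[1]}); "
            f"offending channels: {bad or 'unresolved'}"
        )
    B, *_ = np.linalg.lstsq(Z, Y, rcond=None)        # (p*M, M)
    resid = Y - Z @ B
    sigma = resid.T @ resid / (N - p)
    sigma = 0.5 * (sigma + sigma.T)
    A = np.stack([B[k * M:(k + 1) * M, :].T for k in range(p)])
    return MvarModel(A=A, resid_cov=sigma, fs=fs, n_samples=N,
                     channel_labels=labels)


def select_order_aic(data, p_max: int = 30, fs: float | None = None
                     ) -> tuple[int, np.ndarray]:
    """AIC-optimal model order and the full criterion curve over 1..p_max.

    ``AIC(p) = ln det(Sigma_p) + 2 p M^2 / N`` with M channels and N the
    number of regression samples at order p.
    """
    x, fs, _ = _as_array(data, fs)
    M, N = x.shape
    aic = np.full(p_max, np.nan)
    for p in range(1, p_max + 1):
        model = fit_mvar(x, p, fs=fs)
        sign, logdet = np.linalg.slogdet(model.resid_cov)
        if sign <= 0 or not np.isfinite(logdet):
            raise DegenerateInputError(
                f"degenerate residual covariance at order {p}"
            )
        aic[p - 1] = logdet + 2.0 * p * M * M / (N - p)
    return int(np.argmin(aic)) + 1, aic


def identify_instantaneous(model: MvarModel,
                           ordering: tuple[int, ...] | None = None) -> MvarModel:
    """Extend a strictly causal model with instantaneous (lag-zero) effects.

    Under the supplied causal ordering, the residual covariance is LDL-
    factorized (unit lower-triangular L, diagonal D), giving
    ``B0 = I - L^-1`` (zero diagonal, only "earlier" channels influence
    "later" ones instantaneously), re-expressed lagged coefficients
    ``A_ext_k = L^-1 A_k`` and a diagonal innovation covariance D.  The
    model-implied spectrum is unchanged by the choice of ordering.
    """
    M = model.n_channels
    if ordering is None:
        ordering = tuple(range(M))
    if sorted(ordering) != list(range(M)):
        raise InvalidParameterError(f"ordering must be a permutation of 0..{M - 1}")
    sigma = model.resid_cov
    eigmin = np.min(np.linalg.eigvalsh(0.5 * (sigma + sigma.T)))
    if eigmin <= 0:
        raise DegenerateInputError(
            f"residual covariance not positive definite (min eigenvalue {eigmin:.3g})"
        )
    P = np.eye(M)[list(ordering)]            # permutes channels into causal order
    C = np.linalg.cholesky(P @ sigma @ P.T)  # lower triangular
    d = np.diag(C)
    L_perm = C / d[None, :]                  # unit lower triangular
    L = P.T @ L_perm @ P                     # back to original channel indexing
    Linv = np.linalg.inv(L)
    B0 = np.eye(M) - Linv
    A_ext = np.einsum("ij,pjk->pik", Linv, model.A)
    D = np.diag(d ** 2)
    return MvarModel(A=model.A, resid_cov=model.resid_cov, fs=model.fs,
                     n_samples=model.n_samples,
                     channel_labels=model.channel_labels,
                     B0=B0, A_ext=A_ext,
                     resid_cov_ext=P.T @ D @ P, ordering=tuple(ordering))


def _abar(model: MvarModel, freqs: np.ndarray, extended: bool = False) -> np.ndarray:
    """``Abar(f) = I - sum_k A_k exp(-i 2 pi f k / fs)``, shape (n_f, M, M).

    With ``extended=True`` the instantaneous-adjusted coefficients are used:
    ``Abar_ext(f) = (I - B0) - sum_k A_ext_k exp(...)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    p, M = model.order, model.n_channels
    if extended:
        if model.B0 is None or model.A_ext is None:
            raise InvalidInputError("extended=True requires identify_instantaneous first")
        base = np.eye(M) - model.B0
        A = model.A_ext
    else:
        base = np.eye(M)
        A = model.A
    k = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * freqs[:, None] * k[None, :] / model.fs)  # (n_f, p)
    lagged = np.einsum("fk,kij->fij", phase, A)
    return base[None, :, :] - lagged


def model_spectrum(model: MvarModel, freqs: np.ndarray) -> np.ndarray:
    """Model-implied cross-spectral matrix S(f) = H Sigma H^H, (n_f, M, M)."""
    Ab = _abar(model, freqs, extended=False)
    H = np.linalg.inv(Ab)
    S = H @ model.resid_cov @ np.conj(np.swapaxes(H, -1, -2))
    return S


def model_coherency(model: MvarModel, freqs: np.ndarray) -> CoherencyMatrix:
    """Coherency between all unordered pairs from the fitted model spectrum."""
    if not model.is_stable():
        raise InvalidInputError("model is unstable; spectrum undefined")
    freqs = np.asarray(freqs, dtype=float)
    S = model_spectrum(model, freqs)
    diag = np.real(np.einsum("fii->fi", S))
    if np.any(diag <= 0):
        raise DegenerateInputError("zero diagonal spectral power")
    prs = undirected_pairs(model.n_channels)
    ia, ib = pair_index_arrays(prs)
    coh = S[:, ia, ib] / np.sqrt(diag[:, ia] * diag[:, ib])
    return CoherencyMatrix(values=coh.T, freqs=freqs, n_windows=0, pairs=prs,
                           channel_labels=model.channel_labels)


@dataclass
class PdcMatrix:
    """Complex partial directed coherence of one model/trial.

    ``full[i, j, f]`` is the PDC from source j to target i; ``values`` views
    the ordered off-diagonal pairs (source-major) as a pair x frequency array.
    """

    full: np.ndarray  # complex, (M, M, n_f)
    freqs: np.ndarray
    channel_labels: tuple[str, ...]
    subject: int = 0
    condition: str = ""
    trial: int = 0

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return directed_pairs(self.full.shape[0])

    @property
    def values(self) -> np.ndarray:
        src, tgt = pair_index_arrays(self.pairs)
        return self.full[tgt, src, :]


def model_pdc(model: MvarModel, freqs: np.ndarray, extended: bool = False) -> PdcMatrix:
    """Partial directed coherence ``pdc_ij(f)`` from the model coefficients.

    Column-normalized so that ``sum_i |pdc_ij(f)|^2 = 1`` for every source j
    and frequency, diagonal included.  ``extended=True`` uses the
    instantaneous-adjusted coefficients from :func:`identify_instantaneous`.
    """
    freqs = np.asarray(freqs, dtype=float)
    Ab = _abar(model, freqs, extended=extended)       # (n_f, M, M)
    colnorm = np.sqrt(np.sum(np.abs(Ab) ** 2, axis=1))  # (n_f, M) per source column
    if np.any(colnorm == 0):
        raise DegenerateInputError("all-zero Abar column; PDC normalization undefined")
    pdc = Ab / colnorm[:, None, :]
    return PdcMatrix(full=np.moveaxis(pdc, 0, -1), freqs=freqs,
                     channel_labels=model.channel_labels)


def pool_pdc(trials: list[PdcMatrix]) -> ConnectivitySpectra:
    """Average complex PDC across trials and square: directed spectra.

    Rows follow the ordered (source, target) pair list; the value for
    (j, i) is ``|mean_t pdc_ij|^2``.
    """
    if not trials:
        raise InvalidInputError("no trials to pool")
    first = trials[0]
    for t in trials[1:]:
        if t.full.shape != first.full.shape or not np.allclose(t.freqs, first.freqs):
            raise InvalidInputError("trials have mismatched frequency grids")
    mean_pdc = np.mean([t.values for t in trials], axis=0)
    return ConnectivitySpectra(
        values=np.abs(mean_pdc) ** 2, freqs=first.freqs.copy(),
        pairs=first.pairs, directed=True,
        channel_labels=first.channel_labels,
        subject=first.subject, condition=first.condition,
    )


def fit_trial_pdc(trial: EnvelopeTrial, order: int | str = "auto",
                  p_max: int = 30, freqs: np.ndarray | None = None,
                  extended: bool = False) -> tuple[PdcMatrix, MvarModel]:
    """Order selection + fit + PDC for one conditioned trial.

    Default frequency grid: 0-60 Hz in 0.5-Hz steps (fs = 200).
    """
    if freqs is None:
        freqs = np.arange(0.0, 60.0 + 1e-9, 0.5)
    if order == "auto":
        order, _ = select_order_aic(trial, p_max=p_max)
    model = fit_mvar(trial, int(order))
    if extended:
        model = identify_instantaneous(model)
    pdc = model_pdc(model, freqs, extended=extended)
    pdc.subject, pdc.condition, pdc.trial = trial.subject, trial.condition, trial.trial
    return pdc, model
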