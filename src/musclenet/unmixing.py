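"""NMF spectral unmixing of connectivity spectra into frequency components.

Connectivity spectra of all muscle pairs, conditions and subjects are
stacked into one nonnegative frequency x observation matrix V (0-60 Hz)
and factorized as V ~ W @ H by alternating least squares with nonnegativity
enforced by clipping.  The K columns of W are shared spectral signatures
(frequency components); the loadings H give each component's coupling
strength in every (pair, condition, subject) observation and reshape into
per-component weighted muscle networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coherence import ConnectivitySpectra
from .errors import DegenerateInputError, InvalidInputError, InvalidParameterError


@dataclass
class SpectraStack:
    """Stacked spectra: V (n_freqs x n_obs) with a (subject, condition, pair) index."""

    V: np.ndarray
    freqs: np.ndarray
    index: pd.DataFrame     # columns: subject, condition, source/node_a, target/node_b
    pairs: list[tuple[int, int]]
    directed: bool
    channel_labels: tuple[str, ...]

    @property
    def n_obs(self) -> int:
        return self.V.shape[1]


@dataclass
class NmfFactorization:
    """Result of a projected-ALS nonnegative factorization V ~ W @ H."""

    W: np.ndarray              # (n_freqs, K) basis (spectral signatures)
    H: np.ndarray              # (K, n_obs) loadings (coupling strengths)
    error_history: np.ndarray  # Frobenius error per recorded iteration
    n_iter: int
    restart_index: int
    converged: bool
    freqs: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.W.shape[1]

    @property
    def reconstruction_error(self) -> float:
        return float(self.error_history[-1])


@dataclass
class MuscleNetwork:
    """Weighted adjacency over muscles for one (component, condition, subject).

    For directed networks ``adjacency[s, t]`` is the weight of the edge
    s -> t; undirected adjacencies are symmetric.  Diagonal is zero.
    """

    adjacency: np.ndarray
    directed: bool
    channel_labels: tuple[str, ...]
    component: int = 0
    condition: str = ""
    subject: int = 0

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise InvalidInputError("adjacency must be square")
        if np.any(A < 0):
            raise InvalidInputError("network weights must be nonnegative")
        if np.any(np.diag(A) != 0):
            raise InvalidInputError("adjacency diagonal must be zero")
        if not self.directed and not np.allclose(A, A.T):
            raise InvalidInputError("undirected adjacency must be symmetric")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def stack_spectra(spectra: list[ConnectivitySpectra],
                  band: tuple[float, float] = (0.0, 60.0)) -> SpectraStack:
    """Stack spectra into V, columns ordered subject-major, then condition, then pair."""
    if not spectra:
        raise InvalidInputError("no spectra to stack")
    first = spectra[0]
    for sp in spectra:
        if not np.allclose(sp.freqs, first.freqs):
            raise InvalidInputError("spectra have mismatched frequency grids")
        if sp.pairs != first.pairs or sp.directed != first.directed:
            raise InvalidInputError("spectra have mismatched pair maps")
        if np.any(sp.values < 0):
            raise InvalidInputError("spectra must be nonnegative")
    keep = (first.freqs >= band[0]) & (first.freqs <= band[1])
    freqs = first.freqs[keep]
    conditions = list(dict.fromkeys(sp.condition for sp in spectra))
    by_cell = {(sp.subject, sp.condition): sp for sp in spectra}
    if len(by_cell) != len(spectra):
        raise InvalidInputError("duplicate (subject, condition) spectra")
    subjects = sorted({sp.subject for sp in spectra})
    for s in subjects:
        for c in conditions:
            if (s, c) not in by_cell:
                raise InvalidInputError(f"missing spectra for subject {s}, {c!r}")
    cols, rows = [], []
    a_name, b_name = ("source", "target") if first.directed else ("node_a", "node_b")
    for s in subjects:
        for c in conditions:
            sp = by_cell[(s, c)]
            for k, (a, b) in enumerate(sp.pairs):
                cols.append(sp.values[k, keep])
                rows.append({"subject": s, "condition": c, a_name: a, b_name: b})
    V = np.asarray(cols).T  # (n_freqs, n_obs)
    index = pd.DataFrame(rows)
    return SpectraStack(V=V, freqs=freqs, index=index, pairs=list(first.pairs),
                        directed=first.directed,
                        channel_labels=first.channel_labels)


def unstack_spectra(stack: SpectraStack) -> list[ConnectivitySpectra]:
    """Inverse of :func:`stack_spectra` (band-restricted grid)."""
    out = []
    n_pairs = len(stack.pairs)
    idx = stack.index
    for start in range(0, stack.n_obs, n_pairs):
        block = idx.iloc[start:start + n_pairs]
        out.append(ConnectivitySpectra(
            values=stack.V[:, start:start + n_pairs].T.copy(),
            freqs=stack.freqs.copy(), pairs=list(stack.pairs),
            directed=stack.directed, channel_labels=stack.channel_labels,
            subject=int(block.iloc[0]["subject"]),
            condition=str(block.iloc[0]["condition"]),
        ))
    return out


def _als_run(V: np.ndarray, K: int, tol: float, max_iter: int,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """One projected-ALS run from a random nonnegative initialization.

    The error curve is guaranteed non-increasing: an update that would
    increase the Frobenius error terminates the run with the previous
    factors.
    """
    m, n = V.shape
    W = rng.uniform(0.0, 1.0, size=(m, K)) * V.mean()
    H = np.empty((K, n))
    errors = [np.linalg.norm(V - W @ np.linalg.lstsq(W, V, rcond=None)[0].clip(min=0))]
    prev = (W.copy(), None)
    converged = False
    for _ in range(max_iter):
        H = np.linalg.lstsq(W, V, rcond=None)[0].clip(min=0)
        W = np.linalg.lstsq(H.T, V.T, rcond=None)[0].T.clip(min=0)
        err = np.linalg.norm(V - W @ H)
        if err > errors[-1] + 1e-15:
            W, H = prev  # revert: keep the recorded curve non-increasing
            converged = True
            break
        prev = (W.copy(), H.copy())
        rel_change = abs(errors[-1] - err) / max(errors[-1], 1e-300)
        errors.append(err)
        if rel_change < tol:
            converged = True
            break
    if prev[1] is None:  # max_iter == 0 edge case
        H = np.linalg.lstsq(W, V, rcond=None)[0].clip(min=0)
    else:
        W, H = prev
    return W, H, np.asarray(errors), converged


def nmf_als(V: np.ndarray, K: int = 4, tol: float = 1e-6, max_iter: int = 500,
            n_restarts: int = 10, seed: int | None = None) -> NmfFactorization:
    """Alternating-least-squares NMF, best of ``n_restarts`` by final error."""
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise InvalidInputError("V must be nonnegative")
    if not np.any(V > 0):
        raise DegenerateInputError("V is all zero; nothing to factorize")
    if K < 1 or K > min(V.shape):
        raise InvalidParameterError(
            f"K={K} outside 1..min(V.shape)={min(V.shape)}"
        )
    root = np.random.SeedSequence(seed)
    best = None
    for r, ss in enumerate(root.spawn(n_restarts)):
        W, H, errors, converged = _als_run(V, K, tol, max_iter,
                                           np.random.default_rng(ss))
        if best is None or errors[-1] < best.reconstruction_error:
            best = NmfFactorization(W=W, H=H, error_history=errors,
                                    n_iter=len(errors) - 1, restart_index=r,
                                    converged=converged)
    return best


def order_and_normalize(fact: NmfFactorization,
                        freqs: np.ndarray | None = None) -> NmfFactorization:
    """Resolve NMF scale/permutation ambiguity.

    W columns are scaled to unit Euclidean norm (compensated in H, product
    unchanged) and components sorted by ascending basis peak frequency.
    All-zero components are dropped with a warning.
    """
    if freqs is None:
        freqs = fact.freqs
    W, H = fact.W.copy(), fact.H.copy()
    norms = np.linalg.norm(W, axis=0)
    nonzero = norms > 0
    if not np.all(nonzero):
        warnings.warn(f"dropping {np.count_nonzero(~nonzero)} all-zero NMF "
                      "component(s)", stacklevel=2)
        W, H, norms = W[:, nonzero], H[nonzero], norms[nonzero]
    W = W / norms[None, :]
    H = H * norms[:, None]
    peak_bins = np.argmax(W, axis=0)
    if freqs is not None:
        order = np.argsort(np.asarray(freqs)[peak_bins], kind="stable")
    else:
        order = np.argsort(peak_bins, kind="stable")
    return NmfFactorization(W=W[:, order], H=H[order], error_history=fact.error_history,
                            n_iter=fact.n_iter, restart_index=fact.restart_index,
                            converged=fact.converged, freqs=freqs)


def basis_peak_freqs(fact: NmfFactorization) -> np.ndarray:
    """Peak frequency (Hz) of each basis column."""
    if fact.freqs is None:
        raise InvalidInputError("factorization carries no frequency grid")
    return np.asarray(fact.freqs)[np.argmax(fact.W, axis=0)]


def component_networks(fact: NmfFactorization, stack: SpectraStack
                       ) -> list[MuscleNetwork]:
    """Reshape loadings into one weighted muscle network per
    (component, condition, subject)."""
    if fact.H.shape[1] != stack.n_obs:
        raise InvalidInputError(
            f"loadings have {fact.H.shape[1]} observations but the stack index "
            f"has {stack.n_obs}"
        )
    n = len(stack.channel_labels)
    n_pairs = len(stack.pairs)
    networks = []
    for k in range(fact.K):
        for start in range(0, stack.n_obs, n_pairs):
            block = stack.index.iloc[start:start + n_pairs]
            A = np.zeros((n, n))
            for row, (a, b) in enumerate(stack.pairs):
                w = fact.H[k, start + row]
                if stack.directed:
                    A[a, b] = w
                else:
                    A[a, b] = A[b, a] = w
            networks.append(MuscleNetwork(
                adjacency=A, directed=stack.directed,
                channel_labels=stack.channel_labels, component=k,
                condition=str(block.iloc[0]["condition"]),
                subject=int(block.iloc[0]["subject"]),
            ))
    return networks


def scree(V: np.ndarray, k_values=range(1, 9), tol: float = 1e-6,
          max_iter: int = 500, n_restarts: int = 5,
          seed: int | None = None) -> pd.DataFrame:
    """Reconstruction error versus K — a diagnostic for choosing K."""
    rows = []
    for k in k_values:
        f = nmf_als(V, K=k, tol=tol, max_iter=max_iter,
                    n_restarts=n_restarts, seed=seed)
        rows.append({"K": k, "frobenius_error": f.reconstruction_error,
                     "relative_error": f.reconstruction_error / np.linalg.norm(V)})
    return pd.DataFrame(rows)
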