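"""Channel-pair enumeration shared by every connectivity stage.

Undirected pairs are the n*(n-1)/2 combinations (i, j) with i < j, row-major
over channel order (10 muscles -> 45 pairs).  Directed pairs are the n*(n-1)
ordered (source, target) combinations, source-major (10 muscles -> 90 pairs).
Every pair x frequency array in the package indexes its rows by these lists.
"""

from __future__ import annotations

import numpy as np


def undirected_pairs(n_channels: int) -> list[tuple[int, int]]:
    """Unordered channel pairs (i, j), i < j, in row-major order."""
    return [(i, j) for i in range(n_channels) for j in range(i + 1, n_channels)]


def directed_pairs(n_channels: int) -> list[tuple[int, int]]:
    """Ordered (source, target) channel pairs, source-major, diagonal excluded."""
    return [(s, t) for s in range(n_channels) for t in range(n_channels) if s != t]


def n_undirected(n_channels: int) -> int:
    return n_channels * (n_channels - 1) // 2


def n_directed(n_channels: int) -> int:
    return n_channels * (n_channels - 1)


def pair_index_arrays(pairs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Split a pair list into two integer index arrays (first, second)."""
    a = np.asarray([p[0] for p in pairs], dtype=int)
    b = np.asarray([p[1] for p in pairs], dtype=int)
    return a, b


def pair_labels(pairs, channel_labels) -> list[str]:
    return [f"{channel_labels[a]}-{channel_labels[b]}" for a, b in pairs]
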