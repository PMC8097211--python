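"""Shared helpers: RNG handling and permutation p-value conventions."""

from __future__ import annotations

import numpy as np


def check_rng(seed) -> np.random.Generator:
    """Coerce a seed / Generator into a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def plus_one_p(n_extreme: int, n_replicates: int) -> float:
    """Permutation p-value (b + 1) / (m + 1); never zero."""
    return (n_extreme + 1) / (n_replicates + 1)


def validate_distance_matrix(X, n: int | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("distance matrix must be square")
    if n is not None and X.shape[0] != n:
        raise ValueError(f"distance matrix has {X.shape[0]} rows, expected {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(X, X.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(X), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return X
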