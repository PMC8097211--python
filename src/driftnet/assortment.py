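"""Assortment of the binarized drift network by building.

The mixing matrix ``e`` gives the fraction of (directed) edges running from
building g to building h.  Newman's assortativity coefficient

    r = (Tr e - sum_g a_g b_g) / (1 - sum_g a_g b_g)

with ``a``/``b`` the row/column sums of ``e`` measures the excess of
within-building edges over the random-mixing expectation; its standard
deviation comes from a delete-one-edge jackknife.  For populations whose
buildings were not monitored simultaneously, a constrained destination
randomization conserves each nest's out-degree, restricts destinations to a
feasibility mask encoding which building pairs could have exchanged wasps,
and compares the observed Tr(e) to its null distribution.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._util import check_rng, plus_one_p

__all__ = [
    "mixing_matrix",
    "newman_r",
    "jackknife_sd",
    "ConstrainedTraceNull",
    "constrained_trace_null",
    "mask_from_group_pairs",
]


def _edges_from_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.diag(A).any():
        raise ValueError("self-loops are not meaningful here")
    return np.column_stack(np.nonzero(A != 0))


def mixing_matrix(A, labels, directed: bool = True) -> tuple[np.ndarray, list]:
    """Building-by-building edge fractions e (entries sum to 1)."""
    edges = _edges_from_adjacency(A)
    if len(edges) == 0:
        raise ValueError("network has no edges")
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    idx = {c: k for k, c in enumerate(classes)}
    e = np.zeros((len(classes), len(classes)))
    for i, j in edges:
        e[idx[labels[i]], idx[labels[j]]] += 1.0
        if not directed:
            e[idx[labels[j]], idx[labels[i]]] += 1.0
    e /= e.sum()
    return e, classes


def _r_from_e(e: np.ndarray, n_classes: int | None = None) -> float:
    a = e.sum(axis=1)
    b = e.sum(axis=0)
    ab = float(a @ b)
    if ab == 1.0:
        # all edges in one class-to-class cell; with a single label class r is
        # undefined, otherwise this is the degenerate perfectly assortative limit
        if n_classes is not None and n_classes > 1:
            return 1.0
        return float("nan")
    return (float(np.trace(e)) - ab) / (1.0 - ab)


def newman_r(A, labels, directed: bool = True) -> tuple[np.ndarray, float]:
    """Mixing matrix and Newman assortativity r of a binary network.

    Returns ``(e, r)``; r is NaN when only one label class carries edges.
    """
    e, _ = mixing_matrix(A, labels, directed=directed)
    return e, _r_from_e(e, n_classes=len(set(np.asarray(labels).tolist())))


def jackknife_sd(A, labels, directed: bool = True) -> tuple[float, float]:
    """Delete-one-edge jackknife sd of r, and z = r / sd.

    sd^2 = sum over edges of (r_without_edge - r)^2.  z is infinite when
    every deletion leaves r unchanged (e.g. a perfectly assortative network).
    """
    edges = _edges_from_adjacency(A)
    if len(edges) < 2:
        raise ValueError("jackknife needs at least 2 edges")
    _, r_full = newman_r(A, labels, directed=directed)
    if np.isnan(r_full):
        return float("nan"), float("nan")
    A = np.asarray(A).copy()
    devs = []
    for i, j in edges:
        saved = A[i, j]
        A[i, j] = 0
        _, r_minus = newman_r(A, labels, directed=directed)
        A[i, j] = saved
        devs.append((r_minus - r_full) ** 2)
    sd = float(np.sqrt(np.sum(devs)))
    z = r_full / sd if sd > 0 else float("inf") * np.sign(r_full)
    return sd, z


def mask_from_group_pairs(labels, allowed_pairs) -> np.ndarray:
    """Nest-level allowed-destination mask from permitted group pairs.

    ``allowed_pairs`` is an iterable of (source_group, destination_group);
    the returned boolean matrix permits nest i -> nest j when the pair of
    their groups is listed (self-edges always excluded).
    """
    labels = np.asarray(labels)
    allowed = set(map(tuple, allowed_pairs))
    n = len(labels)
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i != j and (labels[i], labels[j]) in allowed:
                mask[i, j] = True
    return mask


class ConstrainedTraceNull(BaseEstimator):
    """Out-degree-preserving destination randomization for Tr(e).

    Per replicate, each source nest's (binarized) out-edges are re-pointed
    to distinct destinations drawn uniformly from that nest's allowed set;
    the trace of the resulting mixing matrix is recorded.  The p-value is
    the plus-one fraction of replicates with trace >= observed.

    Parameters
    ----------
    n_replicates : int, default 4999
    seed : int or numpy Generator

    ``fit(A, labels, allowed=None)`` — ``allowed`` is a boolean nest-by-nest
    mask of permitted destinations (default: everything off-diagonal).
    Fitted attributes: ``e_``, ``observed_trace_``, ``null_mean_trace_``,
    ``p_value_``, ``r_``, ``n_replicates``-consistent ``null_traces_``.
    """

    def __init__(self, n_replicates: int = 4999, seed=None):
        self.n_replicates = n_replicates
        self.seed = seed

    def fit(self, A, labels, allowed=None):
        A = (np.asarray(A) != 0).astype(int)
        n = A.shape[0]
        labels = np.asarray(labels)
        if allowed is None:
            allowed = ~np.eye(n, dtype=bool)
        allowed = np.asarray(allowed, dtype=bool) & ~np.eye(n, dtype=bool)
        if (A.astype(bool) & ~allowed).any():
            i, j = np.argwhere(A.astype(bool) & ~allowed)[0]
            raise ValueError(f"observed edge {i}->{j} lies outside the allowed mask")

        degrees = A.sum(axis=1)
        n_allowed = allowed.sum(axis=1)
        if (degrees > n_allowed).any():
            i = int(np.argmax(degrees > n_allowed))
            raise ValueError(
                f"source {i} has out-degree {degrees[i]} but only "
                f"{n_allowed[i]} allowed destinations"
            )

        e, classes = mixing_matrix(A, labels)
        obs_trace = float(np.trace(e))
        rng = check_rng(self.seed)
        class_idx = {c: k for k, c in enumerate(classes)}
        lab_idx = np.array([class_idx[c] for c in labels])
        dests = [np.nonzero(allowed[i])[0] for i in range(n)]
        total_edges = int(degrees.sum())

        traces = np.empty(self.n_replicates)
        for rep in range(self.n_replicates):
            same = 0
            for i in np.nonzero(degrees)[0]:
                chosen = rng.choice(dests[i], size=int(degrees[i]), replace=False)
                same += int((lab_idx[chosen] == lab_idx[i]).sum())
            traces[rep] = same / total_edges
        self.e_ = e
        self.classes_ = classes
        self.observed_trace_ = obs_trace
        self.null_traces_ = traces
        self.null_mean_trace_ = float(traces.mean())
        self.p_value_ = plus_one_p(int((traces >= obs_trace).sum()), self.n_replicates)
        self.r_ = _r_from_e(e)
        return self


def constrained_trace_null(A, labels, allowed=None, n_replicates: int = 4999, seed=None) -> ConstrainedTraceNull:
    """Functional wrapper around :class:`ConstrainedTraceNull`."""
    return ConstrainedTraceNull(n_replicates=n_replicates, seed=seed).fit(A, labels, allowed)
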