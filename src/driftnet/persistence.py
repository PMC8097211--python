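"""Edge persistence across monitoring periods and its constrained null.

A directed dyad (donor nest -> recipient nest) is *present* in a period when
at least one unique wasp drifted along it.  Incidence counts the number of
periods a dyad is present; the recurrence table reports how many dyads reach
each incidence threshold (>=1, >=2, >=3, = all periods).

The null keeps, per period, (a) each donor's binarized out-degree and (b)
the period's totals of within- vs between-aggregation edges, while
re-drawing each donor's recipients uniformly without replacement from the
eligible nests.  Observed recurrence above the null indicates temporally
persistent dyad preferences; the transient ">=1" row is tested in the
opposite direction (fewer distinct dyads than the null implies recurrence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from ._util import check_rng, plus_one_p
from .ingest import DriftNetwork

__all__ = [
    "edge_incidence",
    "PersistenceNull",
    "persistence_null",
    "null_period_adjacency",
    "weight_by_persistence",
]


def _check_networks(networks: list[DriftNetwork]) -> list:
    if len(networks) < 2:
        raise ValueError("persistence needs at least 2 monitoring periods")
    nests = networks[0].nests
    for net in networks[1:]:
        if net.nests != nests:
            raise ValueError("all periods must share the same nest index")
    return nests


def edge_incidence(networks: list[DriftNetwork]) -> dict[tuple, int]:
    """Number of periods each directed dyad is present in (presence = O > 0).

    Only dyads seen in at least one period appear in the result.
    """
    nests = _check_networks(networks)
    counts = np.zeros_like(networks[0].O, dtype=int)
    for net in networks:
        counts += (net.O > 0).astype(int)
    out = {}
    for i, j in zip(*np.nonzero(counts)):
        out[(nests[i], nests[j])] = int(counts[i, j])
    return out


def _recurrence_counts(incidence_matrix: np.ndarray, n_periods: int) -> dict:
    return {
        **{f">={k}": int((incidence_matrix >= k).sum()) for k in range(1, n_periods)},
        f"={n_periods}": int((incidence_matrix == n_periods).sum()),
    }


def _deal_tokens(rng, degrees, cap_within, cap_between, total_within):
    """Split each donor's out-degree into within/between-aggregation edges.

    Deals a shuffled multiset of `total_within` within-tokens and the rest
    between-tokens across donors, then repairs capacity violations by
    swapping token types between donors.  Returns the within-edge count per
    donor; both period totals and per-donor degrees hold exactly.
    """
    donors = np.nonzero(degrees)[0]
    total = int(degrees.sum())
    total_between = total - total_within
    if total_within > int(np.minimum(degrees, cap_within)[donors].sum()):
        raise ValueError("infeasible within-aggregation edge total")
    if total_between > int(np.minimum(degrees, cap_between)[donors].sum()):
        raise ValueError("infeasible between-aggregation edge total")

    tokens = np.zeros(total, dtype=int)
    tokens[:total_within] = 1
    rng.shuffle(tokens)
    w = np.zeros(len(degrees), dtype=int)
    pos = 0
    for i in donors:
        d = int(degrees[i])
        w[i] = tokens[pos : pos + d].sum()
        pos += d
    # repair: donor i over its within capacity trades a within token with a
    # donor that can host one more; symmetrically for between capacity
    for _ in range(4 * total + 4):
        over_w = np.nonzero(w > np.minimum(degrees, cap_within))[0]
        over_b = np.nonzero((degrees - w) > np.minimum(degrees, cap_between))[0]
        if len(over_w) == 0 and len(over_b) == 0:
            break
        if len(over_w):
            i = over_w[0]
            cand = np.nonzero((w < np.minimum(degrees, cap_within)) & (degrees - w > 0))[0]
            j = rng.choice(cand)
            w[i] -= 1
            w[j] += 1
        if len(over_b):
            i = over_b[0]
            cand = np.nonzero(((degrees - w) < np.minimum(degrees, cap_between)) & (w > 0))[0]
            j = rng.choice(cand)
            w[i] += 1
            w[j] -= 1
    else:
        raise RuntimeError("could not repair token assignment to feasibility")
    return w


def null_period_adjacency(
    rng,
    degrees: np.ndarray,
    same_agg: np.ndarray,
    n_within: int,
    idx_within=None,
    idx_between=None,
) -> np.ndarray:
    """One null binary adjacency: out-degrees and the within/between split hold.

    ``same_agg`` is the boolean same-aggregation matrix (False diagonal);
    ``n_within`` the required number of within-aggregation edges.
    """
    n = len(degrees)
    diff_agg = ~same_agg & ~np.eye(n, dtype=bool)
    cap_within = same_agg.sum(axis=1)
    cap_between = diff_agg.sum(axis=1)
    if idx_within is None:
        idx_within = [np.nonzero(same_agg[i])[0] for i in range(n)]
    if idx_between is None:
        idx_between = [np.nonzero(diff_agg[i])[0] for i in range(n)]
    w = _deal_tokens(rng, degrees, cap_within, cap_between, n_within)
    A = np.zeros((n, n), dtype=int)
    for i in np.nonzero(degrees)[0]:
        nw, nb = int(w[i]), int(degrees[i] - w[i])
        if nw:
            A[i, rng.choice(idx_within[i], size=nw, replace=False)] = 1
        if nb:
            A[i, rng.choice(idx_between[i], size=nb, replace=False)] = 1
    return A


@dataclass
class RecurrenceTable:
    """Observed vs null edge recurrence per threshold."""

    observed: dict
    null_mean: dict = field(default_factory=dict)
    null_sd: dict = field(default_factory=dict)
    p_value: dict = field(default_factory=dict)
    n_replicates: int = 0
    seed: object = None


class PersistenceNull(BaseEstimator):
    """Destination-randomizing null for edge recurrence.

    Parameters
    ----------
    n_replicates : int, default 10000
    seed : int or numpy Generator

    ``fit(networks, aggregation_of)`` expects per-period
    :class:`~driftnet.ingest.DriftNetwork` objects sharing one nest index and
    a mapping nest -> aggregation label.  Fitted attributes:

    table_ : RecurrenceTable
        observed counts, null mean/sd and plus-one p per threshold; the
        ``>=1`` (transient) threshold is tested as P(null <= observed), all
        others as P(null >= observed).
    """

    def __init__(self, n_replicates: int = 10000, seed=None):
        self.n_replicates = n_replicates
        self.seed = seed

    def fit(self, networks: list[DriftNetwork], aggregation_of: dict):
        nests = _check_networks(networks)
        rng = check_rng(self.seed)
        n = len(nests)
        n_periods = len(networks)
        agg = np.array([aggregation_of[nest] for nest in nests])
        same_agg = agg[:, None] == agg[None, :]
        np.fill_diagonal(same_agg, False)
        diff_agg = agg[:, None] != agg[None, :]
        cap_within = same_agg.sum(axis=1)
        cap_between = diff_agg.sum(axis=1)

        per_period = []
        for net in networks:
            A = net.O > 0
            degrees = A.sum(axis=1)
            if (degrees > n - 1).any():
                bad = nests[int(np.argmax(degrees > n - 1))]
                raise ValueError(f"donor {bad} in period {net.period_id} has infeasible out-degree")
            per_period.append(
                {"degrees": degrees, "n_within": int(A[same_agg].sum()), "n_between": int(A[diff_agg].sum())}
            )

        obs_incidence = np.zeros((n, n), dtype=int)
        for net in networks:
            obs_incidence += (net.O > 0).astype(int)
        observed = _recurrence_counts(obs_incidence, n_periods)

        thresholds = list(observed)
        null_counts = {t: np.empty(self.n_replicates, dtype=int) for t in thresholds}
        idx_within = [np.nonzero(same_agg[i])[0] for i in range(n)]
        idx_between = [np.nonzero(diff_agg[i])[0] for i in range(n)]

        for rep in range(self.n_replicates):
            inc = np.zeros((n, n), dtype=int)
            for info in per_period:
                inc += null_period_adjacency(
                    rng, info["degrees"], same_agg, info["n_within"], idx_within, idx_between
                )
            counts = _recurrence_counts(inc, n_periods)
            for t in thresholds:
                null_counts[t][rep] = counts[t]

        table = RecurrenceTable(observed=observed, n_replicates=self.n_replicates, seed=self.seed)
        for t in thresholds:
            vals = null_counts[t]
            table.null_mean[t] = float(vals.mean())
            table.null_sd[t] = float(vals.std(ddof=1))
            if t == ">=1":  # transient direction: significantly FEWER distinct dyads
                extreme = int((vals <= observed[t]).sum())
            else:
                extreme = int((vals >= observed[t]).sum())
            table.p_value[t] = plus_one_p(extreme, self.n_replicates)
        self.table_ = table
        return self


def persistence_null(networks, aggregation_of, n_replicates: int = 10000, seed=None) -> RecurrenceTable:
    """Functional wrapper around :class:`PersistenceNull`."""
    est = PersistenceNull(n_replicates=n_replicates, seed=seed).fit(networks, aggregation_of)
    return est.table_


def weight_by_persistence(
    networks: list[DriftNetwork],
    incidence: dict | None = None,
    threshold: int = 2,
    n_replicates: int = 4999,
    seed=None,
) -> dict:
    """Compare per-period drift-event counts on persistent vs transient dyads.

    A dyad is *persistent* when its incidence reaches ``threshold`` periods,
    otherwise *transient*.  The samples are the nonzero per-period event
    counts (W matrix) of each group; significance is a rank-sum statistic
    with a label-shuffling permutation p (one-sided: persistent heavier).
    """
    nests = _check_networks(networks)
    if incidence is None:
        incidence = edge_incidence(networks)
    index = {nest: i for i, nest in enumerate(nests)}

    persistent_vals, transient_vals = [], []
    for (di, dj), inc in incidence.items():
        i, j = index[di], index[dj]
        weights = [int(net.W[i, j]) for net in networks if net.W[i, j] > 0]
        (persistent_vals if inc >= threshold else transient_vals).extend(weights)

    out = {
        "threshold": threshold,
        "n_persistent": len(persistent_vals),
        "n_transient": len(transient_vals),
    }
    if not persistent_vals or not transient_vals:
        out["flag"] = "one group empty; no test"
        return out

    a = np.asarray(persistent_vals, dtype=float)
    b = np.asarray(transient_vals, dtype=float)
    out["mean_persistent"] = float(a.mean())
    out["se_persistent"] = float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else float("nan")
    out["mean_transient"] = float(b.mean())
    out["se_transient"] = float(b.std(ddof=1) / np.sqrt(len(b))) if len(b) > 1 else float("nan")

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    w_obs = float(ranks[: len(a)].sum())
    rng = check_rng(seed)
    n_extreme = 0
    for _ in range(n_replicates):
        perm = rng.permutation(len(pooled))
        if ranks[perm[: len(a)]].sum() >= w_obs:
            n_extreme += 1
    out["rank_sum_W"] = w_obs
    out["p_value"] = plus_one_p(n_extreme, n_replicates)
    out["n_replicates"] = n_replicates
    return out
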