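"""Auxiliary permutation statistics on dyadic covariates.

Three tests the drifting analysis leans on: (1) the Spearman correlation of
inter-nest distance with pairwise relatedness, tested by permuting nest
identities within each aggregation (holding nest positions fixed, so the
dyadic dependence structure survives into the null); (2) a permuted rank-sum
comparison of relatedness between distance classes (nearer vs farther than a
threshold); (3) a Welch two-sample t-test of within- vs between-aggregation
distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import check_rng, plus_one_p, validate_distance_matrix

__all__ = ["PermTestResult", "spearman_block_perm", "ranksum_perm", "welch_t"]


@dataclass
class PermTestResult:
    statistic: str
    observed: float
    null_mean: float
    p_value: float
    n_replicates: int
    seed: object = None


def _upper_dyads(n: int, same_block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unordered within-block dyad indices (i < j)."""
    iu, ju = np.triu_indices(n, k=1)
    keep = same_block[iu, ju]
    return iu[keep], ju[keep]


def spearman_block_perm(
    X, r, blocks, n_replicates: int = 4999, seed=None
) -> PermTestResult:
    """Distance-relatedness Spearman correlation with a within-block null.

    ``X`` and ``r`` are nest-by-nest matrices; ``blocks`` assigns each nest
    (by position) to an aggregation.  Dyads are the unordered within-block
    pairs.  The null permutes nest identities within each block — rows and
    columns of the relatedness matrix move together while nest positions
    (hence distances) stay fixed — and the two-sided p uses the plus-one
    rule.
    """
    X = validate_distance_matrix(X)
    r = np.asarray(r, dtype=float)
    n = X.shape[0]
    if r.shape != (n, n):
        raise ValueError("relatedness matrix must match the distance matrix")
    blocks = np.asarray(blocks)
    same_block = blocks[:, None] == blocks[None, :]
    iu, ju = _upper_dyads(n, same_block)
    if len(iu) < 3:
        return PermTestResult("spearman_rho", float("nan"), float("nan"), float("nan"), 0, seed)

    x_vals = X[iu, ju]
    r_vals = r[iu, ju]
    if np.all(r_vals == r_vals[0]) or np.all(x_vals == x_vals[0]):
        return PermTestResult("spearman_rho", float("nan"), float("nan"), float("nan"), 0, seed)
    rho_obs = float(stats.spearmanr(x_vals, r_vals).statistic)

    rng = check_rng(seed)
    null = np.empty(n_replicates)
    members = [np.nonzero(blocks == b)[0] for b in np.unique(blocks)]
    for rep in range(n_replicates):
        perm = np.arange(n)
        for m in members:
            perm[m] = m[rng.permutation(len(m))]
        r_perm = r[np.ix_(perm, perm)]
        null[rep] = stats.spearmanr(x_vals, r_perm[iu, ju]).statistic
    n_extreme = int((np.abs(null) >= abs(rho_obs)).sum())
    return PermTestResult(
        "spearman_rho", rho_obs, float(np.nanmean(null)),
        plus_one_p(n_extreme, n_replicates), n_replicates, seed,
    )


def ranksum_perm(
    a, b, n_replicates: int = 4999, seed=None, alternative: str = "greater"
) -> PermTestResult:
    """Rank-sum statistic of group ``a`` with a label-shuffling null.

    W is the sum of midranks of ``a`` in the pooled sample.  ``alternative``
    is "greater", "less" or "two-sided"; the plus-one rule applies and the
    null mean of W is reported alongside.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    w_obs = float(ranks[: len(a)].sum())
    rng = check_rng(seed)
    null = np.empty(n_replicates)
    for rep in range(n_replicates):
        perm = rng.permutation(len(pooled))
        null[rep] = ranks[perm[: len(a)]].sum()
    if alternative == "greater":
        n_extreme = int((null >= w_obs).sum())
    elif alternative == "less":
        n_extreme = int((null <= w_obs).sum())
    elif alternative == "two-sided":
        centre = float(null.mean())
        n_extreme = int((np.abs(null - centre) >= abs(w_obs - centre)).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return PermTestResult(
        "rank_sum_W", w_obs, float(null.mean()),
        plus_one_p(n_extreme, n_replicates), n_replicates, seed,
    )


def welch_t(within, between) -> tuple[float, float, float]:
    """Welch (unequal-variance) two-sample t-test; returns (t, df, p).

    Used for within- vs between-aggregation nest distances; undefined (NaN)
    when both samples are constant.
    """
    within = np.asarray(within, dtype=float)
    between = np.asarray(between, dtype=float)
    if len(within) < 2 or len(between) < 2:
        raise ValueError("both samples need at least 2 values")
    if within.std() == 0 and between.std() == 0:
        return float("nan"), float("nan"), float("nan")
    res = stats.ttest_ind(within, between, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
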