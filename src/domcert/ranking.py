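"""Rank-order optimisation, rank distances and nonlinear rank tiers.

The dominance-probability matrix is reordered so that the sum of dp values
in the upper triangle — the total probability that higher-positioned animals
beat lower-positioned ones — is maximal. For small groups (n <= 8 by
default) the optimum is found by exhaustive permutation scan; larger groups
use restarted simulated annealing, which is checked against the exact search
on small instances in the test suite.

A linear order is not forced on the data: adjacent individuals whose
dominance probability stays below an ambiguity threshold (0.70 by default)
are merged into rank *tiers*, and an average-linkage tree over the rank
distance |2 dp - 1| provides the equivalent hierarchical-clustering view.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .conductance import DPMatrix
from .errors import InvalidParameterError

DEFAULT_EXACT_MAX_N = 8
DEFAULT_RESTARTS = 50
DEFAULT_COOLING = 0.97
DEFAULT_TIER_THRESHOLD = 0.70

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class RankOrder:
    """A permutation of ids (position 1 = top) with its upper-triangle score."""

    order: tuple[str, ...]
    score: float


@dataclass(frozen=True)
class RankOrderEnsemble:
    """Candidate orders from repeated searches plus the overall best."""

    orders: tuple[RankOrder, ...]
    best: RankOrder
    method: str  # "exact" | "annealed"
    seed: int | None = None
    restarts: int = 1


@dataclass(frozen=True)
class TierAssignment:
    """Contiguous rank tiers along the best order."""

    tiers: dict[str, int]
    threshold: float
    order: tuple[str, ...]


@dataclass(frozen=True)
class RankTree:
    """Average-linkage dendrogram over pairwise rank distances."""

    ids: tuple[str, ...]
    linkage_matrix: np.ndarray = field(repr=False)

    def cut(self, height: float) -> dict[str, int]:
        """Clusters obtained by cutting the tree at ``height``."""
        labels = fcluster(self.linkage_matrix, t=height, criterion="distance")
        return {i: int(c) for i, c in zip(self.ids, labels)}


def _as_index_order(dp: DPMatrix, order: tuple[str, ...] | list[str]) -> list[int]:
    if len(order) != dp.n or set(order) != set(dp.ids):
        raise InvalidParameterError("order must be a permutation of the matrix ids")
    return [dp.index_of(i) for i in order]


def order_score(dp: DPMatrix, order: tuple[str, ...] | list[str]) -> float:
    """Sum of dp(order[a], order[b]) over all positions a < b."""
    idx = _as_index_order(dp, order)
    sub = dp.dp[np.ix_(idx, idx)]
    return float(np.triu(sub, 1).sum())


def best_order_exact(dp: DPMatrix, max_n: int = DEFAULT_EXACT_MAX_N) -> RankOrder:
    """Global maximiser over all n! permutations.

    Permutations are scanned in lexicographic id order and only strict
    improvements are kept, so ties resolve to the lexicographically smallest
    id sequence.
    """
    if dp.n > max_n:
        raise InvalidParameterError(
            f"exact search limited to n <= {max_n} (got n = {dp.n}); "
            "use best_order_annealed"
        )
    mat = dp.dp
    index = {ind: k for k, ind in enumerate(dp.ids)}
    best_order: tuple[str, ...] | None = None
    best_score = -math.inf
    for perm in itertools.permutations(sorted(dp.ids)):
        idx = [index[i] for i in perm]
        score = float(np.triu(mat[np.ix_(idx, idx)], 1).sum())
        if score > best_score + _TIE_TOL:
            best_score = score
            best_order = perm
    assert best_order is not None
    return RankOrder(order=best_order, score=best_score)


def _rowsum_start(dp: DPMatrix) -> list[int]:
    """Start order: descending row sums of dp (ties by id)."""
    sums = np.nansum(dp.dp, axis=1)
    ranked = sorted(range(dp.n), key=lambda k: (-sums[k], dp.ids[k]))
    return ranked


def _pair_swap_delta(a: list[list[float]], perm: list[int], p: int, q: int) -> float:
    """Score change from swapping positions p < q of ``perm``."""
    x, y = perm[p], perm[q]
    d = a[y][x] - a[x][y]
    for m in perm[p + 1 : q]:
        d += a[m][x] - a[x][m] + a[y][m] - a[m][y]
    return d


def best_order_annealed(
    dp: DPMatrix,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    cooling: float = DEFAULT_COOLING,
    moves_per_temp: int | None = None,
    min_temp_fraction: float = 1e-3,
) -> RankOrderEnsemble:
    """Restarted simulated annealing over permutations.

    Each restart starts from the descending row-sum order, proposes adjacent
    transpositions or random pair swaps, accepts by the Metropolis rule under
    geometric cooling (initial temperature = standard deviation of sampled
    swap deltas), and tracks the best order seen. Fully deterministic for a
    given seed.
    """
    if restarts < 1:
        raise InvalidParameterError("restarts must be >= 1")
    if not 0.0 < cooling < 1.0:
        raise InvalidParameterError("cooling must be in (0, 1)")
    n = dp.n
    ids = dp.ids
    # nested lists with a zero diagonal: python-level lookups beat numpy
    # scalar indexing in the move loop
    a = np.nan_to_num(dp.dp, nan=0.0).tolist()
    start = _rowsum_start(dp)
    mpt = moves_per_temp if moves_per_temp is not None else n
    children = np.random.SeedSequence(seed).spawn(restarts)

    def exact_score(perm: list[int]) -> float:
        return float(
            sum(a[perm[i]][perm[j]] for i in range(n) for j in range(i + 1, n))
        )

    orders: list[RankOrder] = []
    for child in children:
        rng = np.random.default_rng(child)
        perm = list(start)
        cur = exact_score(perm)
        # temperature scale from the local score landscape at the start
        deltas = []
        for _ in range(max(20, 2 * n)):
            k = int(rng.integers(0, n - 1))
            x, y = perm[k], perm[k + 1]
            deltas.append(a[y][x] - a[x][y])
        t0 = float(np.std(deltas))
        if t0 <= 0.0:
            t0 = 1e-3
        t_min = t0 * min_temp_fraction
        best_perm = list(perm)
        best_score = cur
        temp = t0
        while temp > t_min:
            for _ in range(mpt):
                if rng.random() < 0.5:
                    k = int(rng.integers(0, n - 1))
                    x, y = perm[k], perm[k + 1]
                    delta = a[y][x] - a[x][y]
                    if delta > 0 or rng.random() < math.exp(delta / temp):
                        perm[k], perm[k + 1] = y, x
                        cur += delta
                else:
                    p = int(rng.integers(0, n))
                    q = int(rng.integers(0, n))
                    if p == q:
                        continue
                    if p > q:
                        p, q = q, p
                    delta = _pair_swap_delta(a, perm, p, q)
                    if delta > 0 or rng.random() < math.exp(delta / temp):
                        perm[p], perm[q] = perm[q], perm[p]
                        cur += delta
                if cur > best_score + _TIE_TOL:
                    best_score = cur
                    best_perm = list(perm)
            temp *= cooling
        score = exact_score(best_perm)  # re-derive: no accumulated drift
        orders.append(RankOrder(tuple(ids[k] for k in best_perm), score))

    best = orders[0]
    for cand in orders[1:]:
        if cand.score > best.score + _TIE_TOL:
            best = cand
        elif abs(cand.score - best.score) <= _TIE_TOL and cand.order < best.order:
            best = cand
    return RankOrderEnsemble(
        orders=tuple(orders),
        best=best,
        method="annealed",
        seed=seed,
        restarts=restarts,
    )


def find_best_order(
    dp: DPMatrix,
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> RankOrderEnsemble:
    """Exact search when feasible, annealing otherwise."""
    if dp.n <= exact_max_n:
        best = best_order_exact(dp, max_n=exact_max_n)
        return RankOrderEnsemble(
            orders=(best,), best=best, method="exact", seed=seed, restarts=1
        )
    return best_order_annealed(dp, restarts=restarts, seed=seed)


def rank_distance(dp: DPMatrix, i: str, j: str) -> float:
    """|2 dp(i,j) - 1|: 0 for a fully ambiguous dyad, 1 for a fully decided
    one. Symmetric because dp(i,j) + dp(j,i) = 1."""
    if i == j:
        raise InvalidParameterError("rank distance requires two distinct ids")
    return abs(2.0 * dp.value(i, j) - 1.0)


def rank_distance_matrix(dp: DPMatrix) -> np.ndarray:
    d = np.abs(2.0 * dp.dp - 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def build_rank_tree(dp: DPMatrix) -> RankTree:
    """Average-linkage agglomerative tree on the rank-distance matrix.

    Individuals that merge low in the tree have ambiguous relationships;
    cutting at a height h yields candidate rank tiers.
    """
    d = rank_distance_matrix(dp)
    condensed = squareform(d, checks=False)
    z = linkage(condensed, method="average")
    return RankTree(ids=dp.ids, linkage_matrix=z)


def rank_tiers(
    dp: DPMatrix,
    best: RankOrder,
    threshold: float = DEFAULT_TIER_THRESHOLD,
) -> TierAssignment:
    """Contiguous rank tiers along the best order.

    Scanning top-down, adjacent individuals whose dominance probability
    (higher-positioned over lower) stays below ``threshold`` are merged into
    the same tier.
    """
    if not 0.5 < threshold <= 1.0:
        raise InvalidParameterError("tier threshold must be in (0.5, 1]")
    order = best.order
    if set(order) != set(dp.ids):
        raise InvalidParameterError("order must be a permutation of the matrix ids")
    tiers: dict[str, int] = {order[0]: 1}
    tier = 1
    for upper, lower in zip(order[:-1], order[1:]):
        if dp.value(upper, lower) >= threshold:
            tier += 1
        tiers[lower] = tier
    return TierAssignment(tiers=tiers, threshold=float(threshold), order=order)
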