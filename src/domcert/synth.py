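"""Synthetic agonistic datasets with known ground truth.

``simulate_group`` draws win/loss matrices from a latent linear hierarchy:
every individual holds a true rank, each dyad either never interacts (a
structural zero, standing in for socio-demographic or ecological barriers)
or meets a Poisson number of times, and each encounter is won by the
higher-ranked member with a logistic probability in the rank difference.
Two parameters carry the biology: the steepness ``a`` (how sharply win
probability favours the higher-ranked member as rank distance grows; a = 0
is a fair coin, large a makes every encounter deterministic) and the
structural-zero fraction ``z`` (sparsity of the observed matrix).

Default parameters (a = 2, lambda = 10, z = 0.3) describe a steep,
moderately sparse hierarchy of the kind reported for despotic macaque
groups, and are the study conditions used throughout the test suite.

The module also builds three fixed topologies used as analytic fixtures:
a linear chain, a directed cycle, and a two-motif network contrasting
consistent with contradictory indirect dominance pathways.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .io_formats import WinLossMatrix

DEFAULT_STEEPNESS = 2.0
DEFAULT_ENCOUNTER_RATE = 10.0
DEFAULT_ZERO_FRACTION = 0.3


@dataclass(frozen=True)
class SimulatedGroup:
    """A simulated win/loss matrix plus its latent ground truth."""

    matrix: WinLossMatrix
    latent_ranks: dict[str, int]  # 1 = top
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def rank_vector(self) -> np.ndarray:
        """Latent ranks in matrix id order."""
        return np.array([self.latent_ranks[i] for i in self.matrix.ids])


def default_ids(n: int) -> tuple[str, ...]:
    """A, B, C, ... for n <= 26, else I01, I02, ..."""
    if n <= 26:
        return tuple(string.ascii_uppercase[:n])
    width = len(str(n))
    return tuple(f"I{k:0{width}d}" for k in range(1, n + 1))


def simulate_group(
    n: int,
    steepness: float = DEFAULT_STEEPNESS,
    encounter_rate: float = DEFAULT_ENCOUNTER_RATE,
    zero_fraction: float = DEFAULT_ZERO_FRACTION,
    seed: int | None = None,
) -> SimulatedGroup:
    """Draw a win/loss matrix from a latent linear hierarchy.

    Each unordered dyad is a structural zero with probability
    ``zero_fraction``, otherwise interacts Poisson(``encounter_rate``)
    times; each encounter is won by the higher-ranked member with
    probability 1 / (1 + exp(-steepness * rank_difference)). Latent ranks
    are a seeded random permutation of the ids, so recovering them from the
    matrix is a genuine inference task. Identical seeds reproduce identical
    groups bit for bit.
    """
    if n < 3:
        raise InvalidParameterError("simulate_group requires n >= 3")
    if steepness < 0:
        raise InvalidParameterError("steepness must be >= 0")
    if not encounter_rate > 0:
        raise InvalidParameterError("encounter_rate must be > 0")
    if not 0.0 <= zero_fraction < 1.0:
        raise InvalidParameterError("zero_fraction must be in [0, 1)")

    rng = np.random.default_rng(seed)
    ids = default_ids(n)
    ranks = rng.permutation(n) + 1  # ranks[k] = latent rank of ids[k]
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < zero_fraction:
                continue
            k = int(rng.poisson(encounter_rate))
            if k == 0:
                continue
            hi, lo = (i, j) if ranks[i] < ranks[j] else (j, i)
            delta = abs(int(ranks[i]) - int(ranks[j]))
            p_hi = 1.0 / (1.0 + np.exp(-steepness * delta))
            wins_hi = int(rng.binomial(k, p_hi))
            counts[hi, lo] += wins_hi
            counts[lo, hi] += k - wins_hi

    return SimulatedGroup(
        matrix=WinLossMatrix(ids, counts),
        latent_ranks={ids[k]: int(ranks[k]) for k in range(n)},
        params={
            "n": n,
            "steepness": steepness,
            "encounter_rate": encounter_rate,
            "zero_fraction": zero_fraction,
        },
        seed=seed,
    )


def linear_chain(n: int, m: int = 1) -> WinLossMatrix:
    """Chain i -> i+1 with m wins each and nothing else: the canonical
    sparse-but-orderable input (most dyads never interact, yet indirect
    pathways fully order the group)."""
    if n < 2:
        raise InvalidParameterError("linear_chain requires n >= 2")
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    ids = default_ids(n)
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        counts[i, i + 1] = m
    return WinLossMatrix(ids, counts)


def cycle_network(n: int, m: int = 1) -> WinLossMatrix:
    """Directed cycle 1 -> 2 -> ... -> n -> 1 with m wins per edge: pure
    circular dominance flow carrying no orderable information."""
    if n < 3:
        raise InvalidParameterError("cycle_network requires n >= 3")
    if m < 1:
        raise InvalidParameterError("m must be >= 1")
    ids = default_ids(n)
    counts = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        counts[i, (i + 1) % n] = m
    return WinLossMatrix(ids, counts)


#: Edges of the two demonstration motifs (all single wins).
_MOTIF_EDGES = (
    # consistent motif: A dominates D through two independent pathways
    # (A -> E -> D and A -> B -> D) without any direct A-D encounter
    ("A", "E"),
    ("E", "D"),
    ("A", "B"),
    ("B", "D"),
    # contradictory motif: the short path I -> J -> F says I over F, while
    # the longer chain F -> G -> H -> I carries dominance the opposite way
    ("I", "J"),
    ("J", "F"),
    ("F", "G"),
    ("G", "H"),
    ("H", "I"),
)


def pathway_motifs() -> WinLossMatrix:
    """Two disconnected motifs contrasting consistent and contradictory
    indirect dominance pathways.

    In the first motif A and D never interact, but two pathways flow the
    same way, so dp(A, D) > 0.5 with high certainty. In the second, F and I
    never interact and the evidence conflicts: I outranks F through J while
    the F -> G -> H -> I chain pushes the other way, so DC(F, I) stays low.
    All counts are 1 (single observed encounters); the second pathway of the
    first motif runs through the auxiliary individual B.
    """
    ids = tuple(sorted({x for e in _MOTIF_EDGES for x in e}))
    index = {ind: k for k, ind in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
    for winner, loser in _MOTIF_EDGES:
        counts[index[winner], index[loser]] = 1
    return WinLossMatrix(ids, counts)
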