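"""Directed dominance network, triangle census and indirect-path enumeration.

The dominance network has one directed edge per strictly positive win count
(both directions of a dyad may coexist). Directed transitivity — the
proportion of fully decided node triples whose dominance directions form a
transitive rather than cyclic pattern — measures how much hierarchical
information indirect pathways carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import InvalidParameterError, UnknownIndividualError
from .io_formats import WinLossMatrix

#: Default maximum indirect-path length (number of edges).
DEFAULT_MAX_PATH_LENGTH = 2

#: Longest supported path length; enumeration is exponential beyond this.
MAX_SUPPORTED_PATH_LENGTH = 6

#: Transitivity to assume when no node triple is fully decided. In sparse,
#: chain-like networks no closed triangle exists at all, so no intransitivity
#: has been observed; a default of 1 keeps indirect chains informative.
DEFAULT_TRANSITIVITY = 1.0


@dataclass(frozen=True)
class DominanceNetwork:
    """Directed multigraph view of a win/loss matrix."""

    ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)
    graph: nx.DiGraph = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, individual: str) -> int:
        try:
            return self.ids.index(individual)
        except ValueError:
            raise UnknownIndividualError(f"unknown individual {individual!r}") from None


@dataclass(frozen=True)
class TriangleCensus:
    """Counts of decided triples in transitive vs cyclic configuration."""

    transitive: int
    intransitive: int


@dataclass(frozen=True)
class PathSet:
    """All simple directed paths from source to target, grouped by length."""

    source: str
    target: str
    by_length: dict[int, tuple[tuple[str, ...], ...]]
    max_length: int

    def all_paths(self) -> tuple[tuple[str, ...], ...]:
        out: list[tuple[str, ...]] = []
        for length in sorted(self.by_length):
            out.extend(self.by_length[length])
        return tuple(out)

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_length.values())


def build_network(matrix: WinLossMatrix) -> DominanceNetwork:
    """One edge per strictly positive cell, weight = win count; isolated
    individuals remain as nodes."""
    g = nx.DiGraph()
    g.add_nodes_from(matrix.ids)
    counts = matrix.counts
    for i, winner in enumerate(matrix.ids):
        for j, loser in enumerate(matrix.ids):
            if counts[i, j] > 0:
                g.add_edge(winner, loser, weight=int(counts[i, j]))
    return DominanceNetwork(matrix.ids, counts, g)


def binarize_directions(counts: np.ndarray) -> np.ndarray:
    """Majority-count dominance direction: D[i, j] = 1 iff c(i,j) > c(j,i).

    Ties (including 0-0 dyads) leave both directions 0 (undecided), so D
    never contains mutual edges.
    """
    return (counts > counts.T).astype(np.int64)


def triad_census(net: DominanceNetwork) -> TriangleCensus:
    """Census of node triples whose three dyads are all majority-decided.

    On the binarized adjacency D (no mutual edges) a fully decided triple has
    exactly three edges: transitive patterns are 2-paths closed by an edge in
    the same direction (sum of D ∘ D²), cyclic patterns are directed
    3-cycles (tr(D³)/3).
    """
    d = binarize_directions(net.counts)
    p2 = d @ d
    transitive = int(np.sum(d * p2))
    intransitive = int(np.trace(p2 @ d)) // 3
    return TriangleCensus(transitive=transitive, intransitive=intransitive)


def transitivity_index(
    census: TriangleCensus, default_t: float = DEFAULT_TRANSITIVITY
) -> float:
    """Proportion of decided triples that are transitive; ``default_t`` when
    no triple is fully decided."""
    total = census.transitive + census.intransitive
    if total == 0:
        return float(default_t)
    return census.transitive / total


def enumerate_paths(
    net: DominanceNetwork,
    source: str,
    target: str,
    max_length: int = DEFAULT_MAX_PATH_LENGTH,
) -> PathSet:
    """All simple directed paths of length 2..max_length from source to target.

    Length counts edges; direct edges (length 1) are excluded — they carry
    observed wins, not indirect information.
    """
    for who in (source, target):
        if who not in net.graph:
            raise UnknownIndividualError(f"unknown individual {who!r}")
    if source == target:
        raise InvalidParameterError("source and target must differ")
    if max_length < 2:
        raise InvalidParameterError("max_length must be >= 2")
    by_length: dict[int, list[tuple[str, ...]]] = {}
    for path in nx.all_simple_paths(net.graph, source, target, cutoff=max_length):
        length = len(path) - 1
        if length >= 2:
            by_length.setdefault(length, []).append(tuple(path))
    frozen = {k: tuple(sorted(v)) for k, v in sorted(by_length.items())}
    return PathSet(source=source, target=target, by_length=frozen, max_length=max_length)
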