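"""Transitivity-weighted evidence imputation and dominance probabilities.

Direct wins alone leave never-interacting dyads undecided. Indirect directed
pathways (i beats k, k beats j) carry dominance information whose reliability
depends on how transitive the network is as a whole: in a highly transitive
network a chain of wins is strong evidence that its endpoints are ordered,
while in a network full of circular pathways chains carry almost none.

Each simple path i -> ... -> j of length l contributes a *fractional win*

    w(path) = beta**(l - 1) * prod_e f(e),      beta = max(0, 2 t - 1),

where t is the directed transitivity and f(e) = c(e) / (c(e) + c(reverse e))
is the directional consistency of each traversed edge. The geometric factor
discounts longer chains; the consistency product discounts chains built on
contested dyads; each path contributes at most one win. At t = 0.5 (as many
cyclic as transitive triangles) beta = 0 and indirect information is fully
discounted; at t = 1 every path counts at full consistency weight.

Summed fractional wins plus direct wins give an evidence matrix, converted
to a dominance probability with a symmetric smoothing prior s (pseudo-wins
per direction):

    dp(i, j) = (e(i, j) + s) / (e(i, j) + e(j, i) + 2 s),

so dp(i, j) + dp(j, i) = 1 and a dyad with no evidence in either direction
sits exactly at 0.5 (fully ambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import InvalidParameterError, UnknownIndividualError
from .network import DEFAULT_MAX_PATH_LENGTH, DominanceNetwork

#: Default smoothing prior: half a pseudo-win per direction (Jeffreys-style),
#: which pins zero-evidence dyads at dp = 0.5.
DEFAULT_PRIOR = 0.5


@dataclass(frozen=True)
class EvidenceMatrix:
    """Direct wins plus summed fractional imputed wins, per ordered pair."""

    ids: tuple[str, ...]
    evidence: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class DPMatrix:
    """Pairwise dominance probabilities; dp(i,j) + dp(j,i) = 1, diagonal NaN."""

    ids: tuple[str, ...]
    dp: np.ndarray = field(repr=False)
    prior: float = DEFAULT_PRIOR

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, individual: str) -> int:
        try:
            return self.ids.index(individual)
        except ValueError:
            raise UnknownIndividualError(f"unknown individual {individual!r}") from None

    def value(self, i: str, j: str) -> float:
        return float(self.dp[self.index_of(i), self.index_of(j)])


def path_weight(t: float, length: int) -> float:
    """Weight of a single indirect path of ``length`` edges at transitivity t.

    beta**(length - 1) with beta = max(0, 2 t - 1): nondecreasing in t,
    nonincreasing in length, zero whenever t <= 0.5.
    """
    if length < 2:
        raise InvalidParameterError("indirect paths have length >= 2")
    beta = max(0.0, 2.0 * float(t) - 1.0)
    return beta ** (length - 1)


def edge_consistency(counts: np.ndarray) -> np.ndarray:
    """f(i,j) = c(i,j) / (c(i,j) + c(j,i)); zero where the dyad never interacts."""
    totals = counts + counts.T
    out = np.zeros(counts.shape, dtype=float)
    np.divide(counts, totals, out=out, where=totals > 0)
    return out


def impute_evidence(
    net: DominanceNetwork,
    max_length: int = DEFAULT_MAX_PATH_LENGTH,
    t: float = 1.0,
) -> EvidenceMatrix:
    """Evidence matrix: direct wins plus weighted fractional wins from all
    simple directed paths of length 2..max_length.

    With max_length = 1 (or beta = 0) the evidence equals the raw counts.
    """
    counts = net.counts
    evidence = counts.astype(float).copy()
    beta = max(0.0, 2.0 * float(t) - 1.0)
    if max_length >= 2 and beta > 0.0:
        f = edge_consistency(counts)
        index = {ind: k for k, ind in enumerate(net.ids)}
        g = net.graph
        for source in net.ids:
            si = index[source]
            for target in net.ids:
                if target == source:
                    continue
                ti = index[target]
                total = 0.0
                for path in nx.all_simple_paths(g, source, target, cutoff=max_length):
                    length = len(path) - 1
                    if length < 2:
                        continue
                    w = beta ** (length - 1)
                    for a, b in zip(path[:-1], path[1:]):
                        w *= f[index[a], index[b]]
                    total += w
                evidence[si, ti] += total
    return EvidenceMatrix(net.ids, evidence)


def dominance_probability(
    ev: EvidenceMatrix, prior: float = DEFAULT_PRIOR
) -> DPMatrix:
    """Smoothed two-sided win proportion per dyad; diagonal is masked NaN."""
    if not prior > 0:
        raise InvalidParameterError("prior must be > 0")
    e = ev.evidence
    dp = (e + prior) / (e + e.T + 2.0 * prior)
    np.fill_diagonal(dp, np.nan)
    return DPMatrix(ev.ids, dp, prior=float(prior))
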