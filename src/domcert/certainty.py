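"""Dominance certainty at the dyadic, individual and group level.

Dominance certainty (DC) measures the degree to which status is decided,
independently of who wins: DC(i, j) = max(dp(i, j), dp(j, i)) lies in
[0.5, 1], with 0.5 meaning a fully ambiguous relationship and 1 a fully
decided one. An individual's DC is the mean certainty across all of its
pairwise relationships (including never-interacting partners, whose dp is
inferred through indirect pathways); group DC is the mean of individual
DCs, which equals the mean over unordered dyads.

Low certainty can be *inferential* (too little data: sparse observation,
few indirect pathways, or low transitivity making pathways uninformative)
or *biological* (animals genuinely avoid interacting or hold unresolved
relationships). ``certainty_diagnostics`` separates the two readings by
comparing the distribution of indirect-path counts across interacting and
non-interacting dyads: when transitivity is high and non-interacting dyads
still sit on abundant pathways, their (un)certainty is informed by data and
is read as biological; when transitivity is low or pathways are scarce, it
is read as inferential.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .conductance import DPMatrix
from .errors import InvalidParameterError
from .network import (
    DEFAULT_MAX_PATH_LENGTH,
    DEFAULT_TRANSITIVITY,
    DominanceNetwork,
    enumerate_paths,
    transitivity_index,
    triad_census,
)

#: Transitivity at or above which indirect paths are considered reliable
#: enough that certainty among non-interacting dyads reflects biology.
DEFAULT_HIGH_TRANSITIVITY = 0.9

#: Non-interacting dyads count as path-rich when their median total
#: indirect-path count reaches this value.
DEFAULT_MIN_MEDIAN_PATHS = 1.0

FLAG_BIOLOGICAL = "likely biological"
FLAG_INFERENTIAL = "likely inferential"
FLAG_ALL_INTERACTING = "all dyads interact; no non-interacting class"


@dataclass(frozen=True)
class CertaintyReport:
    """DC at all three levels plus the transitivity and path diagnostics."""

    ids: tuple[str, ...]
    dp: DPMatrix
    dyadic_dc: np.ndarray = field(repr=False)
    individual_dc: np.ndarray = field(repr=False)
    group_dc: float = 0.5
    transitivity: float = DEFAULT_TRANSITIVITY
    diagnostics: dict | None = None
    params: dict = field(default_factory=dict)

    def individual(self, i: str) -> float:
        return float(self.individual_dc[self.dp.index_of(i)])

    def dyadic(self, i: str, j: str) -> float:
        return float(self.dyadic_dc[self.dp.index_of(i), self.dp.index_of(j)])


def dyadic_certainty(dp: DPMatrix) -> np.ndarray:
    """DC(i, j) = max(dp(i, j), dp(j, i)); symmetric, diagonal NaN."""
    return np.fmax(dp.dp, dp.dp.T)


def individual_certainty(dyadic_dc: np.ndarray) -> np.ndarray:
    """Mean certainty across all of an individual's pairwise relationships."""
    if dyadic_dc.shape[0] < 2:
        raise InvalidParameterError("individual certainty requires n >= 2")
    return np.nanmean(dyadic_dc, axis=1)


def group_certainty(individual_dc: np.ndarray) -> float:
    """Group-level DC: the average of individual DCs."""
    if len(individual_dc) == 0:
        raise InvalidParameterError("group certainty requires at least one individual")
    return float(np.mean(individual_dc))


def _distribution(values: list[int]) -> dict:
    arr = np.asarray(values, dtype=float)
    return {
        "n_dyads": int(arr.size),
        "min": float(arr.min()),
        "q1": float(np.percentile(arr, 25)),
        "median": float(np.median(arr)),
        "q3": float(np.percentile(arr, 75)),
        "mean": float(arr.mean()),
        "max": float(arr.max()),
    }


def certainty_diagnostics(
    net: DominanceNetwork,
    max_length: int = DEFAULT_MAX_PATH_LENGTH,
    high_transitivity: float = DEFAULT_HIGH_TRANSITIVITY,
    min_median_paths: float = DEFAULT_MIN_MEDIAN_PATHS,
    default_t: float = DEFAULT_TRANSITIVITY,
) -> dict:
    """Inferential-vs-biological uncertainty diagnostic.

    Classifies every unordered dyad as interacting (any observed encounter)
    or non-interacting, summarises the distribution of total indirect-path
    counts (both directions, lengths 2..max_length) per class, and emits a
    plain-language flag. Thresholds are reported alongside the flag, never
    applied silently.
    """
    if max_length < 2:
        raise InvalidParameterError("max_length must be >= 2")
    counts = net.counts
    interacting: list[int] = []
    non_interacting: list[int] = []
    for i, j in itertools.combinations(range(net.n), 2):
        a, b = net.ids[i], net.ids[j]
        n_paths = len(enumerate_paths(net, a, b, max_length)) + len(
            enumerate_paths(net, b, a, max_length)
        )
        if counts[i, j] + counts[j, i] > 0:
            interacting.append(n_paths)
        else:
            non_interacting.append(n_paths)

    t = transitivity_index(triad_census(net), default_t=default_t)
    out: dict = {
        "transitivity": t,
        "max_path_length": max_length,
        "thresholds": {
            "high_transitivity": high_transitivity,
            "min_median_paths": min_median_paths,
        },
        "interacting": _distribution(interacting) if interacting else None,
        "non_interacting": _distribution(non_interacting) if non_interacting else None,
    }
    if not non_interacting:
        out["flag"] = FLAG_ALL_INTERACTING
        out["note"] = (
            "every dyad was observed to interact; certainty is grounded in "
            "direct data"
        )
    elif (
        t >= high_transitivity
        and out["non_interacting"]["median"] >= min_median_paths
    ):
        out["flag"] = FLAG_BIOLOGICAL
        out["note"] = (
            "transitivity is high and non-interacting dyads sit on abundant "
            "indirect pathways: low certainty among them likely reflects "
            "genuinely undecided or avoided relationships"
        )
    else:
        out["flag"] = FLAG_INFERENTIAL
        out["note"] = (
            "transitivity is low or indirect pathways are scarce: low "
            "certainty likely reflects lack of information rather than "
            "biology"
        )
    return out


def build_report(
    dp: DPMatrix,
    transitivity: float,
    diagnostics: dict | None = None,
    params: dict | None = None,
) -> CertaintyReport:
    """Assemble the full certainty report from a dominance-probability matrix."""
    dyadic = dyadic_certainty(dp)
    individual = individual_certainty(dyadic)
    group = group_certainty(individual)
    return CertaintyReport(
        ids=dp.ids,
        dp=dp,
        dyadic_dc=dyadic,
        individual_dc=individual,
        group_dc=group,
        transitivity=float(transitivity),
        diagnostics=diagnostics,
        params=dict(params or {}),
    )
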