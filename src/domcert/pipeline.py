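"""End-to-end analysis: matrix -> network -> evidence -> dp -> order -> tiers -> DC."""

from __future__ import annotations

from dataclasses import dataclass, field

from . import certainty as cert
from .conductance import (
    DEFAULT_PRIOR,
    DPMatrix,
    EvidenceMatrix,
    dominance_probability,
    impute_evidence,
)
from .io_formats import WinLossMatrix
from .network import (
    DEFAULT_MAX_PATH_LENGTH,
    DEFAULT_TRANSITIVITY,
    DominanceNetwork,
    TriangleCensus,
    build_network,
    transitivity_index,
    triad_census,
)
from .ranking import (
    DEFAULT_EXACT_MAX_N,
    DEFAULT_RESTARTS,
    DEFAULT_TIER_THRESHOLD,
    RankOrderEnsemble,
    RankTree,
    TierAssignment,
    build_rank_tree,
    find_best_order,
    rank_tiers,
)


@dataclass(frozen=True)
class AnalysisResult:
    """Everything one run of the pipeline computes."""

    matrix: WinLossMatrix
    network: DominanceNetwork
    census: TriangleCensus
    transitivity: float
    evidence: EvidenceMatrix
    dp: DPMatrix
    ensemble: RankOrderEnsemble
    tree: RankTree
    tiers: TierAssignment
    report: cert.CertaintyReport
    config: dict = field(default_factory=dict)


def analyze(
    matrix: WinLossMatrix,
    max_path_length: int = DEFAULT_MAX_PATH_LENGTH,
    prior: float = DEFAULT_PRIOR,
    default_transitivity: float = DEFAULT_TRANSITIVITY,
    transitivity_override: float | None = None,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    tier_threshold: float = DEFAULT_TIER_THRESHOLD,
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
    diagnostics: bool = True,
) -> AnalysisResult:
    """Run the full inference pipeline on a win/loss matrix.

    ``transitivity_override`` fixes the path weight's transitivity input
    instead of estimating it from the triangle census (useful for
    sensitivity analyses); all other parameters are the documented knobs of
    the individual stages.
    """
    config = {
        "max_path_length": max_path_length,
        "prior": prior,
        "default_transitivity": default_transitivity,
        "transitivity_override": transitivity_override,
        "restarts": restarts,
        "seed": seed,
        "tier_threshold": tier_threshold,
        "exact_max_n": exact_max_n,
    }
    net = build_network(matrix)
    census = triad_census(net)
    t = (
        float(transitivity_override)
        if transitivity_override is not None
        else transitivity_index(census, default_t=default_transitivity)
    )
    evidence = impute_evidence(net, max_length=max_path_length, t=t)
    dp = dominance_probability(evidence, prior=prior)
    ensemble = find_best_order(
        dp, exact_max_n=exact_max_n, restarts=restarts, seed=seed
    )
    tree = build_rank_tree(dp)
    tiers = rank_tiers(dp, ensemble.best, threshold=tier_threshold)
    diag = (
        cert.certainty_diagnostics(
            net, max_length=max(2, max_path_length), default_t=default_transitivity
        )
        if diagnostics
        else None
    )
    report = cert.build_report(dp, transitivity=t, diagnostics=diag, params=config)
    return AnalysisResult(
        matrix=matrix,
        network=net,
        census=census,
        transitivity=t,
        evidence=evidence,
        dp=dp,
        ensemble=ensemble,
        tree=tree,
        tiers=tiers,
        report=report,
        config=config,
    )
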