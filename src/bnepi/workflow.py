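"""End-to-end case-control analysis driver.

Chains the package's stages the way a network-based gene-environment
study runs them:

1. on the complete-case subset, learn a prognostic ("causal") network
   with all four algorithms (GS, IAMB, HC, MMHC) under a role-derived
   blacklist and tabulate their scores side by side;
2. relax the blacklist so the outcome may parent other variables
   (the "non-causal"/diagnostic reading), re-run the hill-climber, and
   read off the outcome's Markov blanket — the candidate contributory
   causes;
3. for one focal exposure currently outside that blanket, run the
   EM-based candidate-structure comparison on ALL records (missing
   cells included) and tabulate expected scores;
4. fit the winning structure by EM and emit the prognostic odds-ratio
   table over the outcome's blanket variables.

Every stage records the seed and settings it ran under; identical
configurations produce identical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .ci_tests import TestCounter
from .constraint import constraint_structure, orient_remaining
from .data import DataTable
from .em import candidate_structures, compare_candidates, em_fit
from .inference import odds_ratio_table
from .network import Blacklist, NetworkStructure, markov_blanket
from .scoring import ScoreReport, score_structure
from .search import hill_climb, mmhc

logger = logging.getLogger(__name__)

__all__ = [
    "WorkflowConfig",
    "WorkflowReport",
    "build_blacklist",
    "relax_for_noncausal",
    "run_workflow",
]

#: role vocabulary for blacklist construction
ROLES = ("outcome", "demographic", "behavior", "exposure", "snp")


def build_blacklist(roles: Mapping[str, str]) -> Blacklist:
    """Forbidden-edge set from variable roles (prognostic reading).

    Rules: nothing may parent a demographic; the outcome may not parent
    behaviors; exposures may not parent demographics or behaviors;
    non-genetic variables (everything but SNPs) may not parent SNPs.
    """
    for v, r in roles.items():
        if r not in ROLES:
            raise ValueError(f"unknown role {r!r} for {v!r}; choose from {ROLES}")
    pairs = []
    for a, ra in roles.items():
        for b, rb in roles.items():
            if a == b:
                continue
            if rb == "demographic":
                pairs.append((a, b))
            elif ra == "outcome" and rb == "behavior":
                pairs.append((a, b))
            elif ra == "exposure" and rb == "behavior":
                pairs.append((a, b))
            elif ra != "snp" and rb == "snp":
                pairs.append((a, b))
    return Blacklist(pairs)


def relax_for_noncausal(blacklist: Blacklist, outcome: str) -> Blacklist:
    """Drop the forbidden edges in which the outcome is the parent."""
    return Blacklist((a, b) for a, b in blacklist.forbidden if a != outcome)


@dataclass
class WorkflowConfig:
    data: DataTable
    outcome: str
    focal_exposure: str
    roles: Mapping[str, str]
    alpha: float = 0.05
    metric: str = "k2"
    restarts: int = 100
    perturbations: int = 5
    seed: int = 0
    case_state: str = "1"


@dataclass
class WorkflowReport:
    algorithm_comparison: Dict[str, Dict[str, float]]
    causal_structures: Dict[str, NetworkStructure]
    noncausal_structure: NetworkStructure
    outcome_blanket: List[str]
    candidate_table: List[Tuple[str, ScoreReport]]
    candidate_winners: Dict[str, str]
    final_structure: NetworkStructure
    odds_ratios: List[dict]
    settings: Dict[str, object] = field(default_factory=dict)


def _stage1(
    complete: DataTable, config: WorkflowConfig, blacklist: Blacklist
) -> Tuple[Dict[str, Dict[str, float]], Dict[str, NetworkStructure]]:
    comparison: Dict[str, Dict[str, float]] = {}
    structures: Dict[str, NetworkStructure] = {}
    for algo in ("gs", "iamb"):
        counter = TestCounter()
        pg = constraint_structure(
            complete, config.alpha, algo, blacklist, counter=counter
        )
        dag = orient_remaining(pg, complete, blacklist)
        report = score_structure(complete, dag)
        structures[algo] = dag
        comparison[algo] = {"tests": counter.count, **report.as_dict()}
    counter = TestCounter()
    dag, report, _ = hill_climb(
        complete,
        metric=config.metric,
        blacklist=blacklist,
        restarts=config.restarts,
        perturbations=config.perturbations,
        seed=config.seed,
    )
    structures["hc"] = dag
    comparison["hc"] = {"tests": 0, **report.as_dict()}
    counter = TestCounter()
    dag, report, _ = mmhc(
        complete,
        metric=config.metric,
        alpha=config.alpha,
        blacklist=blacklist,
        restarts=config.restarts,
        perturbations=config.perturbations,
        seed=config.seed,
        counter=counter,
    )
    structures["mmhc"] = dag
    comparison["mmhc"] = {"tests": counter.count, **report.as_dict()}
    return comparison, structures


def run_workflow(config: WorkflowConfig) -> WorkflowReport:
    data = config.data
    if data.n == 0:
        raise ValueError("stage 1: empty dataset")
    complete = data.complete_cases()
    if complete.n == 0:
        raise ValueError("stage 1: no complete-case records")
    logger.info(
        "stage 1: %d complete-case records of %d total", complete.n, data.n
    )
    blacklist = build_blacklist(config.roles)
    comparison, structures = _stage1(complete, config, blacklist)

    # stage 2: diagnostic reading — outcome may parent other variables
    relaxed = relax_for_noncausal(blacklist, config.outcome)
    noncausal, _, _ = hill_climb(
        complete,
        metric=config.metric,
        blacklist=relaxed,
        restarts=config.restarts,
        perturbations=config.perturbations,
        seed=config.seed,
    )
    blanket = sorted(markov_blanket(noncausal, config.outcome))
    logger.info("stage 2: Markov blanket of %s = %s", config.outcome, blanket)

    # stage 3: EM candidate comparison on all records
    if config.focal_exposure in blanket:
        logger.info(
            "stage 3: focal exposure %s already in the blanket; comparing "
            "the learned structure only",
            config.focal_exposure,
        )
        candidates = [("none", noncausal)]
    else:
        candidates = candidate_structures(
            noncausal, config.focal_exposure, config.outcome, relaxed
        )
    table = compare_candidates(data, candidates)

    # stage 4: prognostic odds ratios under the loglik-winning structure
    win_label = table.winners["loglik"]
    final = dict(candidates)[win_label]
    fit = em_fit(data, final)
    profile_vars = sorted(markov_blanket(final, config.outcome))
    reference = {v: final.states[v][0] for v in profile_vars}
    rows = odds_ratio_table(
        final, fit.params, config.outcome, config.case_state, reference
    )
    or_rows = [
        {
            "profile": r.profile,
            "odds_ratio": r.odds_ratio,
            "p_case": r.p_profile,
        }
        for r in rows
    ]
    return WorkflowReport(
        algorithm_comparison=comparison,
        causal_structures=structures,
        noncausal_structure=noncausal,
        outcome_blanket=blanket,
        candidate_table=table.rows,
        candidate_winners=table.winners,
        final_structure=final,
        odds_ratios=or_rows,
        settings={
            "alpha": config.alpha,
            "metric": config.metric,
            "restarts": config.restarts,
            "perturbations": config.perturbations,
            "seed": config.seed,
            "n_records": data.n,
            "n_complete": complete.n,
        },
    )
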