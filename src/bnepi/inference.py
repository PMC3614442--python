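"""Exact probabilistic queries and epidemiological summaries.

Posterior probabilities are computed by summing the factorized joint
over the unobserved nodes — exact to numerical precision, which is
cheap for the network sizes this package targets (tens of binary
nodes). Odds ratios compare a risk profile against a reference profile
through two such queries, the standard prognostic-table construction
for case-control network models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy.stats import norm

from .network import NetworkStructure, ParameterSet

__all__ = [
    "QueryResult",
    "OddsRatioRow",
    "ZeroEvidenceError",
    "query",
    "odds_ratio",
    "odds_ratio_table",
    "log_odds_to_or",
    "prob_codes",
]


class ZeroEvidenceError(ValueError):
    """The evidence configuration has probability zero under the model."""


@dataclass
class QueryResult:
    """Exact posterior of one node given evidence."""

    target: str
    evidence: Dict[str, str]
    posterior: np.ndarray  # over the target's declared states, sums to 1
    states: Tuple[str, ...]
    method: str = "exact-enumeration"

    def prob(self, state: str) -> float:
        return float(self.posterior[self.states.index(str(state))])


@dataclass
class OddsRatioRow:
    """Odds of the case state under a profile, relative to a reference."""

    profile: Dict[str, str]
    reference: Dict[str, str]
    odds_ratio: float
    case_state: str
    p_profile: float
    p_reference: float


def prob_codes(
    structure: NetworkStructure, params: ParameterSet, codes: np.ndarray
) -> np.ndarray:
    """Joint probability of each row of a complete integer code matrix."""
    if (codes < 0).any():
        raise ValueError("code matrix contains missing cells")
    col_of = {v: k for k, v in enumerate(structure.nodes)}
    p = np.ones(len(codes))
    for v in structure.nodes:
        j = np.zeros(len(codes), dtype=np.int64)
        for par in structure.parents(v):
            j = j * structure.n_states(par) + codes[:, col_of[par]]
        p *= params[v][j, codes[:, col_of[v]]]
    return p


def _completion_codes(
    structure: NetworkStructure, evidence: Mapping[str, str]
) -> np.ndarray:
    """Code matrix of every completion consistent with the evidence."""
    axes = []
    for v in structure.nodes:
        if v in evidence:
            axes.append([structure.state_index(v, evidence[v])])
        else:
            axes.append(range(structure.n_states(v)))
    return np.array(list(itertools.product(*axes)), dtype=np.int64)


def query(
    structure: NetworkStructure,
    params: ParameterSet,
    target: str,
    evidence: Optional[Mapping[str, str]] = None,
) -> QueryResult:
    """Exact posterior P(target | evidence) by joint enumeration."""
    evidence = dict(evidence or {})
    structure._check(target)
    if target in evidence:
        raise ValueError("target must not appear in the evidence")
    for v, s in evidence.items():
        structure.state_index(v, s)  # validates node and state

    codes = _completion_codes(structure, evidence)
    probs = prob_codes(structure, params, codes)
    t_col = list(structure.nodes).index(target)
    r = structure.n_states(target)
    posterior = np.bincount(codes[:, t_col], weights=probs, minlength=r)
    total = posterior.sum()
    if total <= 0:
        raise ZeroEvidenceError(
            f"evidence {evidence} has probability 0 under the model"
        )
    return QueryResult(
        target, evidence, posterior / total, structure.states[target]
    )


def odds_ratio(
    structure: NetworkStructure,
    params: ParameterSet,
    target: str,
    case_state: str,
    profile: Mapping[str, str],
    reference: Mapping[str, str],
) -> OddsRatioRow:
    """OR of ``target == case_state`` for ``profile`` vs ``reference``.

    ``[p1/(1-p1)] / [p0/(1-p0)]`` with p1, p0 the exact conditional case
    probabilities. Profiles with degenerate probabilities (0 or 1) yield
    an infinite or zero OR, reported as such.
    """
    if set(profile) != set(reference):
        raise ValueError("profile and reference must assign the same variables")
    if target in profile:
        raise ValueError("profiles must not assign the target")
    p1 = query(structure, params, target, profile).prob(case_state)
    p0 = query(structure, params, target, reference).prob(case_state)
    if p0 in (0.0, 1.0) or p1 in (0.0, 1.0):
        orr = float("inf") if (p1 == 1.0 or p0 == 0.0) else 0.0
    else:
        orr = (p1 / (1 - p1)) / (p0 / (1 - p0))
    return OddsRatioRow(dict(profile), dict(reference), orr, str(case_state), p1, p0)


def odds_ratio_table(
    structure: NetworkStructure,
    params: ParameterSet,
    target: str,
    case_state: str,
    reference: Mapping[str, str],
    profiles: Optional[list] = None,
):
    """ORs for all (or the given) risk-factor combinations, ascending.

    When ``profiles`` is omitted, every combination of states of the
    reference's variables is evaluated — the full prognostic table.
    """
    variables = sorted(reference)
    if profiles is None:
        profiles = [
            dict(zip(variables, combo))
            for combo in itertools.product(
                *[structure.states[v] for v in variables]
            )
        ]
    rows = [
        odds_ratio(structure, params, target, case_state, prof, reference)
        for prof in profiles
    ]
    return sorted(rows, key=lambda r: r.odds_ratio)


def log_odds_to_or(
    coefficient: float, standard_error: float, confidence: float = 0.95
) -> Tuple[float, Tuple[float, float]]:
    """Convert a logistic-regression coefficient to an OR with its CI.

    ``OR = exp(coef)``; the interval is ``exp(coef ± z * se)`` with ``z``
    the two-sided normal quantile of the stated confidence level.
    """
    if standard_error < 0:
        raise ValueError("standard error must be >= 0")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    z = float(norm.ppf(0.5 + confidence / 2.0))
    orr = float(np.exp(coefficient))
    lo = float(np.exp(coefficient - z * standard_error))
    hi = float(np.exp(coefficient + z * standard_error))
    return orr, (lo, hi)
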