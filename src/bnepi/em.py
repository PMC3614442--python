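"""Parameter EM for a fixed structure on incomplete categorical records.

Records with missing cells are probabilistically completed: the E-step
enumerates every completion of a record's missing cells and weights it
by its exact posterior probability given the observed cells under the
current parameters; the M-step re-estimates each CPT from the expected
(fractional) frequencies. Iteration continues until every parameter
individually moves less than the tolerance. The observed-data
log-likelihood is guaranteed non-decreasing and is traced per iteration.

The module also implements the enumerated candidate-structure
comparison: to ask whether a variable T belongs in the Markov blanket of
an outcome Y, fit every structure that would put it there (T as parent
of Y, child of Y, or co-parent of one of Y's children) plus the null,
and compare expected scores after EM convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import DataTable, MISSING_CODE
from .inference import prob_codes
from .network import (
    Blacklist,
    NetworkStructure,
    ParameterSet,
    markov_blanket,
)
from .scoring import ScoreReport, score_from_counts, tabulate_counts_from_codes

logger = logging.getLogger(__name__)

__all__ = [
    "FractionalDataTable",
    "EMResult",
    "CandidateComparison",
    "init_from_complete_cases",
    "e_step",
    "m_step",
    "em_fit",
    "candidate_structures",
    "compare_candidates",
]

DEFAULT_TOLERANCE = 1e-6
DEFAULT_MAX_ITER = 500
DEFAULT_MISSING_CAP = 12  # max missing cells per record for exact enumeration


@dataclass
class FractionalDataTable:
    """Probabilistically completed dataset.

    Each original record appears as one or more completion rows in
    ``codes`` sharing a ``record_id``; the ``weights`` of one record's
    completions sum to 1 (a complete record is its own single completion
    of weight 1).
    """

    structure: NetworkStructure
    codes: np.ndarray  # (m, k) complete integer codes
    record_ids: np.ndarray  # (m,)
    weights: np.ndarray  # (m,)
    n_records: int
    n_dropped: int = 0

    def as_table(self) -> DataTable:
        return DataTable.from_codes(self.codes, self.structure)


@dataclass
class EMResult:
    """Outcome of one EM run on a fixed structure."""

    params: ParameterSet
    n_iter: int
    loglik_trace: List[float]
    converged: bool
    expected_scores: ScoreReport
    completed: FractionalDataTable


@dataclass
class CandidateComparison:
    """Expected scores of each candidate structure after EM."""

    rows: List[Tuple[str, ScoreReport]]
    winners: Dict[str, str] = field(default_factory=dict)

    def winner(self, metric: str) -> str:
        return self.winners[metric]


# ---------------------------------------------------------------------------
# parameter estimation primitives
# ---------------------------------------------------------------------------

def _mle_from_codes(
    structure: NetworkStructure,
    codes: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> ParameterSet:
    """Weighted relative-frequency CPTs; unseen configurations -> uniform."""
    counts = tabulate_counts_from_codes(codes, structure, weights)
    tables = {}
    for v in structure.nodes:
        t = counts.tables[v]
        nij = t.sum(axis=1, keepdims=True)
        r = t.shape[1]
        with np.errstate(invalid="ignore"):
            p = np.where(nij > 0, t / np.where(nij > 0, nij, 1.0), 1.0 / r)
        tables[v] = p
    return ParameterSet(structure, tables)


def init_from_complete_cases(
    data: DataTable, structure: NetworkStructure
) -> ParameterSet:
    """Initial estimates: relative frequencies over the complete records."""
    codes = data.encode(structure)
    complete = codes[(codes >= 0).all(axis=1)]
    if len(complete) == 0:
        logger.warning(
            "no complete records; initializing every CPT to uniform"
        )
        return ParameterSet.uniform(structure)
    return _mle_from_codes(structure, complete)


def _expand_records(
    structure: NetworkStructure, codes: np.ndarray, missing_cap: int
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Enumerate completions of every record (exact E-step support)."""
    rows: List[np.ndarray] = []
    ids: List[np.ndarray] = []
    dropped = 0
    sizes = np.array([structure.n_states(v) for v in structure.nodes])
    for i, rec in enumerate(codes):
        miss = np.flatnonzero(rec == MISSING_CODE)
        if len(miss) == 0:
            rows.append(rec[None, :])
            ids.append(np.array([i]))
            continue
        if len(miss) > missing_cap:
            dropped += 1
            logger.warning(
                "record %d has %d missing cells (> cap %d); dropped",
                i,
                len(miss),
                missing_cap,
            )
            continue
        grids = np.meshgrid(*[np.arange(sizes[c]) for c in miss], indexing="ij")
        combos = np.stack([g.ravel() for g in grids], axis=1)
        block = np.repeat(rec[None, :], len(combos), axis=0)
        block[:, miss] = combos
        rows.append(block)
        ids.append(np.full(len(combos), i))
    if not rows:
        return (
            np.empty((0, len(structure.nodes)), dtype=np.int64),
            np.empty(0, dtype=np.int64),
            dropped,
        )
    return np.vstack(rows), np.concatenate(ids), dropped


def _reweight(
    structure: NetworkStructure,
    expanded: np.ndarray,
    record_ids: np.ndarray,
    params: ParameterSet,
) -> Tuple[np.ndarray, float]:
    """Posterior completion weights and the observed-data log-likelihood."""
    joint = prob_codes(structure, params, expanded)
    n_rec = record_ids.max() + 1 if len(record_ids) else 0
    totals = np.bincount(record_ids, weights=joint, minlength=n_rec)
    zero = totals <= 0.0
    if zero.any():
        logger.warning(
            "%d record(s) have observed cells of probability 0 under the "
            "current parameters; using uniform completion weights",
            int(zero.sum()),
        )
        counts = np.bincount(record_ids, minlength=n_rec)
        joint = np.where(zero[record_ids], 1.0, joint)
        totals = np.where(zero, counts, totals)
    weights = joint / totals[record_ids]
    loglik = float(np.log(totals[~zero]).sum())
    return weights, loglik


def e_step(
    data: DataTable,
    structure: NetworkStructure,
    params: ParameterSet,
    missing_cap: int = DEFAULT_MISSING_CAP,
) -> FractionalDataTable:
    """Probabilistically complete every record under ``params``."""
    codes = data.encode(structure)
    expanded, record_ids, dropped = _expand_records(structure, codes, missing_cap)
    weights, _ = _reweight(structure, expanded, record_ids, params)
    n_kept = len(np.unique(record_ids)) if len(record_ids) else 0
    return FractionalDataTable(
        structure, expanded, record_ids, weights, n_kept, dropped
    )


def m_step(fractional: FractionalDataTable) -> ParameterSet:
    """Re-estimate CPTs from expected (fractional) frequencies."""
    return _mle_from_codes(
        fractional.structure, fractional.codes, fractional.weights
    )


def expected_scores(fractional: FractionalDataTable) -> ScoreReport:
    """Scores on the expected sufficient statistics (fractional counts)."""
    counts = tabulate_counts_from_codes(
        fractional.codes, fractional.structure, fractional.weights
    )
    return score_from_counts(counts)


def em_fit(
    data: DataTable,
    structure: NetworkStructure,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
    missing_cap: int = DEFAULT_MISSING_CAP,
    init: Optional[ParameterSet] = None,
) -> EMResult:
    """EM to convergence: alternate completion and re-estimation.

    Starts from complete-case relative frequencies (or ``init``); stops
    when the largest absolute CPT-entry change drops below ``tolerance``
    or after ``max_iter`` iterations (flagged, still returned). EM is
    deterministic — no randomness is involved.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    codes = data.encode(structure)
    expanded, record_ids, dropped = _expand_records(structure, codes, missing_cap)
    if len(expanded) == 0:
        raise ValueError("no usable records after the missing-cell cap")
    params = init if init is not None else init_from_complete_cases(data, structure)

    trace: List[float] = []
    converged = False
    weights = np.ones(len(expanded))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        weights, loglik = _reweight(structure, expanded, record_ids, params)
        trace.append(loglik)
        frac = FractionalDataTable(
            structure,
            expanded,
            record_ids,
            weights,
            int(len(np.unique(record_ids))),
            dropped,
        )
        new_params = m_step(frac)
        delta = max(
            float(np.abs(new_params[v] - params[v]).max())
            for v in structure.nodes
        )
        params = new_params
        if delta < tolerance:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge within %d iterations", max_iter)
    final = FractionalDataTable(
        structure,
        expanded,
        record_ids,
        _reweight(structure, expanded, record_ids, params)[0],
        int(len(np.unique(record_ids))),
        dropped,
    )
    return EMResult(
        params, n_iter, trace, converged, expected_scores(final), final
    )


# ---------------------------------------------------------------------------
# enumerated candidate-structure comparison
# ---------------------------------------------------------------------------

def candidate_structures(
    base: NetworkStructure,
    target: str,
    outcome: str,
    blacklist: Optional[Blacklist] = None,
) -> List[Tuple[str, NetworkStructure]]:
    """Structures that would place ``target`` in ``outcome``'s blanket.

    Returns the null (base) structure plus: target as parent of the
    outcome, target as child of the outcome, and target as co-parent of
    each of the outcome's children. Candidates that would create a cycle
    or use a blacklisted edge are dropped with a log entry.
    """
    base._check(target)
    base._check(outcome)
    if target in markov_blanket(base, outcome):
        raise ValueError(
            f"{target!r} is already in the Markov blanket of {outcome!r}"
        )
    bl = blacklist or Blacklist()
    proposals: List[Tuple[str, Tuple[str, str]]] = [
        (f"{target} -> {outcome}", (target, outcome)),
        (f"{outcome} -> {target}", (outcome, target)),
    ]
    for child in base.children(outcome):
        proposals.append((f"{target} -> {child}", (target, child)))

    out: List[Tuple[str, NetworkStructure]] = [("none", base)]
    for label, edge in proposals:
        if not bl.allows(*edge):
            logger.info("candidate %s dropped: blacklisted", label)
            continue
        try:
            out.append((label, base.with_edges(add=[edge])))
        except ValueError:
            logger.info("candidate %s dropped: creates a cycle", label)
    return out


def compare_candidates(
    data: DataTable,
    candidates: Sequence[Tuple[str, NetworkStructure]],
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
    missing_cap: int = DEFAULT_MISSING_CAP,
) -> CandidateComparison:
    """EM-fit every candidate and tabulate expected scores per metric."""
    if not candidates:
        raise ValueError("need at least one candidate structure")
    rows: List[Tuple[str, ScoreReport]] = []
    for label, structure in candidates:
        result = em_fit(
            data,
            structure,
            tolerance=tolerance,
            max_iter=max_iter,
            missing_cap=missing_cap,
        )
        rows.append((label, result.expected_scores))
    winners = {}
    for metric in ("loglik", "aic", "bic", "k2"):
        winners[metric] = max(rows, key=lambda r: r[1].metric(metric))[0]
    return CandidateComparison(rows, winners)
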