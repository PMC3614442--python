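"""Decomposable structure scores for discrete networks.

All scores decompose over nodes given the sufficient statistics
``N_ijk`` — the (possibly fractional, when records carry EM weights)
number of records in which node *i* takes its *k*-th state while its
parents sit in their *j*-th configuration. Four scores are provided:

* maximized log-likelihood  ``sum N_ijk ln(N_ijk / N_ij)``;
* AIC  ``loglik - n_p``;
* BIC  ``loglik - (n_p / 2) ln N``;
* log-K2, the log marginal likelihood under uniform Dirichlet(1,...,1)
  parameter priors, written with log-gamma so it extends to fractional
  counts:  ``sum_j [lnG(r_i) - lnG(N_ij + r_i) + sum_k lnG(N_ijk + 1)]``.

``n_p`` counts free parameters, ``(r_i - 1) q_i`` summed over nodes.
Logs are natural throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.special import gammaln

from .data import DataTable
from .network import NetworkStructure, count_free_parameters

__all__ = [
    "ContingencyCounts",
    "ScoreReport",
    "tabulate_counts",
    "log_likelihood",
    "aic",
    "bic",
    "log_k2",
    "local_score",
    "score_structure",
    "METRICS",
]

METRICS = ("loglik", "aic", "bic", "k2")


@dataclass
class ContingencyCounts:
    """Sufficient statistics: one ``(q_i, r_i)`` count table per node."""

    structure: NetworkStructure
    tables: Dict[str, np.ndarray]
    n_effective: float

    def node_table(self, v: str) -> np.ndarray:
        return self.tables[v]


@dataclass
class ScoreReport:
    """One row of an algorithm-comparison table."""

    loglik: float
    aic: float
    bic: float
    log_k2: float
    n_params: int
    n_arcs: int
    n_records: float

    def metric(self, name: str) -> float:
        return {
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "k2": self.log_k2,
        }[name]

    def as_dict(self) -> Dict[str, float]:
        return {
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "log_k2": self.log_k2,
            "n_params": self.n_params,
            "n_arcs": self.n_arcs,
            "n_records": self.n_records,
        }


def _node_counts(
    codes: np.ndarray,
    weights: Optional[np.ndarray],
    structure: NetworkStructure,
    v: str,
    col_of: Dict[str, int],
) -> np.ndarray:
    """Weighted (q_v, r_v) count table for one node from a code matrix."""
    r = structure.n_states(v)
    q = structure.config_count(v)
    child = codes[:, col_of[v]]
    if np.any(child < 0):
        raise ValueError(
            f"missing values in column {v!r}; scores need complete "
            "(or fractionally completed) records"
        )
    if q == 1:
        j = np.zeros(len(child), dtype=np.int64)
    else:
        j = np.zeros(len(child), dtype=np.int64)
        for p in structure.parents(v):
            pc = codes[:, col_of[p]]
            if np.any(pc < 0):
                raise ValueError(f"missing values in parent column {p!r}")
            j = j * structure.n_states(p) + pc
    flat = j * r + child
    w = np.ones(len(child)) if weights is None else np.asarray(weights, dtype=float)
    return np.bincount(flat, weights=w, minlength=q * r).reshape(q, r)


def tabulate_counts(
    data: DataTable,
    structure: NetworkStructure,
    weights: Optional[np.ndarray] = None,
) -> ContingencyCounts:
    """Sufficient statistics of ``data`` under ``structure``.

    ``weights`` (one per row) supports fractionally completed records
    from the E-step; omitted means unit weights.
    """
    codes = data.encode(structure)
    return tabulate_counts_from_codes(codes, structure, weights)


def tabulate_counts_from_codes(
    codes: np.ndarray,
    structure: NetworkStructure,
    weights: Optional[np.ndarray] = None,
) -> ContingencyCounts:
    col_of = {v: k for k, v in enumerate(structure.nodes)}
    tables = {
        v: _node_counts(codes, weights, structure, v, col_of)
        for v in structure.nodes
    }
    n_eff = float(len(codes)) if weights is None else float(np.sum(weights))
    return ContingencyCounts(structure, tables, n_eff)


def _node_loglik(table: np.ndarray) -> float:
    nij = table.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / nij), 0.0)
    return float(terms.sum())


def _node_log_k2(table: np.ndarray) -> float:
    if np.any(table < 0):
        raise ValueError("negative counts")
    r = table.shape[1]
    nij = table.sum(axis=1)
    val = gammaln(r) - gammaln(nij + r) + gammaln(table + 1.0).sum(axis=1)
    return float(val.sum())


def log_likelihood(counts: ContingencyCounts) -> float:
    """Maximized log-likelihood (MLE parameters = relative frequencies)."""
    return sum(_node_loglik(t) for t in counts.tables.values())


def aic(counts: ContingencyCounts, n_params: Optional[int] = None) -> float:
    """``loglik - n_p`` — the lighter of the two penalized scores."""
    np_ = count_free_parameters(counts.structure) if n_params is None else n_params
    if np_ < 0:
        raise ValueError("n_params must be >= 0")
    return log_likelihood(counts) - np_


def bic(
    counts: ContingencyCounts,
    n_params: Optional[int] = None,
    n_records: Optional[float] = None,
) -> float:
    """``loglik - (n_p / 2) ln N``; prefers sparser graphs than AIC."""
    np_ = count_free_parameters(counts.structure) if n_params is None else n_params
    n = counts.n_effective if n_records is None else n_records
    if n < 1:
        raise ValueError("sample size must be >= 1")
    return log_likelihood(counts) - 0.5 * np_ * np.log(n)


def log_k2(counts: ContingencyCounts) -> float:
    """Log marginal likelihood under uniform Dirichlet priors."""
    return sum(_node_log_k2(t) for t in counts.tables.values())


def local_score(table: np.ndarray, metric: str, n_records: float) -> float:
    """One node's contribution to a decomposable score.

    ``table`` is the node's (q, r) count table; the penalty terms use the
    node's own free-parameter count ``(r - 1) q``.
    """
    q, r = table.shape
    n_p = (r - 1) * q
    if metric == "loglik":
        return _node_loglik(table)
    if metric == "aic":
        return _node_loglik(table) - n_p
    if metric == "bic":
        return _node_loglik(table) - 0.5 * n_p * np.log(max(n_records, 1.0))
    if metric == "k2":
        return _node_log_k2(table)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def score_structure(
    data: DataTable,
    structure: NetworkStructure,
    weights: Optional[np.ndarray] = None,
) -> ScoreReport:
    """Full score report (all four metrics) for one structure."""
    counts = tabulate_counts(data, structure, weights)
    return score_from_counts(counts)


def score_from_counts(counts: ContingencyCounts) -> ScoreReport:
    structure = counts.structure
    ll = log_likelihood(counts)
    n_p = count_free_parameters(structure)
    n = counts.n_effective
    return ScoreReport(
        loglik=ll,
        aic=ll - n_p,
        bic=ll - 0.5 * n_p * np.log(n) if n >= 1 else float("nan"),
        log_k2=log_k2(counts),
        n_params=n_p,
        n_arcs=len(structure.edges),
        n_records=n,
    )
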