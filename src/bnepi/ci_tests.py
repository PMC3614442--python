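"""Conditional-independence tests on categorical data.

Constraint-based structure learning decides edge presence with Pearson
chi-square tests of ``X ⊥ Y | S`` and ranks candidates by (conditional)
mutual information. Both statistics are computed on the contingency table
of X and Y within each stratum of the conditioning set S; rows with a
missing value in any involved column are list-wise deleted per test.

Degenerate strata (a zero row or column margin) have those rows/columns
collapsed before computing the statistic, with the degrees of freedom
reduced accordingly; if no degrees of freedom remain the test reports
independence (p = 1) and flags itself degenerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .data import DataTable

logger = logging.getLogger(__name__)

__all__ = ["TestResult", "chi2_test", "mutual_information", "TestCounter"]


@dataclass
class TestResult:
    """Outcome of one conditional-independence test."""

    statistic: float
    dof: int
    p_value: float
    n: int
    x: str
    y: str
    conditioning: Tuple[str, ...]
    mi: Optional[float] = None  # nats; set by mutual_information
    degenerate: bool = False

    def rejects(self, alpha: float) -> bool:
        """True if independence is rejected at level ``alpha``."""
        return (not self.degenerate) and self.p_value < alpha


class TestCounter:
    """Counts CI tests executed during a learner run (comparison-table analogue)."""

    def __init__(self) -> None:
        self.count = 0
        self.trace: List[TestResult] = []

    def record(self, result: TestResult) -> None:
        self.count += 1
        self.trace.append(result)


def _strata_tables(
    data: DataTable, x: str, y: str, s: Tuple[str, ...]
) -> Tuple[List[np.ndarray], int]:
    """Observed X-by-Y count tables, one per configuration of S."""
    cols = [x, y, *s]
    sub = data.df[cols]
    sub = sub[~sub.isna().any(axis=1)]
    n = len(sub)
    if n == 0:
        return [], 0
    x_levels = sorted(sub[x].unique())
    y_levels = sorted(sub[y].unique())
    xi = sub[x].map({v: i for i, v in enumerate(x_levels)}).to_numpy()
    yi = sub[y].map({v: i for i, v in enumerate(y_levels)}).to_numpy()
    if s:
        key = sub[list(s)].astype(str).agg("\x00".join, axis=1)
        _, si = np.unique(key.to_numpy(), return_inverse=True)
        n_strata = si.max() + 1
    else:
        si = np.zeros(n, dtype=int)
        n_strata = 1
    r, c = len(x_levels), len(y_levels)
    flat = (si * r + xi) * c + yi
    counts = np.bincount(flat, minlength=n_strata * r * c).reshape(n_strata, r, c)
    return [counts[k] for k in range(n_strata)], n


def _collapse(table: np.ndarray) -> np.ndarray:
    """Drop all-zero rows/columns (degenerate margins)."""
    table = table[table.sum(axis=1) > 0]
    if table.size:
        table = table[:, table.sum(axis=0) > 0]
    return table


def chi2_test(
    data: DataTable, x: str, y: str, s: Iterable[str] = (),
    counter: Optional[TestCounter] = None,
) -> TestResult:
    """Pearson chi-square test of ``X ⊥ Y | S``.

    The statistic sums ``(observed - expected)^2 / expected`` over every
    stratum of S; degrees of freedom sum ``(r-1)(c-1)`` over the
    non-degenerate strata after margin collapsing. No continuity
    correction is applied.
    """
    s = tuple(s)
    _validate(x, y, s)
    tables, n = _strata_tables(data, x, y, s)
    stat, dof = 0.0, 0
    for t in tables:
        t = _collapse(t)
        if t.shape[0] < 2 or t.shape[1] < 2:
            continue
        total = t.sum()
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
        stat += float(((t - expected) ** 2 / expected).sum())
        dof += (t.shape[0] - 1) * (t.shape[1] - 1)
    result = _finish(stat, dof, n, x, y, s)
    if counter is not None:
        counter.record(result)
    return result


def mutual_information(
    data: DataTable, x: str, y: str, s: Iterable[str] = (),
    counter: Optional[TestCounter] = None,
) -> TestResult:
    """Conditional mutual information MI(X;Y|S) in nats, with its G^2 test.

    ``MI = sum p(x,y,s) ln[ p(x,y|s) / (p(x|s) p(y|s)) ] >= 0`` estimated
    from relative frequencies; the returned TestResult carries the
    likelihood-ratio statistic ``G^2 = 2 N MI`` with the same degrees of
    freedom convention as :func:`chi2_test`.
    """
    s = tuple(s)
    _validate(x, y, s)
    tables, n = _strata_tables(data, x, y, s)
    mi, dof = 0.0, 0
    for t in tables:
        t = _collapse(t)
        if t.shape[0] < 2 or t.shape[1] < 2:
            continue
        total = t.sum()
        expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(t > 0, t * np.log(t / expected), 0.0)
        mi += float(terms.sum()) / max(n, 1)
        dof += (t.shape[0] - 1) * (t.shape[1] - 1)
    result = _finish(2.0 * n * mi, dof, n, x, y, s)
    result.mi = mi
    if counter is not None:
        counter.record(result)
    return result


def _validate(x: str, y: str, s: Tuple[str, ...]) -> None:
    if x == y:
        raise ValueError("X and Y must differ")
    if x in s or y in s:
        raise ValueError("X and Y must not belong to the conditioning set")


def _finish(
    stat: float, dof: int, n: int, x: str, y: str, s: Tuple[str, ...]
) -> TestResult:
    if dof <= 0:
        logger.debug(
            "degenerate CI test %s vs %s | %s (n=%d): no remaining dof", x, y, s, n
        )
        return TestResult(0.0, 0, 1.0, n, x, y, s, degenerate=True)
    p = float(chi2_dist.sf(stat, dof)) if stat > 0 else 1.0
    return TestResult(float(stat), dof, p, n, x, y, s)
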