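"""Constraint-based structure learning: Grow-Shrink and IAMB.

Both algorithms estimate each variable's Markov blanket (parents,
children and co-parents) from conditional-independence tests, differing
only in candidate ordering: Grow-Shrink fixes the order once from the
marginal association with the target, IAMB re-ranks candidates at every
step by conditional mutual information given the current blanket.

The per-node blankets are then compiled into one graph: blanket links are
kept only when found from both sides (AND rule), spousal links are
removed by searching for a d-separating subset, collider triples are
oriented, orientations propagated, and any directed cycle introduced by
compilation is repaired by undirecting its weakest-supported edge.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .ci_tests import TestCounter, chi2_test, mutual_information
from .data import DataTable
from .network import Blacklist, Edge, NetworkStructure, PartialGraph, _meek_orient

logger = logging.getLogger(__name__)

__all__ = [
    "MarkovBlanketEstimate",
    "gs_blanket",
    "iamb_blanket",
    "constraint_structure",
    "orient_remaining",
]

DEFAULT_SEPSET_CAP = 3


@dataclass
class MarkovBlanketEstimate:
    """Estimated Markov blanket with its grow/shrink decision trace."""

    target: str
    members: List[str]
    trace: List[Tuple[str, Tuple[str, ...], float, str]] = field(
        default_factory=list
    )  # (variable, conditioning set, p-value, action)


def _candidates(data: DataTable, x: str) -> List[str]:
    out = []
    for c in data.columns:
        if c == x:
            continue
        if len(data.levels(c)) < 2:
            logger.debug("skipping degenerate variable %s (single level)", c)
            continue
        out.append(c)
    return out


def gs_blanket(
    data: DataTable,
    x: str,
    alpha: float = 0.05,
    counter: Optional[TestCounter] = None,
) -> MarkovBlanketEstimate:
    """Grow-Shrink Markov blanket estimate of ``x``.

    Grow phase: candidates are tried in a static order — descending
    marginal chi-square association with ``x`` (equivalently ascending
    p-value) — and added while dependent on ``x`` given the current set;
    passes repeat until stable. Shrink phase: members rendered
    independent given the rest of the set are removed.
    """
    _check_alpha(alpha)
    est = MarkovBlanketEstimate(x, [])
    cands = _candidates(data, x)
    marginal = {y: chi2_test(data, x, y, (), counter) for y in cands}
    order = sorted(cands, key=lambda y: (marginal[y].p_value, cands.index(y)))
    s: List[str] = []
    changed = True
    while changed:  # grow until a full pass adds nothing
        changed = False
        for y in order:
            if y in s:
                continue
            res = (
                marginal[y]
                if not s
                else chi2_test(data, x, y, tuple(s), counter)
            )
            if res.rejects(alpha):
                s.append(y)
                est.trace.append((y, tuple(s[:-1]), res.p_value, "grow"))
                changed = True
    _shrink(data, x, s, alpha, est, counter)
    est.members = s
    return est


def iamb_blanket(
    data: DataTable,
    x: str,
    alpha: float = 0.05,
    counter: Optional[TestCounter] = None,
) -> MarkovBlanketEstimate:
    """IAMB Markov blanket estimate of ``x``.

    Forward phase: repeatedly admit the candidate with the largest
    mutual information with ``x`` conditional on the current set,
    provided the corresponding G^2 test rejects independence. Backward
    phase: same shrink step as Grow-Shrink. The dynamic re-ranking keeps
    the admitted set small, so fewer false positives need removal.
    """
    _check_alpha(alpha)
    est = MarkovBlanketEstimate(x, [])
    cands = _candidates(data, x)
    s: List[str] = []
    while True:
        best, best_res = None, None
        for y in cands:
            if y in s:
                continue
            res = mutual_information(data, x, y, tuple(s), counter)
            if best_res is None or res.mi > best_res.mi:
                best, best_res = y, res
        if best is None or not best_res.rejects(alpha):
            break
        s.append(best)
        est.trace.append((best, tuple(s[:-1]), best_res.p_value, "grow"))
    _shrink(data, x, s, alpha, est, counter)
    est.members = s
    return est


def _shrink(
    data: DataTable,
    x: str,
    s: List[str],
    alpha: float,
    est: MarkovBlanketEstimate,
    counter: Optional[TestCounter],
) -> None:
    changed = True
    while changed:
        changed = False
        for y in list(s):
            rest = tuple(z for z in s if z != y)
            res = chi2_test(data, x, y, rest, counter)
            if not res.rejects(alpha):
                s.remove(y)
                est.trace.append((y, rest, res.p_value, "shrink"))
                changed = True
                break


def _check_alpha(alpha: float) -> None:
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# blanket compilation into a (partially) directed graph
# ---------------------------------------------------------------------------

def constraint_structure(
    data: DataTable,
    alpha: float = 0.05,
    method: str = "gs",
    blacklist: Optional[Blacklist] = None,
    sepset_cap: int = DEFAULT_SEPSET_CAP,
    counter: Optional[TestCounter] = None,
) -> PartialGraph:
    """Full constraint-based learner: blankets -> skeleton -> orientation.

    Steps: (1) per-node blanket estimates (``method`` in {"gs","iamb"}),
    symmetrized by the AND rule; (2) spousal-link removal by searching
    subsets of the smaller blanket (ascending size, capped at
    ``sepset_cap``) for a separating set; (3) v-structure orientation
    where the middle node is absent from the recorded separating set;
    (4) orientation propagation (Meek rules); (5) blacklist enforcement
    and cycle repair by undirecting weakest-supported edges.
    """
    blanket_fn = {"gs": gs_blanket, "iamb": iamb_blanket}.get(method)
    if blanket_fn is None:
        raise ValueError(f"unknown method {method!r}; choose 'gs' or 'iamb'")
    bl = blacklist or Blacklist()
    nodes = tuple(data.columns)
    blankets = {v: set(blanket_fn(data, v, alpha, counter).members) for v in nodes}
    # AND rule: keep the link only if each node sees the other
    linked: Set[FrozenSet[str]] = set()
    for v in nodes:
        for w in blankets[v]:
            if v in blankets[w]:
                linked.add(frozenset((v, w)))

    # spousal-link removal: look for a d-separating set around each pair
    sepset: Dict[FrozenSet[str], Tuple[str, ...]] = {}
    strength: Dict[FrozenSet[str], float] = {}
    for e in sorted(linked, key=sorted):
        v, w = sorted(e)
        pool = blankets[v] - {w}
        if len(blankets[w] - {v}) < len(pool):
            pool = blankets[w] - {v}
        found = False
        for size in range(0, min(sepset_cap, len(pool)) + 1):
            for cond in itertools.combinations(sorted(pool), size):
                res = chi2_test(data, v, w, cond, counter)
                if not res.rejects(alpha):
                    sepset[e] = cond
                    found = True
                    break
            if found:
                break
        if found:
            linked = linked - {e}
        else:
            strength[e] = chi2_test(data, v, w, (), counter).statistic

    # v-structure orientation: middle node missing from the separating set
    directed: Set[Edge] = set()
    undirected: Set[FrozenSet[str]] = set(linked)
    support: Dict[Edge, float] = {}
    for z in nodes:
        neigh = sorted(v for v in nodes if frozenset((v, z)) in linked)
        for v, w in itertools.combinations(neigh, 2):
            pair = frozenset((v, w))
            if pair in linked or pair not in sepset:
                continue
            if z in sepset[pair]:
                continue
            # conditioning on z creates the dependency: orient v -> z <- w
            res = chi2_test(data, v, w, sepset[pair] + (z,), counter)
            if not res.rejects(alpha):
                continue
            for parent in (v, w):
                e = frozenset((parent, z))
                if not bl.allows(parent, z):
                    logger.warning(
                        "v-structure wants blacklisted edge %s -> %s; left undirected",
                        parent,
                        z,
                    )
                    continue
                if e in undirected:
                    undirected.discard(e)
                    directed.add((parent, z))
                support[(parent, z)] = max(
                    support.get((parent, z), 0.0), res.statistic
                )

    _meek_orient(nodes, directed, undirected)
    # blacklist may forbid a propagated direction: undo to undirected
    for e in [e for e in directed if e in bl]:
        directed.discard(e)
        undirected.add(frozenset(e))
        logger.warning("propagated orientation %s blacklisted; left undirected", e)
    _repair_cycles(nodes, directed, undirected, support)
    return PartialGraph(nodes, directed, undirected)


def _repair_cycles(
    nodes: Sequence[str],
    directed: Set[Edge],
    undirected: Set[FrozenSet[str]],
    support: Dict[Edge, float],
) -> None:
    """Undirect directed-cycle edges, weakest association support first."""
    while True:
        cycle = _find_cycle(nodes, directed)
        if cycle is None:
            return
        victim = min(cycle, key=lambda e: (support.get(e, 0.0), e))
        directed.discard(victim)
        undirected.add(frozenset(victim))
        logger.warning("cycle repaired by undirecting %s -> %s", *victim)


def _find_cycle(nodes: Sequence[str], directed: Set[Edge]) -> Optional[List[Edge]]:
    children: Dict[str, List[str]] = {v: [] for v in nodes}
    for a, b in sorted(directed):
        children[a].append(b)
    color = {v: 0 for v in nodes}
    stack: List[str] = []

    def visit(v: str) -> Optional[List[Edge]]:
        color[v] = 1
        stack.append(v)
        for w in children[v]:
            if color[w] == 1:
                path = stack[stack.index(w):] + [w]
                return list(zip(path[:-1], path[1:]))
            if color[w] == 0:
                found = visit(w)
                if found:
                    return found
        stack.pop()
        color[v] = 2
        return None

    for v in nodes:
        if color[v] == 0:
            found = visit(v)
            if found:
                return found
    return None


def orient_remaining(
    graph: PartialGraph,
    data: DataTable,
    blacklist: Optional[Blacklist] = None,
) -> NetworkStructure:
    """Deterministically extend a partial graph to a full DAG.

    Undirected edges are taken in descending marginal chi-square
    association (ties by name) and oriented away from the node that comes
    earlier in a topological sort of the already-directed part; both-new
    or tied nodes fall back to declaration order. Blacklisted directions
    are flipped when possible. Used to hand constraint-learner output to
    the scoring modules, which need a DAG.
    """
    bl = blacklist or Blacklist()
    states = DataTable(data.df).infer_states()
    directed = set(graph.directed)
    order = {v: i for i, v in enumerate(graph.nodes)}

    def topo_rank() -> Dict[str, int]:
        try:
            topo = NetworkStructure(
                graph.nodes, states, directed
            ).topological_order()
            return {v: i for i, v in enumerate(topo)}
        except ValueError:
            return dict(order)

    ranked = sorted(
        graph.undirected,
        key=lambda e: (-chi2_test(data, *sorted(e)).statistic, sorted(e)),
    )
    for e in ranked:
        a, b = sorted(e, key=lambda v: (topo_rank()[v], order[v]))
        if not bl.allows(a, b):
            a, b = b, a
        if not bl.allows(a, b):
            logger.warning("edge %s - %s blacklisted both ways; dropped", a, b)
            continue
        trial = directed | {(a, b)}
        try:
            NetworkStructure(graph.nodes, states, trial)
        except ValueError:
            a, b = b, a
            if not bl.allows(a, b):
                logger.warning("edge %s - %s cannot be oriented acyclically; dropped", b, a)
                continue
            trial = directed | {(a, b)}
            NetworkStructure(graph.nodes, states, trial)
        directed = trial
    return NetworkStructure(graph.nodes, states, directed)
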