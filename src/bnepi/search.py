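"""Score-based and hybrid structure search.

Hill-climbing walks the space of DAGs by single-edge additions,
deletions and reversals, always taking the move that improves the
decomposable score the most; random restarts re-ascend from perturbed
copies of the incumbent to escape local maxima. MMHC first learns an
undirected skeleton with the Max-Min Parents-and-Children test sequence
and then hill-climbs with edge additions restricted to that skeleton.

Score decomposability makes each move's effect local: only the score
contribution of the node whose parent set changed is recomputed, and all
(node, parent-set) contributions are cached across the whole search.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .ci_tests import TestCounter, chi2_test
from .data import DataTable
from .network import Blacklist, Edge, NetworkStructure
from .scoring import ScoreReport, local_score, score_structure

logger = logging.getLogger(__name__)

__all__ = [
    "SearchState",
    "LocalScoreCache",
    "hill_climb",
    "enumerate_dags",
    "count_dags",
    "mmpc_neighbors",
    "mmhc",
]

_EPS = 1e-9  # minimum score gain for a move to count as an improvement


class LocalScoreCache:
    """Caches per-node score contributions keyed by (node, parent set)."""

    def __init__(self, data: DataTable, metric: str):
        self.metric = metric
        self.columns = list(data.columns)
        states = data.infer_states()
        self.n_states = {c: len(states[c]) for c in self.columns}
        flat = data.encode(data.infer_structure())
        if (flat < 0).any():
            raise ValueError("score-based search needs complete-case data")
        self.codes = {c: flat[:, i] for i, c in enumerate(self.columns)}
        self.n = len(flat)
        self._cache: Dict[Tuple[str, Tuple[str, ...]], float] = {}
        self.evaluations = 0

    def local(self, node: str, parents: Tuple[str, ...]) -> float:
        parents = tuple(sorted(parents))
        key = (node, parents)
        if key not in self._cache:
            r = self.n_states[node]
            q = 1
            j = np.zeros(self.n, dtype=np.int64)
            for p in parents:
                j = j * self.n_states[p] + self.codes[p]
                q *= self.n_states[p]
            flat = j * r + self.codes[node]
            table = np.bincount(flat, minlength=q * r).reshape(q, r).astype(float)
            self._cache[key] = local_score(table, self.metric, self.n)
            self.evaluations += 1
        return self._cache[key]

    def total(self, parent_map: Dict[str, Tuple[str, ...]]) -> float:
        return sum(self.local(v, ps) for v, ps in parent_map.items())


@dataclass
class SearchState:
    """Bookkeeping for one hill-climbing run."""

    edges: Set[Edge]
    score: float
    move_log: List[Tuple[str, Edge, float]] = field(default_factory=list)
    restart_index: int = 0
    seed: Optional[int] = None


def _parent_map(nodes: Sequence[str], edges: Set[Edge]) -> Dict[str, Tuple[str, ...]]:
    out: Dict[str, List[str]] = {v: [] for v in nodes}
    for a, b in edges:
        out[b].append(a)
    return {v: tuple(sorted(ps)) for v, ps in out.items()}


def _creates_cycle(nodes: Sequence[str], edges: Set[Edge], new: Edge) -> bool:
    """Would adding ``new`` close a directed cycle? (path child -> parent)"""
    src, dst = new[1], new[0]
    children: Dict[str, List[str]] = {v: [] for v in nodes}
    for a, b in edges:
        children[a].append(b)
    seen, frontier = {src}, [src]
    while frontier:
        v = frontier.pop()
        for w in children[v]:
            if w == dst:
                return True
            if w not in seen:
                seen.add(w)
                frontier.append(w)
    return False


def _moves(
    nodes: Sequence[str],
    edges: Set[Edge],
    bl: Blacklist,
    allowed_pairs: Optional[Set[FrozenSet[str]]],
) -> Iterable[Tuple[str, Edge]]:
    """Admissible single-edge moves in deterministic tie-break order:
    additions, then deletions, then reversals; edges lexicographic."""
    for u, v in itertools.combinations(sorted(nodes), 2):
        for a, b in ((u, v), (v, u)):
            if (a, b) in edges or (b, a) in edges:
                continue
            if allowed_pairs is not None and frozenset((a, b)) not in allowed_pairs:
                continue
            if not bl.allows(a, b):
                continue
            if not _creates_cycle(nodes, edges, (a, b)):
                yield ("add", (a, b))
    for e in sorted(edges):
        yield ("delete", e)
    for a, b in sorted(edges):
        if not bl.allows(b, a):
            continue
        if not _creates_cycle(nodes, edges - {(a, b)}, (b, a)):
            yield ("reverse", (a, b))


def _apply(edges: Set[Edge], move: Tuple[str, Edge]) -> Set[Edge]:
    kind, (a, b) = move
    if kind == "add":
        return edges | {(a, b)}
    if kind == "delete":
        return edges - {(a, b)}
    return edges - {(a, b)} | {(b, a)}


def _delta(
    cache: LocalScoreCache,
    nodes: Sequence[str],
    edges: Set[Edge],
    move: Tuple[str, Edge],
) -> float:
    """Score change of a move, via decomposability (only changed nodes)."""
    kind, (a, b) = move
    pm = _parent_map(nodes, edges)
    if kind == "add":
        return cache.local(b, pm[b] + (a,)) - cache.local(b, pm[b])
    if kind == "delete":
        new_b = tuple(p for p in pm[b] if p != a)
        return cache.local(b, new_b) - cache.local(b, pm[b])
    new_b = tuple(p for p in pm[b] if p != a)
    d = cache.local(b, new_b) - cache.local(b, pm[b])
    d += cache.local(a, pm[a] + (b,)) - cache.local(a, pm[a])
    return d


def _ascend(
    cache: LocalScoreCache,
    nodes: Sequence[str],
    edges: Set[Edge],
    bl: Blacklist,
    allowed_pairs: Optional[Set[FrozenSet[str]]],
    state: SearchState,
) -> Tuple[Set[Edge], float]:
    score = cache.total(_parent_map(nodes, edges))
    while True:
        best_move, best_delta = None, _EPS
        for move in _moves(nodes, edges, bl, allowed_pairs):
            d = _delta(cache, nodes, edges, move)
            if d > best_delta:
                best_move, best_delta = move, d
        if best_move is None:
            return edges, score
        edges = _apply(edges, best_move)
        score += best_delta
        state.move_log.append((best_move[0], best_move[1], best_delta))


def _perturb(
    rng: np.random.Generator,
    nodes: Sequence[str],
    edges: Set[Edge],
    bl: Blacklist,
    allowed_pairs: Optional[Set[FrozenSet[str]]],
    k: int,
) -> Set[Edge]:
    """k random admissible single-edge changes (the restart operator)."""
    edges = set(edges)
    for _ in range(k):
        moves = list(_moves(nodes, edges, bl, allowed_pairs))
        if not moves:
            break
        edges = _apply(edges, moves[rng.integers(len(moves))])
    return edges


def _start_edges(
    start,
    nodes: Sequence[str],
    bl: Blacklist,
    allowed_pairs: Optional[Set[FrozenSet[str]]],
    rng: np.random.Generator,
) -> Set[Edge]:
    if isinstance(start, NetworkStructure):
        return set(start.edges)
    if start == "empty":
        return set()
    if start == "full":
        order = sorted(nodes)
        edges = set()
        for i, a in enumerate(order):
            for b in order[i + 1:]:
                if bl.allows(a, b) and (
                    allowed_pairs is None or frozenset((a, b)) in allowed_pairs
                ):
                    edges.add((a, b))
        return edges
    if start == "random":
        return _perturb(rng, nodes, set(), bl, allowed_pairs, 2 * len(nodes))
    raise ValueError(f"unknown start {start!r}")


def hill_climb(
    data: DataTable,
    metric: str = "k2",
    blacklist: Optional[Blacklist] = None,
    start="empty",
    restarts: int = 0,
    perturbations: int = 5,
    seed: int = 0,
    allowed_pairs: Optional[Set[FrozenSet[str]]] = None,
) -> Tuple[NetworkStructure, ScoreReport, SearchState]:
    """Greedy hill-climbing over DAGs with random-restart perturbations.

    Each restart perturbs the best structure found so far by
    ``perturbations`` random admissible single-edge changes and
    re-ascends; the best-scoring structure over all restarts is
    returned. Identical seeds give identical output.
    """
    bl = blacklist or Blacklist()
    cache = LocalScoreCache(data, metric)
    nodes = tuple(cache.columns)
    rng = np.random.default_rng(seed)
    state = SearchState(set(), 0.0, seed=seed)

    edges = _start_edges(start, nodes, bl, allowed_pairs, rng)
    best_edges, best_score = _ascend(cache, nodes, edges, bl, allowed_pairs, state)
    if not best_edges and not list(_moves(nodes, set(), bl, allowed_pairs)):
        logger.warning("no admissible moves from the start structure")
    for r in range(restarts):
        state.restart_index = r + 1
        perturbed = _perturb(rng, nodes, best_edges, bl, allowed_pairs, perturbations)
        cand_edges, cand_score = _ascend(
            cache, nodes, perturbed, bl, allowed_pairs, state
        )
        if cand_score > best_score + _EPS:
            best_edges, best_score = cand_edges, cand_score
    states = data.infer_states()
    structure = NetworkStructure(nodes, states, best_edges)
    report = score_structure(data, structure)
    state.edges, state.score = best_edges, best_score
    return structure, report, state


# ---------------------------------------------------------------------------
# exhaustive enumeration (oracle support; DAG counts grow super-exponentially)
# ---------------------------------------------------------------------------

def enumerate_dags(nodes: Sequence[str], max_nodes: int = 5) -> List[FrozenSet[Edge]]:
    """All DAG edge sets over ``nodes`` (exact, duplicate-free; n <= 5)."""
    nodes = list(nodes)
    n = len(nodes)
    if n > max_nodes:
        raise ValueError(
            f"exhaustive enumeration capped at {max_nodes} nodes (got {n}); "
            "the DAG count grows super-exponentially"
        )
    if n == 0:
        return [frozenset()]
    pairs = list(itertools.combinations(nodes, 2))
    out: List[FrozenSet[Edge]] = []

    def acyclic(edges: Tuple[Edge, ...]) -> bool:
        children: Dict[str, List[str]] = {v: [] for v in nodes}
        indeg = {v: 0 for v in nodes}
        for a, b in edges:
            children[a].append(b)
            indeg[b] += 1
        queue = [v for v in nodes if indeg[v] == 0]
        seen = 0
        while queue:
            v = queue.pop()
            seen += 1
            for w in children[v]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        return seen == n

    for choice in itertools.product((None, 0, 1), repeat=len(pairs)):
        edges = tuple(
            (a, b) if c == 0 else (b, a)
            for (a, b), c in zip(pairs, choice)
            if c is not None
        )
        if acyclic(edges):
            out.append(frozenset(edges))
    return out


def count_dags(n: int) -> int:
    """Number of labelled DAGs on n nodes (recurrence oracle).

    a(n) = sum_{k=1..n} (-1)^(k+1) C(n,k) 2^(k(n-k)) a(n-k), a(0) = 1.
    """
    from math import comb

    a = [1]
    for m in range(1, n + 1):
        a.append(
            sum(
                (-1) ** (k + 1) * comb(m, k) * 2 ** (k * (m - k)) * a[m - k]
                for k in range(1, m + 1)
            )
        )
    return a[n]


# ---------------------------------------------------------------------------
# MMPC / MMHC
# ---------------------------------------------------------------------------

def mmpc_neighbors(
    data: DataTable,
    x: str,
    alpha: float = 0.05,
    sepset_cap: int = 3,
    counter: Optional[TestCounter] = None,
) -> Set[str]:
    """Estimated parents-and-children set of ``x`` (Max-Min forward/backward).

    Forward: each remaining candidate's association with ``x`` is
    minimized over conditioning subsets of the current neighbor set
    (subset size capped); the candidate whose minimum association is
    largest — smallest maximum p-value — enters if still significant.
    Candidates whose minimum association becomes non-significant are
    discarded permanently. Backward: neighbors separated from ``x`` by
    any subset of the rest are removed. Unlike a Markov blanket, spouses
    are excluded.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    cpc: List[str] = []
    candidates = [c for c in data.columns if c != x and len(data.levels(c)) >= 2]

    def max_p(y: str, pool: List[str]) -> float:
        worst = 0.0
        for size in range(0, min(sepset_cap, len(pool)) + 1):
            for cond in itertools.combinations(pool, size):
                p = chi2_test(data, x, y, cond, counter).p_value
                worst = max(worst, p)
                if worst >= 1.0:
                    return worst
        return worst

    while candidates:
        scored = [(max_p(y, cpc), y) for y in candidates]
        candidates = [y for p, y in scored if p < alpha]
        if not candidates:
            break
        scored = [(p, y) for p, y in scored if p < alpha]
        _, best = min(scored, key=lambda t: (t[0], t[1]))
        cpc.append(best)
        candidates.remove(best)
    # backward pruning
    for y in list(cpc):
        rest = [z for z in cpc if z != y]
        if max_p(y, rest) >= alpha:
            cpc.remove(y)
    return set(cpc)


def mmpc_skeleton(
    data: DataTable,
    alpha: float = 0.05,
    sepset_cap: int = 3,
    counter: Optional[TestCounter] = None,
) -> Set[FrozenSet[str]]:
    """Symmetrized (AND rule) union of all per-node neighbor sets."""
    neigh = {
        v: mmpc_neighbors(data, v, alpha, sepset_cap, counter)
        for v in data.columns
    }
    return {
        frozenset((v, w))
        for v in data.columns
        for w in neigh[v]
        if v in neigh[w]
    }


def mmhc(
    data: DataTable,
    metric: str = "k2",
    alpha: float = 0.05,
    blacklist: Optional[Blacklist] = None,
    restarts: int = 0,
    perturbations: int = 5,
    seed: int = 0,
    sepset_cap: int = 3,
    counter: Optional[TestCounter] = None,
) -> Tuple[NetworkStructure, ScoreReport, SearchState]:
    """Hybrid learner: MMPC skeleton, then skeleton-constrained hill-climb.

    Additions are only considered for pairs surviving the
    constraint-based phase; deletions and reversals are unrestricted
    within that set.
    """
    skeleton = mmpc_skeleton(data, alpha, sepset_cap, counter)
    return hill_climb(
        data,
        metric=metric,
        blacklist=blacklist,
        restarts=restarts,
        perturbations=perturbations,
        seed=seed,
        allowed_pairs=skeleton,
    )
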