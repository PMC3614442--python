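"""Core data model for discrete Bayesian networks.

A network is a directed acyclic graph (DAG) over named categorical
variables together with one conditional probability table (CPT) per node.
The joint distribution factorizes, by the Markov condition, into the
product of each node's probability given its parents; everything else in
the package (scoring, structure search, EM, exact queries) is built on
this factorization.

Conventions used throughout:

* node order is the declaration order of ``NetworkStructure.nodes``;
* each node's parents are listed in declaration order of the parent;
* CPT rows are indexed by the parent-state configuration enumerated
  row-major over the parents in that order (first parent most
  significant), so serialization is bit-exact and reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np

Edge = Tuple[str, str]

__all__ = [
    "CycleError",
    "UnknownNodeError",
    "NetworkStructure",
    "ParameterSet",
    "Blacklist",
    "PartialGraph",
    "validate_dag",
    "markov_blanket",
    "d_separated",
    "joint_probability",
    "count_free_parameters",
    "raw_joint_size",
    "moralize",
    "equivalence_class",
]


class CycleError(ValueError):
    """Raised when a directed cycle is found; carries one offending cycle."""

    def __init__(self, cycle: Sequence[str]):
        self.cycle = list(cycle)
        super().__init__("directed cycle detected: " + " -> ".join(self.cycle))


class UnknownNodeError(KeyError):
    """Raised when an edge, query or assignment names an undeclared node."""

    def __init__(self, name: str):
        self.node = name
        super().__init__(f"unknown node: {name!r}")


@dataclass(frozen=True)
class NetworkStructure:
    """DAG over named categorical variables.

    Parameters
    ----------
    nodes
        Variable names in declaration order.
    states
        Per node, the ordered list of category labels (at least 2).
    edges
        Directed (parent, child) pairs.
    """

    nodes: Tuple[str, ...]
    states: Mapping[str, Tuple[str, ...]]
    edges: frozenset

    def __init__(
        self,
        nodes: Iterable[str],
        states: Mapping[str, Sequence[str]] | None = None,
        edges: Iterable[Edge] = (),
    ):
        nodes = tuple(nodes)
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate node names")
        if states is None:
            states = {v: ("0", "1") for v in nodes}
        states = {v: tuple(str(s) for s in states[v]) for v in nodes}
        for v, st in states.items():
            if len(st) < 2:
                raise ValueError(f"node {v!r} needs >= 2 states, got {st}")
            if len(set(st)) != len(st):
                raise ValueError(f"node {v!r} has duplicate state labels")
        edge_list = [(str(a), str(b)) for a, b in edges]
        node_set = set(nodes)
        for a, b in edge_list:
            if a not in node_set:
                raise UnknownNodeError(a)
            if b not in node_set:
                raise UnknownNodeError(b)
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
        if len(set(edge_list)) != len(edge_list):
            raise ValueError("duplicate edges")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "edges", frozenset(edge_list))
        # acyclicity is part of the type invariant
        self.topological_order()

    # -- graph accessors ------------------------------------------------
    def parents(self, v: str) -> List[str]:
        """Parents of ``v`` in declaration order."""
        self._check(v)
        return [u for u in self.nodes if (u, v) in self.edges]

    def children(self, v: str) -> List[str]:
        self._check(v)
        return [u for u in self.nodes if (v, u) in self.edges]

    def n_states(self, v: str) -> int:
        return len(self.states[v])

    def state_index(self, v: str, label: str) -> int:
        try:
            return self.states[v].index(str(label))
        except ValueError:
            raise ValueError(
                f"state {label!r} not declared for node {v!r}; "
                f"declared states: {self.states[v]}"
            ) from None

    def _check(self, v: str) -> None:
        if v not in self.states:
            raise UnknownNodeError(v)

    # -- structure operations ------------------------------------------
    def topological_order(self) -> List[str]:
        """Topological order (parents first), deterministic in declaration order.

        Raises
        ------
        CycleError
            carrying one explicit offending cycle.
        """
        color: Dict[str, int] = {v: 0 for v in self.nodes}  # 0 new 1 open 2 done
        order: List[str] = []
        stack_trace: List[str] = []

        def visit(v: str) -> None:
            color[v] = 1
            stack_trace.append(v)
            for w in self.children(v):
                if color[w] == 1:
                    cyc = stack_trace[stack_trace.index(w):] + [w]
                    raise CycleError(cyc)
                if color[w] == 0:
                    visit(w)
            stack_trace.pop()
            color[v] = 2
            order.append(v)

        # outer loop in reverse declaration order so that, after the final
        # reversal, unconstrained nodes keep their declaration order
        for v in reversed(self.nodes):
            if color[v] == 0:
                visit(v)
        order.reverse()
        return order

    def with_edges(self, add: Iterable[Edge] = (), remove: Iterable[Edge] = ()) -> "NetworkStructure":
        """Copy with edges added/removed (validates acyclicity)."""
        edges = set(self.edges) - set(remove) | set(add)
        return NetworkStructure(self.nodes, self.states, edges)

    def skeleton(self) -> Set[frozenset]:
        return {frozenset(e) for e in self.edges}

    def config_count(self, v: str) -> int:
        """Number of parent-state configurations q_v (1 for orphans)."""
        q = 1
        for p in self.parents(v):
            q *= self.n_states(p)
        return q

    def parent_config_index(self, v: str, parent_states: Mapping[str, str]) -> int:
        """Row-major CPT row index for a parent-state assignment."""
        idx = 0
        for p in self.parents(v):
            idx = idx * self.n_states(p) + self.state_index(p, parent_states[p])
        return idx

    def parent_configurations(self, v: str) -> List[Dict[str, str]]:
        """All parent configurations of ``v`` in CPT row order."""
        ps = self.parents(v)
        out = []
        for combo in itertools.product(*[self.states[p] for p in ps]):
            out.append(dict(zip(ps, combo)))
        return out


class ParameterSet(dict):
    """CPTs: maps node -> array of shape ``(q_v, r_v)``.

    Row ``j`` is the distribution of the node given its parents' ``j``-th
    configuration (row-major over parents in declaration order); rows sum
    to 1 within 1e-9.
    """

    def __init__(self, structure: NetworkStructure, tables: Mapping[str, np.ndarray]):
        super().__init__()
        self.structure = structure
        for v in structure.nodes:
            if v not in tables:
                raise UnknownNodeError(v)
            t = np.asarray(tables[v], dtype=float)
            q, r = structure.config_count(v), structure.n_states(v)
            if t.shape != (q, r):
                raise ValueError(
                    f"CPT for {v!r} must have shape {(q, r)}, got {t.shape}"
                )
            if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
                raise ValueError(f"CPT for {v!r} has entries outside [0, 1]")
            if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {v!r} do not sum to 1")
            self[v] = t

    @classmethod
    def uniform(cls, structure: NetworkStructure) -> "ParameterSet":
        tables = {
            v: np.full(
                (structure.config_count(v), structure.n_states(v)),
                1.0 / structure.n_states(v),
            )
            for v in structure.nodes
        }
        return cls(structure, tables)

    def prob(self, v: str, state: str, parent_states: Mapping[str, str]) -> float:
        j = self.structure.parent_config_index(v, parent_states)
        return float(self[v][j, self.structure.state_index(v, state)])


@dataclass(frozen=True)
class Blacklist:
    """Forbidden directed edges; learners may never emit them."""

    forbidden: frozenset = field(default_factory=frozenset)

    def __init__(self, pairs: Iterable[Edge] = ()):
        object.__setattr__(self, "forbidden", frozenset((str(a), str(b)) for a, b in pairs))

    def allows(self, parent: str, child: str) -> bool:
        return (parent, child) not in self.forbidden

    def validate_nodes(self, structure: NetworkStructure) -> None:
        declared = set(structure.nodes)
        for a, b in self.forbidden:
            if a not in declared:
                raise UnknownNodeError(a)
            if b not in declared:
                raise UnknownNodeError(b)

    def __contains__(self, pair: Edge) -> bool:
        return tuple(pair) in self.forbidden

    def __iter__(self):
        return iter(sorted(self.forbidden))


@dataclass
class PartialGraph:
    """Mixed graph: compelled (directed) plus reversible (undirected) edges.

    The output type of the equivalence-class operation and of
    constraint-based learning before final orientation.
    """

    nodes: Tuple[str, ...]
    directed: Set[Edge]
    undirected: Set[frozenset]

    def skeleton(self) -> Set[frozenset]:
        return {frozenset(e) for e in self.directed} | set(self.undirected)


# ---------------------------------------------------------------------------
# free functions (the operational surface)
# ---------------------------------------------------------------------------

def validate_dag(structure: NetworkStructure) -> List[str]:
    """Topological order of the nodes; raises :class:`CycleError` otherwise."""
    return structure.topological_order()


def markov_blanket(structure: NetworkStructure, node: str) -> Set[str]:
    """Parents, children and children's other parents of ``node``."""
    structure._check(node)
    blanket: Set[str] = set(structure.parents(node)) | set(structure.children(node))
    for c in structure.children(node):
        blanket.update(structure.parents(c))
    blanket.discard(node)
    return blanket


def _ancestors(structure: NetworkStructure, seeds: Set[str]) -> Set[str]:
    out = set(seeds)
    frontier = list(seeds)
    while frontier:
        v = frontier.pop()
        for p in structure.parents(v):
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def d_separated(
    structure: NetworkStructure,
    X: Iterable[str],
    Z: Iterable[str],
    Y: Iterable[str] = (),
) -> bool:
    """Whether the node set ``Y`` d-separates ``X`` from ``Z``.

    True iff every path between ``X`` and ``Z`` is blocked given ``Y``:
    serial and divergent connections are blocked by conditioning on the
    middle node; convergent (collider) connections are blocked *unless*
    the collider or one of its descendants is conditioned on.

    Implemented by the ancestral-moral-graph reduction: restrict to the
    ancestors of ``X ∪ Z ∪ Y``, moralize, delete ``Y``, and test
    undirected separation. A path-enumeration oracle in the test suite
    cross-checks this on all small graphs.
    """
    X, Z, Y = set(X), set(Z), set(Y)
    if not X or not Z:
        raise ValueError("X and Z must be nonempty")
    for v in X | Z | Y:
        structure._check(v)
    if X & Z or X & Y or Z & Y:
        raise ValueError("X, Z, Y must be pairwise disjoint")

    anc = _ancestors(structure, X | Z | Y)
    # moralize the ancestral subgraph
    adj: Dict[str, Set[str]] = {v: set() for v in anc}
    for a, b in structure.edges:
        if a in anc and b in anc:
            adj[a].add(b)
            adj[b].add(a)
    for v in anc:
        ps = [p for p in structure.parents(v) if p in anc]
        for p1, p2 in itertools.combinations(ps, 2):
            adj[p1].add(p2)
            adj[p2].add(p1)
    # undirected reachability avoiding Y
    seen = set(X)
    frontier = list(X)
    while frontier:
        v = frontier.pop()
        for w in adj[v]:
            if w in Y or w in seen:
                continue
            if w in Z:
                return False
            seen.add(w)
            frontier.append(w)
    return True


def joint_probability(
    structure: NetworkStructure,
    params: ParameterSet,
    assignment: Mapping[str, str],
) -> float:
    """Probability of one complete assignment under the factorized joint."""
    missing = [v for v in structure.nodes if v not in assignment]
    if missing:
        raise ValueError(f"incomplete assignment; missing {missing}")
    p = 1.0
    for v in structure.nodes:
        p *= params.prob(v, assignment[v], assignment)
    return p


def count_free_parameters(structure: NetworkStructure) -> int:
    """Free parameters of the factorization: sum of (r_v - 1) * q_v."""
    return sum(
        (structure.n_states(v) - 1) * structure.config_count(v)
        for v in structure.nodes
    )


def raw_joint_size(structure: NetworkStructure) -> int:
    """Cells of the unfactored joint table: product of all state counts."""
    n = 1
    for v in structure.nodes:
        n *= structure.n_states(v)
    return n


def moralize(structure: NetworkStructure) -> Set[frozenset]:
    """Undirected Markov network: drop directions and marry co-parents.

    Equivalently, connect each node to every member of its Markov blanket.
    """
    edges = {frozenset(e) for e in structure.edges}
    for v in structure.nodes:
        ps = structure.parents(v)
        for p1, p2 in itertools.combinations(ps, 2):
            edges.add(frozenset((p1, p2)))
    return edges


def _meek_orient(
    nodes: Sequence[str],
    directed: Set[Edge],
    undirected: Set[frozenset],
) -> None:
    """Meek's orientation-propagation rules, applied to a fixed point.

    Orients undirected edges whose direction is forced if no new
    v-structure and no directed cycle may be created. Mutates both sets.
    """

    def adjacent(a: str, b: str) -> bool:
        return (
            (a, b) in directed or (b, a) in directed or frozenset((a, b)) in undirected
        )

    def has_directed_path(src: str, dst: str) -> bool:
        seen = {src}
        frontier = [src]
        while frontier:
            v = frontier.pop()
            for (a, b) in directed:
                if a == v and b not in seen:
                    if b == dst:
                        return True
                    seen.add(b)
                    frontier.append(b)
        return False

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=sorted):
            a, b = sorted(e)
            for (x, y) in ((a, b), (b, a)):
                orient = False
                # R1: z -> x, z not adjacent y  =>  x -> y
                for (z, w) in list(directed):
                    if w == x and z != y and not adjacent(z, y):
                        orient = True
                        break
                # R2: directed path x => y through directed edges
                if not orient and has_directed_path(x, y):
                    orient = True
                # R3: x - z1 -> y, x - z2 -> y, z1/z2 non-adjacent
                if not orient:
                    mids = [
                        z
                        for z in nodes
                        if frozenset((x, z)) in undirected and (z, y) in directed
                    ]
                    for z1, z2 in itertools.combinations(mids, 2):
                        if not adjacent(z1, z2):
                            orient = True
                            break
                if orient:
                    undirected.discard(e)
                    directed.add((x, y))
                    changed = True
                    break
            if changed:
                break


def equivalence_class(structure: NetworkStructure) -> PartialGraph:
    """CPDAG of the DAG: compelled edges directed, reversible ones undirected.

    Two DAGs are observationally equivalent iff they share a skeleton and
    v-structures; the CPDAG keeps the skeleton, directs the v-structure
    edges and everything their orientation forces (Meek closure), and
    leaves the rest undirected.
    """
    directed: Set[Edge] = set()
    undirected: Set[frozenset] = {frozenset(e) for e in structure.edges}
    skeleton = {frozenset(e) for e in structure.edges}
    # v-structures: a -> c <- b with a, b non-adjacent
    for c in structure.nodes:
        ps = structure.parents(c)
        for a, b in itertools.combinations(ps, 2):
            if frozenset((a, b)) not in skeleton:
                for p in (a, b):
                    e = frozenset((p, c))
                    if e in undirected:
                        undirected.discard(e)
                        directed.add((p, c))
    _meek_orient(structure.nodes, directed, undirected)
    return PartialGraph(structure.nodes, directed, undirected)
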