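"""Independent brute-force oracles used to validate the implementation.

Each oracle takes a deliberately different route from the code under
test: d-separation by explicit path enumeration with the serial /
divergent / convergent blocking rules, the K2 marginal likelihood by
numerical integration of the Dirichlet integral, posteriors by summing
the joint over explicit assignments.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, List, Set, Tuple

import numpy as np
from scipy.integrate import quad

from bnepi.network import NetworkStructure


def random_dag(rng: np.random.Generator, n: int, p_edge: float = 0.4) -> NetworkStructure:
    """Random binary-variable DAG: random order + random forward edges."""
    names = [f"V{i}" for i in range(n)]
    order = list(rng.permutation(n))
    edges = []
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p_edge:
            a, b = (order[i], order[j])
            edges.append((names[a], names[b]))
    return NetworkStructure(names, None, edges)


def _descendants(structure: NetworkStructure, v: str) -> Set[str]:
    out, frontier = set(), [v]
    while frontier:
        u = frontier.pop()
        for c in structure.children(u):
            if c not in out:
                out.add(c)
                frontier.append(c)
    return out


def dsep_paths_oracle(
    structure: NetworkStructure,
    X: Iterable[str],
    Z: Iterable[str],
    Y: Iterable[str],
) -> bool:
    """d-separation by enumerating every undirected simple path.

    A path is blocked given Y iff some interior node m is either a
    non-collider in Y, or a collider with neither m nor any descendant
    of m in Y. X and Z are d-separated iff every path is blocked.
    """
    X, Z, Y = set(X), set(Z), set(Y)
    neighbors: Dict[str, Set[str]] = {v: set() for v in structure.nodes}
    for a, b in structure.edges:
        neighbors[a].add(b)
        neighbors[b].add(a)
    desc = {v: _descendants(structure, v) for v in structure.nodes}

    def path_active(path: List[str]) -> bool:
        for i in range(1, len(path) - 1):
            prev, m, nxt = path[i - 1], path[i], path[i + 1]
            collider = (prev, m) in structure.edges and (nxt, m) in structure.edges
            if collider:
                if m not in Y and not (desc[m] & Y):
                    return False  # blocked collider
            else:
                if m in Y:
                    return False  # blocked chain/fork
        return True

    def walk(path: List[str]) -> bool:
        v = path[-1]
        if v in Z and len(path) > 1:
            return path_active(path)
        for w in sorted(neighbors[v]):
            if w in path:
                continue
            if w in X:
                continue
            if walk(path + [w]):
                return True
        return False

    for x in sorted(X):
        if walk([x]):
            return False
    return True


def k2_quad_oracle(counts_by_config: List[List[int]]) -> float:
    """log marginal likelihood of one binary node via numerical integration.

    For each parent configuration with counts (a, b) the contribution is
    ln ∫0^1 θ^a (1-θ)^b dθ  (uniform = Dirichlet(1,1) prior density 1).
    """
    total = 0.0
    for counts in counts_by_config:
        a, b = counts
        val, _ = quad(lambda t: t**a * (1 - t) ** b, 0, 1, epsabs=1e-13, epsrel=1e-13)
        total += np.log(val)
    return total


def posterior_by_enumeration(structure, params, target, evidence) -> np.ndarray:
    """Posterior by summing joint_probability over explicit assignments."""
    from bnepi.network import joint_probability

    states = structure.states
    post = np.zeros(structure.n_states(target))
    free = [v for v in structure.nodes if v not in evidence and v != target]
    for k, t_state in enumerate(states[target]):
        for combo in itertools.product(*[states[v] for v in free]):
            a = dict(evidence)
            a[target] = t_state
            a.update(zip(free, combo))
            post[k] += joint_probability(structure, params, a)
    return post / post.sum()


def dsep_signature(structure: NetworkStructure) -> frozenset:
    """All singleton d-separation facts (x, z, conditioning set)."""
    from bnepi.network import d_separated

    nodes = structure.nodes
    facts = set()
    for x, z in itertools.combinations(nodes, 2):
        rest = [v for v in nodes if v not in (x, z)]
        for r in range(len(rest) + 1):
            for cond in itertools.combinations(rest, r):
                if d_separated(structure, {x}, {z}, set(cond)):
                    facts.add((x, z, cond))
    return frozenset(facts)
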