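"""Synthetic case-control data from ground-truth networks.

Emulates the shape of a case-control gene-environment study: all-binary
categorical tables sampled from a known network, subjects selected by
outcome status (which deliberately distorts the outcome's marginal
relative to the population, exactly as disease-status sampling does),
and missing-completely-at-random holes concentrated in the genotype
columns.

The fixture networks are repository constants chosen for qualitative
realism (documented effect sizes, a gene-gene v-structure at one SNP, a
gene-environment interaction variant); their CPT values are NOT
estimates of any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .data import DataTable, MISSING_CODE
from .network import NetworkStructure, ParameterSet

__all__ = [
    "GeneratorConfig",
    "ancestral_sample",
    "case_control_sample",
    "inject_mcar",
    "fixture_networks",
    "generate",
]


@dataclass
class GeneratorConfig:
    """Declarative description of one synthetic dataset.

    Either ``n`` (population sampling) or ``n_cases``/``n_controls``
    (outcome-conditional sampling) must be given. ``protected`` columns
    never receive missing cells — by default the non-SNP columns, since
    genotyping is where real cohorts lose records.
    """

    structure: NetworkStructure
    params: ParameterSet
    n: Optional[int] = None
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    outcome: Optional[str] = None
    case_state: str = "1"
    mcar_rate: float = 0.0
    protected: Tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mcar_rate < 1:
            raise ValueError("mcar_rate must lie in [0, 1)")
        if self.n is None and (self.n_cases is None or self.n_controls is None):
            raise ValueError("give n, or both n_cases and n_controls")
        if self.n_cases is not None and self.outcome is None:
            raise ValueError("case-control sampling needs an outcome node")
        if self.outcome is not None:
            self.structure._check(self.outcome)


def _sample_codes(
    structure: NetworkStructure,
    params: ParameterSet,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized root-to-leaf ancestral sampling."""
    col_of = {v: k for k, v in enumerate(structure.nodes)}
    codes = np.zeros((n, len(structure.nodes)), dtype=np.int64)
    u = rng.random((n, len(structure.nodes)))
    for v in structure.topological_order():
        j = np.zeros(n, dtype=np.int64)
        for p in structure.parents(v):
            j = j * structure.n_states(p) + codes[:, col_of[p]]
        cum = np.cumsum(params[v][j], axis=1)
        codes[:, col_of[v]] = (u[:, col_of[v]][:, None] > cum).sum(axis=1)
    return codes


def ancestral_sample(
    structure: NetworkStructure,
    params: ParameterSet,
    n: int,
    seed: int = 0,
) -> DataTable:
    """``n`` i.i.d. records drawn from the network's joint distribution."""
    rng = np.random.default_rng(seed)
    return DataTable.from_codes(_sample_codes(structure, params, n, rng), structure)


def case_control_sample(
    structure: NetworkStructure,
    params: ParameterSet,
    outcome: str,
    case_state: str,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
    max_attempts: int = 1000,
) -> DataTable:
    """Outcome-conditional sampling to exact case/control quotas.

    Rejection sampling in batches until both quotas are met; the output
    is shuffled so case status carries no row-order information. Note
    the outcome's marginal in the output is ``n_cases / (n_cases +
    n_controls)`` by construction, not the population marginal — the
    defining distortion of case-control designs.
    """
    structure._check(outcome)
    case_code = structure.state_index(outcome, case_state)
    o_col = list(structure.nodes).index(outcome)
    rng = np.random.default_rng(seed)
    need_cases, need_controls = n_cases, n_controls
    kept = []
    batch = max(4 * (n_cases + n_controls), 100)
    for _ in range(max_attempts):
        if need_cases <= 0 and need_controls <= 0:
            break
        codes = _sample_codes(structure, params, batch, rng)
        is_case = codes[:, o_col] == case_code
        if need_cases > 0:
            take = codes[is_case][:need_cases]
            kept.append(take)
            need_cases -= len(take)
        if need_controls > 0:
            take = codes[~is_case][:need_controls]
            kept.append(take)
            need_controls -= len(take)
    else:
        raise RuntimeError(
            f"case/control quotas not met within {max_attempts} batches of "
            f"{batch}; outcome state {case_state!r} may be too rare"
        )
    out = (
        np.vstack(kept)
        if kept
        else np.empty((0, len(structure.nodes)), dtype=np.int64)
    )
    rng.shuffle(out, axis=0)
    return DataTable.from_codes(out, structure)


def inject_mcar(
    data: DataTable,
    rate: float,
    protected: Iterable[str] = (),
    seed: int = 0,
) -> DataTable:
    """Set each unprotected cell missing independently with probability ``rate``."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    protected = set(protected)
    unknown = protected - set(data.columns)
    if unknown:
        raise ValueError(f"protected columns not in the table: {sorted(unknown)}")
    if rate == 0:
        return DataTable(data.df)
    rng = np.random.default_rng(seed)
    df = data.df.copy()
    for c in data.columns:
        if c in protected:
            continue
        holes = rng.random(len(df)) < rate
        col = df[c].to_numpy(dtype=object)
        col[holes] = None
        df[c] = col
    return DataTable(df)


def generate(config: GeneratorConfig) -> DataTable:
    """One-call generator: sample per the config, then inject missingness.

    Sampling and missingness use independent streams derived from the
    single root seed, so the same seed always yields the same bytes.
    """
    s_sample, s_mcar = np.random.SeedSequence(config.seed).spawn(2)
    seed_sample = int(s_sample.generate_state(1)[0] % (2**31))
    seed_mcar = int(s_mcar.generate_state(1)[0] % (2**31))
    if config.n_cases is not None:
        table = case_control_sample(
            config.structure,
            config.params,
            config.outcome,
            config.case_state,
            config.n_cases,
            config.n_controls,
            seed=seed_sample,
        )
    else:
        table = ancestral_sample(
            config.structure, config.params, config.n, seed=seed_sample
        )
    if config.mcar_rate > 0:
        table = inject_mcar(
            table, config.mcar_rate, config.protected, seed=seed_mcar
        )
    return table


# ---------------------------------------------------------------------------
# fixture networks
# ---------------------------------------------------------------------------

def _net(nodes, edges, cpts) -> Tuple[NetworkStructure, ParameterSet]:
    structure = NetworkStructure(nodes, None, edges)
    tables = {}
    for v in nodes:
        t = np.asarray(cpts[v], dtype=float)
        if t.ndim == 1:
            t = np.stack([1.0 - t, t], axis=1)
        tables[v] = t
    return structure, ParameterSet(structure, tables)


def fixture_networks() -> Dict[str, Tuple[NetworkStructure, ParameterSet]]:
    """Named ground-truth networks used across tests and examples.

    * ``chain3`` / ``fork3`` / ``collider3`` — three-node pedagogy: the
      chain and fork are Markov equivalent; the collider's parents are
      marginally independent but conditionally dependent given the child.
    * ``exposure6`` — the six-node exemplar (three SNPs S1-S3, exposure
      E, biomarker B, cancer C) with strong documented CPTs; its factored
      free-parameter count is 12 against 64 raw joint cells.
    * ``bladder11`` — an 11-variable binary case-control-style network
      (demographics, smoking, toenail-arsenic exposure, six SNPs) whose
      outcome blanket is {GENDER, SMOKER, XRCC3_241, XRCC3_04}, with a
      gene-gene v-structure at XRCC3_241.
    * ``bladder11_arsenic`` — same plus an arsenic -> XRCC3_241 edge,
      giving a gene-environment interaction and pulling TOENAIL_AS into
      the outcome's blanket.

    All CPT entries are arbitrary documented constants (probability of
    state "1"; for nodes with parents, rows follow the CPT row order of
    the structure), not estimates of any cohort.
    """
    nets: Dict[str, Tuple[NetworkStructure, ParameterSet]] = {}

    nets["chain3"] = _net(
        ["A", "B", "C"],
        [("A", "B"), ("B", "C")],
        {"A": [0.4], "B": [0.2, 0.8], "C": [0.25, 0.75]},
    )
    nets["fork3"] = _net(
        ["A", "B", "C"],
        [("B", "A"), ("B", "C")],
        {"B": [0.5], "A": [0.2, 0.8], "C": [0.3, 0.7]},
    )
    nets["collider3"] = _net(
        ["A", "B", "C"],
        [("A", "C"), ("B", "C")],
        # P(C=1 | A,B) rows over (A,B): interaction with no marginal A-B link
        {"A": [0.5], "B": [0.5], "C": [0.05, 0.5, 0.5, 0.95]},
    )

    nets["exposure6"] = _net(
        ["S1", "S2", "S3", "E", "B", "C"],
        [("S2", "S1"), ("S3", "E"), ("E", "B"), ("E", "C"), ("S1", "C")],
        {
            "S2": [0.5],
            "S3": [0.4],
            "S1": [0.2, 0.7],  # rows over S2
            "E": [0.25, 0.75],  # rows over S3
            "B": [0.15, 0.85],  # rows over E
            "C": [0.05, 0.45, 0.35, 0.85],  # rows over (S1, E)
        },
    )

    bladder_nodes = [
        "CANCER",
        "GENDER",
        "AGE",
        "SMOKER",
        "TOENAIL_AS",
        "XRCC3_03",
        "XRCC3_04",
        "XRCC3_241",
        "XPD_03",
        "XPD_09",
        "XPD_312",
    ]
    bladder_edges = [
        ("GENDER", "CANCER"),
        ("GENDER", "SMOKER"),
        ("CANCER", "SMOKER"),
        ("CANCER", "XRCC3_241"),
        ("XRCC3_04", "XRCC3_241"),
        ("AGE", "TOENAIL_AS"),
        ("XRCC3_03", "XPD_312"),
        ("XPD_03", "XPD_09"),
    ]
    bladder_cpts = {
        "GENDER": [0.6],  # "1" = male
        "AGE": [0.5],  # "1" = over 60
        "CANCER": [0.25, 0.45],  # rows over GENDER
        "SMOKER": [0.3, 0.5, 0.5, 0.7],  # rows over (CANCER, GENDER)
        "TOENAIL_AS": [0.08, 0.25],  # rows over AGE; "1" = top-decile arsenic
        "XRCC3_03": [0.35],
        "XRCC3_04": [0.4],
        # rows over (CANCER, XRCC3_04): non-multiplicative, so the two
        # marginally independent parents become dependent given the child
        "XRCC3_241": [0.25, 0.55, 0.55, 0.45],
        "XPD_03": [0.45],
        "XPD_09": [0.25, 0.7],  # rows over XPD_03 (linkage)
        "XPD_312": [0.2, 0.6],  # rows over XRCC3_03 (linkage)
    }
    nets["bladder11"] = _net(bladder_nodes, bladder_edges, bladder_cpts)

    arsenic_edges = bladder_edges + [("TOENAIL_AS", "XRCC3_241")]
    arsenic_cpts = dict(bladder_cpts)
    # rows over (CANCER, TOENAIL_AS, XRCC3_04): arsenic raises the variant
    # probability mainly among cases — a gene-environment interaction
    arsenic_cpts["XRCC3_241"] = [0.2, 0.5, 0.35, 0.6, 0.5, 0.4, 0.8, 0.6]
    nets["bladder11_arsenic"] = _net(bladder_nodes, arsenic_edges, arsenic_cpts)

    return nets
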