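"""File formats: network JSON, DOT export, blacklist CSV, data CSV.

The network file is a JSON document with fields ``nodes`` (ordered),
``states`` (per node, ordered), ``edges`` (list of [parent, child]) and
optionally ``cpts`` (per node, the list of probability rows in the
documented parent-configuration order: row-major over parents in node
declaration order). Because state and configuration order are pinned
down, write/read round-trips are bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .data import DataTable
from .network import Blacklist, NetworkStructure, ParameterSet

__all__ = [
    "read_network",
    "write_network",
    "to_dot",
    "read_blacklist",
    "write_blacklist",
    "read_table",
    "write_table",
]

PathLike = Union[str, Path]
DEFAULT_MISSING_TOKEN = "NA"


def write_network(
    path: PathLike,
    structure: NetworkStructure,
    params: Optional[ParameterSet] = None,
) -> None:
    doc = {
        "nodes": list(structure.nodes),
        "states": {v: list(structure.states[v]) for v in structure.nodes},
        "edges": sorted([list(e) for e in structure.edges]),
    }
    if params is not None:
        doc["cpts"] = {v: params[v].tolist() for v in structure.nodes}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_network(
    path: PathLike,
) -> Tuple[NetworkStructure, Optional[ParameterSet]]:
    doc = json.loads(Path(path).read_text())
    structure = NetworkStructure(
        doc["nodes"], doc.get("states"), [tuple(e) for e in doc.get("edges", [])]
    )
    params = None
    if "cpts" in doc:
        params = ParameterSet(
            structure, {v: np.asarray(t) for v, t in doc["cpts"].items()}
        )
    return structure, params


def to_dot(structure: NetworkStructure, name: str = "bn") -> str:
    """Graphviz DOT text for visualization."""
    lines = [f"digraph {name} {{"]
    for v in structure.nodes:
        lines.append(f'  "{v}";')
    for a, b in sorted(structure.edges):
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def read_blacklist(path: PathLike) -> Blacklist:
    """Two-column CSV ``from,to`` (header required) of forbidden edges."""
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["from", "to"]:
        raise ValueError(
            f"blacklist file must have header 'from,to'; got {list(df.columns)}"
        )
    return Blacklist(
        (str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    )


def write_blacklist(path: PathLike, blacklist: Blacklist) -> None:
    pd.DataFrame(sorted(blacklist.forbidden), columns=["from", "to"]).to_csv(
        path, index=False
    )


def read_table(
    path: PathLike, missing_token: str = DEFAULT_MISSING_TOKEN
) -> DataTable:
    """Read a subjects-by-variables CSV (header row mandatory)."""
    df = pd.read_csv(
        path,
        dtype=str,
        keep_default_na=False,
        na_values=[missing_token],
        skip_blank_lines=True,
    )
    if len(df.columns) == 0 or df.shape[0] == 0:
        raise ValueError(f"empty data file: {path}")
    return DataTable(df)


def write_table(
    path: PathLike,
    table: DataTable,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> None:
    table.df.fillna(missing_token).to_csv(path, index=False)
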