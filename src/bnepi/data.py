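"""Categorical data tables: subjects x variables with a missingness mask.

A :class:`DataTable` wraps a pandas DataFrame of string category labels
(``None``/NaN marks a missing cell) and provides the integer encoding the
numerical modules work on: a matrix of state codes with ``-1`` for
missing. State order follows the network declaration when a structure is
given, otherwise lexicographic order of the observed labels.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .network import NetworkStructure, UnknownNodeError

MISSING_CODE = -1

__all__ = ["DataTable", "MISSING_CODE"]


class DataTable:
    """Rectangular categorical dataset.

    Parameters
    ----------
    df
        DataFrame whose cells are category labels (any scalar; stored as
        strings) or missing (``None``, ``np.nan`` or ``pd.NA``).
    """

    def __init__(self, df: pd.DataFrame):
        if df.shape[1] == 0:
            raise ValueError("data table needs at least one column")
        clean = df.copy()
        for c in clean.columns:
            col = clean[c]
            mask = col.isna()
            clean[c] = col.astype("object").astype(str).where(~mask, other=None)
        self.df: pd.DataFrame = clean.reset_index(drop=True)

    # -- basic properties ----------------------------------------------
    @property
    def columns(self) -> List[str]:
        return [str(c) for c in self.df.columns]

    @property
    def n(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return self.n

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.df.isna()

    @property
    def n_missing_cells(self) -> int:
        return int(self.missing_mask.to_numpy().sum())

    def levels(self, column: str) -> List[str]:
        """Observed labels of a column, lexicographically sorted."""
        if column not in self.df.columns:
            raise UnknownNodeError(column)
        vals = self.df[column].dropna().unique()
        return sorted(str(v) for v in vals)

    # -- derived tables -------------------------------------------------
    def complete_cases(self, columns: Optional[Sequence[str]] = None) -> "DataTable":
        """Rows with no missing cell (optionally only over ``columns``)."""
        sub = self.df if columns is None else self.df[list(columns)]
        keep = ~sub.isna().any(axis=1)
        return DataTable(self.df.loc[keep])

    def select(self, columns: Sequence[str]) -> "DataTable":
        return DataTable(self.df[list(columns)])

    # -- encoding --------------------------------------------------------
    def infer_states(self) -> Dict[str, List[str]]:
        """Per-column ordered state lists (lexicographic label order)."""
        out = {}
        for c in self.columns:
            lv = self.levels(c)
            if len(lv) < 2:
                raise ValueError(
                    f"column {c!r} has fewer than 2 observed levels: {lv}"
                )
            out[c] = lv
        return out

    def infer_structure(self, edges=()) -> NetworkStructure:
        """Edge-free (or given-edge) structure over the table's columns."""
        return NetworkStructure(self.columns, self.infer_states(), edges)

    def encode(self, structure: NetworkStructure) -> np.ndarray:
        """Integer code matrix, columns in ``structure.nodes`` order.

        Missing cells become :data:`MISSING_CODE`. Raises on labels not
        declared in the structure.
        """
        n = self.n
        codes = np.empty((n, len(structure.nodes)), dtype=np.int64)
        for k, v in enumerate(structure.nodes):
            if v not in self.df.columns:
                raise UnknownNodeError(v)
            mapping = {s: i for i, s in enumerate(structure.states[v])}
            col = self.df[v]
            enc = col.map(mapping)
            bad = enc.isna() & ~col.isna()
            if bad.any():
                label = col[bad].iloc[0]
                raise ValueError(
                    f"unseen category label {label!r} in column {v!r}; "
                    f"declared states: {structure.states[v]}"
                )
            codes[:, k] = enc.fillna(MISSING_CODE).astype(np.int64).to_numpy()
        return codes

    @classmethod
    def from_codes(
        cls, codes: np.ndarray, structure: NetworkStructure
    ) -> "DataTable":
        """Inverse of :meth:`encode` (codes may contain MISSING_CODE)."""
        cols = {}
        for k, v in enumerate(structure.nodes):
            labels = np.asarray(structure.states[v], dtype=object)
            col = np.where(codes[:, k] >= 0, labels[codes[:, k]], None)
            cols[v] = col
        return cls(pd.DataFrame(cols, columns=list(structure.nodes)))

    def __eq__(self, other) -> bool:
        if not isinstance(other, DataTable):
            return NotImplemented
        return self.df.equals(other.df)

    def __repr__(self) -> str:
        return (
            f"DataTable({self.n} rows x {len(self.columns)} columns, "
            f"{self.n_missing_cells} missing cells)"
        )
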