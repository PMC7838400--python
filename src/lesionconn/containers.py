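"""Shared in-memory containers: node tables, connectomes, binary graphs.

A *node table* is a pandas DataFrame with columns
``node_id, x, y, z, module, hemisphere``: one row per brain region (node),
MNI-like millimetre coordinates, an integer module label in ``1..M`` and a
hemisphere in ``{"L", "R"}`` derived from the sign of ``x`` (x < 0 is left;
generated tables never place nodes exactly on the midline).

A :class:`Connectome` is one subject's symmetric node-by-node matrix of
Fisher-z transformed correlations over the subject's *retained* nodes (after
any lesion, a subset of the full node space). The diagonal carries no
information and is excluded from every downstream computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import IncompatibleInputError, ParameterError

NODE_TABLE_COLUMNS = ["node_id", "x", "y", "z", "module", "hemisphere"]

GROUPS = ("HC", "REAL", "PSEUDO", "TARGETED")


def validate_node_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check node-table invariants and return the table unchanged.

    Raises
    ------
    ParameterError
        If node ids are not unique and contiguous from 0, a module is not
        bilateral, or the hemisphere column disagrees with the sign of x.
    """
    missing = [c for c in NODE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ParameterError(f"node table missing columns: {missing}")
    ids = np.sort(table["node_id"].to_numpy())
    if not np.array_equal(ids, np.arange(len(table))):
        raise ParameterError("node_id must be unique and contiguous from 0")
    hemi = np.where(table["x"].to_numpy() < 0, "L", "R")
    if not np.array_equal(hemi, table["hemisphere"].to_numpy()):
        raise ParameterError("hemisphere must be 'L' iff x < 0")
    for m, sub in table.groupby("module"):
        sides = set(sub["hemisphere"])
        if sides != {"L", "R"}:
            raise ParameterError(f"module {m} is not bilateral (sides: {sides})")
    return table


def hemisphere_nodes(table: pd.DataFrame, hemisphere: str) -> np.ndarray:
    """Node ids of one hemisphere, in node-id order."""
    if hemisphere not in ("L", "R"):
        raise ParameterError(f"hemisphere must be 'L' or 'R', got {hemisphere!r}")
    sub = table.loc[table["hemisphere"] == hemisphere, "node_id"]
    return np.sort(sub.to_numpy())


@dataclass
class Connectome:
    """Symmetric Fisher-z correlation matrix over a subject's retained nodes.

    Attributes
    ----------
    z : (n', n') float array, symmetric, zero diagonal.
    nodes : (n',) int array of retained node ids, ascending.
    subject_id : identifier of the source subject.
    group : one of ``HC, REAL, PSEUDO, TARGETED``.
    mask_id : lesion-mask identifier for lesioned connectomes, else None.
    """

    z: np.ndarray
    nodes: np.ndarray
    subject_id: str = "s0"
    group: str = "HC"
    mask_id: str | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.nodes = np.asarray(self.nodes, dtype=int)
        n = len(self.nodes)
        if self.z.shape != (n, n):
            raise IncompatibleInputError(
                f"matrix shape {self.z.shape} does not match {n} retained nodes"
            )
        if self.group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def copy(self) -> "Connectome":
        return replace(self, z=self.z.copy(), nodes=self.nodes.copy())

    def index_of(self, node_ids) -> np.ndarray:
        """Positional indices of ``node_ids`` within ``self.nodes``."""
        pos = {nid: i for i, nid in enumerate(self.nodes)}
        try:
            return np.array([pos[int(n)] for n in node_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise IncompatibleInputError(f"node {exc.args[0]} not retained") from exc


@dataclass
class BinaryGraph:
    """Undirected binary graph from proportional thresholding.

    ``adjacency`` is a symmetric boolean matrix with zero diagonal over the
    same retained-node ordering as the source connectome; ``threshold_p`` is
    the retained edge proportion.
    """

    adjacency: np.ndarray
    nodes: np.ndarray
    threshold_p: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        self.nodes = np.asarray(self.nodes, dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


def subset_connectome(conn: Connectome, keep_ids: np.ndarray, **changes) -> Connectome:
    """Restrict a connectome to ``keep_ids`` (which must all be retained)."""
    keep_ids = np.sort(np.asarray(list(keep_ids), dtype=int))
    idx = conn.index_of(keep_ids)
    return replace(
        conn, z=conn.z[np.ix_(idx, idx)].copy(), nodes=keep_ids, **changes
    )
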