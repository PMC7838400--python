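"""Proportional thresholding and hemispheric restriction.

Connectomes are turned into undirected binary graphs by keeping the top
fraction ``p`` of the strongest (most positive) Fisher-z entries and
binarizing — the standard proportional-threshold construction for binary
functional-connectome analyses. Metrics are stabilized by averaging across a
set of proportions (default 10/20/25/30/40%).

Ranking is on signed z: the most positive entries are kept. Ties at the cut
are broken deterministically (larger z first, then lexicographically smaller
(i, j)), which makes edge sets nested across thresholds. The retained edge
count is round(p * n_pairs) with half-away-from-zero rounding, over the
*retained* node pairs only, so lesioned (smaller) matrices keep
proportionally fewer edges.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import BinaryGraph, Connectome, hemisphere_nodes, subset_connectome
from .errors import EmptyResultError, ParameterError

#: Edge-retention proportions used throughout unless overridden.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.10, 0.20, 0.25, 0.30, 0.40)


def _round_half_away(x: float) -> int:
    """round(x) with .5 going away from zero, independent of banker's rounding."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def ranked_pairs(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs of ``z`` ordered by (z desc, i asc, j asc)."""
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = z[iu, ju]
    # np.lexsort: last key is primary.
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


def proportional_threshold(conn: Connectome, p: float) -> BinaryGraph:
    """Binarize a connectome at edge-retention proportion ``p``.

    Keeps the ``round(p * n_pairs)`` most positive upper-triangle z entries
    as edges (ties broken by smaller (i, j)); all kept edges get weight 1.

    Raises
    ------
    ParameterError
        If ``p`` is outside (0, 1] or the connectome has fewer than 2 nodes.
    """
    if not (0.0 < p <= 1.0):
        raise ParameterError(f"threshold proportion must be in (0, 1], got {p}")
    n = conn.n_nodes
    if n < 2:
        raise ParameterError("connectome must retain at least 2 nodes")
    n_pairs = n * (n - 1) // 2
    n_keep = _round_half_away(p * n_pairs)
    iu, ju = ranked_pairs(conn.z)
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[:n_keep], ju[:n_keep]] = True
    adj |= adj.T
    return BinaryGraph(
        adjacency=adj,
        nodes=conn.nodes,
        threshold_p=p,
        provenance=f"{conn.group}:{conn.subject_id}",
    )


def hemisphere_subgraph(obj, node_table: pd.DataFrame, hemisphere: str):
    """Restrict a Connectome or BinaryGraph to one hemisphere's nodes.

    For hemispheric modularity, restrict the *connectome* first and threshold
    the restricted matrix (the default convention here); restricting an
    already-thresholded BinaryGraph is also supported for the alternative
    whole-brain-threshold convention.
    """
    hemi_ids = hemisphere_nodes(node_table, hemisphere)
    keep = np.intersect1d(hemi_ids, obj.nodes)
    if keep.size == 0:
        raise EmptyResultError(f"no retained nodes in hemisphere {hemisphere}")
    if isinstance(obj, Connectome):
        return subset_connectome(obj, keep)
    if isinstance(obj, BinaryGraph):
        pos = {nid: i for i, nid in enumerate(obj.nodes)}
        idx = np.array([pos[n] for n in keep], dtype=int)
        return BinaryGraph(
            adjacency=obj.adjacency[np.ix_(idx, idx)].copy(),
            nodes=keep,
            threshold_p=obj.threshold_p,
            provenance=obj.provenance,
        )
    raise ParameterError(f"unsupported object type {type(obj).__name__}")


def multi_threshold_metric(
    conn: Connectome,
    metric: Callable[[BinaryGraph], np.ndarray | float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
):
    """Average a graph metric across proportional thresholds.

    ``metric`` maps a BinaryGraph to a scalar (e.g. modularity) or a per-node
    vector (e.g. participation coefficients); per-node outputs are averaged
    nodewise. Returns the arithmetic mean across thresholds.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ParameterError("threshold set must be non-empty")
    values = [metric(proportional_threshold(conn, p)) for p in thresholds]
    if np.ndim(values[0]) == 0:
        return float(np.mean([float(v) for v in values]))
    return np.mean(np.stack([np.asarray(v, dtype=float) for v in values]), axis=0)
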