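"""Fixed-partition modularity, hub metrics, and hub identification.

The modular organisation is a *reference* partition fixed across subjects and
lesion conditions: it is derived once by agglomerative (Ward) clustering of
the group-average connectivity matrix and every graph — intact or lesioned —
is evaluated against it. There is no per-graph community detection; lesioned
nodes are simply absent from the graph being scored.

Metrics, for an undirected binary graph with L edges:

* Newman's modularity  Q = sum_s [ l_s / L  -  (d_s / 2L)^2 ]
  over modules s, with l_s the number of within-module-s edges and d_s the
  summed degree of module-s nodes.
* Participation coefficient  PC_i = 1 - sum_s (kappa_is / k_i)^2, the
  evenness of node i's edges across modules (kappa_is edges into module s,
  k_i total degree). High PC marks global (connector) hubs. PC_i = 0 for
  isolated nodes by convention.
* Within-module degree z-score  WD_i = (kappa_i - mu_m) / sigma_m, node i's
  within-module degree standardised over its module m. High WD marks local
  (provincial) hubs. WD_i = 0 when sigma_m = 0.

Hubs are the nodes whose group-template PC (global) or WD (local) lies
strictly more than one standard deviation above the template mean.
Population (divide-by-n) standard deviations are the default everywhere;
sample SD is available via ``ddof=1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as sp_distance

from .containers import BinaryGraph
from .errors import DegenerateInputError, ParameterError, UndefinedMetricError


@dataclass
class Partition:
    """A fixed assignment of every node in the full node space to a module.

    ``module_of`` maps node_id -> module label; labels are contiguous 1..M.
    Graphs over a retained subset are scored against the restriction of this
    mapping (lesioned nodes are simply absent).
    """

    module_of: Mapping[int, int]

    @property
    def n_modules(self) -> int:
        return len(set(self.module_of.values()))

    def labels_for(self, nodes: np.ndarray) -> np.ndarray:
        """Module labels aligned with ``nodes``; raises on unmapped nodes."""
        try:
            return np.array([self.module_of[int(n)] for n in nodes], dtype=int)
        except KeyError as exc:
            raise ParameterError(f"node {exc.args[0]} has no module label") from exc

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "Partition":
        return cls({i: int(m) for i, m in enumerate(labels)})


def reference_partition(
    avg_matrix: np.ndarray, k: int, distance: str = "correlation"
) -> Partition:
    """Ward-cluster the rows of a group-average z matrix into ``k`` modules.

    Each node's connectivity profile is its matrix row with the
    uninformative diagonal replaced by the row's maximum off-diagonal value.
    By default profiles are compared by correlation distance (1 - Pearson r
    between rows), which groups nodes by the *shape* of their connectivity
    and is insensitive to uniform offsets such as a hub's elevated baseline;
    ``distance="euclidean"`` compares raw profiles instead. Cluster labels
    are renumbered 1..k in order of first node appearance.
    """
    avg_matrix = np.asarray(avg_matrix, dtype=float)
    n = avg_matrix.shape[0]
    if avg_matrix.shape != (n, n):
        raise ParameterError("avg_matrix must be square")
    if not (1 <= k <= n):
        raise ParameterError(f"cluster count k={k} outside 1..{n}")
    if distance not in ("correlation", "euclidean"):
        raise ParameterError(f"distance must be correlation or euclidean, got {distance!r}")
    profiles = avg_matrix.copy()
    off = profiles + np.diag(np.full(n, -np.inf))
    np.fill_diagonal(profiles, off.max(axis=1))
    condensed = sp_distance.pdist(
        profiles, metric="correlation" if distance == "correlation" else "euclidean"
    )
    linkage = sch.linkage(condensed, method="ward")
    raw = sch.fcluster(linkage, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return Partition.from_labels(labels)


def _module_onehot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mods = np.unique(labels)
    onehot = (labels[:, None] == mods[None, :]).astype(float)
    return mods, onehot


def modularity_q(graph: BinaryGraph, partition: Partition) -> float:
    """Newman's Q of a binary graph against the fixed partition."""
    labels = partition.labels_for(graph.nodes)
    A = graph.adjacency.astype(float)
    L = A.sum() / 2.0
    if L == 0:
        raise UndefinedMetricError("modularity undefined for an edgeless graph")
    _, onehot = _module_onehot(labels)
    within = np.einsum("is,ij,js->s", onehot, A, onehot) / 2.0  # l_s
    d_s = A.sum(axis=1) @ onehot
    return float(np.sum(within / L - (d_s / (2.0 * L)) ** 2))


def participation_coefficients(graph: BinaryGraph, partition: Partition) -> np.ndarray:
    """Per-node participation coefficient; 0 for isolated nodes."""
    labels = partition.labels_for(graph.nodes)
    A = graph.adjacency.astype(float)
    _, onehot = _module_onehot(labels)
    kappa = A @ onehot  # edges from node i into each module
    k = A.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k[:, None] > 0, kappa / k[:, None], 0.0)
    pc = 1.0 - (frac**2).sum(axis=1)
    pc[k == 0] = 0.0
    return pc


def within_module_degree_z(
    graph: BinaryGraph, partition: Partition, ddof: int = 0
) -> np.ndarray:
    """Per-node within-module degree z-score; 0 where the module SD is 0."""
    labels = partition.labels_for(graph.nodes)
    A = graph.adjacency.astype(float)
    _, onehot = _module_onehot(labels)
    kappa_all = A @ onehot
    kappa = kappa_all[np.arange(len(labels)), np.searchsorted(np.unique(labels), labels)]
    wd = np.zeros(len(labels))
    for m in np.unique(labels):
        sel = labels == m
        mu = kappa[sel].mean()
        sigma = kappa[sel].std(ddof=ddof) if sel.sum() > ddof else 0.0
        if sigma > 0:
            wd[sel] = (kappa[sel] - mu) / sigma
    return wd


def identify_hubs(values: Mapping[int, float] | pd.Series, ddof: int = 0) -> set[int]:
    """Nodes whose score strictly exceeds mean + 1 SD of all finite scores."""
    series = pd.Series(dict(values)) if not isinstance(values, pd.Series) else values
    finite = series[np.isfinite(series.to_numpy(dtype=float))]
    if len(finite) < 2:
        raise DegenerateInputError("hub identification needs >= 2 finite values")
    arr = finite.to_numpy(dtype=float)
    cut = arr.mean() + arr.std(ddof=ddof)
    return {int(i) for i, v in finite.items() if v > cut}


@dataclass
class HubTemplate:
    """Group-average per-node PC and WD with the derived hub sets.

    ``pc_mean``/``wd_mean`` are indexed by node_id and averaged over the
    subjects in which the node was retained; ``n_contributing`` counts those
    subjects. Nodes retained in no subject are excluded entirely.
    """

    pc_mean: pd.Series
    wd_mean: pd.Series
    n_contributing: pd.Series
    global_hubs: set[int] = field(default_factory=set)
    local_hubs: set[int] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "pc_mean": self.pc_mean,
                "wd_mean": self.wd_mean,
                "n_contributing": self.n_contributing,
            }
        )
        df.index = df.index.rename("node_id")
        df["is_global_hub"] = df.index.isin(sorted(self.global_hubs))
        df["is_local_hub"] = df.index.isin(sorted(self.local_hubs))
        return df


def build_hub_template(
    per_subject_pc: Sequence[pd.Series],
    per_subject_wd: Sequence[pd.Series],
    ddof: int = 0,
) -> HubTemplate:
    """Average per-subject nodal PC/WD into a group template and call hubs.

    Each per-subject Series is indexed by that subject's retained node ids
    (subjects in lesioned cohorts cover different subsets). The template is
    the nodewise mean over the subjects retaining the node.
    """
    if len(per_subject_pc) == 0 or len(per_subject_pc) != len(per_subject_wd):
        raise ParameterError("need >= 1 subject with matching PC and WD series")
    pc_df = pd.DataFrame({i: s for i, s in enumerate(per_subject_pc)})
    wd_df = pd.DataFrame({i: s for i, s in enumerate(per_subject_wd)})
    n_contrib = pc_df.notna().sum(axis=1)
    keep = n_contrib[n_contrib >= 1].index
    pc_mean = pc_df.loc[keep].mean(axis=1, skipna=True).sort_index()
    wd_mean = wd_df.loc[keep].mean(axis=1, skipna=True).sort_index()
    template = HubTemplate(
        pc_mean=pc_mean,
        wd_mean=wd_mean,
        n_contributing=n_contrib.loc[pc_mean.index].astype(int),
    )
    template.global_hubs = identify_hubs(pc_mean, ddof=ddof)
    template.local_hubs = identify_hubs(wd_mean, ddof=ddof)
    return template
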