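"""Lesion masks, node subtraction, and hub-damage scores.

A lesion is represented either as a resolved set of lesioned node ids or as
a binary voxel grid with an affine (NIfTI-style). Voxel masks are resolved
to node sets by rasterizing a sphere around each node's coordinate and
calling the node *lesioned* when strictly more than ``frac_threshold`` of
its sphere voxels are damaged (default 25%).

Node subtraction removes the lesioned nodes' rows and columns from a
connectome — nothing else changes. Pseudo-lesion cohorts apply every mask to
every healthy-control connectome (n_masks x n_controls connectomes);
targeted lesions remove a chosen hub set instead of a patient's mask.

A mask's *damage scores* quantify how hard it hits the group's hubs: the
mean healthy-template PC (global-hub damage) and WD (local-hub damage) over
the mask's nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Connectome, subset_connectome
from .errors import (
    CoverageError,
    DegenerateInputError,
    InvalidNodeError,
    ParameterError,
)
from .metrics import HubTemplate

#: Default sphere radius (mm) for node ROIs when resolving voxel masks.
DEFAULT_SPHERE_RADIUS_MM = 5.0
#: Default lesioned-node rule: strictly more than this fraction of sphere
#: voxels damaged. Sensitivity values 0.10/0.20/0.30 are also supported.
DEFAULT_FRAC_THRESHOLD = 0.25


@dataclass
class LesionMask:
    """A lesion as a node-id set ("nodes" form) or voxel grid ("voxel" form)."""

    mask_id: str
    form: str  # "nodes" | "voxel"
    node_set: frozenset[int] | None = None
    grid: np.ndarray | None = None
    affine: np.ndarray | None = None
    resolved_nodes: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.form not in ("nodes", "voxel"):
            raise ParameterError(f"mask form must be 'nodes' or 'voxel', got {self.form!r}")
        if self.form == "nodes":
            if self.node_set is None:
                raise ParameterError("nodes-form mask requires node_set")
            self.node_set = frozenset(int(n) for n in self.node_set)
            self.resolved_nodes = self.node_set
        else:
            if self.grid is None or self.affine is None:
                raise ParameterError("voxel-form mask requires grid and affine")
            self.grid = np.asarray(self.grid)
            if not np.isin(self.grid, (0, 1)).all():
                raise ParameterError("voxel grid must be binary")


def sphere_voxel_indices(
    coord_mm: np.ndarray,
    grid_shape: tuple[int, int, int],
    affine: np.ndarray,
    radius_mm: float,
) -> np.ndarray:
    """Voxel indices whose *centers* lie within ``radius_mm`` of ``coord_mm``.

    Raises CoverageError if the sphere's bounding box extends past the grid
    or contains no voxel centers.
    """
    inv = np.linalg.inv(affine)
    center_vox = (inv @ np.append(coord_mm, 1.0))[:3]
    # conservative voxel-space bounding box of the sphere
    scale = np.abs(inv[:3, :3]).sum(axis=1)
    lo = np.floor(center_vox - radius_mm * scale).astype(int)
    hi = np.ceil(center_vox + radius_mm * scale).astype(int)
    if (lo < 0).any() or (hi >= np.asarray(grid_shape)).any():
        raise CoverageError(
            f"sphere at {np.round(coord_mm, 1).tolist()} not covered by grid {grid_shape}"
        )
    ranges = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = vox @ affine[:3, :3].T + affine[:3, 3]
    inside = np.linalg.norm(centers - coord_mm, axis=1) <= radius_mm
    if not inside.any():
        raise CoverageError(
            f"no voxel centers inside sphere at {np.round(coord_mm, 1).tolist()}"
        )
    return vox[inside]


def lesioned_nodes_from_voxel_mask(
    mask: LesionMask,
    node_table: pd.DataFrame,
    sphere_radius_mm: float = DEFAULT_SPHERE_RADIUS_MM,
    frac_threshold: float = DEFAULT_FRAC_THRESHOLD,
) -> frozenset[int]:
    """Resolve a voxel mask to node ids by the strict >frac_threshold rule.

    A node is lesioned iff (damaged sphere voxels / sphere voxels) is
    STRICTLY greater than ``frac_threshold``; a fraction exactly at the
    threshold does not lesion the node.
    """
    if mask.form != "voxel":
        raise ParameterError("mask is not in voxel form")
    if not (0.0 <= frac_threshold < 1.0):
        raise ParameterError(f"frac_threshold must be in [0, 1), got {frac_threshold}")
    grid = np.asarray(mask.grid)
    lesioned = set()
    for row in node_table.itertuples(index=False):
        vox = sphere_voxel_indices(
            np.array([row.x, row.y, row.z], dtype=float),
            grid.shape,
            mask.affine,
            sphere_radius_mm,
        )
        damaged = grid[vox[:, 0], vox[:, 1], vox[:, 2]].sum()
        if damaged / len(vox) > frac_threshold:
            lesioned.add(int(row.node_id))
    mask.resolved_nodes = frozenset(lesioned)
    return mask.resolved_nodes


def apply_lesion(conn: Connectome, node_set, group: str = "PSEUDO", mask_id=None) -> Connectome:
    """Remove ``node_set`` rows/columns from a connectome (node subtraction)."""
    node_set = {int(n) for n in node_set}
    unknown = node_set - set(conn.nodes.tolist())
    if unknown:
        raise InvalidNodeError(f"nodes not retained in connectome: {sorted(unknown)}")
    keep = np.array(sorted(set(conn.nodes.tolist()) - node_set), dtype=int)
    out = subset_connectome(conn, keep, group=group, mask_id=mask_id)
    return out


def targeted_lesion(conn: Connectome, hub_set) -> Connectome:
    """Remove a targeted hub set (simulated targeted attack)."""
    return apply_lesion(conn, hub_set, group="TARGETED")


def make_pseudo_cohort(
    hc_connectomes: list[Connectome], masks: list[LesionMask]
) -> list[Connectome]:
    """Apply every resolved mask to every control: n_masks x n_controls outputs.

    Ordered mask-major: all controls for mask 0, then mask 1, ...
    """
    cohort = []
    for mask in masks:
        if mask.resolved_nodes is None:
            raise ParameterError(f"mask {mask.mask_id} is not resolved to nodes")
        for conn in hc_connectomes:
            cohort.append(
                apply_lesion(conn, mask.resolved_nodes, group="PSEUDO", mask_id=mask.mask_id)
            )
    return cohort


@dataclass
class DamageScore:
    """Mean template PC/WD over a mask's lesioned nodes."""

    mask_id: str
    pc_damage: float
    wd_damage: float
    n_lesioned: int


def damage_scores(template: HubTemplate, node_set, mask_id: str = "") -> DamageScore:
    """Average the healthy-template PC and WD over the lesioned nodes."""
    nodes = sorted(int(n) for n in node_set)
    if not nodes:
        raise DegenerateInputError("damage score of an empty node set is undefined")
    missing = [n for n in nodes if n not in template.pc_mean.index]
    if missing:
        raise InvalidNodeError(f"nodes absent from template: {missing}")
    return DamageScore(
        mask_id=mask_id,
        pc_damage=float(template.pc_mean.loc[nodes].mean()),
        wd_damage=float(template.wd_mean.loc[nodes].mean()),
        n_lesioned=len(nodes),
    )
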