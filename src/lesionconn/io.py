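"""Reading and writing the pipeline's file formats.

Node tables, connectomes, binary graphs, partitions, hub templates and
damage tables travel as plain CSV; voxel lesion masks as binary NIfTI
images (via nibabel); run manifests as JSON. Connectome CSVs carry the
retained node ids as header row and index column, so lesioned (subset)
matrices round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import Connectome, validate_node_table
from .errors import ParameterError
from .lesioning import LesionMask
from .metrics import HubTemplate, Partition


def read_node_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_node_table(table)


def write_node_table(table: pd.DataFrame, path) -> None:
    validate_node_table(table).to_csv(path, index=False)


def write_connectome(conn: Connectome, path) -> None:
    df = pd.DataFrame(conn.z, index=conn.nodes, columns=conn.nodes)
    df.index.name = "node_id"
    df.to_csv(path)


def read_connectome(path, subject_id: str = "s0", group: str = "HC") -> Connectome:
    df = pd.read_csv(path, index_col=0)
    nodes = df.index.to_numpy(dtype=int)
    if not np.array_equal(nodes, df.columns.to_numpy(dtype=int)):
        raise ParameterError("connectome CSV rows and columns disagree")
    return Connectome(z=df.to_numpy(dtype=float), nodes=nodes,
                      subject_id=subject_id, group=group)


def read_timeseries(path) -> np.ndarray:
    """T x N time-series CSV with a header row of node ids."""
    return pd.read_csv(path).to_numpy(dtype=float)


def write_partition(partition: Partition, path) -> None:
    df = pd.DataFrame(
        sorted(partition.module_of.items()), columns=["node_id", "module"]
    )
    df.to_csv(path, index=False)


def read_partition(path) -> Partition:
    df = pd.read_csv(path)
    return Partition({int(r.node_id): int(r.module) for r in df.itertuples()})


def write_hub_template(template: HubTemplate, path) -> None:
    template.to_frame().to_csv(path)


def read_hub_template(path) -> HubTemplate:
    df = pd.read_csv(path, index_col="node_id")
    df.index.name = None

    def _col(name):
        return df[name].rename(None)

    return HubTemplate(
        pc_mean=_col("pc_mean"),
        wd_mean=_col("wd_mean"),
        n_contributing=_col("n_contributing").astype(int),
        global_hubs=set(df.index[df["is_global_hub"]].astype(int)),
        local_hubs=set(df.index[df["is_local_hub"]].astype(int)),
    )


def write_node_mask(mask: LesionMask, path) -> None:
    if mask.form != "nodes":
        raise ParameterError("write_node_mask expects a nodes-form mask")
    pd.DataFrame({"node_id": sorted(mask.node_set)}).to_csv(path, index=False)


def read_node_mask(path, mask_id: str | None = None) -> LesionMask:
    df = pd.read_csv(path)
    return LesionMask(
        mask_id=mask_id or Path(path).stem,
        form="nodes",
        node_set=frozenset(df["node_id"].astype(int)),
    )


def write_voxel_mask(mask: LesionMask, path) -> None:
    if mask.form != "voxel":
        raise ParameterError("write_voxel_mask expects a voxel-form mask")
    nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine), str(path))


def read_voxel_mask(path, mask_id: str | None = None) -> LesionMask:
    img = nib.load(str(path))
    grid = np.asarray(img.get_fdata() > 0.5, dtype=np.uint8)
    return LesionMask(
        mask_id=mask_id or Path(path).stem.replace(".nii", ""),
        form="voxel",
        grid=grid,
        affine=np.asarray(img.affine),
    )


def write_cohort(connectomes, outdir, manifest_extra: dict | None = None) -> None:
    """Per-subject connectome CSVs plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, conn in enumerate(connectomes):
        name = f"{conn.group.lower()}_{conn.subject_id}"
        if conn.mask_id:
            name += f"_{conn.mask_id}"
        fname = f"{name}.csv"
        write_connectome(conn, outdir / fname)
        entries.append(
            {
                "file": fname,
                "subject_id": conn.subject_id,
                "group": conn.group,
                "mask_id": conn.mask_id,
                "n_nodes": int(conn.n_nodes),
            }
        )
    manifest = {"connectomes": entries}
    manifest.update(manifest_extra or {})
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def write_edge_list(graph, path) -> None:
    """Binary graph as an edge list: one (i, j) node-id pair per row."""
    iu, ju = np.where(np.triu(graph.adjacency, 1))
    pd.DataFrame(
        {"i": graph.nodes[iu], "j": graph.nodes[ju]}
    ).to_csv(path, index=False)


def write_adjacency(graph, path) -> None:
    """Binary graph as a 0/1 adjacency CSV with node-id header row/column."""
    df = pd.DataFrame(
        graph.adjacency.astype(int), index=graph.nodes, columns=graph.nodes
    )
    df.index.name = "node_id"
    df.to_csv(path)
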