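"""Synthetic modular connectome cohorts, lesion masks, and re-organization.

This module generates everything the downstream analyses need at desk
scale, emulating the statistical structure of a healthy-control task-fMRI
cohort rather than any real anatomy:

* a bilateral node space (mirrored left/right coordinate pairs on a jittered
  millimetre grid, every module present in both hemispheres);
* per-subject Fisher-z connectomes from a block-modular model: within-module
  entries centred at arctanh(r_within), between-module at arctanh(r_between),
  plus a cohort-level pair heterogeneity field (fixed per cohort seed) and
  independent per-subject noise. Planted *global hubs* get an additive boost
  on their between-module rows; planted *local hubs* on their within-module
  rows;
* spatially contiguous left-hemisphere lesion masks grown breadth-first over
  a k-nearest-neighbour adjacency, emulating middle-cerebral-artery-territory
  strokes of varying hub overlap;
* voxel-grid renderings of node-set masks, for exercising the
  voxel-overlap lesioned-node rule;
* an explicit *re-organization* transform expressing the hypothesis that a
  real lesion's long-term effect is node subtraction *plus* systematic
  connectivity change among the remaining nodes.

The pair heterogeneity field (``pair_sd``) matters: with a clean two-level
block model the proportional threshold never cuts inside the within- or
between-module weight distribution, so fixed-partition modularity barely
responds to hub removal. Real connectome edge weights overlap heavily
across blocks; ``pair_sd`` reproduces that overlap and with it the
targeted-attack phenomenology.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import Connectome, validate_node_table
from .errors import ParameterError
from .lesioning import DamageScore, LesionMask, sphere_voxel_indices

# ---------------------------------------------------------------------------
# parameters


@dataclass
class CohortParams:
    """Generator settings for one healthy-control-like cohort.

    Defaults give a 60-node, 6-module, 10-subject cohort with 6 planted
    global and 6 planted local hubs — a desk-scale analogue of a
    235-node / 10-module / 10-control study.

    r_within / r_between are target mean correlations (applied as their
    arctanh in z space); hub_boost and pair_sd / noise_sd are additive in z
    space. pair_sd is the SD of a cohort-level heterogeneity field shared by
    all subjects (the cohort's "true" connectome); noise_sd is the SD of
    independent per-subject perturbations around it.
    """

    n_nodes: int = 60
    n_modules: int = 6
    r_within: float = 0.5
    r_between: float = 0.1
    n_global_hubs: int = 6
    n_local_hubs: int = 8
    hub_boost: float = 0.4
    hub_boost_local: float = 0.45
    pair_sd: float = 0.25
    pair_sd_within: float | None = None  # defaults to pair_sd
    noise_sd: float = 0.1
    n_subjects: int = 10
    seed: int = 0
    noise_seed: int | None = None  # separate stream for subject noise; None
    # draws it from `seed`, so two cohorts with the same `seed` but distinct
    # noise_seeds share one population structure (base matrix, hubs) while
    # their subjects differ

    def validate(self) -> "CohortParams":
        if not (0.0 <= self.r_between < self.r_within < 1.0):
            raise ParameterError("need 0 <= r_between < r_within < 1")
        if self.noise_sd < 0 or self.pair_sd < 0:
            raise ParameterError("noise_sd and pair_sd must be >= 0")
        if self.n_global_hubs + self.n_local_hubs > self.n_nodes:
            raise ParameterError("more planted hubs than nodes")
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        return self


@dataclass
class ReorgParams:
    """The post-lesion re-organization hypothesis, as an explicit transform.

    pc_coupling couples a mask's PC (global-hub) damage to the modularity of
    the re-organized connectome: negative values add inter-module
    connectivity in proportion to the damage (compensatory recruitment of
    new connector routes), which *lowers* modularity for hub-damaging masks.
    wd_coupling is the analogue for WD (local-hub) damage acting on
    within-module connectivity. pc_ref / wd_ref are the damage levels at
    which the compensation balances out (the pipeline supplies the
    cohort-mean damage; None falls back to 0, i.e. uncentered), so the
    coupling tilts the damage-modularity relationship without shifting the
    whole group's modularity. new_hub_count remaining nodes are promoted
    to hub-level connectivity (alternating local/global promotions, drawn
    once per parameter seed so the whole cohort re-organizes consistently),
    each landing on the right hemisphere with probability rh_bias. With all
    parameters zero the transform is the identity.
    """

    pc_coupling: float = 0.0
    wd_coupling: float = 0.0
    pc_ref: float | None = None
    wd_ref: float | None = None
    new_hub_count: int = 0
    rh_bias: float = 0.5
    promotion_boost: float = 0.5
    seed: int = 0

    def validate(self) -> "ReorgParams":
        if not (0.0 <= self.rh_bias <= 1.0):
            raise ParameterError("rh_bias must be in [0, 1]")
        if self.new_hub_count < 0:
            raise ParameterError("new_hub_count must be >= 0")
        return self


# ---------------------------------------------------------------------------
# node space


def generate_node_space(n_nodes: int, n_modules: int, seed: int = 0) -> pd.DataFrame:
    """Generate a bilateral node table with mirrored L/R coordinate pairs.

    Left-hemisphere nodes (ids 0..n/2-1) sit on a jittered 3-D grid with
    ~18 mm spacing in an MNI-like box (x < 0); right-hemisphere nodes
    (ids n/2..n-1) are their x-mirrors. Pair i and its mirror share a module;
    modules are contiguous runs of pairs, so every module is bilateral.
    """
    if n_nodes % 2 != 0 or n_nodes < 2 * n_modules:
        raise ParameterError(
            f"n_nodes must be even and >= 2*n_modules (got {n_nodes}, {n_modules})"
        )
    rng = np.random.default_rng(seed)
    n_half = n_nodes // 2
    spacing = 18.0
    # lattice big enough for n_half points, filled x-fastest then y then z
    per_axis = int(np.ceil(n_half ** (1 / 3)))
    pts = []
    for kz in range(per_axis + 1):
        for ky in range(per_axis + 1):
            for kx in range(per_axis + 1):
                pts.append((kx, ky, kz))
                if len(pts) >= n_half:
                    break
            if len(pts) >= n_half:
                break
        if len(pts) >= n_half:
            break
    lattice = np.array(pts[:n_half], dtype=float)
    coords = np.empty((n_half, 3))
    coords[:, 0] = -12.0 - spacing * lattice[:, 0]  # x strictly negative
    coords[:, 1] = -80.0 + spacing * lattice[:, 1]
    coords[:, 2] = -40.0 + spacing * lattice[:, 2]
    coords += rng.uniform(-2.0, 2.0, size=coords.shape)
    coords[:, 0] = np.minimum(coords[:, 0], -5.0)  # keep off the midline

    # modules interleave across the lattice: functional systems are
    # spatially distributed, so a contiguous lesion samples many systems
    # partially rather than consuming one whole module
    pair_module = 1 + (np.arange(n_half) % n_modules)
    left = pd.DataFrame(
        {
            "node_id": np.arange(n_half),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "module": pair_module,
            "hemisphere": "L",
        }
    )
    right = pd.DataFrame(
        {
            "node_id": np.arange(n_half, n_nodes),
            "x": -coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "module": pair_module,
            "hemisphere": "R",
        }
    )
    table = pd.concat([left, right], ignore_index=True)
    return validate_node_table(table)


# ---------------------------------------------------------------------------
# connectome cohorts


def _symmetric_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    noise = np.zeros((n, n))
    if sd > 0:
        iu, ju = np.triu_indices(n, k=1)
        vals = rng.normal(0.0, sd, size=len(iu))
        noise[iu, ju] = vals
        noise[ju, iu] = vals
    return noise


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth (planted structure).

    Behaves as a sequence of Connectomes; the planted hub sets and the
    noise-free cohort-mean matrix are kept for recovery checks.
    """

    connectomes: list[Connectome]
    node_table: pd.DataFrame
    params: CohortParams
    planted_global_hubs: frozenset[int]
    planted_local_hubs: frozenset[int]
    base_z: np.ndarray

    def __len__(self) -> int:
        return len(self.connectomes)

    def __iter__(self):
        return iter(self.connectomes)

    def __getitem__(self, i):
        return self.connectomes[i]


def plant_hub_nodes(
    node_table: pd.DataFrame, params: CohortParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Choose planted global- and local-hub node ids for a cohort.

    Hubs are planted as mirrored (homotopic) pairs so both hemispheres carry
    equal hub counts (an odd count keeps only the left member of its last
    pair). The two kinds are segregated into disjoint module halves and the
    local-hub pairs are placed as far as possible from the global-hub pairs:
    connector hubs concentrate in particular territory (as they do in real
    connectomes) and a contiguous lesion then cannot trivially confound PC
    with WD damage.
    """
    table = node_table.sort_values("node_id")
    labels = table["module"].to_numpy()
    n = len(table)
    n_half = n // 2
    pair_module = labels[:n_half]
    coords = table[["x", "y", "z"]].to_numpy()[:n_half]
    mods = rng.permutation(np.unique(labels))
    g_mods = set(mods[: max(1, len(mods) // 2)].tolist())
    pair_order = rng.permutation(n_half)

    def _expand(pairs: list[int], count: int) -> np.ndarray:
        chosen: list[int] = []
        for p in pairs:
            if len(chosen) >= count:
                break
            chosen.append(int(p))
            if len(chosen) < count:
                chosen.append(int(p) + n_half)
        return np.array(chosen[:count], dtype=int)

    def _round_robin(n_pairs: int, preferred_mods, used: set, key) -> list[int]:
        """One pair per module before any module gets a second (avoids
        crowding a module with hubs, which would dilute their WD z-scores)."""
        mod_cycle = list(preferred_mods) + [m for m in mods if m not in preferred_mods]
        picked: list[int] = []
        while len(picked) < n_pairs:
            progress = False
            for m in mod_cycle:
                if len(picked) >= n_pairs:
                    break
                cands = [p for p in pair_order if pair_module[p] == m and p not in used]
                if cands:
                    best = min(cands, key=key)
                    used.add(best)
                    picked.append(int(best))
                    progress = True
            if not progress:
                break
        return picked

    used: set = set()
    order_pos = {int(p): i for i, p in enumerate(pair_order)}
    g_pairs = _round_robin(
        (params.n_global_hubs + 1) // 2, sorted(g_mods), used, key=lambda p: order_pos[p]
    )
    ghubs = _expand(g_pairs, params.n_global_hubs)
    if params.n_local_hubs:
        gcoords = coords[g_pairs] if g_pairs else coords[:0]
        if len(gcoords):
            dist_to_g = np.linalg.norm(
                coords[:, None, :] - gcoords[None, :, :], axis=2
            ).min(axis=1)
        else:
            dist_to_g = np.zeros(n_half)
        l_mods = sorted(set(mods.tolist()) - g_mods) or sorted(g_mods)
        l_pairs = _round_robin(
            (params.n_local_hubs + 1) // 2, l_mods, used, key=lambda p: -dist_to_g[p]
        )
        lhubs = _expand(l_pairs, params.n_local_hubs)
    else:
        lhubs = np.array([], dtype=int)
    return ghubs, lhubs


def generate_connectome_cohort(
    node_table: pd.DataFrame, params: CohortParams, subject_prefix: str = "hc"
) -> SyntheticCohort:
    """Generate per-subject Fisher-z connectomes with planted modular/hub structure.

    The cohort-mean ("base") matrix is blocks + pair heterogeneity + hub
    boosts, drawn from ``params.seed``; each subject adds independent
    symmetric Gaussian noise (``noise_sd``). With ``noise_sd = 0`` all
    subjects are identical. Diagonals are zero and excluded downstream.
    """
    params = params.validate()
    table = validate_node_table(node_table)
    n = len(table)
    if n != params.n_nodes:
        params = replace(params, n_nodes=n)
    rng = np.random.default_rng(params.seed)
    labels = table.sort_values("node_id")["module"].to_numpy()
    same = labels[:, None] == labels[None, :]
    z_w = np.arctanh(params.r_within)
    z_b = np.arctanh(params.r_between)
    base = np.where(same, z_w, z_b).astype(float)
    # pair-level heterogeneity: stronger (within-system) connections vary
    # more across pairs than weak between-system ones
    sd_within = (
        params.pair_sd_within if params.pair_sd_within is not None else params.pair_sd
    )
    het = _symmetric_noise(rng, n, 1.0)
    base += het * np.where(same, sd_within, params.pair_sd)

    ghubs, lhubs = plant_hub_nodes(table, params, rng)
    boost = np.zeros((n, n))
    all_mods = np.unique(labels)
    for g in ghubs:
        # connector hubs bridge *particular* foreign systems, not all
        # equally: boosting only a subset keeps the hub's connectivity
        # profile module-shaped (a uniformly elevated row has no shape)
        foreign = all_mods[all_mods != labels[g]]
        targets = rng.choice(foreign, size=(len(foreign) + 1) // 2, replace=False)
        sel = np.isin(labels, targets)
        boost[g, sel] += params.hub_boost
    for l in lhubs:
        boost[l, same[l]] += params.hub_boost_local
    boost = np.maximum(boost, boost.T)  # symmetric; shared pairs take the max
    base += boost
    np.fill_diagonal(base, 0.0)

    noise_rng = (
        rng if params.noise_seed is None else np.random.default_rng(params.noise_seed)
    )
    connectomes = []
    for s in range(params.n_subjects):
        z = base + _symmetric_noise(noise_rng, n, params.noise_sd)
        np.fill_diagonal(z, 0.0)
        connectomes.append(
            Connectome(
                z=z,
                nodes=table["node_id"].to_numpy(),
                subject_id=f"{subject_prefix}{s:02d}",
                group="HC",
            )
        )
    return SyntheticCohort(
        connectomes=connectomes,
        node_table=table,
        params=params,
        planted_global_hubs=frozenset(int(g) for g in ghubs),
        planted_local_hubs=frozenset(int(l) for l in lhubs),
        base_z=base,
    )


# ---------------------------------------------------------------------------
# lesion masks


def _knn_adjacency(coords: np.ndarray, k: int) -> list[np.ndarray]:
    """Symmetrized k-nearest-neighbour lists (by Euclidean distance)."""
    n = len(coords)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    neigh = [set(np.argsort(d[i], kind="stable")[: min(k, n - 1)].tolist()) for i in range(n)]
    for i in range(n):
        for j in neigh[i]:
            neigh[j].add(i)
    return [np.array(sorted(s), dtype=int) for s in neigh]


def generate_lesion_masks(
    node_table: pd.DataFrame,
    n_masks: int = 25,
    size_min: int = 6,
    size_max: int = 12,
    seed: int = 0,
    k_neighbors: int = 6,
) -> list[LesionMask]:
    """Grow contiguous left-hemisphere masks of varying size and hub overlap.

    Each mask is a breadth-first region over the 6-nearest-neighbour
    adjacency of the left-hemisphere nodes, seeded at a random L node, with
    neighbour visits ordered by node id; sizes are uniform on
    [size_min, size_max].
    """
    table = validate_node_table(node_table)
    left = table[table["hemisphere"] == "L"].sort_values("node_id")
    left_ids = left["node_id"].to_numpy()
    if not (1 <= size_min <= size_max <= len(left_ids)):
        raise ParameterError(
            f"need 1 <= size_min <= size_max <= {len(left_ids)} left-hemisphere nodes"
        )
    coords = left[["x", "y", "z"]].to_numpy()
    neigh = _knn_adjacency(coords, k_neighbors)
    rng = np.random.default_rng(seed)
    # stratified seeding: cycle growth seeds over all L nodes (shuffled) so
    # the mask set tiles the hemisphere like a patient series tiles the MCA
    # territory, rather than oversampling a random corner
    seed_cycle = list(rng.permutation(len(left_ids)))
    while len(seed_cycle) < n_masks:
        seed_cycle += list(rng.permutation(len(left_ids)))
    masks = []
    for m in range(n_masks):
        size = int(rng.integers(size_min, size_max + 1))
        grown: list[int] | None = None
        for attempt in range(50):  # reseed if the component is too small
            start = seed_cycle[m] if attempt == 0 else int(rng.integers(len(left_ids)))
            seen = {start}
            queue = deque([start])
            order = []
            while queue and len(order) < size:
                cur = queue.popleft()
                order.append(cur)
                for nb in neigh[cur]:
                    if nb not in seen:
                        seen.add(int(nb))
                        queue.append(int(nb))
            if len(order) >= size:
                grown = order[:size]
                break
        if grown is None:
            raise ParameterError(
                f"could not grow a connected mask of size {size}; adjacency too sparse"
            )
        masks.append(
            LesionMask(
                mask_id=f"mask{m:02d}",
                form="nodes",
                node_set=frozenset(int(left_ids[i]) for i in grown),
            )
        )
    return masks


def generate_voxel_mask(
    node_table: pd.DataFrame,
    node_set,
    voxel_size_mm: float = 2.0,
    covered_fraction: float = 1.0,
    seed: int = 0,
    sphere_radius_mm: float = 5.0,
    pad_mm: float = 10.0,
) -> LesionMask:
    """Render a node-set lesion as a binary voxel grid with an affine.

    For each node in ``node_set``, round(covered_fraction * sphere voxels)
    of the voxels inside the node's sphere are set (chosen at random);
    voxels inside any *other* node's sphere are never touched, so downstream
    resolution sees other nodes' spheres clean.
    """
    if not (0.0 <= covered_fraction <= 1.0):
        raise ParameterError("covered_fraction must be in [0, 1]")
    table = validate_node_table(node_table)
    node_set = sorted(int(n) for n in node_set)
    unknown = set(node_set) - set(table["node_id"].tolist())
    if unknown:
        raise ParameterError(f"unknown nodes in node_set: {sorted(unknown)}")
    coords = table.sort_values("node_id")[["x", "y", "z"]].to_numpy()
    lo = coords.min(axis=0) - sphere_radius_mm - pad_mm
    hi = coords.max(axis=0) + sphere_radius_mm + pad_mm
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / voxel_size_mm)) + 1 for d in range(3))
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size_mm
    affine[:3, 3] = lo
    grid = np.zeros(shape, dtype=np.uint8)
    rng = np.random.default_rng(seed)
    all_spheres = {
        int(nid): sphere_voxel_indices(coords[nid], shape, affine, sphere_radius_mm)
        for nid in table["node_id"]
    }
    forbidden = set()
    for nid, vox in all_spheres.items():
        if nid not in node_set:
            forbidden.update(map(tuple, vox.tolist()))
    for nid in node_set:
        vox = all_spheres[nid]
        usable = np.array(
            [v for v in vox.tolist() if tuple(v) not in forbidden], dtype=int
        )
        n_target = int(round(covered_fraction * len(vox)))
        if n_target > len(usable):
            raise ParameterError(
                f"node {nid}: cannot cover {n_target} voxels, only {len(usable)} "
                "outside other nodes' spheres"
            )
        if n_target > 0:
            pick = usable[rng.permutation(len(usable))[:n_target]]
            grid[pick[:, 0], pick[:, 1], pick[:, 2]] = 1
    return LesionMask(mask_id="voxmask", form="voxel", grid=grid, affine=affine)


# ---------------------------------------------------------------------------
# re-organization


def _promotion_slots(
    node_table: pd.DataFrame, params: ReorgParams, n_slots: int
) -> list[tuple[int, str]]:
    """Deterministic ranked list of (node_id, kind) promotions for a cohort."""
    rng = np.random.default_rng(params.seed)
    by_hemi = {
        h: list(node_table.loc[node_table["hemisphere"] == h, "node_id"].to_numpy())
        for h in ("L", "R")
    }
    for h in by_hemi:
        rng.shuffle(by_hemi[h])
    slots: list[tuple[int, str]] = []
    kinds = ("local", "global")
    while len(slots) < n_slots and (by_hemi["L"] or by_hemi["R"]):
        want_r = rng.random() < params.rh_bias
        hemi = "R" if want_r else "L"
        if not by_hemi[hemi]:
            hemi = "L" if hemi == "R" else "R"
        node = int(by_hemi[hemi].pop())
        slots.append((node, kinds[len(slots) % 2]))
    return slots


def apply_reorganization(
    lesioned: Connectome,
    mask_damage: DamageScore,
    params: ReorgParams,
    node_table: pd.DataFrame,
) -> Connectome:
    """Add systematic post-lesion connectivity change to a subtracted connectome.

    Damage-coupled terms: every between-module entry gains
    ``-pc_coupling * pc_damage`` and every within-module entry gains
    ``-wd_coupling * wd_damage`` (z space), so with negative couplings a
    harder hub hit produces more compensatory connectivity and lower
    modularity. Hub promotions (see :class:`ReorgParams`) then boost whole
    rows of the promoted nodes. Identity when all parameters are zero.
    """
    params = params.validate()
    table = validate_node_table(node_table)
    module_of = dict(zip(table["node_id"], table["module"]))
    labels = np.array([module_of[int(n)] for n in lesioned.nodes])
    same = labels[:, None] == labels[None, :]
    z = lesioned.z.copy()
    off_diag = ~np.eye(len(z), dtype=bool)
    if params.pc_coupling != 0.0:
        excess = mask_damage.pc_damage - (params.pc_ref or 0.0)
        z[~same] += -params.pc_coupling * excess
    if params.wd_coupling != 0.0:
        excess = mask_damage.wd_damage - (params.wd_ref or 0.0)
        z[same & off_diag] += -params.wd_coupling * excess
    if params.new_hub_count:
        retained = set(lesioned.nodes.tolist())
        if params.new_hub_count > len(retained):
            raise ParameterError("new_hub_count exceeds remaining nodes")
        slots = _promotion_slots(table, params, n_slots=len(table))
        promoted = [(n, kind) for n, kind in slots if n in retained][: params.new_hub_count]
        pos = {int(n): i for i, n in enumerate(lesioned.nodes)}
        for node, kind in promoted:
            i = pos[node]
            row_sel = (same[i] if kind == "local" else ~same[i]) & off_diag[i]
            z[i, row_sel] += params.promotion_boost
            z[row_sel, i] += params.promotion_boost
    np.fill_diagonal(z, 0.0)
    return replace(lesioned, z=z, group="REAL")
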