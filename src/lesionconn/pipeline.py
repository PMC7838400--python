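"""End-to-end orchestration of the three lesion-connectome analyses.

Analysis 1 — *simulated targeted lesions*: remove the healthy template's
global hubs (or local hubs) from every healthy-control connectome and
compare modularity to intact via paired t-tests. Expected directions:
global-hub removal raises Q (modules lose their inter-module bridges and
segregate), local-hub removal lowers Q (modules internally degrade).

Analysis 2 — *pseudo- vs real-lesions*: apply each patient lesion mask to
every control (pseudo-lesion: pure node subtraction) and to the patient's
own connectome (real lesion, here emulated as subtraction plus an optional
re-organization transform). Correlate mask-level PC/WD damage scores with
modularity per group, test by mask-permutation, and compare the real
group's correlation to the bootstrap distribution of the pseudo group's
mean correlation. Right-hemisphere modularity is reported for the real
group only: left-hemisphere-only masks leave pseudo RH connectomes
identical to the healthy ones.

Analysis 3 — *hub topography*: identify global/local hubs per group at a
single threshold (default 25%) and compare the sets ("lost" and "new"
hubs), with a chi-square test of the right-hemisphere share.

All randomness flows from ``PipelineConfig.seed`` through named
``numpy`` child seeds, so a run is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import Connectome
from .errors import ParameterError
from .graphs import DEFAULT_THRESHOLDS, hemisphere_subgraph, multi_threshold_metric
from .inference import (
    bootstrap_compare,
    group_permutation_p,
    group_ttests,
    permutation_p,
    compare_hub_sets,
)
from .lesioning import (
    DamageScore,
    LesionMask,
    apply_lesion,
    damage_scores,
    make_pseudo_cohort,
    targeted_lesion,
)
from .metrics import (
    HubTemplate,
    Partition,
    build_hub_template,
    modularity_q,
    participation_coefficients,
    reference_partition,
    within_module_degree_z,
)
from .synth import (
    CohortParams,
    ReorgParams,
    SyntheticCohort,
    apply_reorganization,
    generate_connectome_cohort,
    generate_lesion_masks,
    generate_node_space,
)

log = logging.getLogger("lesionconn")


# ---------------------------------------------------------------------------
# configuration


#: Re-organization settings emulating a chronic-stroke cohort: compensatory
#: inter-module recruitment proportional to connector-hub damage (negative
#: pc_coupling) plus promotion of 12 spared nodes to hub-level connectivity,
#: 90% of them right-hemisphere.
STUDY_REORG = ReorgParams(
    pc_coupling=-2.0,
    wd_coupling=0.0,
    new_hub_count=12,
    rh_bias=0.9,
    promotion_boost=0.6,
)


@dataclass
class PipelineConfig:
    """All knobs for a synthetic end-to-end run (see module docstring)."""

    # cohort geometry / generative model
    n_nodes: int = 60
    n_modules: int = 6
    r_within: float = 0.5
    r_between: float = 0.1
    n_global_hubs: int = 6
    n_local_hubs: int = 8
    hub_boost: float = 0.4
    hub_boost_local: float = 0.45
    pair_sd: float = 0.25
    pair_sd_within: float | None = None
    noise_sd: float = 0.1
    n_controls: int = 10
    # lesions
    n_masks: int = 25
    mask_size_min: int = 6
    mask_size_max: int = 12
    # re-organization hypothesis (real group = subtraction + this transform)
    reorg: ReorgParams = field(
        default_factory=lambda: dataclasses.replace(STUDY_REORG)
    )
    # graph construction / hub calling
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    hub_threshold: float = 0.25  # single threshold for hub-topography analysis
    ddof: int = 0
    # inference
    n_perm: int = 10_000
    n_boot: int = 10_000
    side: str = "one_sided"
    # master seed; all child seeds derive from it
    seed: int = 0

    def child_seed(self, name: str) -> int:
        """Deterministic child seed below 2**31 derived from (seed, name)."""
        digest = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def cohort_params(self, n_subjects: int, name: str) -> CohortParams:
        return CohortParams(
            n_nodes=self.n_nodes,
            n_modules=self.n_modules,
            r_within=self.r_within,
            r_between=self.r_between,
            n_global_hubs=self.n_global_hubs,
            n_local_hubs=self.n_local_hubs,
            hub_boost=self.hub_boost,
            hub_boost_local=self.hub_boost_local,
            pair_sd=self.pair_sd,
            pair_sd_within=self.pair_sd_within,
            noise_sd=self.noise_sd,
            n_subjects=n_subjects,
            seed=self.child_seed(name),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "reorg" in d and isinstance(d["reorg"], dict):
            d["reorg"] = ReorgParams(**d["reorg"])
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-subject metric helpers


def subject_modularity(
    conn: Connectome,
    partition: Partition,
    thresholds=DEFAULT_THRESHOLDS,
) -> float:
    """Whole-connectome Q averaged across the threshold set."""
    return multi_threshold_metric(conn, lambda g: modularity_q(g, partition), thresholds)


def subject_hemispheric_modularity(
    conn: Connectome,
    partition: Partition,
    node_table: pd.DataFrame,
    hemisphere: str,
    thresholds=DEFAULT_THRESHOLDS,
) -> float:
    """Hemispheric Q: restrict to one hemisphere, then threshold at the same p."""
    sub = hemisphere_subgraph(conn, node_table, hemisphere)
    return multi_threshold_metric(sub, lambda g: modularity_q(g, partition), thresholds)


def subject_nodal_metrics(
    conn: Connectome,
    partition: Partition,
    thresholds=DEFAULT_THRESHOLDS,
    ddof: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """(PC, WD) per node averaged across thresholds, indexed by node id."""
    pc = multi_threshold_metric(
        conn, lambda g: participation_coefficients(g, partition), thresholds
    )
    wd = multi_threshold_metric(
        conn, lambda g: within_module_degree_z(g, partition, ddof=ddof), thresholds
    )
    return (
        pd.Series(pc, index=conn.nodes),
        pd.Series(wd, index=conn.nodes),
    )


def cohort_hub_template(
    connectomes,
    partition: Partition,
    thresholds=DEFAULT_THRESHOLDS,
    ddof: int = 0,
) -> HubTemplate:
    """Group hub template from a cohort's threshold-averaged nodal metrics."""
    pcs, wds = [], []
    for conn in connectomes:
        pc, wd = subject_nodal_metrics(conn, partition, thresholds, ddof=ddof)
        pcs.append(pc)
        wds.append(wd)
    return build_hub_template(pcs, wds, ddof=ddof)


def group_average_matrix(connectomes) -> np.ndarray:
    """Entrywise mean z matrix over a cohort sharing one node space."""
    return np.mean(np.stack([c.z for c in connectomes]), axis=0)


def make_real_cohort(
    patients: SyntheticCohort,
    masks: list[LesionMask],
    template: HubTemplate,
    reorg: ReorgParams,
    node_table: pd.DataFrame,
) -> tuple[list[Connectome], list[DamageScore]]:
    """Synthetic real-lesion group: one patient per mask, subtracted then re-organized."""
    if len(patients) != len(masks):
        raise ParameterError(
            f"need one patient connectome per mask ({len(patients)} vs {len(masks)})"
        )
    scores = [
        damage_scores(template, m.resolved_nodes, mask_id=m.mask_id) for m in masks
    ]
    # compensation is centered at the cohort-typical damage unless the
    # caller pinned the reference levels explicitly
    if reorg.pc_ref is None or reorg.wd_ref is None:
        reorg = dataclasses.replace(
            reorg,
            pc_ref=(
                reorg.pc_ref
                if reorg.pc_ref is not None
                else float(np.mean([d.pc_damage for d in scores]))
            ),
            wd_ref=(
                reorg.wd_ref
                if reorg.wd_ref is not None
                else float(np.mean([d.wd_damage for d in scores]))
            ),
        )
    cohort = []
    for conn, mask, dmg in zip(patients, masks, scores):
        lesioned = apply_lesion(conn, mask.resolved_nodes, group="REAL", mask_id=mask.mask_id)
        cohort.append(apply_reorganization(lesioned, dmg, reorg, node_table))
    return cohort, scores


# ---------------------------------------------------------------------------
# world construction


@dataclass
class SyntheticWorld:
    """Everything one end-to-end run operates on."""

    config: PipelineConfig
    node_table: pd.DataFrame
    hc: SyntheticCohort
    masks: list[LesionMask]
    partition: Partition
    template: HubTemplate
    damage: list[DamageScore]
    pseudo: list[Connectome]
    real: list[Connectome]


def build_world(config: PipelineConfig) -> SyntheticWorld:
    """Generate a full synthetic world from the config's master seed.

    The reference partition is Ward clustering of the healthy group-average
    matrix at the generative module count; the hub template averages PC/WD
    over the healthy cohort across the threshold set.
    """
    table = generate_node_space(
        config.n_nodes, config.n_modules, seed=config.child_seed("nodes")
    )
    hc = generate_connectome_cohort(
        table, config.cohort_params(config.n_controls, "hc"), subject_prefix="hc"
    )
    masks = generate_lesion_masks(
        table,
        n_masks=config.n_masks,
        size_min=config.mask_size_min,
        size_max=config.mask_size_max,
        seed=config.child_seed("masks"),
    )
    partition = reference_partition(group_average_matrix(hc), config.n_modules)
    template = cohort_hub_template(hc, partition, config.thresholds, ddof=config.ddof)
    # patients come from the same population as the controls (same base
    # matrix and planted hubs), with their own independent subject noise
    patient_params = dataclasses.replace(
        config.cohort_params(config.n_masks, "hc"),
        noise_seed=config.child_seed("patients-noise"),
    )
    patients = generate_connectome_cohort(table, patient_params, subject_prefix="pt")
    reorg = dataclasses.replace(config.reorg, seed=config.child_seed("reorg"))
    real, damage = make_real_cohort(patients, masks, template, reorg, table)
    pseudo = make_pseudo_cohort(list(hc), masks)
    log.info(
        "world: %d nodes, %d controls, %d masks, %d pseudo, %d real",
        len(table), len(hc), len(masks), len(pseudo), len(real),
    )
    return SyntheticWorld(
        config=config,
        node_table=table,
        hc=hc,
        masks=masks,
        partition=partition,
        template=template,
        damage=damage,
        pseudo=pseudo,
        real=real,
    )


# ---------------------------------------------------------------------------
# analyses


def run_analysis1(world: SyntheticWorld) -> dict:
    """Simulated targeted lesions of template hubs, vs intact modularity."""
    cfg = world.config
    if not world.template.global_hubs or not world.template.local_hubs:
        log.warning("empty hub set in template; targeted-lesion analysis skipped")
        return {"skipped": True, "reason": "empty hub set in template"}
    rows = []
    for conn in world.hc:
        q_intact = subject_modularity(conn, world.partition, cfg.thresholds)
        q_global = subject_modularity(
            targeted_lesion(conn, world.template.global_hubs), world.partition, cfg.thresholds
        )
        q_local = subject_modularity(
            targeted_lesion(conn, world.template.local_hubs), world.partition, cfg.thresholds
        )
        rows.append(
            {
                "subject_id": conn.subject_id,
                "q_intact": q_intact,
                "q_global_attack": q_global,
                "q_local_attack": q_local,
            }
        )
    table = pd.DataFrame(rows)
    ttests = group_ttests(
        {
            "global_attack": table["q_global_attack"].to_numpy(),
            "local_attack": table["q_local_attack"].to_numpy(),
            "intact": table["q_intact"].to_numpy(),
        },
        [("global_attack", "intact", "paired"), ("local_attack", "intact", "paired")],
        n_comparisons=2,
    )
    return {
        "skipped": False,
        "per_subject": table,
        "ttests": ttests,
        "delta_q_global": float((table["q_global_attack"] - table["q_intact"]).mean()),
        "delta_q_local": float((table["q_local_attack"] - table["q_intact"]).mean()),
    }


def _damage_vector(world: SyntheticWorld, measure: str) -> np.ndarray:
    attr = "pc_damage" if measure == "PC" else "wd_damage"
    return np.array([getattr(d, attr) for d in world.damage])


def modularity_tables(world: SyntheticWorld) -> dict:
    """Q per scope for all groups: HC and real vectors, pseudo mask x control matrices."""
    cfg = world.config
    tbl = world.node_table

    def q_whole(c):
        return subject_modularity(c, world.partition, cfg.thresholds)

    def q_hemi(c, h):
        return subject_hemispheric_modularity(c, world.partition, tbl, h, cfg.thresholds)

    n_m, n_c = len(world.masks), len(world.hc)
    pseudo_whole = np.array([q_whole(c) for c in world.pseudo]).reshape(n_m, n_c)
    pseudo_lh = np.array([q_hemi(c, "L") for c in world.pseudo]).reshape(n_m, n_c)
    return {
        "hc": {
            "whole": np.array([q_whole(c) for c in world.hc]),
            "LH": np.array([q_hemi(c, "L") for c in world.hc]),
            "RH": np.array([q_hemi(c, "R") for c in world.hc]),
        },
        "real": {
            "whole": np.array([q_whole(c) for c in world.real]),
            "LH": np.array([q_hemi(c, "L") for c in world.real]),
            "RH": np.array([q_hemi(c, "R") for c in world.real]),
        },
        # pseudo RH is identical to healthy RH (left-only masks): not analyzed
        "pseudo": {"whole": pseudo_whole, "LH": pseudo_lh},
    }


def run_analysis2(world: SyntheticWorld, q_tables: dict | None = None) -> dict:
    """Damage-modularity correlations, permutation and bootstrap inference."""
    cfg = world.config
    q_tables = q_tables or modularity_tables(world)
    rng = np.random.default_rng(cfg.child_seed("analysis2"))
    rows = []
    for scope in ("whole", "LH", "RH"):
        for measure in ("PC", "WD"):
            dmg = _damage_vector(world, measure)
            if scope in q_tables["pseudo"]:
                r_controls, mean_r, p_pseudo = group_permutation_p(
                    dmg, q_tables["pseudo"][scope], cfg.n_perm, cfg.side, rng
                )
            else:
                r_controls, mean_r, p_pseudo = None, np.nan, np.nan
            r_real, p_real = permutation_p(
                dmg, q_tables["real"][scope], cfg.n_perm, cfg.side, rng
            )
            p_boot = (
                bootstrap_compare(r_real, r_controls, cfg.n_boot, rng)
                if r_controls is not None
                else np.nan
            )
            rows.append(
                {
                    "scope": scope,
                    "measure": measure,
                    "pseudo_mean_r": mean_r,
                    "pseudo_p_perm": p_pseudo,
                    "pseudo_applicable": scope in q_tables["pseudo"],
                    "real_r": r_real,
                    "real_p_perm": p_real,
                    "bootstrap_p": p_boot,
                }
            )
    corr = pd.DataFrame(rows)
    ttests = group_ttests(
        {
            "HC": q_tables["hc"]["whole"],
            "PSEUDO": q_tables["pseudo"]["whole"].ravel(),
            "REAL": q_tables["real"]["whole"],
        },
        [
            ("HC", "PSEUDO", "independent"),
            ("HC", "REAL", "independent"),
            ("PSEUDO", "REAL", "independent"),
        ],
        n_comparisons=3,
    )
    dmg_table = pd.DataFrame(
        {
            "mask_id": [d.mask_id for d in world.damage],
            "pc_damage": _damage_vector(world, "PC"),
            "wd_damage": _damage_vector(world, "WD"),
            "n_lesioned": [d.n_lesioned for d in world.damage],
        }
    )
    return {"correlations": corr, "ttests": ttests, "damage": dmg_table, "q_tables": q_tables}


def run_analysis3(world: SyntheticWorld) -> dict:
    """Hub topography per group at the single hub threshold; lost/new hubs."""
    cfg = world.config
    thr = (cfg.hub_threshold,)
    templates = {
        "HC": cohort_hub_template(world.hc, world.partition, thr, ddof=cfg.ddof),
        "PSEUDO": cohort_hub_template(world.pseudo, world.partition, thr, ddof=cfg.ddof),
        "REAL": cohort_hub_template(world.real, world.partition, thr, ddof=cfg.ddof),
    }
    comparisons = {}
    for kind in ("global", "local"):
        sets = {g: getattr(t, f"{kind}_hubs") for g, t in templates.items()}
        comparisons[kind] = {
            "pseudo_vs_real": compare_hub_sets(sets["PSEUDO"], sets["REAL"], world.node_table),
            "hc_vs_real": compare_hub_sets(sets["HC"], sets["REAL"], world.node_table),
            "hc_vs_pseudo": compare_hub_sets(sets["HC"], sets["PSEUDO"], world.node_table),
            "counts": {g: len(s) for g, s in sets.items()},
        }
    return {"templates": templates, "comparisons": comparisons}


def run_all(config: PipelineConfig, outdir=None) -> dict:
    """Build the world, run all three analyses, optionally write outputs."""
    world = build_world(config)
    report = {
        "world": world,
        "analysis1": run_analysis1(world),
        "analysis2": run_analysis2(world),
        "analysis3": run_analysis3(world),
    }
    if outdir is not None:
        write_report(report, config, Path(outdir))
    return report


def write_report(report: dict, config: PipelineConfig, outdir: Path) -> None:
    """Write result tables as CSV and a reproducibility manifest as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world: SyntheticWorld = report["world"]
    world.node_table.to_csv(outdir / "node_table.csv", index=False)
    a1 = report["analysis1"]
    if not a1.get("skipped"):
        a1["per_subject"].to_csv(outdir / "analysis1_per_subject.csv", index=False)
        a1["ttests"].to_csv(outdir / "analysis1_ttests.csv", index=False)
    a2 = report["analysis2"]
    a2["correlations"].to_csv(outdir / "analysis2_correlations.csv", index=False)
    a2["ttests"].to_csv(outdir / "analysis2_ttests.csv", index=False)
    a2["damage"].to_csv(outdir / "analysis2_damage_scores.csv", index=False)
    a3 = report["analysis3"]
    for g, t in a3["templates"].items():
        t.to_frame().to_csv(outdir / f"analysis3_template_{g.lower()}.csv")
    summary = {
        kind: {
            name: {
                "lost": sorted(cmp.lost),
                "new": sorted(cmp.new),
                "shared": sorted(cmp.shared),
                "rh_fraction_B": cmp.rh_fraction_B,
                "chi2_B": cmp.chi2_B,
                "p_B": cmp.p_B,
            }
            for name, cmp in d.items()
            if name != "counts"
        }
        for kind, d in a3["comparisons"].items()
    }
    with open(outdir / "analysis3_hub_comparisons.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    import lesionconn

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": lesionconn.__version__,
        "numpy": np.__version__,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
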