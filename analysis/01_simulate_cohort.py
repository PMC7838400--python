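#!/usr/bin/env python
"""Generate the synthetic study inputs: node space, healthy cohort, lesion masks.

Writes the node table, per-subject healthy-control connectomes and the 25
left-hemisphere lesion masks under results/, and prints what was planted so
later steps can be judged against the ground truth.
"""

import argparse
from pathlib import Path

import pandas as pd

import lesionconn as lc
from lesionconn import io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = lc.PipelineConfig(seed=args.seed)
    table = lc.generate_node_space(cfg.n_nodes, cfg.n_modules, seed=cfg.child_seed("nodes"))
    cohort = lc.generate_connectome_cohort(table, cfg.cohort_params(cfg.n_controls, "hc"))
    masks = lc.generate_lesion_masks(
        table, cfg.n_masks, cfg.mask_size_min, cfg.mask_size_max, seed=cfg.child_seed("masks")
    )

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    io.write_node_table(table, out / "node_table.csv")
    io.write_cohort(cohort, out / "hc_cohort", {"seed": cfg.seed})
    masks_dir = out / "lesion_masks"
    masks_dir.mkdir(exist_ok=True)
    for m in masks:
        io.write_node_mask(m, masks_dir / f"{m.mask_id}.csv")

    sizes = [len(m.node_set) for m in masks]
    print(f"node space: {len(table)} nodes, {cfg.n_modules} bilateral modules")
    print(f"healthy cohort: {len(cohort)} subjects, noise_sd={cfg.noise_sd}")
    print(f"planted global hubs: {sorted(cohort.planted_global_hubs)}")
    print(f"planted local hubs:  {sorted(cohort.planted_local_hubs)}")
    print(f"lesion masks: {len(masks)}, sizes {min(sizes)}-{max(sizes)} (all left-hemisphere)")
    print(f"wrote inputs to {out}/")


if __name__ == "__main__":
    main()
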