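#!/usr/bin/env python
"""Pseudo- vs real-lesion damage-modularity relationships (analysis 2).

Applies each lesion mask to every control (pseudo-lesions: pure node
subtraction) and to the matching synthetic patient (real lesions:
subtraction plus compensatory re-organization), then correlates PC/WD
damage scores with modularity per group, with mask-permutation and
bootstrap inference.
"""

import argparse
from pathlib import Path

import lesionconn as lc


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = lc.PipelineConfig(seed=args.seed)
    world = lc.build_world(cfg)
    rep = lc.run_analysis2(world)

    args.outdir.mkdir(parents=True, exist_ok=True)
    rep["correlations"].to_csv(args.outdir / "analysis2_correlations.csv", index=False)
    rep["ttests"].to_csv(args.outdir / "analysis2_ttests.csv", index=False)
    rep["damage"].to_csv(args.outdir / "analysis2_damage_scores.csv", index=False)

    corr = rep["correlations"].set_index(["scope", "measure"])
    pc = corr.loc[("whole", "PC")]
    wd = corr.loc[("whole", "WD")]
    print("whole-brain damage-modularity correlations over 25 masks:")
    print(f"  pseudo PC: mean r = {pc.pseudo_mean_r:+.2f} (perm p = {pc.pseudo_p_perm:.4f})")
    print(f"  pseudo WD: mean r = {wd.pseudo_mean_r:+.2f} (perm p = {wd.pseudo_p_perm:.4f})")
    print(f"  real   PC: r = {pc.real_r:+.2f} (perm p = {pc.real_p_perm:.4f}); "
          f"real-vs-pseudo bootstrap p = {pc.bootstrap_p:.4f}")
    if pc.pseudo_mean_r > 0 > pc.real_r:
        print("  -> subtraction predicts the pseudo group; the re-organized real "
              "group flips the PC relationship, as expected under compensatory "
              "inter-module recruitment")
    print(rep["ttests"].to_string(index=False))


if __name__ == "__main__":
    main()
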