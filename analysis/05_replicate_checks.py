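#!/usr/bin/env python
"""Replicate-level statistical checks of the whole pipeline.

Two small Monte-Carlo suites (reduced replicate counts; the acceptance
script runs the full versions): null cohorts verify that post-FDR rejection
rates stay at the nominal level, and effect cohorts verify that the
left-hemisphere lesion is recovered with the right direction and spatial
specificity.
"""

import argparse

import pandas as pd

from common import outdir
from semiconn.pipeline import compare_cohort, run_cohort
from semiconn.synthetic import SyntheticConfig, generate_cohort, generate_volumes


def replicate(cfg, with_volumes=True):
    subjects, manifest = generate_cohort(cfg)
    vols = generate_volumes(cfg) if with_volumes else None
    return compare_cohort(run_cohort(subjects, manifest, subject_volumes=vols))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--null-reps", type=int, default=10)
    ap.add_argument("--effect-reps", type=int, default=8)
    ap.add_argument("--seed", type=int, default=2026)
    args = ap.parse_args()

    rows = []
    for rep in range(args.null_reps):
        cfg = SyntheticConfig(n_per_group=45, n_nodes=40,
                              effect_attenuation=1.0, seed=args.seed * 100 + rep)
        fams = replicate(cfg)
        for fid, df in fams.items():
            rows.append({"suite": "null", "rep": rep, "family": fid,
                         "n": len(df), "rejected": int(df["significant"].sum())})
    null_df = pd.DataFrame(rows)
    rates = (null_df.groupby("family")[["rejected", "n"]].sum()
             .assign(rate=lambda d: d.rejected / d.n).round(4))

    hits = dict(left=0, bai=0, right_ns=0, inter_ns=0)
    for rep in range(args.effect_reps):
        cfg = SyntheticConfig(n_per_group=45, n_nodes=90, seed=args.seed * 200 + rep)
        t = replicate(cfg, with_volumes=False)["smr_scales"].set_index("label")
        hits["left"] += bool(t.loc["smr_left", "significant"]
                             and t.loc["smr_left", "direction"] == "high>low")
        hits["bai"] += bool(t.loc["bai", "significant"]
                            and t.loc["bai", "direction"] == "high>low")
        hits["right_ns"] += not t.loc["smr_right", "significant"]
        hits["inter_ns"] += not t.loc["smr_inter", "significant"]
    recovery = pd.Series(hits, name="count").to_frame()
    recovery["rate"] = recovery["count"] / args.effect_reps

    out = outdir()
    rates.to_csv(out / "null_rejection_rates.csv")
    recovery.to_csv(out / "effect_recovery_rates.csv")
    print(f"null rejection rates over {args.null_reps} replicates "
          f"(nominal alpha 0.05):")
    print(rates.to_string())
    print(f"\neffect recovery over {args.effect_reps} replicates:")
    print(recovery.to_string())
    print(f"\ntables written to {out}")


if __name__ == "__main__":
    main()
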