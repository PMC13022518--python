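#!/usr/bin/env python
"""Behavioral statistics: accuracy, stay/switch, latency, ANOVA, regressions.

Summarizes performance per subject x condition, runs the 2 (context) x 2
(valence) within-subject ANOVA on accuracy with Bonferroni-corrected paired
contrasts, the learning-rate x inverse-temperature composite, and the
accuracy-on-parameters regressions when a fit table is available.
"""

import argparse
from pathlib import Path

import pandas as pd

from contextrl.behavior import accuracy_on_params_regression, \
    composite_index, condition_wide, glme_export, paired_contrast, \
    rm_anova_2x2, summarize_conditions
from contextrl.io import read_dataset, write_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--fits", type=Path, default=Path("results/fits_mle.csv"))
    ap.add_argument("--one-tailed", action="store_true",
                    help="one-tailed replication-style contrasts")
    ap.add_argument("--export-glme", action="store_true")
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    dataset = read_dataset(args.cohort)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    summary = summarize_conditions(dataset)
    write_table(summary, args.out_dir / "behavior_summary.csv")

    wide = condition_wide(summary, "accuracy")
    res = rm_anova_2x2(wide)
    write_table(res.as_frame(), args.out_dir / "anova_accuracy.csv")
    print("2x2 within-subject ANOVA on accuracy:")
    print(res.as_frame()[["name", "F", "df1", "df2", "p", "eta_sq"]]
          .round(4).to_string(index=False))

    contrasts = [
        ("reward mixed > reward only", "reward_mixed", "reward_only"),
        ("punishment mixed > punishment only", "punishment_mixed", "punishment_only"),
        ("reward mixed > punishment mixed", "reward_mixed", "punishment_mixed"),
        ("reward only > punishment only", "reward_only", "punishment_only"),
    ]
    rows = []
    for name, a, b in contrasts:
        c = paired_contrast(wide[a], wide[b], name, m=len(contrasts),
                            one_tailed=args.one_tailed)
        rows.append(vars(c))
    ct = pd.DataFrame(rows)
    write_table(ct, args.out_dir / "paired_contrasts.csv")
    print("paired contrasts (Bonferroni family of %d):" % len(contrasts))
    print(ct.round(4).to_string(index=False))

    if args.fits.exists():
        fits = composite_index(pd.read_csv(args.fits))
        write_table(fits, args.out_dir / "fits_with_composite.csv")
        for cond in ("reward_mixed", "reward_only"):
            acc = (summary[summary.condition == cond]
                   .set_index("subject")["accuracy"])
            reg = accuracy_on_params_regression(acc, fits, cond)
            write_table(reg, args.out_dir / f"regression_{cond}.csv")
            print(f"accuracy ~ parameters ({cond}):")
            print(reg.round(4).to_string(index=False))

    if args.export_glme:
        write_table(glme_export(dataset), args.out_dir / "glme_trials.csv")
        print("wrote long-format per-trial table for mixed-model software")


if __name__ == "__main__":
    main()
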