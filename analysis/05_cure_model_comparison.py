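#!/usr/bin/env python
"""Mixture-cure Cox analysis on the 20-cell cure grid, vs. the traditional fits.

Runs the full cure grid (logistic + Cox + EM mixture-cure on every
replicate) at a scaled-down replication count and writes the summary and
long-format curve tables.  Things to look for in the output: the cure
model's OR and HR tests hold their level under the null, and without
background heritability the cure-model medians track the simulated OR/HR
while the traditional estimates are biased.
"""

import argparse
from pathlib import Path

from curegwas import run_grid, summarize_curves

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--reps", type=int, default=50)
    parser.add_argument("--bootstrap", type=int, default=20)
    parser.add_argument("--seed", type=int, default=3)
    parser.add_argument("--workers", type=int, default=1)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)

    table = run_grid("cure", n_reps=args.reps, alpha=0.1, seed=args.seed,
                     parallel_workers=args.workers, bootstrap_reps=args.bootstrap)
    path = OUT / "cure_grid.tsv"
    table.to_csv(path, sep="\t", index=False)
    for quantity in ("rejection", "median_or", "median_hr"):
        curves = summarize_curves(table, quantity)
        curves.to_csv(OUT / f"cure_grid_{quantity}.tsv", sep="\t", index=False)
    print(f"wrote {len(table)} cells -> {path} (+ curve tables)\n")

    effect = table[(table.h2_snp_logistic == 0.01) & (table.h2_bg_logistic == 0.0)]
    print("1% effects, no background (cure fraction, medians vs truth):")
    for _, row in effect.iterrows():
        print(
            f"  cure={row['cure_fraction']:.1f}: "
            f"cure-model OR {row['cure_or_median']:.3f} / logistic {row['logistic_median']:.3f} "
            f"(true {row['true_or']:.3f}); "
            f"cure-model HR {row['cure_hr_median']:.3f} / Cox {row['cox_median']:.3f} "
            f"(true {row['true_hr']:.3f})"
        )

    null = table[(table.h2_snp_logistic == 0.0) & (table.h2_bg_logistic == 0.0)]
    print("\nnull cells, no background (type-1 error at alpha=0.1):")
    for _, row in null.iterrows():
        print(f"  cure={row['cure_fraction']:.1f}: cure-model OR test "
              f"{row['cure_or_rejection']:.2f}, HR test {row['cure_hr_rejection']:.2f}")


if __name__ == "__main__":
    main()
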