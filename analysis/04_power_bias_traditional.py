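#!/usr/bin/env python
"""Power and bias of logistic vs. Cox analysis on mixture-cure data.

For the three kinds of genetic variant (risk-only, onset-only, both at 1%
SNP heritability), with and without 50% background heritability, this runs
the traditional analyses across cure fractions and writes rejection rates
and median OR/HR estimates.  The headline patterns: Cox has power against
risk-only effects it should be blind to, the logistic OR is underestimated
everywhere, and the Cox HR is overestimated when a risk effect coexists.
"""

import argparse
from pathlib import Path

import pandas as pd

from curegwas import SimDesign, run_cell

OUT = Path(__file__).resolve().parent.parent / "results"

VARIANT_KINDS = {
    "risk_only": dict(h2_snp_logistic=0.01, h2_snp_survival=0.0),
    "onset_only": dict(h2_snp_logistic=0.0, h2_snp_survival=0.01),
    "both": dict(h2_snp_logistic=0.01, h2_snp_survival=0.01),
}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--reps", type=int, default=300)
    parser.add_argument("--seed", type=int, default=2)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)

    rows = []
    for kind, h2 in VARIANT_KINDS.items():
        for h2_bg in (0.0, 0.5):
            for cure in [round(0.1 * i, 1) for i in range(1, 10)]:
                design = SimDesign(
                    cure_fraction=cure,
                    h2_bg_logistic=h2_bg,
                    h2_bg_survival=h2_bg,
                    **h2,
                )
                row = run_cell(design, analyses=("logistic", "cox"),
                               n_reps=args.reps, alpha=0.1, seed=args.seed)
                row["variant_kind"] = kind
                rows.append(row)
    table = pd.DataFrame(rows)
    path = OUT / "power_bias_traditional.tsv"
    table.to_csv(path, sep="\t", index=False)
    print(f"wrote {len(table)} cells -> {path}\n")

    risk = table[(table.variant_kind == "risk_only") & (table.h2_bg_logistic == 0)]
    mid = risk[risk.cure_fraction == 0.5].iloc[0]
    print("risk-only variant, cure fraction 0.5, no background:")
    print(f"  Cox rejection rate {mid['cox_rejection']:.2f} despite no onset effect "
          f"(logistic: {mid['logistic_rejection']:.2f})")
    print(f"  median logistic OR {mid['logistic_median']:.3f} vs simulated "
          f"{mid['true_or']:.3f} — underestimated")

    both = table[(table.variant_kind == "both") & (table.h2_bg_logistic == 0)]
    mid = both[both.cure_fraction == 0.5].iloc[0]
    print("both effects, cure fraction 0.5, no background:")
    print(f"  median Cox HR {mid['cox_median']:.3f} vs simulated {mid['true_hr']:.3f} "
          f"— overestimated by the risk effect leaking in")


if __name__ == "__main__":
    main()
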