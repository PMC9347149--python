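#!/usr/bin/env python
"""Frequency-estimation bias from threshold truncation.

Simulates 1,000 binomial read draws at depth 100 for each true mutant-allele
frequency on a grid, and compares the mean estimated frequency from all
draws against the mean from only the draws whose observed proportion reaches
tau = 0.05.  The truncated estimate can never fall below tau and is sharply
inflated for low true frequencies.

Writes results/truncation_bias.tsv.
"""

from pathlib import Path

import numpy as np

from tmbbias.experiments import run_truncation_bias

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    report = run_truncation_bias(
        f_grid=np.round(np.arange(0.01, 0.51, 0.01), 10),
        size=100,
        tau=0.05,
        n_reps=1000,
        seed=1,
    )
    OUT.mkdir(exist_ok=True)
    report.table.to_csv(OUT / "truncation_bias.tsv", sep="\t", index=False)

    table = report.table.set_index("f")
    print("Truncation bias of the estimated mutant-allele frequency")
    print(f"  depth 100, tau 0.05, retention count >= 5, 1000 reps per f\n")
    for f in (0.01, 0.02, 0.05, 0.1, 0.3):
        row = table.loc[f]
        print(
            f"  f={f:5.2f}: untruncated mean {row['mean_untruncated']:.4f}, "
            f"truncated mean {row['mean_truncated']:.4f} "
            f"(n_retained={int(row['n_retained'])})"
        )
    print(
        f"\n  Largest upward bias of the truncated estimate: "
        f"{report.summary['max_bias_truncated']:.4f}"
    )
    print(f"  Wrote {OUT / 'truncation_bias.tsv'}")


if __name__ == "__main__":
    main()
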